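"""Ordination contributions and the iterative rank-enrichment test.

The question: do SNPs that change the encoded amino acid (kN) drive the
genetic structure among localities, or is that structure carried by
synonymous (kS) and untranslated-region (oCDS) variants?  SNP
contributions to PCA axes / DAPC discriminant functions are ranked in
descending order, and a one-tailed Wilcoxon rank-sum test is applied to
successively deeper rank prefixes (top-10, top-11, ... top-200),
asking at each depth whether the kN SNPs sit nearer the top than the
kS/oCDS SNPs.  Per-iteration p-values are reported without
multiple-testing correction across iterations (as in the procedure this
mirrors); the series must be read per iteration, never as a single
summary p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .association import impute_genotypes
from .types import GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# locality frequency matrix + PCA
# ---------------------------------------------------------------------

def locality_freqs(gm: GenotypeMatrix, pops: np.ndarray) -> pd.DataFrame:
    """Alternate-allele frequency per locality per locus.

    Cells with no non-missing calls are NaN (mean-imputed by the
    ordinations, with a log message).
    """
    pops = np.asarray(pops)
    labels = list(pd.unique(pops))
    if any((pops == l).sum() == 0 for l in labels):
        raise ValueError("empty locality")
    called = gm.called()
    geno = np.where(called, gm.genotypes, 0)
    rows = []
    for l in labels:
        sel = pops == l
        copies = 2.0 * called[sel].sum(axis=0)
        alt = geno[sel].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows.append(np.where(copies > 0, alt / np.maximum(copies, 1), np.nan))
    return pd.DataFrame(rows, index=[str(l) for l in labels], columns=gm.locus_ids)


@dataclass
class OrdinationContributions:
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    contributions: pd.DataFrame  # loci x axes, percent, sums to 100/axis
    scores: np.ndarray | None = None
    n_pca: int | None = None
    a_score_curve: pd.Series | None = None
    bic_curve: pd.Series | None = None


def pca_contributions(
    freq: pd.DataFrame, center: bool = True, scale: bool = False
) -> OrdinationContributions:
    """PCA of a locality x locus frequency matrix with per-SNP
    contributions.

    The contribution of SNP ``j`` to axis ``k`` is ``100 * v_jk^2``
    where ``v_k`` is the unit eigenvector of the column covariance;
    contributions therefore sum to 100 per axis.  NaN cells are
    replaced by column means before decomposition.
    """
    X = freq.to_numpy(dtype=float).copy()
    if np.isnan(X).any():
        log.info("mean-imputing %d missing frequency cells", int(np.isnan(X).sum()))
        means = np.nanmean(X, axis=0)
        X[np.isnan(X)] = np.broadcast_to(means, X.shape)[np.isnan(X)]
    cols = freq.columns
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            log.warning("dropping %d constant columns under scaling", int((~keep).sum()))
            X, cols = X[:, keep], cols[keep]
            sd = sd[keep]
        X = X / sd
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    k = max(int((s > (s[0] if len(s) else 0) * 1e-12).sum()), 1) if len(s) else 0
    eig = eig[:k]
    contrib = 100.0 * (Vt[:k] ** 2)
    axes = [f"PC{i + 1}" for i in range(k)]
    contributions = pd.DataFrame(contrib.T, index=cols, columns=axes)
    # re-attach dropped constant columns as zero contribution
    if len(cols) != len(freq.columns):
        contributions = contributions.reindex(freq.columns, fill_value=0.0)
    total = eig.sum()
    return OrdinationContributions(
        eigenvalues=eig,
        variance_pct=100.0 * eig / total if total > 0 else np.zeros_like(eig),
        contributions=contributions,
        scores=U[:, :k] * s[:k],
    )


# ---------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------

def _pca_reduce(X: np.ndarray, n_pca: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and loadings (columns are unit axes)."""
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pca = min(n_pca, len(s))
    return U[:, :n_pca] * s[:n_pca], Vt[:n_pca].T


def _lda_directions(
    T: np.ndarray, labels: np.ndarray, ridge: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized eigenvectors of between/within scatter on scores T."""
    classes = pd.unique(labels)
    mu = T.mean(axis=0)
    d = T.shape[1]
    B = np.zeros((d, d))
    W = np.zeros((d, d))
    for cl in classes:
        Tc = T[labels == cl]
        mc = Tc.mean(axis=0)
        B += len(Tc) * np.outer(mc - mu, mc - mu)
        W += (Tc - mc).T @ (Tc - mc)
    W = W + ridge * np.trace(W) / d * np.eye(d) if np.linalg.matrix_rank(W) < d else W
    try:
        evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    except np.linalg.LinAlgError:
        W = W + 1e-6 * np.eye(d)
        log.warning("singular within-class scatter; ridge added")
        evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    evals = np.real(evals)
    evecs = np.real(evecs)
    order = np.argsort(evals)[::-1]
    n_func = min(len(classes) - 1, d)
    w = evecs[:, order[:n_func]]
    w = w / np.linalg.norm(w, axis=0)
    # eigenvalue reported as between/within variance ratio per function
    lam = np.array([
        (w[:, f] @ B @ w[:, f]) / max(w[:, f] @ W @ w[:, f], 1e-300)
        for f in range(n_func)
    ])
    return lam, w


def dapc_fit(
    gm_or_matrix: GenotypeMatrix | pd.DataFrame,
    clusters: np.ndarray,
    n_pca: int,
) -> OrdinationContributions:
    """Discriminant analysis of principal components.

    Step 1: PCA of the centered (imputed) data keeping ``n_pca`` axes.
    Step 2: linear discriminant analysis of the retained PC scores on
    the cluster labels.  The discriminant eigenvalue is the
    between/within variance ratio on each function; SNP contributions
    are ``100 * b_jf^2 / sum_j b_jf^2`` with ``b_f`` the discriminant
    axis mapped back to SNP space through the PCA loadings.
    """
    if isinstance(gm_or_matrix, GenotypeMatrix):
        X = impute_genotypes(gm_or_matrix)
        cols = pd.Index(gm_or_matrix.locus_ids)
    else:
        X = gm_or_matrix.to_numpy(dtype=float).copy()
        if np.isnan(X).any():
            means = np.nanmean(X, axis=0)
            X[np.isnan(X)] = np.broadcast_to(means, X.shape)[np.isnan(X)]
        cols = gm_or_matrix.columns
    clusters = np.asarray(clusters)
    if n_pca < 1:
        raise ValueError("n_pca must be >= 1")
    if n_pca >= X.shape[0]:
        raise ValueError("n_pca must be below the number of samples")
    if len(pd.unique(clusters)) < 2:
        raise ValueError("need at least 2 clusters")
    T, P = _pca_reduce(X, n_pca)
    lam, w = _lda_directions(T, clusters)
    b = P @ w  # loci x functions
    denom = (b**2).sum(axis=0)
    contrib = 100.0 * b**2 / np.where(denom > 0, denom, 1.0)
    axes = [f"LD{i + 1}" for i in range(b.shape[1])]
    return OrdinationContributions(
        eigenvalues=lam,
        variance_pct=100.0 * lam / lam.sum() if lam.sum() > 0 else np.zeros_like(lam),
        contributions=pd.DataFrame(contrib, index=cols, columns=axes),
        scores=T @ w,
        n_pca=T.shape[1],
    )


def _reassignment_proportion(
    X: np.ndarray, clusters: np.ndarray, n_pca: int
) -> float:
    """Mean per-cluster proportion of individuals reassigned to their own
    cluster by nearest-centroid classification in discriminant space."""
    T, _P = _pca_reduce(X, n_pca)
    lam, w = _lda_directions(T, clusters)
    S = T @ w
    classes = pd.unique(clusters)
    centroids = np.stack([S[clusters == cl].mean(axis=0) for cl in classes])
    d = ((S[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = np.asarray(classes)[np.argmin(d, axis=1)]
    props = [np.mean(assigned[clusters == cl] == cl) for cl in classes]
    return float(np.mean(props))


def optimize_a_score(
    gm_or_matrix: GenotypeMatrix | pd.DataFrame,
    clusters: np.ndarray,
    n_pca_grid: list[int],
    n_sim: int = 10,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Pick the PC count maximizing the a-score.

    a-score(n) = observed reassignment proportion − mean reassignment
    proportion over ``n_sim`` random relabelings (ties take the
    smallest n).  Returns (optimal n_pca, a-score curve).
    """
    if isinstance(gm_or_matrix, GenotypeMatrix):
        X = impute_genotypes(gm_or_matrix)
    else:
        X = gm_or_matrix.to_numpy(dtype=float)
    clusters = np.asarray(clusters)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(clusters) for _ in range(n_sim)]
    scores = {}
    for n_pca in n_pca_grid:
        obs = _reassignment_proportion(X, clusters, n_pca)
        null = np.mean([
            _reassignment_proportion(X, perm, n_pca) for perm in perms
        ])
        scores[n_pca] = obs - null
    curve = pd.Series(scores).sort_index()
    best = curve.index[np.argmax(curve.to_numpy())]
    # ties -> smallest n_pca
    best = min(i for i in curve.index if curve[i] == curve[best])
    return int(best), curve


def find_clusters_bic(
    gm_or_matrix: GenotypeMatrix | pd.DataFrame,
    k_max: int,
    n_pca: int,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, pd.Series]:
    """k-means cluster search on retained PC scores with a BIC curve.

    ``BIC(k) = n ln(W_k / n) + k ln(n)`` with ``W_k`` the total
    within-cluster sum of squares; the assignment at the argmin is
    returned together with the curve.
    """
    if isinstance(gm_or_matrix, GenotypeMatrix):
        X = impute_genotypes(gm_or_matrix)
    else:
        X = gm_or_matrix.to_numpy(dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n)
    T, _ = _pca_reduce(X, n_pca)
    bic = {}
    assignments = {}
    for k in range(1, k_max + 1):
        if k == 1:
            W = float(((T - T.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(T)
            W = float(km.inertia_)
            labels = km.labels_
        bic[k] = n * np.log(max(W, 1e-300) / n) + k * np.log(n)
        assignments[k] = labels
    curve = pd.Series(bic).sort_index()
    best = int(curve.idxmin())
    return assignments[best], curve


# ---------------------------------------------------------------------
# contribution ranking + iterative Wilcoxon
# ---------------------------------------------------------------------

def rank_contributions(contrib: pd.Series) -> list[str]:
    """Locus ids in descending contribution order (ties by id)."""
    if not np.all(np.isfinite(contrib.to_numpy(dtype=float))):
        raise ValueError("non-finite contributions")
    df = contrib.rename("c").rename_axis("locus_id").reset_index()
    df = df.sort_values(["c", "locus_id"], ascending=[False, True], kind="mergesort")
    return list(df["locus_id"])


def cumulative_contribution(contrib: pd.Series, m: int) -> float:
    """Percent of total contribution captured by the top-``m`` SNPs."""
    values = np.sort(contrib.to_numpy(dtype=float))[::-1]
    if m > len(values):
        raise ValueError("m exceeds the number of SNPs")
    total = values.sum()
    return float(100.0 * values[:m].sum() / total) if total > 0 else 0.0


@dataclass
class EnrichmentSeries:
    axis: str
    table: pd.DataFrame  # columns m, n_kN, n_other, statistic, p
    start: int = 10
    stop: int = 200

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[t["p"] < alpha]


def iterative_wilcoxon(
    ranked_is_kn: np.ndarray | list[bool],
    start: int = 10,
    stop: int = 200,
    alpha: float = 0.05,
    axis: str = "",
) -> EnrichmentSeries:
    """One-tailed Wilcoxon rank-sum over growing rank prefixes.

    ``ranked_is_kn`` marks, in descending contribution order, whether
    each SNP is non-synonymous.  For each depth ``m`` from ``start`` to
    ``stop`` the within-top-``m`` ranks (1..m, no ties by construction)
    of the kN group are tested against those of the other group with
    alternative "kN ranks are smaller" (nearer the top).  The exact
    null distribution is used when both groups have <= 25 members; the
    normal approximation with continuity correction otherwise.
    Iterations with an empty group are recorded with ``p = NaN``.
    """
    labels = np.asarray(ranked_is_kn, dtype=bool)
    if stop < start:
        raise ValueError("stop must be >= start")
    if stop > len(labels):
        raise ValueError(
            f"stop={stop} exceeds the number of ranked SNPs ({len(labels)})"
        )
    rows = []
    for m in range(start, stop + 1):
        head = labels[:m]
        ranks = np.arange(1, m + 1)
        kn = ranks[head]
        other = ranks[~head]
        if len(kn) == 0 or len(other) == 0:
            rows.append((m, len(kn), len(other), np.nan, np.nan))
            continue
        method = "exact" if max(len(kn), len(other)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(kn, other, alternative="less", method=method)
        rows.append((m, len(kn), len(other), float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["m", "n_kN", "n_other", "statistic", "p"])
    return EnrichmentSeries(axis=axis, table=table, start=start, stop=stop)


def enrichment_for_axes(
    contributions: pd.DataFrame,
    kn_locus_ids: set[str],
    start: int = 10,
    stop: int = 200,
) -> dict[str, EnrichmentSeries]:
    """Run the iterative test on every axis of a contribution table."""
    out = {}
    for axis in contributions.columns:
        order = rank_contributions(contributions[axis])
        stop_axis = min(stop, len(order))
        flags = [lid in kn_locus_ids for lid in order]
        out[axis] = iterative_wilcoxon(
            flags, start=start, stop=stop_axis, axis=str(axis)
        )
    return out
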