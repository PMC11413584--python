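"""Genotype–environment association scans and their consensus.

Three detection channels are provided:

* :func:`rda_scan` — redundancy analysis (constrained ordination of the
  centered genotype matrix on environmental predictors) with
  permutation significance and a ±k-SD loading-outlier rule;
* :func:`lfmm_scan` — latent-factor association scan: per-SNP linear
  model of genotype on one predictor plus K latent factors (top
  singular vectors of the predictor-residualized genotype matrix), with
  the median-z genomic-inflation correction
  ``lambda = median(z^2) / 0.454936`` and chi-square p-values;
* :func:`fst_outlier_scan` — a permutation FST-outlier scan (stand-in
  for a Bayesian genome scan): per-locus Weir–Cockerham theta against a
  pooled permutation null, Benjamini–Hochberg FDR control.

Candidate loci are those flagged by at least two channels
(:func:`consensus`); "neutral" loci are flagged by none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import _pop_counts, _wc_components, _ratio_of_sums
from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = 0.454936


# ---------------------------------------------------------------------
# predictor collinearity pruning
# ---------------------------------------------------------------------

def prune_collinear(
    env: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop predictors until all pairwise |Pearson r| <= threshold.

    At each step the pair with the largest |r| above the threshold is
    found and its later-listed member dropped (ties keep the
    first-listed predictor).  Constant predictors are dropped first.
    Returns the pruned table and the removal log.
    """
    env = env.copy()
    removed: list[str] = []
    for col in list(env.columns):
        if env[col].nunique() <= 1 or env[col].std() == 0:
            log.warning("dropping constant predictor %s", col)
            env = env.drop(columns=col)
            removed.append(col)
    while env.shape[1] >= 2:
        corr = env.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        drop_idx = max(i, j)  # later-listed member
        col = env.columns[drop_idx]
        removed.append(col)
        env = env.drop(columns=col)
    return env, removed


# ---------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------

def impute_genotypes(gm: GenotypeMatrix) -> np.ndarray:
    """Float genotype matrix with missing calls replaced by locus means."""
    G = gm.genotypes.astype(float)
    called = gm.called()
    with np.errstate(invalid="ignore"):
        means = np.where(called, G, 0.0).sum(axis=0) / np.maximum(
            called.sum(axis=0), 1
        )
    return np.where(called, G, means[None, :])


def env_per_sample(
    env: pd.DataFrame, sample_localities: np.ndarray
) -> pd.DataFrame:
    """Expand locality-level predictors to one row per individual."""
    missing = sorted(set(map(str, sample_localities)) - set(env.index.astype(str)))
    if missing:
        raise ValueError(f"localities without env data: {missing}")
    return env.loc[list(sample_localities)].reset_index(drop=True)


# ---------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------

@dataclass
class RdaResult:
    eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    site_scores: np.ndarray
    loadings: pd.DataFrame  # loci x axes
    full_model_p: float
    axis_p: np.ndarray
    proportion_explained: float
    pseudo_f: float


def _constrained_decomposition(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Fit Y ~ X, eigen-decompose fitted values. Returns
    (eigenvalues, residual eigenvalues, site scores, loadings, rank)."""
    n = Y.shape[0]
    beta, _res, rank, _sv = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ beta
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    q = min(rank, int(np.sum(s > s[0] * 1e-9 if len(s) else 0)))
    resid = Y - Yhat
    s_res = np.linalg.svd(resid, compute_uv=False)
    eig_res = s_res**2 / (n - 1)
    site = U[:, :q] * s[:q]
    loadings = Vt[:q].T
    return eig[:q], eig_res, site, loadings, q


def rda_scan(
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    sample_localities: np.ndarray,
    n_perm: int = 1000,
    sd_cutoff: float = 3.0,
    axis_alpha: float = 0.01,
    seed: int = 0,
) -> tuple[RdaResult, set[str]]:
    """Redundancy analysis with permutation tests and loading outliers.

    Missing genotypes are mean-imputed; each individual inherits its
    locality's predictor values.  Significance of the full model uses
    the pseudo-F statistic under row permutations of the predictor
    table; per-axis p compares each constrained eigenvalue with its
    permutation distribution.  A SNP is flagged when its loading on any
    axis with p <= ``axis_alpha`` lies more than ``sd_cutoff`` standard
    deviations from the mean loading of that axis.
    """
    Y = impute_genotypes(gm)
    Y = Y - Y.mean(axis=0)
    Xdf = env_per_sample(env, sample_localities)
    X = Xdf.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    n = Y.shape[0]
    if X.shape[1] >= len(env):
        log.warning(
            "predictors (%d) >= localities (%d): constrained rank limited",
            X.shape[1], len(env),
        )
    eig, eig_res, site, load, q = _constrained_decomposition(Y, X)
    tot = eig.sum() + eig_res.sum()
    df_res = max(n - q - 1, 1)
    pseudo_f = (eig.sum() / q) / max(eig_res.sum() / df_res, 1e-300)

    rng = np.random.default_rng(seed)
    hits_full = 0
    hits_axis = np.zeros(q)
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        eig_p, eig_res_p, _, _, qp = _constrained_decomposition(Y, Xp)
        f_p = (eig_p.sum() / max(qp, 1)) / max(
            eig_res_p.sum() / max(n - qp - 1, 1), 1e-300
        )
        if f_p >= pseudo_f:
            hits_full += 1
        k = min(q, len(eig_p))
        hits_axis[:k] += eig_p[:k] >= eig[:k]
    full_p = (1 + hits_full) / (n_perm + 1)
    axis_p = (1 + hits_axis) / (n_perm + 1)

    loadings = pd.DataFrame(
        load, index=gm.locus_ids, columns=[f"RDA{k + 1}" for k in range(q)]
    )
    flagged: set[str] = set()
    for k in range(q):
        if axis_p[k] <= axis_alpha:
            v = load[:, k]
            mu, sd = v.mean(), v.std()
            if sd == 0:
                continue
            out = np.abs(v - mu) > sd_cutoff * sd
            flagged.update(np.asarray(gm.locus_ids)[out])
    result = RdaResult(
        eigenvalues=eig,
        residual_eigenvalues=eig_res,
        site_scores=site,
        loadings=loadings,
        full_model_p=full_p,
        axis_p=axis_p,
        proportion_explained=float(eig.sum() / tot) if tot > 0 else np.nan,
        pseudo_f=float(pseudo_f),
    )
    return result, flagged


# ---------------------------------------------------------------------
# LFMM-style latent factor scan
# ---------------------------------------------------------------------

@dataclass
class LfmmResult:
    z: np.ndarray
    K: int
    gif: float
    p_adjusted: np.ndarray
    alpha: float
    predictor: str = ""


def lfmm_scan(
    gm: GenotypeMatrix,
    predictor: np.ndarray | pd.Series,
    K: int,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[LfmmResult, set[str]]:
    """Latent-factor association scan for one predictor.

    Latent factors are the top-``K`` left singular vectors of the
    centered, imputed genotype matrix after regressing the predictor
    out (one round).  Each SNP is then fit by OLS on
    ``[1, predictor, factors]``; the predictor z-score is rescaled by
    the genomic inflation factor ``lambda = median(z^2)/0.454936`` and
    converted to an upper-tail chi-square(1) p-value.
    """
    name = predictor.name if isinstance(predictor, pd.Series) else ""
    x = np.asarray(predictor, dtype=float)
    if len(x) != gm.n_samples:
        raise ValueError("predictor length must match sample count")
    n = gm.n_samples
    if K >= min(n, gm.n_loci):
        raise ValueError("K must be smaller than min(samples, loci)")
    Y = impute_genotypes(gm)
    Y = Y - Y.mean(axis=0)
    sd = x.std()
    x = (x - x.mean()) / (sd if sd > 0 else 1.0)

    if K > 0:
        # one round of residualization so factors do not absorb the signal
        coef = (x @ Y) / (x @ x)
        Y1 = Y - np.outer(x, coef)
        U, _s, _Vt = np.linalg.svd(Y1, full_matrices=False)
        factors = U[:, :K]
        D = np.column_stack([np.ones(n), x, factors])
    else:
        D = np.column_stack([np.ones(n), x])
    DtD_inv = np.linalg.pinv(D.T @ D)
    beta = DtD_inv @ D.T @ Y
    resid = Y - D @ beta
    dof = max(n - D.shape[1], 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(DtD_inv[1, 1] * sigma2, 1e-300))
    z = beta[1] / se
    gif = float(np.median(z**2) / CHI2_1_MEDIAN)
    gif = max(gif, 1e-12)
    p_adj = stats.chi2.sf(z**2 / gif, df=1)
    flagged = set(np.asarray(gm.locus_ids)[p_adj < alpha])
    return (
        LfmmResult(z=z, K=K, gif=gif, p_adjusted=p_adj, alpha=alpha, predictor=str(name)),
        flagged,
    )


def lfmm_scan_all(
    gm: GenotypeMatrix,
    env: pd.DataFrame,
    sample_localities: np.ndarray,
    K: int,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[dict[str, LfmmResult], set[str]]:
    """Run :func:`lfmm_scan` per predictor; union of flagged loci."""
    Xdf = env_per_sample(env, sample_localities)
    results: dict[str, LfmmResult] = {}
    flagged: set[str] = set()
    for col in Xdf.columns:
        res, f = lfmm_scan(gm, Xdf[col], K=K, alpha=alpha, seed=seed)
        results[col] = res
        flagged |= f
    return results, flagged


def choose_k(
    gm: GenotypeMatrix, k_max: int, seed: int = 0, mask_frac: float = 0.1
) -> int:
    """Pick the latent-factor count by masked-entry cross-validation.

    10% of matrix entries are masked (replaced by locus means); K is
    the rank whose truncated-SVD reconstruction best predicts the
    masked entries.
    """
    if k_max >= min(gm.n_samples, gm.n_loci):
        raise ValueError("k_max must be below min(samples, loci)")
    rng = np.random.default_rng(seed)
    M = impute_genotypes(gm)
    mask = rng.random(M.shape) < mask_frac
    Mm = M.copy()
    col_means = np.where(~mask, M, 0).sum(axis=0) / np.maximum(
        (~mask).sum(axis=0), 1
    )
    Mm[mask] = np.broadcast_to(col_means, M.shape)[mask]
    mu = Mm.mean(axis=0)
    C = Mm - mu
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    errors = []
    for k in range(k_max + 1):
        approx = mu + (U[:, :k] * s[:k]) @ Vt[:k] if k else np.broadcast_to(mu, M.shape)
        errors.append(float(((approx[mask] - M[mask]) ** 2).mean()))
    return int(np.argmin(errors))


# ---------------------------------------------------------------------
# permutation FST outlier scan (Bayesian genome-scan stand-in)
# ---------------------------------------------------------------------

def fst_outlier_scan(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 5000,
    fdr: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Permutation FST-outlier scan with BH FDR control.

    Per-locus Weir–Cockerham theta is compared with a pooled null built
    by permuting individuals across populations; the null is shared
    across loci, so ``n_perm`` is the target size of the pooled null
    (the number of whole-matrix permutation replicates is
    ``ceil(n_perm / n_loci)``).  Empirical p-values use the add-one
    estimator and are fed to Benjamini–Hochberg at ``fdr``.

    This is a frequency-based stand-in for a Bayesian genome scan; it
    retains only the outlier-vs-null logic and the FDR level.
    """
    pops = np.asarray(pops)
    n_called, alt, n_het, _ = _pop_counts(gm, pops)
    a, b, c = _wc_components(n_called, alt, n_het)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta_obs = np.where(np.abs(denom) > 0, a / denom, np.nan)
    rng = np.random.default_rng(seed)
    n_reps = max(1, int(np.ceil(n_perm / max(gm.n_loci, 1))))
    null: list[np.ndarray] = []
    for _ in range(n_reps):
        perm = rng.permutation(pops)
        nc_, alt_, het_, _ = _pop_counts(gm, perm)
        ap, bp, cp = _wc_components(nc_, alt_, het_)
        with np.errstate(invalid="ignore", divide="ignore"):
            dp = ap + bp + cp
            tp = np.where(np.abs(dp) > 0, ap / dp, np.nan)
        null.append(tp[np.isfinite(tp)])
    null_arr = np.sort(np.concatenate(null))
    N = len(null_arr)
    p = np.full(gm.n_loci, np.nan)
    finite = np.isfinite(theta_obs)
    # count null >= obs via searchsorted on the sorted pooled null
    ge = N - np.searchsorted(null_arr, theta_obs[finite], side="left")
    p[finite] = (1.0 + ge) / (N + 1.0)
    flagged: set[str] = set()
    reject = np.zeros(gm.n_loci, dtype=bool)
    if finite.any():
        rej, _padj, _, _ = multipletests(p[finite], alpha=fdr, method="fdr_bh")
        reject[np.flatnonzero(finite)] = rej
        flagged = set(np.asarray(gm.locus_ids)[reject])
    table = pd.DataFrame(
        {"locus_id": gm.locus_ids, "theta": theta_obs, "p": p, "flagged": reject}
    ).set_index("locus_id")
    return table, flagged


# ---------------------------------------------------------------------
# consensus partition
# ---------------------------------------------------------------------

@dataclass
class CandidatePartition:
    by_method: dict[str, set[str]]
    consensus: set[str]
    union: set[str]
    neutral: set[str]
    venn: dict[str, int] = field(default_factory=dict)


def consensus(
    flagged_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    min_methods: int = 2,
) -> CandidatePartition:
    """Partition loci into consensus (>= ``min_methods`` channels),
    union (>= 1) and neutral (none)."""
    universe = set(universe)
    for name, s in flagged_sets.items():
        extra = s - universe
        if extra:
            raise ValueError(f"{name} flags loci outside the universe: "
                             f"{sorted(extra)[:5]}")
    counts: dict[str, int] = {}
    for s in flagged_sets.values():
        for lid in s:
            counts[lid] = counts.get(lid, 0) + 1
    union = {l for l, c in counts.items() if c >= 1}
    cons = {l for l, c in counts.items() if c >= min_methods}
    neutral = universe - union
    venn: dict[str, int] = {}
    names = list(flagged_sets)
    for mask in range(1, 2 ** len(names)):
        combo = [names[i] for i in range(len(names)) if mask >> i & 1]
        members = set(universe)
        for i, name in enumerate(names):
            if mask >> i & 1:
                members &= flagged_sets[name]
            else:
                members -= flagged_sets[name]
        venn["&".join(combo)] = len(members)
    return CandidatePartition(
        by_method={k: set(v) for k, v in flagged_sets.items()},
        consensus=cons,
        union=union,
        neutral=neutral,
        venn=venn,
    )
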