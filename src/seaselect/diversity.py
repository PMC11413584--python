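"""Population diversity and structure statistics.

All statistics operate on a :class:`~seaselect.types.GenotypeMatrix`
plus an array of population labels aligned to its samples.  Missing
calls are pairwise-deleted per locus.

Definitions
-----------
* ``Ho`` — observed heterozygote fraction among non-missing calls.
* ``He`` — unbiased expected heterozygosity (gene diversity)
  ``k/(k-1) * (1 - p^2 - q^2)`` with ``k`` non-missing gene copies.
* ``theta_pi`` — nucleotide diversity as the mean number of pairwise
  differences, summed over SNP loci:
  ``pi_l = 2 x (k - x) / (k (k - 1))`` with ``x`` alternate copies.
  Per locus this equals unbiased He (an identity the test-suite
  asserts).
* ``FIS`` — multilocus ratio-of-sums inbreeding coefficient
  ``1 - sum(Ho_l) / sum(He_l)`` over loci polymorphic in the
  population.
* ``theta`` — the Weir & Cockerham (1984) moment estimator of FST from
  among-population (a), among-individual (b) and within-individual (c)
  variance components, combined across loci as ratio of sums.
* AMOVA — hierarchical partition of the variance of individual
  allele-count vectors into among-region / among-locality / within
  strata, with Phi statistics and permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# per-population counting
# ---------------------------------------------------------------------

def _pop_labels(pops: np.ndarray) -> tuple[np.ndarray, list[str]]:
    pops = np.asarray(pops)
    labels = list(pd.unique(pops))
    index = np.array([labels.index(p) for p in pops])
    return index, [str(l) for l in labels]


def _pop_counts(
    gm: GenotypeMatrix, pops: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Return ``(n_called, alt_copies, n_het)`` with shape (P, L)."""
    idx, labels = _pop_labels(pops)
    P, L = len(labels), gm.n_loci
    called = gm.called()
    geno = np.where(called, gm.genotypes, 0)
    het = (gm.genotypes == 1)
    n_called = np.zeros((P, L))
    alt = np.zeros((P, L))
    n_het = np.zeros((P, L))
    for p in range(P):
        sel = idx == p
        if not sel.any():
            continue
        n_called[p] = called[sel].sum(axis=0)
        alt[p] = geno[sel].sum(axis=0)
        n_het[p] = het[sel].sum(axis=0)
    return n_called, alt, n_het, labels


# ---------------------------------------------------------------------
# Ho / He / theta_pi / FIS
# ---------------------------------------------------------------------

def observed_heterozygosity(
    gm: GenotypeMatrix, pops: np.ndarray
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-pop per-locus and multilocus observed heterozygosity."""
    n_called, _alt, n_het, labels = _pop_counts(gm, pops)
    if (n_called.sum(axis=1) == 0).any():
        raise ValueError("population with no genotype calls")
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    per_locus = pd.DataFrame(ho, index=labels, columns=gm.locus_ids)
    return per_locus, per_locus.mean(axis=1)


def _he_matrix(n_called: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Unbiased He per pop per locus; nan where < 2 gene copies."""
    k = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(k, 1)
        he = k / np.maximum(k - 1, 1) * (1.0 - p**2 - (1.0 - p) ** 2)
    he[k < 2] = np.nan
    return he


def expected_heterozygosity(
    gm: GenotypeMatrix, pops: np.ndarray
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-pop per-locus and multilocus unbiased expected heterozygosity."""
    n_called, alt, _het, labels = _pop_counts(gm, pops)
    he = _he_matrix(n_called, alt)
    per_locus = pd.DataFrame(he, index=labels, columns=gm.locus_ids)
    return per_locus, per_locus.mean(axis=1)


def theta_pi(gm: GenotypeMatrix, pops: np.ndarray) -> pd.Series:
    """Nucleotide diversity summed over loci (mean pairwise multilocus
    differences per population)."""
    n_called, alt, _het, labels = _pop_counts(gm, pops)
    k = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (k - alt) / np.maximum(k * (k - 1.0), 1)
    pi[k < 2] = np.nan
    return pd.Series(np.nansum(pi, axis=1), index=labels, name="theta_pi")


def fis(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Multilocus FIS per population, optional permutation p-value.

    The permutation null shuffles gene copies among the individuals of
    the population at each locus (breaking genotypic, keeping allelic,
    structure); p is the one-tailed fraction of permuted FIS >= observed
    (heterozygote-deficit direction).
    """
    idx, labels = _pop_labels(pops)
    rng = np.random.default_rng(seed)
    rows = []
    for p, label in enumerate(labels):
        sub = gm.take_samples(idx == p)
        value = _fis_single(sub.genotypes)
        pval = np.nan
        if n_perm > 0 and np.isfinite(value):
            hits = 0
            for _ in range(n_perm):
                perm = _permute_gene_copies(sub.genotypes, rng)
                pv = _fis_single(perm)
                if np.isfinite(pv) and pv >= value:
                    hits += 1
            pval = (1 + hits) / (n_perm + 1)
        rows.append((label, value, pval))
    return pd.DataFrame(rows, columns=["population", "fis", "p"]).set_index(
        "population"
    )


def _fis_single(genotypes: np.ndarray) -> float:
    called = genotypes != MISSING
    n_called = called.sum(axis=0).astype(float)
    alt = np.where(called, genotypes, 0).sum(axis=0).astype(float)
    n_het = (genotypes == 1).sum(axis=0).astype(float)
    he = _he_matrix(n_called[None, :], alt[None, :])[0]
    poly = np.isfinite(he) & (he > 0)
    if not poly.any():
        return np.nan
    with np.errstate(invalid="ignore"):
        ho = n_het[poly] / n_called[poly]
    return float(1.0 - ho.sum() / he[poly].sum())


def _permute_gene_copies(
    genotypes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reassemble genotypes from shuffled allele copies, per locus."""
    out = np.full_like(genotypes, MISSING)
    n, L = genotypes.shape
    for j in range(L):
        called = np.flatnonzero(genotypes[:, j] != MISSING)
        if len(called) == 0:
            continue
        g = genotypes[called, j]
        copies = np.concatenate(
            [np.repeat(1, g.sum()), np.repeat(0, 2 * len(g) - g.sum())]
        )
        rng.shuffle(copies)
        out[called, j] = copies[: len(g)] + copies[len(g) :]
    return out


# ---------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------

@dataclass
class FstResult:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_locus_theta: np.ndarray
    theta: float
    p: float = np.nan
    n_perm: int = 0


def _wc_components(
    n_called: np.ndarray, alt: np.ndarray, n_het: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WC84 variance components per locus from (P, L) count arrays."""
    present = n_called >= 1
    r = present.sum(axis=0).astype(float)  # pops with data, per locus
    ntot = n_called.sum(axis=0)
    valid = r >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = ntot / np.maximum(r, 1)
        sum_n2 = (n_called**2).sum(axis=0)
        nc = (ntot - sum_n2 / np.maximum(ntot, 1)) / np.maximum(r - 1, 1)
        p_i = np.where(present, alt / np.maximum(2 * n_called, 1), 0.0)
        pbar = alt.sum(axis=0) / np.maximum(2 * ntot, 1)
        s2 = (
            (n_called * (p_i - pbar[None, :]) ** 2).sum(axis=0)
            / np.maximum((r - 1) * nbar, 1e-300)
        )
        h_i = np.where(present, n_het / np.maximum(n_called, 1), 0.0)
        hbar = (n_called * h_i).sum(axis=0) / np.maximum(ntot, 1)
        pq = pbar * (1 - pbar)
        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2 - (pq - (r - 1) / r * s2 - hbar / 4) / np.maximum(nbar - 1, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = ~valid | (nbar <= 1)
    a[bad] = np.nan
    b[bad] = np.nan
    c[bad] = np.nan
    return a, b, c


def wc_theta(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
) -> FstResult:
    """Multilocus Weir–Cockerham theta with optional permutation test.

    Monomorphic loci contribute zero to every component (ratio-of-sums
    convention); the permutation p-value is the fraction of
    label-shuffled multilocus thetas >= the observed one.
    """
    n_called, alt, n_het, _labels = _pop_counts(gm, pops)
    a, b, c = _wc_components(n_called, alt, n_het)
    theta = _ratio_of_sums(a, b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        per_locus = np.where(np.abs(denom) > 0, a / denom, np.nan)
    pval = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pops = np.asarray(pops)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pops)
            nc_, alt_, het_, _ = _pop_counts(gm, perm)
            ap, bp, cp = _wc_components(nc_, alt_, het_)
            if _ratio_of_sums(ap, bp, cp) >= theta:
                hits += 1
        pval = (1 + hits) / (n_perm + 1)
    return FstResult(a=a, b=b, c=c, per_locus_theta=per_locus, theta=theta,
                     p=pval, n_perm=n_perm)


def _ratio_of_sums(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    if denom == 0:
        return np.nan
    return float(np.nansum(a[ok]) / denom)


def pairwise_fst(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise multilocus theta and permutation p for every pop pair."""
    pops = np.asarray(pops)
    _, labels = _pop_labels(pops)
    P = len(labels)
    theta = pd.DataFrame(np.zeros((P, P)), index=labels, columns=labels)
    pval = pd.DataFrame(np.full((P, P), np.nan), index=labels, columns=labels)
    rng = np.random.default_rng(seed)
    for i in range(P):
        for j in range(i + 1, P):
            sel = (pops == labels[i]) | (pops == labels[j])
            if (pops == labels[i]).sum() < 2 or (pops == labels[j]).sum() < 2:
                theta.iloc[i, j] = theta.iloc[j, i] = np.nan
                log.warning("pair (%s, %s) has <2 samples; NA", labels[i], labels[j])
                continue
            sub = gm.take_samples(sel)
            res = wc_theta(
                sub, pops[sel], n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            theta.iloc[i, j] = theta.iloc[j, i] = res.theta
            pval.iloc[i, j] = pval.iloc[j, i] = res.p
    return theta, pval


# ---------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------

@dataclass
class AmovaResult:
    components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]
    negative_components: list[str]


def _sq_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Squared Euclidean distances between individual allele-count
    vectors; missing loci pairwise-deleted with rescaling to the full
    locus count."""
    G = gm.genotypes.astype(float)
    called = gm.called()
    G0 = np.where(called, G, 0.0)
    C = called.astype(float)
    # sum over shared loci of (g_i - g_j)^2, expanded into matrix products
    sq = G0**2
    shared = C @ C.T
    cross = G0 @ G0.T
    si = sq @ C.T  # sum_i g_il^2 over loci called in both -> sq_i restricted to j's calls
    d2 = si + si.T - 2 * cross
    L = gm.n_loci
    d2 = np.where(shared > 0, d2 * (L / np.maximum(shared, 1)), 0.0)
    np.fill_diagonal(d2, 0.0)
    return d2


def _ss_within_groups(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def _amova_stats(
    d2: np.ndarray, pops: np.ndarray, regions: np.ndarray | None
) -> tuple[dict, dict, dict, dict]:
    N = d2.shape[0]
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_wp = _ss_within_groups(d2, pops)
    pop_sizes = pd.Series(pops).value_counts()
    P = len(pop_sizes)
    if regions is None:
        df_a, df_w = P - 1, N - P
        ssd_ap = ss_total - ss_wp
        sigma_c = ss_wp / df_w
        n0 = (N - (pop_sizes**2).sum() / N) / df_a
        sigma_a = (ssd_ap / df_a - sigma_c) / n0
        total = sigma_a + sigma_c
        comps = {"among_localities": sigma_a, "within_locality": sigma_c}
        phi = {"phi_st": sigma_a / total if total else np.nan}
        df = {"among_localities": df_a, "within_locality": df_w}
        return comps, phi, df, {"ss_total": ss_total}
    # 3-level
    ss_wg = _ss_within_groups(d2, regions)
    region_of_pop = {}
    for p, r in zip(pops, regions):
        region_of_pop[p] = r
    G = len(pd.unique(regions))
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ssd_wp = ss_wp
    ssd_ap_wg = ss_wg - ss_wp
    ssd_ag = ss_total - ss_wg
    sigma_c = ssd_wp / df_wp
    group_sizes = pd.Series(regions).value_counts()
    # coefficients for unequal sizes (standard AMOVA moment equations)
    sum_npop2_over_group = 0.0
    for g, gsize in group_sizes.items():
        in_g = pop_sizes[[p for p in pop_sizes.index if region_of_pop[p] == g]]
        sum_npop2_over_group += (in_g**2).sum() / gsize
    n1 = (N - sum_npop2_over_group) / df_ap
    n2 = (sum_npop2_over_group - (pop_sizes**2).sum() / N) / df_ag
    n3 = (N - (group_sizes**2).sum() / N) / df_ag
    sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    comps = {
        "among_regions": sigma_a,
        "among_localities_within_region": sigma_b,
        "within_locality": sigma_c,
    }
    phi = {
        "phi_ct": sigma_a / total if total else np.nan,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else np.nan,
        "phi_st": (sigma_a + sigma_b) / total if total else np.nan,
    }
    df = {
        "among_regions": df_ag,
        "among_localities_within_region": df_ap,
        "within_locality": df_wp,
    }
    return comps, phi, df, {"ss_total": ss_total}


def amova(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    regions: np.ndarray | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA on squared Euclidean allele-count distances.

    With ``regions`` given (aligned per sample) the three-level design
    among-regions / among-localities-within-region / within-locality is
    fitted; otherwise the two-level design.  Negative variance
    components are reported as estimated and flagged.  Permutation
    p-values: Phi_ST by permuting individuals freely; Phi_SC by
    permuting individuals among localities within their region; Phi_CT
    by permuting whole localities among regions.
    """
    pops = np.asarray(pops)
    sizes = pd.Series(pops).value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        log.warning("excluding singleton localities from AMOVA: %s", singletons)
        keep = ~np.isin(pops, singletons)
        gm = gm.take_samples(keep)
        if regions is not None:
            regions = np.asarray(regions)[keep]
        pops = pops[keep]
    if regions is not None:
        regions = np.asarray(regions)
        if len(pd.unique(regions)) < 2:
            log.warning("fewer than 2 regions; falling back to 2-level AMOVA")
            regions = None
    d2 = _sq_distance_matrix(gm)
    comps, phi, df, _ = _amova_stats(d2, pops, regions)
    total = sum(comps.values())
    percentages = {k: 100.0 * v / total for k, v in comps.items()}
    negative = [k for k, v in comps.items() if v < 0]

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_perm > 0:
        hits = {k: 0 for k in phi}
        idx = np.arange(len(pops))
        for _ in range(n_perm):
            perm_all = rng.permutation(idx)
            _, phi_g, _, _ = _amova_stats(
                d2, pops[perm_all], None if regions is None else regions[perm_all]
            )
            key = "phi_st"
            if phi_g.get(key, np.nan) >= phi[key] - 1e-12:
                hits[key] += 1
            if regions is not None:
                # within-region shuffles for phi_sc
                perm_w = idx.copy()
                for g in pd.unique(regions):
                    sel = np.flatnonzero(regions == g)
                    perm_w[sel] = sel[rng.permutation(len(sel))]
                _, phi_w, _, _ = _amova_stats(d2, pops[perm_w], regions)
                if phi_w["phi_sc"] >= phi["phi_sc"] - 1e-12:
                    hits["phi_sc"] += 1
                # whole-locality shuffles among regions for phi_ct
                locs = pd.unique(pops)
                reg_of = {p: r for p, r in zip(pops, regions)}
                shuffled = rng.permutation([reg_of[l] for l in locs])
                new_reg_of = dict(zip(locs, shuffled))
                regions_p = np.array([new_reg_of[p] for p in pops])
                _, phi_c, _, _ = _amova_stats(d2, pops, regions_p)
                if phi_c["phi_ct"] >= phi["phi_ct"] - 1e-12:
                    hits["phi_ct"] += 1
        for k in phi:
            p_values[k] = (1 + hits[k]) / (n_perm + 1)
    return AmovaResult(
        components=comps,
        percentages=percentages,
        phi=phi,
        p_values=p_values,
        df=df,
        negative_components=negative,
    )


# ---------------------------------------------------------------------
# Ho vs He comparison
# ---------------------------------------------------------------------

def compare_ho_he(
    gm: GenotypeMatrix, pops: np.ndarray
) -> tuple[float, float, float, float]:
    """Bartlett variance test and paired t-test on per-locus (Ho, He).

    Per-locus values are averaged across populations (ignoring pops
    without calls at a locus); loci with undefined values are dropped.
    Returns ``(bartlett_stat, bartlett_p, t_stat, t_p)``.
    """
    ho_mat, _ = observed_heterozygosity(gm, pops)
    he_mat, _ = expected_heterozygosity(gm, pops)
    ho = ho_mat.mean(axis=0, skipna=True).to_numpy()
    he = he_mat.mean(axis=0, skipna=True).to_numpy()
    ok = np.isfinite(ho) & np.isfinite(he)
    ho, he = ho[ok], he[ok]
    if len(ho) < 2:
        raise ValueError("need at least 2 loci with defined Ho and He")
    if np.allclose(ho, ho[0]) and np.allclose(he, he[0]):
        return np.nan, 1.0, 0.0, 1.0
    bart_stat, bart_p = stats.bartlett(ho, he)
    if np.allclose(ho - he, (ho - he)[0]):
        t_stat, t_p = (np.inf if (ho - he)[0] != 0 else 0.0), (
            0.0 if (ho - he)[0] != 0 else 1.0
        )
    else:
        t_stat, t_p = stats.ttest_rel(ho, he)
    return float(bart_stat), float(bart_p), float(t_stat), float(t_p)


def diversity_report(
    gm: GenotypeMatrix,
    pops: np.ndarray,
    n_perm_fis: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population diversity table (n, theta_pi, Ho, He, FIS)."""
    _, ho = observed_heterozygosity(gm, pops)
    _, he = expected_heterozygosity(gm, pops)
    tp = theta_pi(gm, pops)
    f = fis(gm, pops, n_perm=n_perm_fis, seed=seed)
    n = pd.Series(pops).value_counts()
    out = pd.DataFrame({
        "n_samples": n.reindex(ho.index),
        "theta_pi": tp,
        "Ho": ho,
        "He": he,
        "FIS": f["fis"],
        "FIS_p": f["p"],
    })
    out.index.name = "population"
    return out
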