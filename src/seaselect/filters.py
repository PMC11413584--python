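"""Locus-level genotype filters for GBS- and RNA-Seq-style call sets.

Each filter returns the retained matrix together with a
:class:`FilterReport` whose per-rule counts attribute every removed
locus to the *first* rule (in the documented order) that fails it;
loci failing several rules are additionally listed for auditing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input_loci: int
    n_removed_by_rule: dict[str, int]
    n_output_loci: int
    params: dict[str, float]
    multi_rule_loci: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total_removed = sum(self.n_removed_by_rule.values())
        if self.n_input_loci != self.n_output_loci + total_removed:
            raise ValueError("filter report counts do not reconcile")


def _apply_rules(
    gm: GenotypeMatrix, rules: list[tuple[str, np.ndarray]], params: dict[str, float]
) -> tuple[GenotypeMatrix, FilterReport]:
    """``rules`` = ordered (name, fail_mask) pairs; first failure wins."""
    n = gm.n_loci
    removed_by: dict[str, int] = {}
    attributed = np.full(n, -1)
    for k, (name, fail) in enumerate(rules):
        newly = fail & (attributed < 0)
        attributed[newly] = k
        removed_by[name] = int(newly.sum())
    keep = attributed < 0
    multi: dict[str, list[str]] = {}
    n_failures = np.sum([fail for _, fail in rules], axis=0)
    for j in np.flatnonzero(n_failures > 1):
        multi[gm.locus_ids[j]] = [name for name, fail in rules if fail[j]]
    report = FilterReport(
        n_input_loci=n,
        n_removed_by_rule=removed_by,
        n_output_loci=int(keep.sum()),
        params=params,
        multi_rule_loci=multi,
    )
    return gm.take_loci(keep), report


def filter_maf_missing(
    gm: GenotypeMatrix, maf_min: float = 0.01, miss_max: float = 0.20
) -> tuple[GenotypeMatrix, FilterReport]:
    """GBS-style filter: drop loci with MAF < ``maf_min`` or with a
    missing-genotype fraction > ``miss_max``.

    Rule order: missingness first, then MAF (a fully missing locus is
    removed by the missingness rule and never reaches the MAF
    computation).
    """
    miss = gm.missing_fraction()
    with np.errstate(invalid="ignore"):
        maf = gm.maf()
    fail_missing = miss > miss_max
    fail_maf = ~(maf >= maf_min)  # nan (no calls) counts as failing
    rules = [("missingness", fail_missing), ("maf", fail_maf)]
    return _apply_rules(gm, rules, {"maf_min": maf_min, "miss_max": miss_max})


def filter_rna_variants(
    gm: GenotypeMatrix,
    min_qual: float = 30.0,
    min_dp4: float = 10.0,
    mac: int = 4,
    max_missing: float = 0.98,
    maf: float = 0.01,
) -> tuple[GenotypeMatrix, FilterReport]:
    """RNA-Seq-style filter mirroring the bcftools/vcftools thresholds.

    A locus is kept iff variant base quality >= ``min_qual``, summed
    alt-strand coverage (DP4) >= ``min_dp4``, minor allele count over
    gene copies >= ``mac``, call rate >= ``max_missing`` (vcftools
    ``--max-missing`` semantics: the minimum fraction of samples with a
    genotype), and MAF >= ``maf``.  Quality/DP4 rules are skipped with a
    warning when the matrix carries no such QC fields.

    Rule order: quality, dp4, mac, call-rate, maf.
    """
    rules: list[tuple[str, np.ndarray]] = []
    if gm.base_quality is not None:
        rules.append(("quality", ~(np.nan_to_num(gm.base_quality, nan=np.inf) >= min_qual)))
    else:
        log.warning("no base_quality field; quality rule skipped")
    if gm.dp4_alt is not None:
        rules.append(("dp4", ~(np.nan_to_num(gm.dp4_alt, nan=np.inf) >= min_dp4)))
    else:
        log.warning("no dp4_alt field; DP4 rule skipped")
    called = gm.called()
    alt_copies = np.where(called, gm.genotypes, 0).sum(axis=0)
    copies = 2 * called.sum(axis=0)
    minor_count = np.minimum(alt_copies, copies - alt_copies)
    rules.append(("mac", minor_count < mac))
    call_rate = called.mean(axis=0)
    rules.append(("call_rate", call_rate < max_missing))
    with np.errstate(invalid="ignore"):
        maf_vals = gm.maf()
    rules.append(("maf", ~(maf_vals >= maf)))
    params = {
        "min_qual": min_qual,
        "min_dp4": min_dp4,
        "mac": mac,
        "max_missing": max_missing,
        "maf": maf,
    }
    return _apply_rules(gm, rules, params)
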