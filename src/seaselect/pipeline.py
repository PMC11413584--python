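"""End-to-end orchestration: filter → diversity ∥ association →
consensus → effect annotation → kN/kS → ordination enrichment.

The pipeline runs either on user inputs (VCF + sample map + env CSV +
FASTA/ORF table) or on fully synthetic data with known ground truth.
A single root seed drives every stochastic stage through deterministic
child seeds, so reruns with the same config are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association, diversity, effects, enrichment, filters, simulate, vcfio
from .types import GenotypeMatrix, pops_as_array

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``vcf``/``samples``/``env`` paths or ``simulate: true`` with
    simulation parameters.
    """

    seed: int = 0
    out_dir: str | None = None
    # inputs
    vcf: str | None = None
    samples: str | None = None
    env: str | None = None
    fasta: str | None = None
    orfs: str | None = None
    # or simulation
    simulate: bool = True
    sim: dict[str, Any] = field(default_factory=dict)
    n_transcripts: int = 40
    snp_plan: dict[str, int] = field(default_factory=lambda: {
        "synonymous": 40, "nonsynonymous": 15, "oCDS": 25,
    })
    # stage parameters
    maf_min: float = 0.01
    miss_max: float = 0.20
    collinearity_threshold: float = 0.8
    rda_n_perm: int = 199
    rda_sd_cutoff: float = 3.0
    lfmm_alpha: float = 0.01
    lfmm_k: int | None = None
    k_max: int = 8
    fst_n_perm: int = 5000
    fst_fdr: float = 0.05
    min_methods: int = 2
    min_orf_codons: int = 100
    enrich_start: int = 10
    enrich_stop: int = 200
    n_perm_amova: int = 99
    n_perm_fst_global: int = 99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("vcf", "samples", "env", "fasta", "orfs"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config {key}: no such file {val}")
        return cfg


def _child_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full workflow; returns the (JSON-serializable) report."""
    seeds = _child_seeds(config.seed, 8)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    # ---- stage 0: inputs -------------------------------------------
    truth_classes: dict[str, str] = {}
    ts = None
    orfs = None
    if config.simulate:
        sim_kwargs = dict(config.sim)
        sim_kwargs.setdefault("seed", seeds[0])
        params = simulate.SimParams(**sim_kwargs)
        env = simulate.simulate_env(params.n_pops, seed=seeds[1])
        gm, meta, truth = simulate.simulate_genotypes(params, env)
        ts, loci_tbl, ttruth = simulate.simulate_transcriptome(
            config.n_transcripts,
            snp_plan=config.snp_plan,
            seed=seeds[2],
            min_codons=config.min_orf_codons,
        )
        gm = simulate.attach_transcript_loci(gm, loci_tbl)
        truth_classes = dict(ttruth.snp_classes)
        orfs = ts.orfs
        report["stages"]["simulate"] = {
            "params": dataclasses.asdict(params),
            "n_transcript_snps": len(loci_tbl),
            "adaptive_locus_ids": truth.adaptive_locus_ids,
        }
    else:
        if not (config.vcf and config.samples and config.env):
            raise ValueError("non-simulated runs need vcf, samples and env paths")
        gm = vcfio.read_vcf(config.vcf)
        meta, env, orfs = vcfio.read_tables(config.samples, config.env,
                                            config.orfs)
        if config.fasta:
            ts = vcfio.read_fasta(config.fasta)

    pops = pops_as_array(gm, meta, "locality")
    regions = pops_as_array(gm, meta, "region")

    # ---- stage 1: filtering ----------------------------------------
    gm_f, freport = filters.filter_maf_missing(
        gm, maf_min=config.maf_min, miss_max=config.miss_max
    )
    report["stages"]["filter"] = {
        "n_input": freport.n_input_loci,
        "n_output": freport.n_output_loci,
        "removed_by_rule": freport.n_removed_by_rule,
        "params": freport.params,
    }
    log.info("filter: %d -> %d loci", freport.n_input_loci, freport.n_output_loci)

    # ---- stage 2: diversity ----------------------------------------
    div = diversity.diversity_report(gm_f, pops, seed=seeds[3])
    fst = diversity.wc_theta(gm_f, pops, n_perm=config.n_perm_fst_global,
                             seed=seeds[3])
    am = diversity.amova(gm_f, pops, regions, n_perm=config.n_perm_amova,
                         seed=seeds[4])
    bart_s, bart_p, t_s, t_p = diversity.compare_ho_he(gm_f, pops)
    report["stages"]["diversity"] = {
        "per_population": _jsonable(div),
        "global_theta": fst.theta,
        "global_theta_p": fst.p,
        "amova_percentages": am.percentages,
        "amova_phi": am.phi,
        "amova_p": am.p_values,
        "ho_vs_he": {"bartlett_stat": bart_s, "bartlett_p": bart_p,
                     "t_stat": t_s, "t_p": t_p},
    }

    # ---- stage 3: association --------------------------------------
    env_pruned, removed = association.prune_collinear(
        env, threshold=config.collinearity_threshold
    )
    K = (
        config.lfmm_k
        if config.lfmm_k is not None
        else association.choose_k(
            gm_f, k_max=min(config.k_max, gm_f.n_samples - 1, gm_f.n_loci - 1),
            seed=seeds[5],
        )
    )
    rda_res, rda_flags = association.rda_scan(
        gm_f, env_pruned, pops, n_perm=config.rda_n_perm,
        sd_cutoff=config.rda_sd_cutoff, seed=seeds[5],
    )
    _lf_res, lf_flags = association.lfmm_scan_all(
        gm_f, env_pruned, pops, K=K, alpha=config.lfmm_alpha, seed=seeds[6]
    )
    _fst_tbl, fst_flags = association.fst_outlier_scan(
        gm_f, pops, n_perm=config.fst_n_perm, fdr=config.fst_fdr, seed=seeds[7]
    )
    part = association.consensus(
        {"rda": rda_flags, "lfmm": lf_flags, "fst_outlier": fst_flags},
        universe=gm_f.locus_ids,
        min_methods=config.min_methods,
    )
    report["stages"]["association"] = {
        "predictors_retained": list(env_pruned.columns),
        "predictors_removed": removed,
        "lfmm_K": K,
        "rda_full_model_p": rda_res.full_model_p,
        "n_flagged": {k: len(v) for k, v in part.by_method.items()},
        "n_consensus": len(part.consensus),
        "n_union": len(part.union),
        "n_neutral": len(part.neutral),
        "venn": part.venn,
        "consensus": sorted(part.consensus),
    }

    # ---- stage 4: effect annotation + kN/kS ------------------------
    if ts is not None and orfs is not None:
        on_transcript = [
            i for i, c in enumerate(gm_f.chrom) if c in ts.sequences
        ]
        loci = pd.DataFrame({
            "locus_id": [gm_f.locus_ids[i] for i in on_transcript],
            "transcript_id": [gm_f.chrom[i] for i in on_transcript],
            "pos": gm_f.pos[on_transcript],
            "ref": gm_f.ref[on_transcript],
            "alt": gm_f.alt[on_transcript],
        })
        classified = effects.classify_table(ts.sequences, orfs, loci)
        classified = classified.dropna(subset=["effect_class"])
        class_of = dict(zip(classified["locus_id"], classified["effect_class"]))
        adaptive_ids = part.union & set(class_of)
        neutral_ids = part.neutral & set(class_of)
        counts_adaptive = effects.count_effects(
            class_of[l] for l in adaptive_ids
        )
        counts_neutral = effects.count_effects(class_of[l] for l in neutral_ids)
        eff_report: dict[str, Any] = {
            "adaptive": dataclasses.asdict(counts_adaptive),
            "adaptive_ratio": counts_adaptive.ratio,
            "neutral": dataclasses.asdict(counts_neutral),
            "neutral_ratio": counts_neutral.ratio,
        }
        if truth_classes:
            agree = np.mean([
                truth_classes[l] == c
                for l, c in class_of.items()
                if l in truth_classes
            ])
            eff_report["truth_agreement"] = float(agree)
        try:
            chi2, dof, p = effects.compare_knks(counts_adaptive, counts_neutral)
            eff_report["knks_chi2"] = {"chi2": chi2, "df": dof, "p": p}
        except ValueError as exc:
            eff_report["knks_chi2"] = {"error": str(exc)}
        report["stages"]["effects"] = eff_report

        # ---- stage 5: ordination + iterative Wilcoxon --------------
        tr_ids = list(classified["locus_id"])
        sub = gm_f.take_loci(np.isin(gm_f.locus_ids, tr_ids))
        freq = enrichment.locality_freqs(sub, pops)
        pca = enrichment.pca_contributions(freq)
        kn_ids = {l for l, c in class_of.items() if c == "nonsynonymous"}
        stop = min(config.enrich_stop, sub.n_loci)
        start = min(config.enrich_start, stop)
        series = enrichment.enrichment_for_axes(
            pca.contributions.iloc[:, :2], kn_ids, start=start, stop=stop
        )
        report["stages"]["enrichment"] = {
            axis: {
                "variance_pct": float(pca.variance_pct[i]),
                "n_significant": int((s.table["p"] < 0.05).sum()),
                "series": _jsonable(s.table),
            }
            for i, (axis, s) in enumerate(series.items())
        }

    report = _jsonable(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        vcfio.write_vcf(gm_f, out / "filtered.vcf")
    return report
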