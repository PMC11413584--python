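"""Synthetic genotype, environment and transcriptome generators.

Every downstream stage of the pipeline is testable against these
generators because the ground truth (which loci are environment-linked,
which planted SNP has which coding effect) is recorded alongside the
data.

Population allele frequencies follow the Balding–Nichols model: around
an ancestral frequency ``p`` each population draws
``p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F)``, so the expected Wright FST of
the simulated populations is ``F`` — which gives an analytic target for
estimator-recovery tests.  Environment-linked ("adaptive") loci instead
follow a deterministic logit-linear cline in one designated predictor:
``logit(p_k) = logit(p) + beta * z_k`` with ``z`` the standardized
predictor value of population ``k``.

The cline is applied on top of the Balding–Nichols draw, so at
``beta = 0`` adaptive loci are exactly neutral.  Genotypes are
Binomial(2, p_k) per individual (Hardy–Weinberg within populations);
missingness is applied uniformly at random (MCAR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, REGIONS, GenotypeMatrix, TranscriptSet

log = logging.getLogger(__name__)

DEFAULT_PREDICTORS = [
    "Long", "Lat", "AnnPrec", "PrecWett", "TempAnnRang",
    "ChloMean", "pH", "Salinity", "Sstrange", "Curvssrange",
]

STOPS = ("TAA", "TAG", "TGA")
FOURFOLD_PREFIXES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")

CODON_TABLE = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        CODON_TABLE[stop] = "*"


_build_codon_table()


@dataclass
class SimParams:
    """Study conditions for the genotype simulator.

    Defaults mirror the sampling design the pipeline targets: ~11 rocky
    shore localities with a handful of diploid snails each, a few
    thousand biallelic SNPs, weak background differentiation, and a
    small set of loci tied to an environmental gradient.
    """

    n_pops: int = 11
    n_per_pop: int = 8
    n_loci: int = 2000
    F: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_adaptive: int = 20
    beta: float = 1.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must be in (0, 1)")
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive cannot exceed n_loci")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    adaptive_locus_ids: list[str] = field(default_factory=list)
    ancestral_freq: np.ndarray | None = None
    pop_freqs: np.ndarray | None = None  # (n_pops, n_loci)
    adaptive_predictor: dict[str, str] = field(default_factory=dict)
    snp_classes: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def simulate_env(
    n_pops: int,
    predictor_names: list[str] | None = None,
    env_corr: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-locality predictor values from a multivariate normal.

    ``env_corr`` is the target correlation matrix (identity by default);
    empirical correlations converge to it as ``n_pops`` grows.
    """
    if predictor_names is None:
        predictor_names = list(DEFAULT_PREDICTORS)
    p = len(predictor_names)
    if env_corr is None:
        env_corr = np.eye(p)
    env_corr = np.asarray(env_corr, dtype=float)
    if env_corr.shape != (p, p) or not np.allclose(env_corr, env_corr.T):
        raise ValueError("env_corr must be a symmetric (p, p) matrix")
    eigvals = np.linalg.eigvalsh(env_corr)
    if eigvals.min() < -1e-10:
        raise ValueError("env_corr is not positive semi-definite")
    rng = np.random.default_rng(seed)
    # eigen factorization tolerates PSD (rank-deficient) targets
    w, v = np.linalg.eigh(env_corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_pops, p)) @ root.T
    localities = [f"L{i + 1:02d}" for i in range(n_pops)]
    return pd.DataFrame(z, index=pd.Index(localities, name="locality"),
                        columns=predictor_names)


def make_sample_metadata(
    env: pd.DataFrame, n_per_pop: int, n_regions: int = 3
) -> pd.DataFrame:
    """Assign ``n_per_pop`` samples to each locality, localities to regions.

    Consecutive localities are grouped into ``n_regions`` contiguous
    coastal regions (NE / SE / S by default).
    """
    localities = list(env.index.astype(str))
    n_regions = min(n_regions, len(localities), len(REGIONS))
    groups = np.array_split(np.arange(len(localities)), n_regions)
    region_of = {}
    for r, idx in enumerate(groups):
        for i in idx:
            region_of[localities[i]] = REGIONS[r]
    rows = []
    for loc in localities:
        for k in range(n_per_pop):
            rows.append((f"{loc}_s{k + 1:02d}", loc, region_of[loc]))
    return pd.DataFrame(rows, columns=["sample_id", "locality", "region"])


def simulate_genotypes(
    params: SimParams, env: pd.DataFrame, adaptive_predictor: str | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate genotypes under Balding–Nichols drift plus optional clines.

    Returns ``(genotypes, sample_metadata, truth)``.  The first
    ``n_adaptive`` loci (shuffled ids ``adp_*``) track the standardized
    ``adaptive_predictor`` column of ``env`` (first column by default)
    on the logit scale with slope ``beta``.
    """
    if len(env) != params.n_pops:
        raise ValueError(
            f"env has {len(env)} rows but params.n_pops={params.n_pops}"
        )
    rng = np.random.default_rng(params.seed)
    n_pops, n_loci = params.n_pops, params.n_loci
    lo, hi = params.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_loci)
    F = params.F
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    pop_freqs = rng.beta(a[None, :], b[None, :], size=(n_pops, n_loci))

    if adaptive_predictor is None:
        adaptive_predictor = str(env.columns[0])
    z = env[adaptive_predictor].to_numpy(dtype=float)
    sd = z.std(ddof=0)
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)

    # the cline acts on top of drift: at beta=0 adaptive loci are
    # exactly Balding-Nichols, i.e. indistinguishable from neutral ones
    adaptive_idx = np.arange(params.n_adaptive)
    if params.n_adaptive:
        base = np.clip(pop_freqs[:, adaptive_idx], 1e-6, 1 - 1e-6)
        logit = np.log(base / (1.0 - base))
        shifted = logit + params.beta * z[:, None]
        p_adapt = 1.0 / (1.0 + np.exp(-shifted))
        n_clamped = int(np.sum((p_adapt < 0.001) | (p_adapt > 0.999)))
        if n_clamped:
            log.debug("clamped %d adaptive pop frequencies", n_clamped)
        pop_freqs[:, adaptive_idx] = np.clip(p_adapt, 0.001, 0.999)

    meta = make_sample_metadata(env, params.n_per_pop)
    pop_index = {loc: k for k, loc in enumerate(env.index.astype(str))}
    sample_pop = np.array([pop_index[l] for l in meta["locality"]])
    geno = rng.binomial(2, pop_freqs[sample_pop, :]).astype(np.int16)
    if params.missing_rate > 0:
        mask = rng.random(geno.shape) < params.missing_rate
        geno[mask] = MISSING

    locus_ids = [
        f"adp{j:05d}" if j < params.n_adaptive else f"tag{j:05d}"
        for j in range(n_loci)
    ]
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_loci)
    alt_i = (ref_i + rng.integers(1, 4, size=n_loci)) % 4
    gm = GenotypeMatrix(
        genotypes=geno,
        sample_ids=list(meta["sample_id"]),
        locus_ids=locus_ids,
        chrom=list(locus_ids),
        pos=np.zeros(n_loci, dtype=np.int64),
        ref=bases[ref_i],
        alt=bases[alt_i],
    )
    truth = SimTruth(
        adaptive_locus_ids=locus_ids[: params.n_adaptive],
        ancestral_freq=p_anc,
        pop_freqs=pop_freqs,
        adaptive_predictor={
            lid: adaptive_predictor for lid in locus_ids[: params.n_adaptive]
        },
        seed=params.seed,
    )
    return gm, meta, truth


# ---------------------------------------------------------------------
# transcriptome with planted SNP effect classes
# ---------------------------------------------------------------------

def _random_sense_codon(rng: np.random.Generator) -> str:
    bases = "ACGT"
    while True:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in STOPS:
            return c


def _random_transcript(
    rng: np.random.Generator, cds_len_codons: int, utr_len: int
) -> tuple[str, int, int]:
    """One transcript = 5'UTR + ATG + sense codons + stop + 3'UTR."""
    bases = list("ACGT")
    utr5 = "".join(rng.choice(bases, size=utr_len))
    utr3 = "".join(rng.choice(bases, size=utr_len))
    body = "".join(_random_sense_codon(rng) for _ in range(cds_len_codons - 2))
    stop = STOPS[rng.integers(0, 3)]
    seq = utr5 + "ATG" + body + stop + utr3
    orf_start = utr_len
    orf_end = utr_len + 3 * cds_len_codons
    return seq, orf_start, orf_end


def _plant_snp(
    rng: np.random.Generator, seq: str, orf_start: int, orf_end: int, klass: str
) -> tuple[int, str, str] | None:
    """Choose (pos, ref, alt) inside ``seq`` guaranteed to have ``klass``."""
    bases = "ACGT"
    if klass == "oCDS":
        utr_positions = list(range(0, orf_start)) + list(range(orf_end, len(seq)))
        pos = int(rng.choice(utr_positions))
        ref = seq[pos]
        alt = rng.choice([b for b in bases if b != ref])
        return pos, ref, str(alt)
    # CDS classes: try codons (skip ATG start and the stop codon except
    # for nonsense which may hit any sense codon)
    codon_order = rng.permutation((orf_end - orf_start) // 3 - 1)  # sense codons
    for ci in codon_order:
        if ci == 0:  # keep the start codon intact
            continue
        cstart = orf_start + 3 * ci
        codon = seq[cstart : cstart + 3]
        aa = CODON_TABLE[codon]
        offsets = rng.permutation(3)
        for off in offsets:
            ref = codon[off]
            for alt in rng.permutation([b for b in bases if b != ref]):
                mutated = codon[:off] + alt + codon[off + 1 :]
                aa2 = CODON_TABLE[mutated]
                if klass == "synonymous" and aa2 == aa and aa2 != "*":
                    return cstart + off, ref, str(alt)
                if klass == "nonsynonymous" and aa2 != aa and "*" not in (aa, aa2):
                    return cstart + off, ref, str(alt)
                if klass == "nonsense" and aa != "*" and aa2 == "*":
                    return cstart + off, ref, str(alt)
    return None


def simulate_transcriptome(
    n_transcripts: int,
    cds_len_codons: int = 150,
    utr_len: int = 60,
    snp_plan: dict[str, int] | None = None,
    seed: int = 0,
    min_codons: int = 100,
) -> tuple[TranscriptSet, pd.DataFrame, SimTruth]:
    """Build single-ORF transcripts and plant SNPs of known effect class.

    ``snp_plan`` maps class names (``synonymous`` / ``nonsynonymous`` /
    ``nonsense`` / ``oCDS``) to desired counts.  Returns the transcript
    set (with its true ORF table), a locus table (columns transcript_id,
    pos, ref, alt, locus_id) and the truth record with the planted class
    per locus id.

    Transcripts are rejection-sampled until ORF prediction at
    ``min_codons`` finds exactly the planted ORF, so the single-ORF
    filter keeps all of them.
    """
    from .effects import predict_orfs

    if cds_len_codons < max(min_codons, 4):
        raise ValueError("cds_len_codons too short for the requested min_codons")
    snp_plan = dict(snp_plan or {})
    unknown = set(snp_plan) - {"synonymous", "nonsynonymous", "nonsense", "oCDS"}
    if unknown:
        raise ValueError(f"unknown SNP classes in plan: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    orf_rows = []
    for t in range(n_transcripts):
        tid = f"tr{t + 1:04d}"
        for _attempt in range(200):
            seq, orf_start, orf_end = _random_transcript(rng, cds_len_codons, utr_len)
            found = predict_orfs(seq, min_codons=min_codons)
            if len(found) == 1 and (found[0].orf_start, found[0].orf_end) == (
                orf_start,
                orf_end,
            ):
                break
        else:  # pragma: no cover - rejection virtually always succeeds
            raise RuntimeError("could not sample a clean single-ORF transcript")
        seqs[tid] = seq
        orf_rows.append((tid, orf_start, orf_end, 0))
    orfs = pd.DataFrame(
        orf_rows, columns=["transcript_id", "orf_start", "orf_end", "frame"]
    )
    ts = TranscriptSet(sequences=seqs, orfs=orfs)

    # distribute planted SNPs round-robin over transcripts
    tids = list(seqs)
    orf_of = {r.transcript_id: (r.orf_start, r.orf_end) for r in orfs.itertuples()}
    locus_rows = []
    truth = SimTruth(seed=seed)
    snp_i = 0
    plan_items = [(k, v) for k, v in snp_plan.items() for _ in range(v)]
    used_positions: dict[str, set[int]] = {tid: set() for tid in tids}
    for klass, _ in zip([k for k, _ in plan_items], range(len(plan_items))):
        planted = None
        for _try in range(20 * len(tids)):
            tid = tids[rng.integers(0, len(tids))]
            ostart, oend = orf_of[tid]
            planted = _plant_snp(rng, seqs[tid], ostart, oend, klass)
            if planted is not None and planted[0] not in used_positions[tid]:
                break
            planted = None
        if planted is None:
            raise ValueError(f"infeasible SNP plan: no site available for {klass}")
        pos, ref, alt = planted
        used_positions[tid].add(pos)
        lid = f"tsnp{snp_i:05d}"
        locus_rows.append((lid, tid, pos, ref, alt))
        truth.snp_classes[lid] = klass
        snp_i += 1
    loci = pd.DataFrame(
        locus_rows, columns=["locus_id", "transcript_id", "pos", "ref", "alt"]
    )
    return ts, loci, truth


def attach_transcript_loci(gm: GenotypeMatrix, loci: pd.DataFrame) -> GenotypeMatrix:
    """Re-home the first ``len(loci)`` loci of ``gm`` onto transcripts.

    Used to combine :func:`simulate_genotypes` (population process) with
    :func:`simulate_transcriptome` (coding context): genotype columns
    keep their frequencies but acquire transcript coordinates, alleles
    and ids from the planted-SNP table.
    """
    k = len(loci)
    if k > gm.n_loci:
        raise ValueError("more transcript loci than genotype columns")
    chrom = list(loci["transcript_id"]) + gm.chrom[k:]
    pos = np.concatenate([loci["pos"].to_numpy(np.int64), gm.pos[k:]])
    ref = np.concatenate([loci["ref"].to_numpy(dtype="U1"), gm.ref[k:]])
    alt = np.concatenate([loci["alt"].to_numpy(dtype="U1"), gm.alt[k:]])
    locus_ids = list(loci["locus_id"]) + gm.locus_ids[k:]
    return GenotypeMatrix(
        genotypes=gm.genotypes,
        sample_ids=gm.sample_ids,
        locus_ids=locus_ids,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        base_quality=gm.base_quality,
        dp4_alt=gm.dp4_alt,
    )
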