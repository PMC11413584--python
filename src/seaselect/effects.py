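"""ORF prediction and SNP coding-effect classification.

SNPs on transcripts are classified against a single predicted open
reading frame into:

* ``synonymous`` — the substituted codon encodes the same amino acid
  (stop→stop included);
* ``nonsynonymous`` — both codons are sense codons encoding different
  amino acids;
* ``nonsense`` — a sense codon becomes a stop (or a stop becomes sense);
  excluded from the non-synonymous count kN;
* ``oCDS`` — position outside the coding sequence (UTRs).

kN/kS is a plain count ratio of non-synonymous to synonymous SNPs, not
a site-normalized substitution rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import chi2_contingency

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "nonsense", "oCDS")


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame on a transcript (0-based half-open,
    stop codon included in the span)."""

    transcript_id: str
    orf_start: int
    orf_end: int
    frame: int

    @property
    def n_codons(self) -> int:
        return (self.orf_end - self.orf_start) // 3

    def __post_init__(self) -> None:
        if (self.orf_end - self.orf_start) % 3:
            raise ValueError("ORF span must be a multiple of 3")


def predict_orfs(
    sequence: str, min_codons: int = 100, transcript_id: str = ""
) -> list[OrfAnnotation]:
    """Scan the forward strand for ATG→stop open reading frames.

    One ORF is reported per (frame, stop codon): the span from the
    5'-most ATG to that stop, provided it is at least ``min_codons``
    codons long (start and stop codons counted).  ORFs still open at the
    transcript end are not reported.  Results are sorted longest-first.
    """
    seq = sequence.upper()
    orfs: list[OrfAnnotation] = []
    stops = set(standard_dna_table.stop_codons)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in stops:
                end = i + 3
                if (end - start) // 3 >= min_codons:
                    orfs.append(OrfAnnotation(transcript_id, start, end, frame))
                start = None
    orfs.sort(key=lambda o: (-(o.orf_end - o.orf_start), o.orf_start))
    return orfs


def predict_all_orfs(
    sequences: dict[str, str], min_codons: int = 100
) -> pd.DataFrame:
    rows = []
    for tid, seq in sequences.items():
        for orf in predict_orfs(seq, min_codons=min_codons, transcript_id=tid):
            rows.append((tid, orf.orf_start, orf.orf_end, orf.frame))
    return pd.DataFrame(
        rows, columns=["transcript_id", "orf_start", "orf_end", "frame"]
    )


def filter_single_orf(
    transcript_ids: Iterable[str], orfs: pd.DataFrame
) -> set[str]:
    """Transcripts with exactly one predicted ORF.

    Multi-ORF transcripts would give ambiguous SNP annotations and are
    dropped; zero-ORF transcripts are also excluded (their SNPs have no
    coding reference to classify against).
    """
    counts = orfs.groupby("transcript_id").size()
    return {t for t in transcript_ids if counts.get(t, 0) == 1}


def classify_snp(
    transcript_seq: str, orf: OrfAnnotation, pos: int, ref: str, alt: str
) -> str:
    """Classify a single-nucleotide substitution against one ORF."""
    seq = transcript_seq.upper()
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"ambiguous or non-SNP alleles {ref}>{alt}")
    if not (0 <= pos < len(seq)):
        raise ValueError(f"position {pos} outside transcript (len {len(seq)})")
    if seq[pos] != ref:
        raise ValueError(
            f"reference mismatch at position {pos}: transcript has "
            f"{seq[pos]}, variant claims {ref}"
        )
    if pos < orf.orf_start or pos >= orf.orf_end:
        return "oCDS"
    offset = pos - orf.orf_start
    cstart = orf.orf_start + 3 * (offset // 3)
    codon = seq[cstart : cstart + 3]
    within = pos - cstart
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_ref, aa_alt = CODON_TO_AA[codon], CODON_TO_AA[mutated]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref == "*" or aa_alt == "*":
        return "nonsense"
    return "nonsynonymous"


def classify_table(
    sequences: dict[str, str], orfs: pd.DataFrame, loci: pd.DataFrame
) -> pd.DataFrame:
    """Classify a locus table (transcript_id, pos, ref, alt) against the
    single ORF of each transcript; loci on excluded transcripts get
    class NA."""
    keep = filter_single_orf(sequences.keys(), orfs)
    orf_of = {
        r.transcript_id: OrfAnnotation(
            r.transcript_id, int(r.orf_start), int(r.orf_end), int(r.frame)
        )
        for r in orfs.itertuples()
        if r.transcript_id in keep
    }
    classes = []
    for r in loci.itertuples():
        orf = orf_of.get(r.transcript_id)
        if orf is None:
            classes.append(None)
        else:
            classes.append(
                classify_snp(sequences[r.transcript_id], orf, int(r.pos), r.ref, r.alt)
            )
    out = loci.copy()
    out["effect_class"] = classes
    return out


@dataclass
class EffectCounts:
    """Tallies of SNP effect classes.

    ``kN`` excludes nonsense (stop-gain / stop-loss) variants, which are
    tallied separately.
    """

    kN: int = 0
    kS: int = 0
    nonsense: int = 0
    oCDS: int = 0

    @property
    def cds_total(self) -> int:
        return self.kN + self.kS + self.nonsense

    @property
    def ratio(self) -> float | None:
        """kN/kS count ratio, rounded to 3 decimals; None when kS == 0."""
        if self.kS == 0:
            return None
        return round(self.kN / self.kS, 3)


def count_effects(classes: Iterable[str]) -> EffectCounts:
    tally = Counter(classes)
    unknown = set(tally) - set(EFFECT_CLASSES)
    if unknown:
        raise ValueError(f"unclassified SNPs present: {sorted(unknown)}")
    return EffectCounts(
        kN=tally.get("nonsynonymous", 0),
        kS=tally.get("synonymous", 0),
        nonsense=tally.get("nonsense", 0),
        oCDS=tally.get("oCDS", 0),
    )


def compare_knks(
    adaptive: EffectCounts, neutral: EffectCounts, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 [set] x [kN, kS] table.

    Returns ``(chi2, df, p)``.  Continuity correction is off by default
    (plain Pearson test).
    """
    table = [[adaptive.kN, adaptive.kS], [neutral.kN, neutral.kS]]
    if min(sum(row) for row in table) == 0 or min(
        table[0][j] + table[1][j] for j in range(2)
    ) == 0:
        raise ValueError(
            "zero margin in kN/kS contingency table; use an exact test"
        )
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)
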