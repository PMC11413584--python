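"""Core in-memory containers for the pipeline.

Genotypes are held as a dense samples x loci integer matrix with values
0/1/2 = count of the alternate allele and ``MISSING`` (-1) for no-calls.
All positions are 0-based half-open internally; VCF files on disk are
1-based (the conversion happens at the I/O boundary only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Never enters arithmetic.
MISSING: int = -1

VALID_BASES = frozenset("ACGT")

REGIONS = ("NE", "SE", "S")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of samples.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_loci)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    sample_ids, locus_ids
        Unique string identifiers for rows and columns.
    chrom
        Per-locus chromosome / transcript id (GBS tags use the locus id
        itself).
    pos
        Per-locus 0-based position on ``chrom``.
    ref, alt
        Single-nucleotide reference and alternate alleles per locus.
    base_quality
        Optional per-locus phred-scaled variant quality (VCF QUAL).
    dp4_alt
        Optional per-locus alternate-allele read coverage summed over
        strands (the DP4 alt forward + reverse counts).
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    base_quality: np.ndarray | None = None
    dp4_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x loci)")
        self.sample_ids = list(map(str, self.sample_ids))
        self.locus_ids = list(map(str, self.locus_ids))
        self.chrom = list(map(str, self.chrom))
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        for name, arr in (
            ("locus_ids", self.locus_ids),
            ("chrom", self.chrom),
            ("pos", self.pos),
            ("ref", self.ref),
            ("alt", self.alt),
        ):
            if len(arr) != m:
                raise ValueError(f"{name} length mismatch ({len(arr)} != {m})")
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.locus_ids, "locus_ids")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"invalid genotype values: {np.unique(self.genotypes[bad])}"
            )
        for allele_arr, what in ((self.ref, "ref"), (self.alt, "alt")):
            bad_alleles = set(allele_arr) - VALID_BASES
            if bad_alleles:
                raise ValueError(f"non-ACGT {what} allele(s): {bad_alleles}")
        if np.any(self.ref == self.alt):
            raise ValueError("ref == alt at some loci (not biallelic)")
        for name in ("base_quality", "dp4_alt"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (m,):
                    raise ValueError(f"{name} must have one value per locus")
                setattr(self, name, v)

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    # -- derived per-locus quantities ----------------------------------
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.genotypes != MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls.

        Loci with no calls give ``nan``.
        """
        called = self.called()
        alt_copies = np.where(called, self.genotypes, 0).sum(axis=0)
        copies = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt_copies / np.maximum(copies, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (~self.called()).mean(axis=0)

    # -- subsetting ----------------------------------------------------
    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index],
            sample_ids=self.sample_ids,
            locus_ids=[self.locus_ids[i] for i in index],
            chrom=[self.chrom[i] for i in index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            base_quality=None if self.base_quality is None else self.base_quality[index],
            dp4_alt=None if self.dp4_alt is None else self.dp4_alt[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            genotypes=self.genotypes[index, :],
            sample_ids=[self.sample_ids[i] for i in index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and self.chrom == other.chrom
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample map (columns sample_id, locality, region).

    Every sample must appear once and every locality must map to exactly
    one region.
    """
    required = {"sample_id", "locality", "region"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"sample map missing columns: {sorted(missing_cols)}")
    _check_unique(list(meta["sample_id"]), "sample_id")
    per_loc = meta.groupby("locality")["region"].nunique()
    bad = per_loc[per_loc > 1]
    if len(bad):
        raise ValueError(
            f"localities mapped to multiple regions: {list(bad.index)}"
        )
    return meta.reset_index(drop=True)


def validate_env_table(env: pd.DataFrame) -> pd.DataFrame:
    """Validate a locality x predictor table (index = locality)."""
    if env.index.has_duplicates:
        dup = env.index[env.index.duplicated()].tolist()
        raise ValueError(f"duplicate locality rows in env table: {dup}")
    values = env.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = env.columns[~np.isfinite(values).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in env predictors: {bad}")
    return env


@dataclass
class TranscriptSet:
    """Assembled transcripts plus (optional) ORF annotations.

    ``orfs`` is a DataFrame with columns transcript_id, orf_start,
    orf_end (0-based half-open, stop codon included), frame.
    """

    sequences: dict[str, str]
    orfs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for tid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for transcript {tid}")
            extra = set(seq.upper()) - set("ACGTN")
            if extra:
                raise ValueError(f"invalid bases in {tid}: {extra}")
        if self.orfs is not None:
            unknown = set(self.orfs["transcript_id"]) - set(self.sequences)
            if unknown:
                raise ValueError(f"ORFs for unknown transcripts: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.sequences)


def pops_as_array(
    gm: GenotypeMatrix, meta: pd.DataFrame, column: str = "locality"
) -> np.ndarray:
    """Align the sample map to ``gm`` sample order; return labels per sample."""
    lookup: Mapping[str, str] = dict(zip(meta["sample_id"], meta[column]))
    missing = [s for s in gm.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples absent from sample map: {missing[:5]}")
    return np.array([lookup[s] for s in gm.sample_ids])
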