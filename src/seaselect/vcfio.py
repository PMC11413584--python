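"""Readers and writers for the formats the pipeline touches.

VCF handling goes through :mod:`pysam`; coordinates are converted to the
package's internal 0-based half-open convention at this boundary.
Multiallelic and non-SNP records are dropped with a logged count (the
analyses operate on biallelic SNPs only).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .types import (
    MISSING,
    GenotypeMatrix,
    TranscriptSet,
    validate_env_table,
    validate_sample_metadata,
)

log = logging.getLogger(__name__)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required) into a :class:`GenotypeMatrix`.

    QUAL is captured as per-locus ``base_quality``.  If the INFO field
    carries ``DP4`` (4 strand/allele read counts) the alternate-allele
    coverage (forward + reverse) is captured as ``dp4_alt``; a scalar
    DP4 is taken as the alt coverage directly.  Indels and multiallelic
    records are skipped (counts logged).
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    # DP4 = raw 4-count strand field; DP4A = pre-summed alt coverage
    dp4_key = next((k for k in ("DP4", "DP4A") if k in vf.header.info), None)
    gts: list[np.ndarray] = []
    locus_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    dp4s: list[float] = []
    any_qual = False
    any_dp4 = False
    n_skipped_multi = 0
    n_skipped_indel = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped_multi += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "N" or alt == "N":
            n_skipped_indel += 1
            continue
        row = np.full(len(samples), MISSING, dtype=np.int16)
        for i, s in enumerate(samples):
            alleles = rec.samples[s].get("GT")
            if alleles is None or any(a is None for a in alleles):
                continue
            row[i] = int(sum(alleles))
        gts.append(row)
        locus_ids.append(
            rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        )
        chroms.append(rec.chrom)
        poss.append(rec.start)  # pysam .start is already 0-based
        refs.append(ref)
        alts.append(alt)
        if rec.qual is not None:
            any_qual = True
            quals.append(float(rec.qual))
        else:
            quals.append(np.nan)
        dp4 = rec.info.get(dp4_key) if dp4_key else None
        if dp4 is not None:
            any_dp4 = True
            if isinstance(dp4, (tuple, list)):
                dp4s.append(float(dp4[-2] + dp4[-1]) if len(dp4) == 4 else float(sum(dp4)))
            else:
                dp4s.append(float(dp4))
        else:
            dp4s.append(np.nan)
    vf.close()
    if n_skipped_multi or n_skipped_indel:
        log.warning(
            "skipped %d multiallelic and %d non-SNP records in %s",
            n_skipped_multi, n_skipped_indel, path,
        )
    n_loci = len(gts)
    genotypes = (
        np.stack(gts, axis=1) if n_loci else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(
        genotypes=genotypes,
        sample_ids=samples,
        locus_ids=locus_ids,
        chrom=chroms,
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype="U1"),
        alt=np.asarray(alts, dtype="U1"),
        base_quality=np.asarray(quals) if any_qual else None,
        dp4_alt=np.asarray(dp4s) if any_dp4 else None,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write ``gm`` as an uncompressed VCF v4.2 with per-sample GT.

    ``read_vcf(write_vcf(gm))`` reproduces genotypes, ids, positions and
    alleles exactly.
    """
    header = pysam.VariantHeader()
    for contig in dict.fromkeys(gm.chrom):
        header.contigs.add(contig)
    header.info.add("DP4A", 1, "Integer", "Alt-allele coverage (DP4 fwd+rev)")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.sample_ids:
        header.add_sample(s)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(gm.n_loci):
            rec = out.new_record(
                contig=gm.chrom[j],
                start=int(gm.pos[j]),
                stop=int(gm.pos[j]) + 1,
                alleles=(str(gm.ref[j]), str(gm.alt[j])),
                id=gm.locus_ids[j],
            )
            if gm.base_quality is not None and np.isfinite(gm.base_quality[j]):
                rec.qual = float(gm.base_quality[j])
            if gm.dp4_alt is not None and np.isfinite(gm.dp4_alt[j]):
                rec.info["DP4A"] = int(gm.dp4_alt[j])
            for i, s in enumerate(gm.sample_ids):
                rec.samples[s]["GT"] = gt_codes[int(gm.genotypes[i, j])]
            out.write(rec)


def read_sample_map(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_metadata(meta)


def write_sample_map(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    env = pd.read_csv(path, index_col="locality")
    return validate_env_table(env)


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, index_label="locality")


def read_orf_table(path: str | Path) -> pd.DataFrame:
    orfs = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "orf_start", "orf_end", "frame"}
    missing = required - set(orfs.columns)
    if missing:
        raise ValueError(f"ORF table missing columns: {sorted(missing)}")
    return orfs


def write_orf_table(orfs: pd.DataFrame, path: str | Path) -> None:
    orfs.to_csv(path, sep="\t", index=False)


def read_tables(
    sample_map_path: str | Path,
    env_path: str | Path,
    orf_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and cross-validate the sample map, env table and ORF table.

    Every locality in the sample map must have an env-table row.
    """
    meta = read_sample_map(sample_map_path)
    env = read_env_table(env_path)
    unknown = sorted(set(meta["locality"]) - set(env.index.astype(str)))
    if unknown:
        raise ValueError(
            f"sample-map localities absent from env table: {unknown}"
        )
    orfs = read_orf_table(orf_path) if orf_path is not None else None
    return meta, env, orfs


def read_fasta(path: str | Path) -> TranscriptSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return TranscriptSet(sequences=seqs)


def write_fasta(ts: TranscriptSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, seq in ts.sequences.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
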