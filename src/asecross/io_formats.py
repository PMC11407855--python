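"""Readers and writers for the minimal file dialects the pipeline touches.

Coordinate conventions are enforced here and nowhere else: VCF positions are
1-based, BED-like gene/interval files are 0-based half-open.  Only biallelic
SNPs are supported end to end; multi-allelic or indel VCF rows are dropped
with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Chromosome-arm universe (An. gambiae nomenclature) plus a catch-all bucket.
ARMS = ("2L", "2R", "3L", "3R", "X")
ARM_OTHER = "other"
AUTOSOMES = ("2L", "2R", "3L", "3R")

#: Fixed column order of the gene-level results table (bit-stable for diffing).
RESULT_COLUMNS = [
    "cross_id", "gene_id", "n_snps", "maf", "maternal_fraction",
    "p_ase", "p_het", "q_ase", "q_het", "direction",
]

COUNT_COLUMNS = ["sample", "chrom", "pos", "gene_id", "count_a", "count_b", "phase_known"]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP site with diploid calls for a set of individuals.

    ``genotypes`` maps individual id to an unordered pair of allele indices
    (0 = ref, 1 = alt) or ``None`` for a missing call.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("allele strings must be non-empty")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval on a chromosome arm (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    arm: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start} >= {self.end})")
        if self.arm not in ARMS + (ARM_OTHER,):
            raise ValueError(f"{self.gene_id}: unknown arm label {self.arm!r}")
        if self.arm != ARM_OTHER and self.arm != self.chrom:
            raise ValueError(f"{self.gene_id}: arm {self.arm!r} inconsistent with chrom {self.chrom!r}")


@dataclass(frozen=True)
class IntervalRecord:
    """A labelled genomic interval (0-based half-open), e.g. a swept region or CRM."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end ({self.start} >= {self.end})")


@dataclass(frozen=True)
class CountTableRow:
    """Allelic read counts at one exonic SNP of one gene in one sample/cross."""

    sample: str
    chrom: str
    pos: int
    gene_id: str
    count_a: int
    count_b: int
    phase_known: bool

    def __post_init__(self):
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("allelic counts must be non-negative")


# ---------------------------------------------------------------------------
# VCF


def read_vcf_subset(path, individuals: Optional[Sequence[str]] = None) -> list[VariantRecord]:
    """Read biallelic SNP records (GT only) from a VCF 4.x file.

    Multi-allelic and indel rows are dropped (count logged).  Requesting an
    individual absent from the header raises ``ValueError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if individuals is None:
        individuals = samples
    else:
        missing = [i for i in individuals if i not in samples]
        if missing:
            raise ValueError(f"individuals absent from VCF header: {missing}")
    idx = [samples.index(i) for i in individuals]

    records: list[VariantRecord] = []
    n_dropped = 0
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        try:
            raw = v.genotypes
        except Exception as exc:  # pragma: no cover - cyvcf2 internal failure
            raise ValueError(f"malformed VCF record #{line_no} at {v.CHROM}:{v.POS}") from exc
        gts = {}
        for ind, j in zip(individuals, idx):
            a, b = raw[j][0], raw[j][1]
            if a < 0 or b < 0:
                gts[ind] = None
            elif a > 1 or b > 1:
                raise ValueError(
                    f"allele index out of range at {v.CHROM}:{v.POS} for {ind}")
            else:
                gts[ind] = (a, b)
        records.append(VariantRecord(v.CHROM, v.POS, v.REF, v.ALT[0], gts))
    if n_dropped:
        logger.info("read_vcf_subset: dropped %d non-biallelic-SNP rows from %s", n_dropped, path)
    return records


def write_vcf_subset(records: Sequence[VariantRecord], individuals: Sequence[str], path) -> None:
    """Write records as a minimal uncompressed VCF 4.2 with GT-only calls."""
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(individuals) + "\n")
        for r in records:
            calls = []
            for ind in individuals:
                gt = r.genotypes.get(ind)
                calls.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# BED-like tables


def read_gene_annotation(path) -> list[GeneModel]:
    """Read a 5-column BED-like TSV: chrom, start, end, gene_id, arm."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{line_no}: expected 5 columns, got {len(fields)}")
            chrom, start, end, gene_id, arm = fields[:5]
            try:
                genes.append(GeneModel(gene_id, chrom, int(start), int(end), arm))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from exc
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.arm}\n")


def read_bed_intervals(path) -> list[IntervalRecord]:
    """Read labelled intervals from a BED TSV (chrom, start, end[, label])."""
    out: list[IntervalRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >=3 columns")
            label = fields[3] if len(fields) > 3 else f"iv{line_no}"
            try:
                out.append(IntervalRecord(fields[0], int(fields[1]), int(fields[2]), label))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from exc
    return out


def write_bed_intervals(intervals: Sequence[IntervalRecord], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# Count and result tables


def read_count_table(path) -> pd.DataFrame:
    """Read a per-SNP allelic count TSV.

    Columns: sample, chrom, pos, gene_id, count_a, count_b, phase_known.
    ``count_a`` is the maternal allele when ``phase_known`` is true, otherwise
    an arbitrary but consistent allele (reference-like).
    """
    df = pd.read_csv(path, sep="\t")
    for col in COUNT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df[COUNT_COLUMNS].copy()
    if (df["count_a"] < 0).any() or (df["count_b"] < 0).any():
        raise ValueError(f"{path}: negative allelic counts")
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    df["count_a"] = df["count_a"].astype(int)
    df["count_b"] = df["count_b"].astype(int)
    df["phase_known"] = df["phase_known"].astype(int).astype(bool)
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    out = df[COUNT_COLUMNS].copy()
    out["phase_known"] = out["phase_known"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write the gene-level ASE results table with the fixed column order."""
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[RESULT_COLUMNS]


def read_copy_number(path) -> pd.DataFrame:
    """Read a long-format copy-number TSV: gene_id, individual, copy_number."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "individual", "copy_number"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["copy_number"] < 0).any():
        raise ValueError(f"{path}: negative copy numbers")
    return df


def write_copy_number(df: pd.DataFrame, path) -> None:
    df[["gene_id", "individual", "copy_number"]].to_csv(path, sep="\t", index=False)


def read_presence_absence(path) -> pd.DataFrame:
    """Read a gene x taxon presence/absence matrix (TSV, gene_id index, 0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError(f"{path}: presence/absence matrix must be 0/1")
    return df.astype(int)


def write_presence_absence(df: pd.DataFrame, path) -> None:
    df.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def read_tree(path):
    """Read a rooted Newick species tree (dendropy.Tree)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
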