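"""Readers and writers for the external representations the pipeline touches.

All on-disk formats are plain text (gzip-transparent): a long-form
allele-count TSV, a minimal VCF or TSV SNP table, BED6 gene annotation,
bedGraph coverage, and the result TSVs.  Internally coordinates are 0-based
half-open; conversion to/from 1-based (VCF, pileup) happens only at the I/O
boundary, and SNP positions are stored 1-based in :class:`SnpLocus` because
every consumer in the pipeline addresses single bases by their VCF position.
Alleles are always expressed on the reference strand; the strand of a read
observation refers to the alignment strand.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
STRANDS = ("+", "-")

ALLELE_COUNT_COLUMNS = [
    "cell_id",
    "chrom",
    "pos",
    "nt",
    "strand",
    "count",
    "max_dup_frac",
]

STAGES = ("oocyte", "2cell", "4cell", "8cell", "TE", "ICM", "epiblast", "ES")


class FormatError(ValueError):
    """A file failed schema or content validation."""


@dataclass(frozen=True)
class SnpLocus:
    """An annotated SNP position (1-based, as in VCF/dbSNP).

    ``tx_strand`` is the transcribed strand per the gene annotation:
    '+' or '-', or 'conflict' when annotation supports transcription of
    both strands at this position (such loci fail locus selection).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str = ""
    tx_strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"SNP position must be >= 1, got {self.pos}")
        for name, nt in (("ref", self.ref), ("alt", self.alt)):
            if nt not in NUCLEOTIDES:
                raise FormatError(f"{name} allele {nt!r} is not one of A/C/G/T")
        if self.ref == self.alt:
            raise FormatError(
                f"ref and alt alleles identical ({self.ref}) at {self.chrom}:{self.pos}"
            )
        if self.tx_strand not in ("+", "-", "conflict"):
            raise FormatError(f"invalid tx_strand {self.tx_strand!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class CellMeta:
    """Identity of one sequenced cell."""

    cell_id: str
    embryo_id: str
    stage: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.is_control and self.embryo_id:
            raise FormatError("control cells carry no embryo pairing")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# allele-count TSV
# ---------------------------------------------------------------------------

def read_allele_counts(path) -> pd.DataFrame:
    """Read the long-form allele-count table.

    Columns: cell_id, chrom, pos (1-based), nt, strand (+/-), count,
    max_dup_frac (largest fraction of reads supporting ``nt`` that share one
    identical alignment position, pooled over strands).

    Raises :class:`FormatError` naming the offending line for malformed rows.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ALLELE_COUNT_COLUMNS:
            raise FormatError(
                f"{path}: bad header {header!r}; expected {ALLELE_COUNT_COLUMNS}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(ALLELE_COUNT_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(ALLELE_COUNT_COLUMNS)} columns, got {len(parts)}")
            cell_id, chrom, pos, nt, strand, count, dup = parts
            try:
                pos_i = int(pos)
                count_i = int(count)
                dup_f = float(dup)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if count_i < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count_i}")
            if nt not in NUCLEOTIDES:
                raise FormatError(f"{path}:{lineno}: unknown nucleotide {nt!r}")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if not (0.0 <= dup_f <= 1.0):
                raise FormatError(f"{path}:{lineno}: max_dup_frac {dup_f} outside [0,1]")
            rows.append((cell_id, chrom, pos_i, nt, strand, count_i, dup_f))
    return pd.DataFrame(rows, columns=ALLELE_COUNT_COLUMNS)


def write_allele_counts(df: pd.DataFrame, path) -> None:
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"allele-count table missing columns {missing}")
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, columns=ALLELE_COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# SNP tables (VCF-like and TSV dialects)
# ---------------------------------------------------------------------------

def read_snp_table(path, dialect: str = "tsv") -> dict[tuple[str, int], SnpLocus]:
    """Parse a SNP annotation table into ``{(chrom, pos): SnpLocus}``.

    dialect 'vcf': a minimal plain-text VCF (CHROM/POS/REF/ALT used; no
    INFO/FORMAT interpretation).  dialect 'tsv': header
    chrom/pos/ref/alt[/gene_id/tx_strand].  Duplicate (chrom, pos) entries
    are rejected in both dialects.
    """
    if dialect == "vcf":
        loci = _read_snp_vcf(path)
    elif dialect == "tsv":
        loci = _read_snp_tsv(path)
    else:
        raise ValueError(f"unknown SNP table dialect {dialect!r}")
    out: dict[tuple[str, int], SnpLocus] = {}
    for locus in loci:
        if locus.key in out:
            raise FormatError(
                f"duplicate SNP entry at {locus.chrom}:{locus.pos} in {path}"
            )
        out[locus.key] = locus
    return out


def _read_snp_vcf(path) -> list[SnpLocus]:
    import pysam

    loci = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            loci.append(SnpLocus(chrom=rec.chrom, pos=rec.pos,
                                 ref=rec.ref, alt=rec.alts[0]))
    return loci


def _read_snp_tsv(path) -> list[SnpLocus]:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SNP TSV must have columns {sorted(required)}")
    loci = []
    for row in df.itertuples(index=False):
        loci.append(SnpLocus(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene_id=str(getattr(row, "gene_id", "") or ""),
            tx_strand=str(getattr(row, "tx_strand", "+") or "+"),
        ))
    return loci


def write_snp_vcf(loci: Iterable[SnpLocus], path) -> None:
    """Write a minimal VCF (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({l.chrom for l in loci})
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for l in sorted(loci, key=lambda l: (l.chrom, l.pos)):
            fh.write(f"{l.chrom}\t{l.pos}\t.\t{l.ref}\t{l.alt}\t.\t.\t.\n")


def write_snp_tsv(loci: Iterable[SnpLocus], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("chrom\tpos\tref\talt\tgene_id\ttx_strand\n")
        for l in sorted(loci, key=lambda l: (l.chrom, l.pos)):
            fh.write(f"{l.chrom}\t{l.pos}\t{l.ref}\t{l.alt}\t{l.gene_id}\t{l.tx_strand}\n")


# ---------------------------------------------------------------------------
# BED-lite gene annotation and locus annotation
# ---------------------------------------------------------------------------

def read_bed_genes(path) -> pd.DataFrame:
    """Read BED6 (chrom, start, end, name, score, strand); 0-based half-open."""
    with _open_text(path) as fh:
        df = pd.read_csv(
            fh, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise FormatError(f"{path}: BED interval with end <= start at {bad['chrom']}:{bad['start']}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: BED strand column must be + or -")
    return df


def write_bed_genes(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, header=False,
                  columns=["chrom", "start", "end", "name", "score", "strand"])


def annotate_loci(
    loci: Mapping[tuple[str, int], SnpLocus], genes: pd.DataFrame
) -> dict[tuple[str, int], SnpLocus]:
    """Assign gene_id and transcribed strand to each SNP from BED annotation.

    A SNP covered by genes on both strands gets tx_strand='conflict'; a SNP
    covered by no gene keeps its existing annotation.
    """
    out = {}
    for key, locus in loci.items():
        chrom, pos = key
        start0 = pos - 1  # BED is 0-based half-open
        hits = genes[(genes["chrom"] == chrom)
                     & (genes["start"] <= start0) & (start0 < genes["end"])]
        if len(hits) == 0:
            out[key] = locus
            continue
        strands = set(hits["strand"])
        tx = "conflict" if len(strands) > 1 else strands.pop()
        out[key] = SnpLocus(chrom=chrom, pos=pos, ref=locus.ref, alt=locus.alt,
                            gene_id=";".join(sorted(set(hits["name"]))), tx_strand=tx)
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> pd.DataFrame:
    """Read bedGraph (chrom, start, end, value); 0-based half-open."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    if (df["value"] < 0).any():
        raise FormatError(f"{path}: negative coverage value")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, header=False,
                  columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

RESULT_STAGES = ("ase", "ai", "utr", "summary")


def write_results(tables: Mapping[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write the per-locus ASE table, AI table, UTR predictions and the
    per-cell summary.  Refuses partial results, naming the missing stage."""
    missing = [s for s in RESULT_STAGES if s not in tables]
    if missing:
        raise FormatError(f"incomplete results: missing stage(s) {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stage in RESULT_STAGES:
        path = outdir / f"{stage}.tsv"
        tables[stage].to_csv(path, sep="\t", index=False)
        paths[stage] = path
    return paths
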