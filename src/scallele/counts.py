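"""Strand-resolved allele counting and locus selection.

A :class:`StrandedAlleleCounts` records, for one (cell, SNP) pair, how many
uniquely aligned reads supported each nucleotide on each alignment strand,
plus per-nucleotide PCR-duplicate bookkeeping (the largest fraction of a
nucleotide's supporting reads that share one identical alignment position).

Loci enter the allelic analysis only when they pass five criteria:

1. the sequence data shows more than one nucleotide at the position;
2. the observed non-reference nucleotide is the annotated (dbSNP) alt allele;
3. coverage is at least ``min_coverage`` (default 25) uniquely aligned reads;
4. for every observed nucleotide, no more than ``max_dup_frac`` (default 50%)
   of its supporting reads align to one identical position (PCR replication);
5. the annotation supports transcription of only one strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io import NUCLEOTIDES, STRANDS, SnpLocus


@dataclass
class StrandedAlleleCounts:
    """Per (cell, locus) nucleotide counts split by alignment strand."""

    cell_id: str
    chrom: str
    pos: int  # 1-based
    counts: dict = field(default_factory=dict)          # (nt, strand) -> int
    dup_modal_frac: dict = field(default_factory=dict)  # nt -> float in [0,1]

    def count(self, nt: str, strand: str | None = None) -> int:
        if strand is None:
            return sum(self.counts.get((nt, s), 0) for s in STRANDS)
        return self.counts.get((nt, strand), 0)

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    def observed_nts(self) -> list[str]:
        """Nucleotides with at least one supporting read, most frequent first."""
        totals = {nt: self.count(nt) for nt in NUCLEOTIDES if self.count(nt) > 0}
        return sorted(totals, key=lambda nt: (-totals[nt], nt))

    def ref_alt(self, locus: SnpLocus) -> tuple[int, int]:
        """Strand-summed counts of the two annotated alleles."""
        return self.count(locus.ref), self.count(locus.alt)


@dataclass(frozen=True)
class LocusFilterResult:
    criterion1: bool  # multiple nucleotides observed
    criterion2: bool  # observed non-reference nucleotide is the dbSNP alt
    criterion3: bool  # coverage >= min_coverage
    criterion4: bool  # duplicate-position fraction <= max_dup_frac per allele
    criterion5: bool  # single transcribed strand

    @property
    def passed(self) -> bool:
        return (self.criterion1 and self.criterion2 and self.criterion3
                and self.criterion4 and self.criterion5)


# cell_id -> (chrom, pos) -> StrandedAlleleCounts
CountsByCell = dict[str, dict[tuple[str, int], StrandedAlleleCounts]]


def count_alleles(
    observations: Iterable[tuple],
    loci: Mapping[tuple[str, int], SnpLocus],
) -> CountsByCell:
    """Tally pileup-style read observations into stranded counts per locus.

    ``observations`` yields (cell_id, chrom, pos, nt, strand, aln_start)
    tuples, one per read overlapping a SNP.  Observations at positions not in
    ``loci`` are ignored.  ``dup_modal_frac`` per nucleotide is the size of
    the largest identical-``aln_start`` group among that nucleotide's reads
    (strands pooled), divided by its read count.
    """
    tallies: dict[tuple[str, str, int], dict] = {}
    for cell_id, chrom, pos, nt, strand, aln_start in observations:
        if (chrom, pos) not in loci:
            continue
        if nt not in NUCLEOTIDES or strand not in STRANDS:
            raise ValueError(f"bad observation ({nt!r}, {strand!r}) at {chrom}:{pos}")
        key = (cell_id, chrom, pos)
        entry = tallies.setdefault(key, {"counts": Counter(), "starts": defaultdict(Counter)})
        entry["counts"][(nt, strand)] += 1
        entry["starts"][nt][aln_start] += 1

    out: CountsByCell = defaultdict(dict)
    for (cell_id, chrom, pos), entry in tallies.items():
        dup = {nt: max(starts.values()) / sum(starts.values())
               for nt, starts in entry["starts"].items()}
        out[cell_id][(chrom, pos)] = StrandedAlleleCounts(
            cell_id=cell_id, chrom=chrom, pos=pos,
            counts=dict(entry["counts"]), dup_modal_frac=dup)
    return dict(out)


def counts_from_frame(df: pd.DataFrame) -> CountsByCell:
    """Build stranded counts from the long-form allele-count table."""
    out: CountsByCell = defaultdict(dict)
    for (cell_id, chrom, pos), group in df.groupby(["cell_id", "chrom", "pos"], sort=False):
        counts = {}
        dup = {}
        for row in group.itertuples(index=False):
            if row.count > 0:
                counts[(row.nt, row.strand)] = counts.get((row.nt, row.strand), 0) + row.count
                dup[row.nt] = float(row.max_dup_frac)
        out[cell_id][(chrom, int(pos))] = StrandedAlleleCounts(
            cell_id=cell_id, chrom=chrom, pos=int(pos), counts=counts, dup_modal_frac=dup)
    return dict(out)


def counts_to_frame(counts: CountsByCell) -> pd.DataFrame:
    """Inverse of :func:`counts_from_frame` (zero-count rows dropped)."""
    rows = []
    for cell_id in sorted(counts):
        for (chrom, pos) in sorted(counts[cell_id]):
            sac = counts[cell_id][(chrom, pos)]
            for nt in NUCLEOTIDES:
                for strand in STRANDS:
                    c = sac.counts.get((nt, strand), 0)
                    if c > 0:
                        rows.append((cell_id, chrom, pos, nt, strand, c,
                                     round(sac.dup_modal_frac.get(nt, 0.0), 6)))
    from .io import ALLELE_COUNT_COLUMNS
    return pd.DataFrame(rows, columns=ALLELE_COUNT_COLUMNS)


def select_loci(
    counts: StrandedAlleleCounts,
    locus: SnpLocus,
    min_coverage: int = 25,
    max_dup_frac: float = 0.5,
) -> LocusFilterResult:
    """Evaluate the five locus-selection criteria (pure predicate).

    Criterion 2 is evaluated on the most frequent non-reference nucleotide:
    if any nucleotide other than ref is observed, the top one must equal the
    annotated alt.  Third/fourth nucleotides count toward coverage but are
    never part of ratios.
    """
    if (counts.chrom, counts.pos) != locus.key:
        raise ValueError("counts do not belong to locus")
    observed = counts.observed_nts()
    c1 = len(observed) >= 2
    non_ref = [nt for nt in observed if nt != locus.ref]
    c2 = (len(non_ref) == 0) or (non_ref[0] == locus.alt)
    c3 = counts.coverage >= min_coverage
    c4 = all(frac <= max_dup_frac for frac in counts.dup_modal_frac.values())
    c5 = locus.tx_strand != "conflict"
    return LocusFilterResult(c1, c2, c3, c4, c5)


def minor_allele_frequency(counts: StrandedAlleleCounts, locus: SnpLocus) -> float:
    """min(ref, alt) / (ref + alt) over strand-summed annotated-allele counts.

    Raw counts, no pseudocount; undefined (error) at zero allele coverage.
    """
    ref, alt = counts.ref_alt(locus)
    total = ref + alt
    if total == 0:
        raise ValueError(f"no annotated-allele coverage at {locus.chrom}:{locus.pos}")
    return min(ref, alt) / total


def allelic_ratio(
    counts: StrandedAlleleCounts, locus: SnpLocus, pseudocount: int = 1
) -> float:
    """(ref + pseudocount) / (alt + pseudocount); the +1 avoids singularities
    at loci where one allele is unobserved."""
    ref, alt = counts.ref_alt(locus)
    if ref + alt == 0:
        raise ValueError(f"no annotated-allele coverage at {locus.chrom}:{locus.pos}")
    return (ref + pseudocount) / (alt + pseudocount)


def raw_allelic_ratio(counts: StrandedAlleleCounts, locus: SnpLocus) -> float:
    """ref / alt with no pseudocount; requires alt > 0."""
    ref, alt = counts.ref_alt(locus)
    if alt == 0:
        raise ValueError("raw allelic ratio undefined with zero alt reads")
    return ref / alt
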