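"""Allele-specific expression calling against an empirical strand-balance null.

Double-strand cDNA synthesis gives every allele two complementary
observables: reads aligning to the + strand and reads aligning to the -
strand.  For a heterozygous SNP let a1/b1 be the ref-allele read counts on
the +/- strands and a2/b2 the alt-allele counts.  The strand-balance
statistic

    B = (a1 + b2 + 1) / (a2 + b1 + 1)

mixes the two alleles across the two strands, so it equals 1 in expectation
whatever the true allelic skew; deviations of B from 1 measure pure
library/instrument bias.  The distribution D of log2(B) over all
heterozygous loci of one cell is therefore an empirical null for that
cell's log2 allelic ratios: a locus's two-tailed rank p-value against D
tests H0 "balanced allelic expression" while absorbing the cell's technical
noise.  Loci with p < 0.01 are called ASE.

The +1 pseudocount mirrors the allelic-ratio convention and guards the
B statistic against division by zero.  The two-tailed test is centred at
the median of D, absorbing any residual global reference bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .counts import StrandedAlleleCounts, allelic_ratio
from .io import SnpLocus

logger = logging.getLogger(__name__)

MIN_NULL_LOCI = 50


@dataclass
class BalanceDistribution:
    """Per-cell empirical distribution of log2 strand-balance values."""

    cell_id: str
    values: np.ndarray  # log2(B) per heterozygous locus
    center: float       # median of values

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AseCall:
    cell_id: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    log2_ratio: float  # pseudocounted
    p_value: float
    is_ase: bool


def strand_balance(counts: StrandedAlleleCounts, locus: SnpLocus) -> float:
    """B = (a1 + b2 + 1)/(a2 + b1 + 1): ref(+) with alt(-) over alt(+) with
    ref(-).  Equals 1 for unbiased strands regardless of allelic skew."""
    a1 = counts.count(locus.ref, "+")
    b1 = counts.count(locus.ref, "-")
    a2 = counts.count(locus.alt, "+")
    b2 = counts.count(locus.alt, "-")
    return (a1 + b2 + 1) / (a2 + b1 + 1)


def build_balance_distribution(
    het_counts: Iterable[tuple[StrandedAlleleCounts, SnpLocus]],
    cell_id: str | None = None,
) -> BalanceDistribution:
    """Empirical null from all heterozygous loci of one cell."""
    values = []
    cid = cell_id
    for counts, locus in het_counts:
        if cid is None:
            cid = counts.cell_id
        elif cell_id is None and counts.cell_id != cid:
            raise ValueError("balance distribution mixes cells "
                             f"({cid!r} and {counts.cell_id!r})")
        values.append(math.log2(strand_balance(counts, locus)))
    if len(values) < MIN_NULL_LOCI:
        raise ValueError(
            f"insufficient heterozygous loci for empirical null: "
            f"{len(values)} < {MIN_NULL_LOCI}")
    arr = np.asarray(values, dtype=float)
    return BalanceDistribution(cell_id=cid or "", values=arr,
                               center=float(np.median(arr)))


def ase_pvalue(log2_ratio: float, null: BalanceDistribution) -> float:
    """Two-tailed empirical rank p-value of a log2 allelic ratio against D.

    p = (1 + #{v in D : |v - center| >= |log2_ratio - center|}) / (n + 1);
    the add-one correction makes the minimum attainable p equal 1/(n+1) and
    keeps p in (0, 1].
    """
    dev = abs(log2_ratio - null.center)
    tail = int(np.count_nonzero(np.abs(null.values - null.center) >= dev))
    return min(1.0, (1 + tail) / (null.n + 1))


class AseCaller(BaseEstimator):
    """ASE caller for one cell: fit the strand-balance null, then test loci.

    Parameters
    ----------
    alpha : float, default 0.01
        Empirical p-value threshold below which a heterozygous locus is
        called allele-specifically expressed.
    pseudocount : int, default 1
        Added to both allele counts in the reported allelic ratio.

    Attributes
    ----------
    null_ : BalanceDistribution
        The cell's empirical log2(B) distribution.
    """

    def __init__(self, alpha: float = 0.01, pseudocount: int = 1):
        self.alpha = alpha
        self.pseudocount = pseudocount

    def fit(self, het_counts: Sequence[tuple[StrandedAlleleCounts, SnpLocus]]) -> "AseCaller":
        self.null_ = build_balance_distribution(het_counts)
        return self

    def pvalues(self, het_counts: Sequence[tuple[StrandedAlleleCounts, SnpLocus]]) -> np.ndarray:
        self._check_fitted()
        return np.array([
            ase_pvalue(math.log2(allelic_ratio(c, l, self.pseudocount)), self.null_)
            for c, l in het_counts])

    def _decide(self, p: np.ndarray | float):
        # alpha >= 1 disables the test entirely (every locus called), which
        # the strict inequality alone would miss at loci with p exactly 1
        if self.alpha >= 1.0:
            return np.ones_like(np.asarray(p), dtype=bool) if np.ndim(p) else True
        return p < self.alpha

    def predict(self, het_counts: Sequence[tuple[StrandedAlleleCounts, SnpLocus]]) -> np.ndarray:
        """Boolean ASE calls (p < alpha) per heterozygous locus."""
        return self._decide(self.pvalues(het_counts))

    def calls(self, het_counts: Sequence[tuple[StrandedAlleleCounts, SnpLocus]]) -> list[AseCall]:
        self._check_fitted()
        out = []
        for counts, locus in het_counts:
            ref, alt = counts.ref_alt(locus)
            lr = math.log2(allelic_ratio(counts, locus, self.pseudocount))
            p = ase_pvalue(lr, self.null_)
            out.append(AseCall(counts.cell_id, counts.chrom, counts.pos,
                               ref, alt, lr, p, bool(self._decide(p))))
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "null_"):
            raise ValueError("AseCaller is not fitted; call fit() first")


def call_ase(
    het_counts: Sequence[tuple[StrandedAlleleCounts, SnpLocus]],
    alpha: float = 0.01,
    n_selected: int | None = None,
) -> tuple[list[AseCall], dict]:
    """Fit the per-cell null and call ASE on the same heterozygous loci.

    Returns the calls plus a per-cell summary with the conventional columns:
    number of selected loci (if given), heterozygous loci, ASE calls, the
    expected number of ASE false positives (#het x alpha), and ASE%.
    """
    caller = AseCaller(alpha=alpha).fit(het_counts)
    calls = caller.calls(het_counts)
    n_het = len(calls)
    n_ase = sum(c.is_ase for c in calls)
    summary = {
        "cell_id": calls[0].cell_id if calls else "",
        "n_selected": n_selected if n_selected is not None else n_het,
        "n_het": n_het,
        "n_ase": n_ase,
        "expected_ase_fp": n_het * alpha,
        "ase_pct": 100.0 * n_ase / n_het if n_het else float("nan"),
    }
    return calls, summary


def direction_concordance(
    calls_by_cell: Mapping[str, Mapping[tuple[str, int], AseCall]],
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Fraction of shared heterozygous loci skewed in the same direction.

    For each named group of cells (e.g. the blastomeres of one embryo, or
    same-stage cells across embryos) a locus qualifies when at least two
    cells of the group carry a het call with a nonzero log2 ratio; it is
    concordant when those nonzero ratios all share one sign.
    """
    rows = []
    for group_id, cells in groups.items():
        n_qual = 0
        n_conc = 0
        shared_keys = set()
        for c in cells:
            shared_keys.update(calls_by_cell.get(c, {}))
        for key in sorted(shared_keys):
            signs = [np.sign(calls_by_cell[c][key].log2_ratio)
                     for c in cells if key in calls_by_cell.get(c, {})]
            signs = [s for s in signs if s != 0]
            if len(signs) < 2:
                continue
            n_qual += 1
            n_conc += int(len(set(signs)) == 1)
        if n_qual == 0:
            logger.warning("no qualifying shared het loci for group %s", group_id)
            frac = float("nan")
        else:
            frac = n_conc / n_qual
        rows.append((group_id, n_qual, n_conc, frac))
    return pd.DataFrame(rows, columns=["group", "n_loci", "n_concordant", "concordance"])
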