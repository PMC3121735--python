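"""Allelic imbalance (AI) between sister blastomeres of one embryo.

Sister blastomeres share a genome, so a change in the allelic ratio of a
heterozygous SNP between them cannot be genetic: it indicates stochastic
(or technically noisy) allelic expression.  AI at a shared heterozygous
locus is the ratio of the two cells' pseudocounted allelic ratios; a locus
is called AI when both

* the fold change passes (AI > 2 or AI < 0.5), and
* the Pearson chi-square test (1 df, no continuity correction) on the raw
  2x2 ref/alt x cell table gives p < 0.05.

Expected AI false positives per embryo are estimated by margin-preserving
hypergeometric resampling of each tested table: the per-locus probability
that a null table passes both filters, summed over tested loci.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .counts import StrandedAlleleCounts, allelic_ratio
from .io import SnpLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AiCall:
    embryo_id: str
    cell_id_1: str
    cell_id_2: str
    chrom: str
    pos: int
    table: tuple  # ((ref1, alt1), (ref2, alt2)) raw counts
    ai_value: float
    log2_ai: float
    chi2_stat: float
    p_value: float
    fc_pass: bool
    small_counts: bool  # some expected cell < 5; tested anyway, flagged
    is_ai: bool


def _chi2_2x2(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df, no Yates) with degenerate-margin guard."""
    table = np.asarray(table, dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0, True
    stat, p, _, expected = chi2_contingency(table, correction=False)
    return float(stat), float(p), bool(expected.min() < 5)


def call_ai(
    counts1: StrandedAlleleCounts,
    counts2: StrandedAlleleCounts,
    locus: SnpLocus,
    embryo_id: str = "",
    alpha: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    pseudocount: int = 1,
) -> AiCall:
    """Paired-cell allelic imbalance test at one shared heterozygous locus."""
    r1, a1 = counts1.ref_alt(locus)
    r2, a2 = counts2.ref_alt(locus)
    ai = allelic_ratio(counts1, locus, pseudocount) / allelic_ratio(counts2, locus, pseudocount)
    stat, p, small = _chi2_2x2([[r1, a1], [r2, a2]])
    fc_pass = ai > fc_hi or ai < fc_lo
    return AiCall(
        embryo_id=embryo_id,
        cell_id_1=counts1.cell_id, cell_id_2=counts2.cell_id,
        chrom=locus.chrom, pos=locus.pos,
        table=((r1, a1), (r2, a2)),
        ai_value=ai, log2_ai=math.log2(ai),
        chi2_stat=stat, p_value=p,
        fc_pass=fc_pass, small_counts=small,
        is_ai=bool(fc_pass and p < alpha),
    )


def call_ai_embryo(
    counts_by_cell: Mapping[str, Mapping[tuple[str, int], StrandedAlleleCounts]],
    het_keys_by_cell: Mapping[str, set],
    loci: Mapping[tuple[str, int], SnpLocus],
    embryo_id: str,
    cells: Sequence[str],
    alpha: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> list[AiCall]:
    """AI tests over all within-embryo cell pairs at shared het loci.

    Two blastomeres per embryo is the canonical design; for 4- and 8-cell
    embryos every pair is tested and per-pair calls are all returned (an
    embryo-level locus counts as AI when any pair is significant).
    """
    calls = []
    for c1, c2 in itertools.combinations(sorted(cells), 2):
        shared = sorted(het_keys_by_cell.get(c1, set()) & het_keys_by_cell.get(c2, set()))
        for key in shared:
            calls.append(call_ai(
                counts_by_cell[c1][key], counts_by_cell[c2][key], loci[key],
                embryo_id=embryo_id, alpha=alpha, fc_hi=fc_hi, fc_lo=fc_lo))
    return calls


def expected_ai_fp(
    calls: Sequence[AiCall],
    alpha: float = 0.05,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    n_draws: int = 50,
    seed: int = 0,
) -> float:
    """Expected number of null AI calls among the tested loci.

    For each tested 2x2 table, resample ``n_draws`` tables with the same
    margins (hypergeometric draw, i.e. allele labels independent of cell
    labels), and record the fraction passing both the chi-square and the
    fold-change filter; the sum over loci estimates the count of false
    positives expected if no locus were truly imbalanced.
    """
    rng = np.random.default_rng(seed)
    total = 0.0
    for call in calls:
        (r1, a1), (r2, a2) = call.table
        n1 = r1 + a1
        n2 = r2 + a2
        nref = r1 + r2
        if n1 == 0 or n2 == 0 or nref == 0 or (a1 + a2) == 0:
            continue
        draws = rng.hypergeometric(nref, a1 + a2, n1, size=n_draws)
        hits = 0
        for d1 in draws:
            t = np.array([[d1, n1 - d1], [nref - d1, n2 - (nref - d1)]], dtype=float)
            stat, p, _ = _chi2_2x2(t)
            if p >= alpha:
                continue
            ai = ((t[0, 0] + 1) / (t[0, 1] + 1)) / ((t[1, 0] + 1) / (t[1, 1] + 1))
            if ai > fc_hi or ai < fc_lo:
                hits += 1
        total += hits / n_draws
    return total


def ai_summary(
    calls: Sequence[AiCall],
    alpha: float = 0.05,
    estimate_fp: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-embryo AI counts: loci tested, AI calls, AI%, expected false
    positives.  A locus counts once per embryo (AI when any pair is
    significant); paired cells share the embryo's AI count by construction.
    """
    rows = []
    by_embryo: dict[str, list[AiCall]] = {}
    for call in calls:
        by_embryo.setdefault(call.embryo_id, []).append(call)
    for embryo_id, embryo_calls in sorted(by_embryo.items()):
        loci = {}
        for call in embryo_calls:
            key = (call.chrom, call.pos)
            loci[key] = loci.get(key, False) or call.is_ai
        n_tested = len(loci)
        n_ai = sum(loci.values())
        fp = expected_ai_fp(embryo_calls, alpha=alpha, seed=seed) if estimate_fp else float("nan")
        rows.append((embryo_id, n_tested, n_ai,
                     100.0 * n_ai / n_tested if n_tested else float("nan"), fp))
    df = pd.DataFrame(rows, columns=["embryo_id", "n_tested", "n_ai", "ai_pct", "expected_ai_fp"])
    if df.empty:
        logger.warning("AI summary over zero tested loci")
    return df
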