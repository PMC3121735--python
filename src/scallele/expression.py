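"""Per-cell expression summaries: RPM, expressed-transcript detection,
fold-change flags and inter-cell correlation.

RPM (reads per million mapped reads) is the depth-normalised expression
unit; a transcript counts as expressed when RPM strictly exceeds 0.1.
Fold-change flags compare group mean RPM with a small pseudocount (0.01
RPM) guarding division by zero; inter-cell similarity is the Pearson
correlation of log2(RPM + 1) vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

FC_PSEUDOCOUNT_RPM = 0.01


def compute_rpm(counts, total_mapped: int) -> np.ndarray:
    """counts / total_mapped * 1e6, elementwise."""
    if total_mapped <= 0:
        raise ValueError(f"total mapped reads must be positive, got {total_mapped}")
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    return counts / total_mapped * 1e6


def detect_expressed(rpm, threshold: float = 0.1) -> np.ndarray:
    """Boolean mask: expressed iff RPM strictly exceeds the threshold."""
    return np.asarray(rpm, dtype=float) > threshold


def fold_change_flags(group_a_rpm, group_b_rpm, hi: float = 2.0,
                      lo: float = 0.5) -> np.ndarray:
    """Per-transcript 'up'/'down'/'unchanged' from group mean RPM ratios.

    Inputs are (n_cells, n_transcripts) arrays (or 1-D per-cell vectors);
    means are taken over cells and pseudocounted before the ratio.
    """
    a = np.atleast_2d(np.asarray(group_a_rpm, dtype=float)).mean(axis=0)
    b = np.atleast_2d(np.asarray(group_b_rpm, dtype=float)).mean(axis=0)
    if a.shape != b.shape:
        raise ValueError("fold change requires matched transcript sets")
    fc = (a + FC_PSEUDOCOUNT_RPM) / (b + FC_PSEUDOCOUNT_RPM)
    return np.where(fc > hi, "up", np.where(fc < lo, "down", "unchanged"))


def cell_correlation(rpm1, rpm2) -> float:
    """Pearson correlation of log2(RPM + 1) between two cells."""
    x = np.log2(np.asarray(rpm1, dtype=float) + 1)
    y = np.log2(np.asarray(rpm2, dtype=float) + 1)
    if x.shape != y.shape:
        raise ValueError("correlation requires matched transcript sets")
    if x.size < 100:
        raise ValueError(f"need at least 100 shared transcripts, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(pearsonr(x, y).statistic)


def expression_table(counts_by_cell: dict, total_by_cell: dict) -> pd.DataFrame:
    """Long-form per-cell counts and RPM (transcript rows, cell columns pairs)."""
    rows = []
    for cell_id in sorted(counts_by_cell):
        counts = counts_by_cell[cell_id]
        txs = sorted(counts)
        rpm = compute_rpm([counts[t] for t in txs], total_by_cell[cell_id])
        for tx, c, r in zip(txs, [counts[t] for t in txs], rpm):
            rows.append((cell_id, tx, c, r))
    return pd.DataFrame(rows, columns=["cell_id", "transcript_id", "count", "rpm"])
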