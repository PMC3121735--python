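"""3'UTR isoform inference from 3'-biased single-cell coverage.

Poly(T)-primed reverse transcription covers mRNAs from the 3' end, so read
coverage over a transcript's terminal region decays going 5' and nearly
vanishes ~1.5 kb upstream of a poly(A) site.  When a gene expresses both a
short (proximal poly(A) site) and a long (distal site) 3'UTR isoform, the
coverage track shows a step at the proximal site: the proximal isoform's
reads stop there while the distal isoform's continue.  The predictor
smooths the track with a running median, scans for positions where the mean
coverage over an upstream window exceeds the downstream mean by a
configurable ratio, and reports up to six cleavage-site candidates with
per-isoform abundance estimates (upstream-mean minus downstream-mean, in
mean-coverage units).  Genuine cleavage sites are expected to carry a
canonical poly(A) signal (CPSF hexamer AATAAA or ATTAAA) ~20 nt upstream;
:func:`scan_cpsf` reports the offset of the nearest motif.  A cross-cell
consensus keeps only ends reproduced in at least half of the cells.

Coordinates are transcript-oriented: position increases toward the 3' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

CPSF_MOTIFS = ("AATAAA", "ATTAAA")
MAX_ENDS = 6


@dataclass
class CoverageTrack:
    """Per-base coverage over one transcript's terminal region, oriented so
    that the position index increases toward the 3' end."""

    transcript_id: str
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage must be non-negative")


@dataclass
class UtrPrediction:
    transcript_id: str
    cell_id: str  # or "consensus"
    ends: list[int] = field(default_factory=list)          # strictly increasing
    abundances: list[float] = field(default_factory=list)  # mean-coverage units
    cpsf_offsets: list[int | None] = field(default_factory=list)
    consensus_support: float | None = None

    def __post_init__(self) -> None:
        if len(self.ends) > MAX_ENDS:
            raise ValueError(f"at most {MAX_ENDS} predicted ends per transcript")
        if any(b <= a for a, b in zip(self.ends, self.ends[1:])):
            raise ValueError("predicted ends must be strictly increasing")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be non-negative")


def track_from_bedgraph(bedgraph, transcript_id: str, strand: str = "+") -> CoverageTrack:
    """Expand bedGraph rows for one transcript into a per-base track.

    The bedGraph chromosome field names the transcript; intervals are
    0-based half-open in transcript orientation.
    """
    rows = bedgraph[bedgraph["chrom"] == transcript_id]
    if len(rows) == 0:
        return CoverageTrack(transcript_id, strand, np.zeros(0))
    length = int(rows["end"].max())
    values = np.zeros(length)
    for row in rows.itertuples(index=False):
        values[int(row.start):int(row.end)] = row.value
    return CoverageTrack(transcript_id, strand, values)


class UtrEndPredictor(BaseEstimator):
    """Coverage-step detector for alternative poly(A) sites.

    Parameters
    ----------
    min_step_ratio : float, default 3
        Minimum upstream-mean / downstream-mean ratio for a candidate
        cleavage site.
    smooth_window : int, default 50
        Running-median window (nt).
    min_segment : int, default 100
        Window (nt) over which the upstream and downstream means are taken;
        also the minimum separation between reported ends.
    max_ends : int, default 6
        Maximum number of reported ends, strongest steps first.
    """

    def __init__(self, min_step_ratio: float = 3.0, smooth_window: int = 50,
                 min_segment: int = 100, max_ends: int = MAX_ENDS):
        self.min_step_ratio = min_step_ratio
        self.smooth_window = smooth_window
        self.min_segment = min_segment
        self.max_ends = max_ends

    # step-ratio profile ----------------------------------------------------

    def _step_ratio(self, smoothed: np.ndarray) -> np.ndarray:
        """ratio[x] = mean(cov[x-w:x]) / mean(cov[x:x+w]) with zero padding
        downstream (the track must extend past the distal end)."""
        w = self.min_segment
        padded = np.concatenate([smoothed, np.zeros(w)])
        csum = np.concatenate([[0.0], np.cumsum(padded)])
        n = smoothed.size
        ratio = np.zeros(n + 1)
        eps = 1e-9
        for x in range(w, n + 1):
            up = (csum[x] - csum[x - w]) / w
            down = (csum[x + w] - csum[x]) / w
            ratio[x] = (up + eps) / (down + eps)
        return ratio

    def predict(self, track: CoverageTrack, cell_id: str = "") -> UtrPrediction:
        """Predict up to ``max_ends`` cleavage sites on one coverage track."""
        if track.values.size == 0 or track.values.max() <= 0:
            logger.warning("zero-coverage track for %s; no UTR predictions",
                           track.transcript_id)
            return UtrPrediction(track.transcript_id, cell_id)
        smoothed = median_filter(track.values, size=self.smooth_window,
                                 mode="constant", cval=0.0)
        ratio = self._step_ratio(smoothed)
        w = self.min_segment

        # local maxima of the step-ratio profile above threshold
        candidates = []
        for x in range(w, ratio.size):
            r = ratio[x]
            if r < self.min_step_ratio:
                continue
            lo = max(0, x - w // 2)
            hi = min(ratio.size, x + w // 2 + 1)
            if r >= ratio[lo:hi].max():
                candidates.append((r, x))
        # greedy strongest-first with min separation
        picked: list[int] = []
        for r, x in sorted(candidates, key=lambda t: (-t[0], t[1])):
            if all(abs(x - y) >= w for y in picked):
                picked.append(x)
            if len(picked) == self.max_ends:
                break
        picked.sort()

        ends, abundances = [], []
        padded = np.concatenate([smoothed, np.zeros(w)])
        for x in picked:
            up = padded[max(0, x - w):x].mean() if x > 0 else 0.0
            down = padded[x:x + w].mean()
            ends.append(x)
            abundances.append(max(0.0, float(up - down)))
        return UtrPrediction(track.transcript_id, cell_id, ends, abundances,
                             [None] * len(ends))


def predict_utr_ends(track: CoverageTrack, min_step_ratio: float = 3.0,
                     smooth_window: int = 50, min_segment: int = 100,
                     cell_id: str = "") -> UtrPrediction:
    return UtrEndPredictor(min_step_ratio, smooth_window, min_segment).predict(
        track, cell_id=cell_id)


def scan_cpsf(sequence: str, cleavage_pos: int, window: int = 50,
              motifs: Sequence[str] = CPSF_MOTIFS) -> int | None:
    """Offset (motif start minus cleavage position; negative = upstream) of
    the closest poly(A)-signal hexamer within +/- ``window`` nt, or None.

    ``sequence`` is in transcript orientation; a genuine cleavage site is
    expected to show a motif near -20.
    """
    sequence = sequence.upper()
    lo = max(0, cleavage_pos - window)
    hi = min(len(sequence), cleavage_pos + window + len(max(motifs, key=len)))
    if hi - lo < min(len(m) for m in motifs):
        logger.debug("sequence too short to scan around position %d", cleavage_pos)
        return None
    best: int | None = None
    for motif in motifs:
        start = sequence.find(motif, lo)
        while start != -1 and start < hi:
            offset = start - cleavage_pos
            if abs(offset) <= window and (best is None or abs(offset) < abs(best)):
                best = offset
            start = sequence.find(motif, start + 1)
    return best


def annotate_cpsf(prediction: UtrPrediction, sequence: str,
                  window: int = 50) -> UtrPrediction:
    prediction.cpsf_offsets = [scan_cpsf(sequence, end, window) for end in prediction.ends]
    return prediction


def proximal_distal_ratio(prediction: UtrPrediction) -> float:
    """Abundance of the most-proximal predicted isoform over the most-distal
    one; +inf when the distal abundance is zero."""
    if len(prediction.ends) < 2:
        raise ValueError("proximal:distal ratio needs at least two predicted ends")
    proximal = prediction.abundances[0]
    distal = prediction.abundances[-1]
    if distal == 0:
        return float("inf")
    return proximal / distal


def consensus_utr(predictions: Sequence[UtrPrediction], tolerance: int = 50,
                  min_fraction: float = 0.5) -> UtrPrediction:
    """Cross-cell consensus: cluster per-cell ends within ``tolerance`` nt and
    keep clusters reproduced in at least ``min_fraction`` of the cells.

    Consensus end and abundance are medians over the supporting cells.
    """
    if len(predictions) < 2:
        raise ValueError("consensus requires predictions from at least two cells")
    tx = {p.transcript_id for p in predictions}
    if len(tx) != 1:
        raise ValueError(f"consensus mixes transcripts {sorted(tx)}")
    n_cells = len({p.cell_id for p in predictions})

    points = sorted(
        (end, ab, p.cell_id)
        for p in predictions for end, ab in zip(p.ends, p.abundances))
    clusters: list[list[tuple[int, float, str]]] = []
    for point in points:
        if clusters and point[0] - clusters[-1][-1][0] <= tolerance:
            clusters[-1].append(point)
        else:
            clusters.append([point])

    kept = []
    for cluster in clusters:
        cells = {c for _, _, c in cluster}
        support = len(cells) / n_cells
        if support >= min_fraction:
            end = int(np.median([e for e, _, _ in cluster]))
            ab = float(np.median([a for _, a, _ in cluster]))
            kept.append((support, end, ab))
    kept.sort(key=lambda t: (-t[0], -t[2]))
    kept = kept[:MAX_ENDS]
    kept.sort(key=lambda t: t[1])
    return UtrPrediction(
        transcript_id=tx.pop(), cell_id="consensus",
        ends=[e for _, e, _ in kept], abundances=[a for _, _, a in kept],
        cpsf_offsets=[None] * len(kept),
        consensus_support=float(np.mean([s for s, _, _ in kept])) if kept else None)
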