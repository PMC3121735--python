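"""Heterozygosity calling calibrated on near-homozygous control cells.

Reverse transcription, PCR amplification and sequencing error make truly
homozygous loci look weakly polymorphic.  Rather than model those error
sources, the caller is calibrated empirically: minor-allele frequencies
(MAF) are pooled from control cells known to be (nearly) homozygous
everywhere, and the heterozygosity threshold is set at an upper percentile
of that pooled distribution.  With the default 95th percentile, a truly
homozygous locus with adequate coverage exceeds the threshold at most 5% of
the time, so calling a locus heterozygous when MAF > threshold bounds the
false-heterozygote rate at 5%.  (On the original mouse ES-cell controls
this construction yields a threshold of 0.066.)

The percentile uses the nearest-rank convention on the sorted pooled list
(the smallest value whose empirical CDF is >= p), which is distribution-free
and guarantees that at least a fraction p of the calibration MAFs do not
exceed the threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .counts import CountsByCell, StrandedAlleleCounts, minor_allele_frequency, select_loci
from .io import SnpLocus

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "hom_alt", "het")


@dataclass(frozen=True)
class GenotypeCall:
    cell_id: str
    chrom: str
    pos: int
    maf: float
    genotype: str  # hom_ref | hom_alt | het


def nearest_rank_percentile(values: Sequence[float], p: float) -> float:
    """Smallest element of ``values`` whose empirical CDF is >= p."""
    if not 0 < p <= 1:
        raise ValueError(f"percentile must be in (0, 1], got {p}")
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty list")
    k = math.ceil(p * arr.size)
    return float(arr[k - 1])


class HeterozygosityCaller(BaseEstimator):
    """Genotype caller with an empirically calibrated MAF threshold.

    Parameters
    ----------
    percentile : float, default 0.95
        Percentile of the pooled control-cell MAF distribution used as the
        het/hom decision threshold; the expected false-heterozygote rate on
        homozygous loci is bounded by ``1 - percentile``.
    min_coverage : int, default 25
        Minimum uniquely-aligned read coverage for a locus to enter
        calibration or be genotyped.
    max_dup_frac : float, default 0.5
        PCR-duplicate ceiling (locus-selection criterion 4).
    min_pooled : int, default 100
        Minimum number of pooled calibration loci for a usable model.

    Attributes
    ----------
    threshold_ : float
        Calibrated MAF threshold; a locus is called heterozygous iff its
        MAF is strictly greater.
    pooled_maf_ : ndarray
        The pooled calibration MAF values.
    n_loci_pooled_ : int
    """

    def __init__(self, percentile: float = 0.95, min_coverage: int = 25,
                 max_dup_frac: float = 0.5, min_pooled: int = 100):
        self.percentile = percentile
        self.min_coverage = min_coverage
        self.max_dup_frac = max_dup_frac
        self.min_pooled = min_pooled

    # -- calibration --------------------------------------------------------

    def fit(self, control_counts: CountsByCell,
            loci: Mapping[tuple[str, int], SnpLocus]) -> "HeterozygosityCaller":
        """Pool control-cell MAFs and set the threshold.

        Control cells contribute every annotated locus meeting coverage and
        the duplicate/strand criteria (criteria 3-5); single-nucleotide loci
        are deliberately kept — they are the calibration substrate and enter
        with MAF 0.
        """
        pooled: list[float] = []
        for cell_id, cell in control_counts.items():
            for key, sac in cell.items():
                locus = loci.get(key)
                if locus is None:
                    continue
                flt = select_loci(sac, locus, self.min_coverage, self.max_dup_frac)
                if not (flt.criterion3 and flt.criterion4 and flt.criterion5):
                    continue
                if sum(sac.ref_alt(locus)) == 0:
                    continue
                pooled.append(minor_allele_frequency(sac, locus))
        if len(pooled) < self.min_pooled:
            raise ValueError(
                f"insufficient calibration loci: pooled {len(pooled)} < {self.min_pooled}")
        self.pooled_maf_ = np.asarray(pooled, dtype=float)
        self.n_loci_pooled_ = len(pooled)
        self.threshold_ = nearest_rank_percentile(pooled, self.percentile)
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, maf: Iterable[float]) -> np.ndarray:
        """Vectorised het/hom decision on MAF values ('het' vs 'hom')."""
        self._check_fitted()
        maf = np.asarray(list(maf), dtype=float)
        return np.where(maf > self.threshold_, "het", "hom")

    def call(self, counts: StrandedAlleleCounts, locus: SnpLocus) -> GenotypeCall:
        """Full genotype call for one locus: het iff MAF strictly exceeds the
        threshold, otherwise homozygous toward the majority annotated allele."""
        self._check_fitted()
        maf = minor_allele_frequency(counts, locus)
        if maf > self.threshold_:
            genotype = "het"
        else:
            ref, alt = counts.ref_alt(locus)
            genotype = "hom_ref" if ref >= alt else "hom_alt"
        return GenotypeCall(counts.cell_id, counts.chrom, counts.pos, maf, genotype)

    def expected_het_false_positives(self, n_tested: int) -> float:
        """Expected number of homozygous loci miscalled het among n_tested."""
        return n_tested * (1.0 - self.percentile)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        hist, edges = np.histogram(self.pooled_maf_, bins=50, range=(0.0, 0.5))
        payload = {
            "percentile": self.percentile,
            "min_coverage": self.min_coverage,
            "max_dup_frac": self.max_dup_frac,
            "threshold": self.threshold_,
            "n_loci_pooled": self.n_loci_pooled_,
            "pooled_maf_histogram": {
                "bin_edges": [round(float(e), 6) for e in edges],
                "counts": [int(c) for c in hist],
            },
            "pooled_maf": [round(float(v), 6) for v in np.sort(self.pooled_maf_)],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "HeterozygosityCaller":
        payload = json.loads(Path(path).read_text())
        model = cls(percentile=payload["percentile"],
                    min_coverage=payload["min_coverage"],
                    max_dup_frac=payload["max_dup_frac"])
        model.pooled_maf_ = np.asarray(payload["pooled_maf"], dtype=float)
        model.n_loci_pooled_ = payload["n_loci_pooled"]
        model.threshold_ = payload["threshold"]
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "threshold_"):
            raise ValueError("HeterozygosityCaller is not fitted; call fit() first")


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def calibrate(control_counts: CountsByCell,
              loci: Mapping[tuple[str, int], SnpLocus],
              percentile: float = 0.95, min_coverage: int = 25) -> HeterozygosityCaller:
    return HeterozygosityCaller(
        percentile=percentile, min_coverage=min_coverage
    ).fit(control_counts, loci)


def call_genotype(counts: StrandedAlleleCounts, locus: SnpLocus,
                  model: HeterozygosityCaller) -> GenotypeCall:
    if model is None:
        raise ValueError("calibration model required")
    return model.call(counts, locus)


def expected_het_fp(model: HeterozygosityCaller, n_tested: int) -> float:
    return model.expected_het_false_positives(n_tested)


def flag_discordant_sisters(
    calls_by_cell: Mapping[str, Mapping[tuple[str, int], GenotypeCall]],
    embryo_of: Mapping[str, str],
) -> list[tuple[str, tuple[str, int], dict]]:
    """Flag loci where sister cells of one embryo disagree on genotype.

    Sister blastomeres share their genome, so discordance indicates a calling
    error at the locus in at least one cell; flagged, never auto-corrected.
    """
    by_embryo: dict[str, list[str]] = {}
    for cell_id, embryo_id in embryo_of.items():
        by_embryo.setdefault(embryo_id, []).append(cell_id)
    flags = []
    for embryo_id, cells in sorted(by_embryo.items()):
        shared = set.intersection(*(set(calls_by_cell.get(c, {})) for c in cells)) if cells else set()
        for key in sorted(shared):
            genotypes = {c: calls_by_cell[c][key].genotype for c in cells}
            if len(set(genotypes.values())) > 1:
                flags.append((embryo_id, key, genotypes))
    return flags
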