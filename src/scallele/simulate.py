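"""Synthetic single-cell allele-count and 3'-coverage data with known truth.

The generator emulates the statistical structure the pipeline assumes for
cleavage-stage mouse embryos sequenced one blastomere at a time:

* every SNP in a single cell is either homozygous or heterozygous, and
  sister blastomeres of one embryo share their genotype at every locus;
* homozygous loci acquire false minor-allele reads through RT/PCR and
  sequencing error, modelled as beta-binomial (a per-locus error rate drawn
  around ``error_rate`` with overdispersion ``error_overdispersion``, then
  binomial counts) — locus-level overdispersion is what makes the empirical
  heterozygosity calibration non-trivial;
* a fraction of heterozygous loci carry a true allelic skew (log2 allelic
  ratio drawn from ``ase_log2_skew_law``), shared between sister cells
  except for an ``ai_fraction`` of loci whose skew is re-drawn
  independently per cell (stochastic allelic imbalance);
* double-strand cDNA synthesis assigns each read to an alignment strand
  with probability ``strand_bias`` (0.5 = unbiased);
* PCR duplicates are reads sharing one identical alignment position;
  duplicate groups are built read-by-read (a new read joins an existing
  read's position with probability ``dup_rate``) and the modal
  identical-position fraction is recorded per nucleotide;
* 3'-biased transcript coverage decays exponentially upstream of each
  poly(A) site (scale ``decay_length``, near zero beyond ~1.5 kb), with one
  or two isoforms per gene and Poisson noise per base.

One master seed deterministically spawns per-cell child seeds, so the same
configuration always yields byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ALLELE_COUNT_COLUMNS, NUCLEOTIDES, CellMeta, SnpLocus

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["embryo_id", "cell_id", "chrom", "pos", "genotype",
                 "log2_skew", "is_ai"]
UTR_TRUTH_COLUMNS = ["transcript_id", "n_isoforms", "proximal_end",
                     "distal_end", "proximal_abundance", "distal_abundance"]


@dataclass
class UtrSimParams:
    """Per-gene 3'UTR simulation settings (positions in nt, transcript
    orientation)."""

    n_genes: int = 100
    isoforms_per_gene: int = 2
    proximal_end: int = 1000
    distal_end: int = 2500
    position_jitter: int = 200
    abundance_ratio: float = 5.0   # proximal : distal, the two-cell regime
    base_abundance: float = 4.0    # distal-isoform coverage at its 3' end (reads/nt)
    decay_length: float = 600.0    # exponential scale; near zero by 1.5 kb
    margin: int = 500              # zero-coverage margin past the distal end
    noise: bool = True             # per-base Poisson noise


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_embryos: int = 4
    cells_per_embryo: int = 2
    n_loci: int = 2000
    genotype_probs: dict = field(default_factory=lambda: {
        "hom_ref": 0.25, "hom_alt": 0.15, "het": 0.60})
    control_genotype_probs: dict = field(default_factory=lambda: {
        "hom_ref": 0.599, "hom_alt": 0.398, "het": 0.003})
    coverage_law: dict = field(default_factory=lambda: {
        "name": "negative_binomial", "mean": 60.0, "dispersion": 5.0, "min": 1})
    error_rate: float = 0.02
    error_overdispersion: float = 0.1
    ase_fraction: float = 0.45
    ase_log2_skew_law: dict = field(default_factory=lambda: {
        "name": "normal", "mean": 0.0, "sd": 2.0})
    ai_fraction: float = 0.06
    dup_rate: float = 0.3
    strand_bias: float = 0.5
    utr_params: UtrSimParams = field(default_factory=UtrSimParams)

    def __post_init__(self) -> None:
        if isinstance(self.utr_params, dict):
            self.utr_params = UtrSimParams(**self.utr_params)
        self.validate()

    def validate(self) -> None:
        for name in ("error_rate", "error_overdispersion", "ase_fraction",
                     "ai_fraction", "dup_rate", "strand_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_embryos", "cells_per_embryo", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for pname, probs in (("genotype_probs", self.genotype_probs),
                             ("control_genotype_probs", self.control_genotype_probs)):
            if set(probs) != {"hom_ref", "hom_alt", "het"}:
                raise ValueError(f"{pname} must have keys hom_ref/hom_alt/het")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"{pname} values must be in [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{pname} must sum to 1 (got {sum(probs.values())})")
        if self.coverage_law.get("name") not in ("negative_binomial", "poisson", "fixed"):
            raise ValueError(f"unknown coverage_law {self.coverage_law.get('name')!r}")
        u = self.utr_params
        if u.proximal_end >= u.distal_end:
            raise ValueError(
                f"utr_params: proximal_end {u.proximal_end} must be strictly "
                f"upstream of distal_end {u.distal_end}")


@dataclass
class SimResult:
    counts: pd.DataFrame           # long-form allele-count table
    truth: pd.DataFrame            # per (embryo, cell, locus) truth
    loci: dict                     # (chrom, pos) -> SnpLocus
    cells: list                    # CellMeta


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def _sample_coverage(rng: np.random.Generator, law: dict, n: int) -> np.ndarray:
    name = law["name"]
    if name == "fixed":
        cov = np.full(n, int(law["mean"]))
    elif name == "poisson":
        cov = rng.poisson(law["mean"], size=n)
    else:  # negative binomial, mean m and dispersion k (var = m + m^2/k)
        k = float(law.get("dispersion", 5.0))
        m = float(law["mean"])
        cov = rng.negative_binomial(k, k / (k + m), size=n)
    minimum = int(law.get("min", 1))
    for _ in range(1000):
        mask = cov < minimum
        if not mask.any():
            break
        cov[mask] = _sample_coverage(rng, {**law, "min": 0}, int(mask.sum()))
    cov = np.maximum(cov, minimum)
    return cov.astype(int)


def _sample_error_rates(rng: np.random.Generator, mean: float, rho: float,
                        n: int) -> np.ndarray:
    """Per-locus error rates: Beta with mean ``mean`` and intraclass
    correlation ``rho`` (rho=0 collapses to the constant rate)."""
    if mean == 0 or rho == 0:
        return np.full(n, mean)
    a = mean * (1 - rho) / rho
    b = (1 - mean) * (1 - rho) / rho
    return rng.beta(a, b, size=n)


def _sample_skews(rng: np.random.Generator, law: dict, n: int) -> np.ndarray:
    name = law["name"]
    if name == "normal":
        return rng.normal(law.get("mean", 0.0), law.get("sd", 2.0), size=n)
    if name == "constant":
        return np.full(n, float(law["value"]))
    if name == "uniform":
        return rng.uniform(law["low"], law["high"], size=n)
    raise ValueError(f"unknown ase_log2_skew_law {name!r}")


def _dup_modal_frac(rng: np.random.Generator, n_reads: int, dup_rate: float) -> float:
    """Modal identical-alignment-position fraction among ``n_reads`` reads.

    Reads arrive sequentially; each joins the alignment position of a
    uniformly chosen earlier read with probability ``dup_rate``, otherwise
    starts a fresh position (so PCR-duplicate clusters grow in proportion
    to their size, as reamplification does).
    """
    if n_reads == 0:
        return 0.0
    if dup_rate == 0.0:
        return 1.0 / n_reads
    group_of = np.empty(n_reads, dtype=np.int64)
    group_of[0] = 0
    n_groups = 1
    joins = rng.random(n_reads - 1) < dup_rate
    picks = rng.integers(0, n_reads, size=n_reads - 1)  # modded below
    for i in range(1, n_reads):
        if joins[i - 1]:
            group_of[i] = group_of[picks[i - 1] % i]
        else:
            group_of[i] = n_groups
            n_groups += 1
    return float(np.bincount(group_of).max() / n_reads)


def _split_strands(rng: np.random.Generator, n: int, strand_bias: float) -> tuple[int, int]:
    plus = int(rng.binomial(n, strand_bias)) if n else 0
    return plus, n - plus


# ---------------------------------------------------------------------------
# loci and genotypes
# ---------------------------------------------------------------------------

def make_loci(config: SimulationConfig,
              rng: np.random.Generator) -> dict[tuple[str, int], SnpLocus]:
    loci = {}
    for i in range(config.n_loci):
        ref, alt = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
        locus = SnpLocus(chrom="chr1", pos=1000 + 100 * i,
                         ref=NUCLEOTIDES[ref], alt=NUCLEOTIDES[alt],
                         gene_id=f"gene{i:05d}", tx_strand="+")
        loci[locus.key] = locus
    return loci


def _draw_genotypes(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    states = np.array(["hom_ref", "hom_alt", "het"])
    p = np.array([probs["hom_ref"], probs["hom_alt"], probs["het"]])
    return states[rng.choice(3, size=n, p=p)]


def _simulate_cell_counts(
    rng: np.random.Generator,
    config: SimulationConfig,
    loci_list: list[SnpLocus],
    genotypes: np.ndarray,
    skews: np.ndarray,
) -> list[tuple]:
    """Rows of the long-form count table for one cell (fixed locus order)."""
    n = len(loci_list)
    coverage = _sample_coverage(rng, config.coverage_law, n)
    err = _sample_error_rates(rng, config.error_rate,
                              config.error_overdispersion, n)
    rows = []
    for i, locus in enumerate(loci_list):
        c = int(coverage[i])
        g = genotypes[i]
        if g == "het":
            p_ref = 2.0 ** skews[i] / (1.0 + 2.0 ** skews[i])
            n_ref = int(rng.binomial(c, p_ref))
        elif g == "hom_ref":
            n_ref = c - int(rng.binomial(c, err[i]))
        else:  # hom_alt
            n_ref = int(rng.binomial(c, err[i]))
        n_alt = c - n_ref
        for nt, count in ((locus.ref, n_ref), (locus.alt, n_alt)):
            if count == 0:
                continue
            dup = round(_dup_modal_frac(rng, count, config.dup_rate), 6)
            plus, minus = _split_strands(rng, count, config.strand_bias)
            for strand, sc in (("+", plus), ("-", minus)):
                if sc > 0:
                    rows.append((None, locus.chrom, locus.pos, nt, strand, sc, dup))
    return rows


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_cells(config: SimulationConfig) -> SimResult:
    """Simulate allele-count tables for every blastomere plus the truth table.

    Genotypes are drawn once per embryo (sister cells share them); true
    skews are shared between sisters except at AI loci, where each cell
    re-draws its own skew.
    """
    ss_loci = np.random.SeedSequence((config.seed, 0x10))
    ss_embryos = np.random.SeedSequence((config.seed, 0x20))
    loci = make_loci(config, np.random.default_rng(ss_loci))
    loci_list = [loci[k] for k in sorted(loci)]
    n = len(loci_list)

    all_rows = []
    truth_rows = []
    cells = []
    embryo_seeds = ss_embryos.spawn(config.n_embryos)
    for e in range(config.n_embryos):
        embryo_id = f"E{e + 1}"
        e_rng = np.random.default_rng(embryo_seeds[e])
        genotypes = _draw_genotypes(e_rng, config.genotype_probs, n)
        het = genotypes == "het"
        skewed = het & (e_rng.random(n) < config.ase_fraction)
        base_skew = np.where(skewed, _sample_skews(e_rng, config.ase_log2_skew_law, n), 0.0)
        is_ai = het & (e_rng.random(n) < config.ai_fraction)

        cell_seeds = embryo_seeds[e].spawn(config.cells_per_embryo)
        for b in range(config.cells_per_embryo):
            cell_id = f"{config.cells_per_embryo}cell_{embryo_id}_B{b + 1}"
            cells.append(CellMeta(cell_id=cell_id, embryo_id=embryo_id,
                                  stage=f"{config.cells_per_embryo}cell"
                                  if config.cells_per_embryo in (2, 4, 8) else "2cell"))
            c_rng = np.random.default_rng(cell_seeds[b])
            cell_skew = base_skew.copy()
            if is_ai.any():
                cell_skew[is_ai] = _sample_skews(
                    c_rng, config.ase_log2_skew_law, int(is_ai.sum()))
            rows = _simulate_cell_counts(c_rng, config, loci_list, genotypes, cell_skew)
            all_rows.extend((cell_id,) + r[1:] for r in rows)
            for i, locus in enumerate(loci_list):
                truth_rows.append((embryo_id, cell_id, locus.chrom, locus.pos,
                                   genotypes[i], float(cell_skew[i]), bool(is_ai[i])))

    counts = pd.DataFrame(all_rows, columns=ALLELE_COUNT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimResult(counts=counts, truth=truth, loci=loci, cells=cells)


def generate_control_cells(config: SimulationConfig, n_cells: int = 12) -> SimResult:
    """Simulate near-homozygous control cells from one shared genotype draw.

    All cells come from the same (nearly inbred) line, so the genotype is
    drawn once and shared; residual heterozygosity above 1% triggers a
    warning because it degrades the calibration.
    """
    probs = config.control_genotype_probs
    if probs["het"] > 0.01:
        logger.warning("control-cell heterozygous mass %.3f > 0.01; "
                       "calibration validity is doubtful", probs["het"])
    # the SNP catalog is shared with generate_cells: one dbSNP-like
    # annotation serves both the experiment and the control line
    master = np.random.SeedSequence((config.seed, 0xC0)).spawn(1 + n_cells)
    loci = make_loci(config, np.random.default_rng(
        np.random.SeedSequence((config.seed, 0x10))))
    loci_list = [loci[k] for k in sorted(loci)]
    n = len(loci_list)
    genotypes = _draw_genotypes(np.random.default_rng(master[0]), probs, n)
    skews = np.zeros(n)

    all_rows = []
    truth_rows = []
    cells = []
    for j in range(n_cells):
        cell_id = f"ES_{j + 1}"
        cells.append(CellMeta(cell_id=cell_id, embryo_id="", stage="ES",
                              is_control=True))
        c_rng = np.random.default_rng(master[1 + j])
        rows = _simulate_cell_counts(c_rng, config, loci_list, genotypes, skews)
        all_rows.extend((cell_id,) + r[1:] for r in rows)
        for i, locus in enumerate(loci_list):
            truth_rows.append(("", cell_id, locus.chrom, locus.pos,
                               genotypes[i], 0.0, False))

    counts = pd.DataFrame(all_rows, columns=ALLELE_COUNT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimResult(counts=counts, truth=truth, loci=loci, cells=cells)


def utr_profile(params: UtrSimParams, ends: list[int],
                abundances: list[float]) -> np.ndarray:
    """Noise-free coverage: sum over isoforms of abundance x exponential
    decay of the distance upstream of that isoform's 3' end."""
    length = max(ends) + params.margin
    x = np.arange(length, dtype=float)
    profile = np.zeros(length)
    for end, ab in zip(ends, abundances):
        upstream = x < end
        profile[upstream] += ab * np.exp(-(end - x[upstream]) / params.decay_length)
    return profile


def generate_utr_coverage(
    config: SimulationConfig,
    cell_ids: Iterable[str] = ("cell_1",),
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, str]]:
    """Per-cell 3'-region coverage (bedGraph rows per cell), truth, sequences.

    All cells share each gene's true isoform structure (poly(A) sites and
    abundances); per-base Poisson noise is drawn independently per cell.
    Sequences are random with the canonical poly(A) hexamer AATAAA planted
    20 nt upstream of each true cleavage site.
    """
    params = config.utr_params
    if params.proximal_end >= params.distal_end:
        raise ValueError("proximal site must be strictly upstream of distal site")
    cell_ids = list(cell_ids)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x37)))
    truth_rows = []
    sequences = {}
    profiles = {}
    for g in range(params.n_genes):
        tx = f"tx{g:04d}"
        jit = params.position_jitter
        proximal = int(params.proximal_end + rng.integers(-jit, jit + 1))
        distal = int(params.distal_end + rng.integers(-jit, jit + 1))
        if params.isoforms_per_gene == 1:
            ends = [distal]
            abundances = [params.base_abundance * params.abundance_ratio]
        else:
            ends = [proximal, distal]
            abundances = [params.base_abundance * params.abundance_ratio,
                          params.base_abundance]
        profiles[tx] = utr_profile(params, ends, abundances)
        seq = rng.choice(list("ACGT"), size=profiles[tx].size)
        for end in ends:
            seq[end - 20:end - 14] = list("AATAAA")
        sequences[tx] = "".join(seq)
        truth_rows.append((tx, len(ends), ends[0] if len(ends) == 2 else -1,
                           ends[-1], abundances[0], abundances[-1]))

    bedgraphs = {}
    for cell_id in cell_ids:
        bed_rows = []
        for tx in sorted(profiles):
            observed = (rng.poisson(profiles[tx]).astype(float)
                        if params.noise else profiles[tx])
            for pos, value in enumerate(observed):
                if value > 0:
                    bed_rows.append((tx, pos, pos + 1, value))
        bedgraphs[cell_id] = pd.DataFrame(
            bed_rows, columns=["chrom", "start", "end", "value"])
    truth = pd.DataFrame(truth_rows, columns=UTR_TRUTH_COLUMNS)
    return bedgraphs, truth, sequences


def generate_expression(
    n_transcripts: int = 16000,
    depth: int = 10_000_000,
    seed: int = 0,
    n_cells: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Sister-cell expression counts: shared log-normal transcript means,
    independent Poisson sampling per cell at the given depth (default 1e7
    reads, the deep-sequencing regime of single-cell transcriptome libraries).

    Returns (counts array of shape (n_cells, n_transcripts), expected counts).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE)))
    weights = rng.lognormal(mean=0.0, sigma=2.0, size=n_transcripts)
    expected = weights / weights.sum() * depth
    counts = rng.poisson(expected, size=(n_cells, n_transcripts))
    return counts, expected
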