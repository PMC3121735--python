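"""Shared fixtures: small synthetic datasets reused across test modules.

Session-scoped fixtures hold the expensive simulations (a calibration pool,
a balanced null cell) so each is generated once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from scallele.counts import StrandedAlleleCounts, counts_from_frame
from scallele.genotype import HeterozygosityCaller
from scallele.io import SnpLocus
from scallele.simulate import SimulationConfig, generate_cells, generate_control_cells

COVERAGE_GE25 = {"name": "negative_binomial", "mean": 60.0, "dispersion": 5.0, "min": 25}
ALL_HET = {"hom_ref": 0.0, "hom_alt": 0.0, "het": 1.0}
ALL_HOM = {"hom_ref": 0.6, "hom_alt": 0.4, "het": 0.0}


def make_counts(locus: SnpLocus, ref_plus=0, ref_minus=0, alt_plus=0, alt_minus=0,
                cell_id="cell", dup_ref=0.1, dup_alt=0.1, extra=None) -> StrandedAlleleCounts:
    """Hand-build stranded counts for one locus."""
    counts = {}
    for nt, strand, c in ((locus.ref, "+", ref_plus), (locus.ref, "-", ref_minus),
                          (locus.alt, "+", alt_plus), (locus.alt, "-", alt_minus)):
        if c:
            counts[(nt, strand)] = c
    if extra:
        counts.update(extra)
    dup = {}
    if ref_plus + ref_minus:
        dup[locus.ref] = dup_ref
    if alt_plus + alt_minus:
        dup[locus.alt] = dup_alt
    for (nt, _), c in (extra or {}).items():
        dup.setdefault(nt, 0.1)
    return StrandedAlleleCounts(cell_id=cell_id, chrom=locus.chrom, pos=locus.pos,
                                counts=counts, dup_modal_frac=dup)


@pytest.fixture()
def locus() -> SnpLocus:
    return SnpLocus(chrom="chr1", pos=100, ref="A", alt="G", gene_id="g1", tx_strand="+")


@pytest.fixture(scope="session")
def calibration():
    """12 simulated control cells (coverage >= 25) plus a fitted caller and
    fresh homozygous-cell MAFs drawn from the same error law."""
    config = SimulationConfig(seed=101, n_loci=2500, coverage_law=dict(COVERAGE_GE25))
    control = generate_control_cells(config, 12)
    model = HeterozygosityCaller().fit(counts_from_frame(control.counts), control.loci)

    fresh_config = SimulationConfig(
        seed=202, n_embryos=1, cells_per_embryo=1, n_loci=5000,
        genotype_probs=dict(ALL_HOM), coverage_law=dict(COVERAGE_GE25))
    fresh = generate_cells(fresh_config)
    cell = next(iter(counts_from_frame(fresh.counts).values()))
    from scallele.counts import minor_allele_frequency
    fresh_maf = np.array([
        minor_allele_frequency(sac, fresh.loci[key])
        for key, sac in sorted(cell.items())
        if sum(sac.ref_alt(fresh.loci[key])) > 0])
    return {"model": model, "control": control, "fresh_maf": fresh_maf}


@pytest.fixture(scope="session")
def balanced_cell():
    """One het-only cell with no true allelic skew: the ASE null regime."""
    config = SimulationConfig(
        seed=77, n_embryos=1, cells_per_embryo=1, n_loci=5000,
        ase_fraction=0.0, ai_fraction=0.0, genotype_probs=dict(ALL_HET),
        coverage_law=dict(COVERAGE_GE25))
    result = generate_cells(config)
    cell = next(iter(counts_from_frame(result.counts).values()))
    het = [(sac, result.loci[key]) for key, sac in sorted(cell.items())]
    return het
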