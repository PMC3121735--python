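"""Simulator contracts: determinism, truth invariants, count conservation."""

import numpy as np
import pandas as pd
import pytest

from scallele.counts import counts_from_frame
from scallele.simulate import (SimulationConfig, generate_cells,
                               generate_control_cells, generate_utr_coverage)

from conftest import ALL_HET


def small_config(**kw):
    defaults = dict(seed=1, n_embryos=2, cells_per_embryo=2, n_loci=200)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw, match", [
        (dict(error_rate=1.5), "error_rate"),
        (dict(dup_rate=-0.1), "dup_rate"),
        (dict(genotype_probs={"hom_ref": 0.5, "hom_alt": 0.4, "het": 0.2}),
         "sum to 1"),
        (dict(genotype_probs={"hom_ref": 0.5, "het": 0.5}), "keys"),
        (dict(coverage_law={"name": "cauchy", "mean": 10}), "coverage_law"),
        (dict(n_loci=0), "n_loci"),
    ])
    def test_invalid_config_names_parameter(self, kw, match):
        with pytest.raises(ValueError, match=match):
            small_config(**kw)


class TestGenerateCells:
    def test_deterministic_under_seed(self):
        a = generate_cells(small_config())
        b = generate_cells(small_config())
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self):
        a = generate_cells(small_config(seed=1))
        b = generate_cells(small_config(seed=2))
        assert not a.counts.equals(b.counts)

    def test_zero_error_hom_ref_only(self):
        config = small_config(
            error_rate=0.0,
            genotype_probs={"hom_ref": 1.0, "hom_alt": 0.0, "het": 0.0})
        result = generate_cells(config)
        merged = result.counts.merge(
            pd.DataFrame([(l.chrom, l.pos, l.ref) for l in result.loci.values()],
                         columns=["chrom", "pos", "ref"]), on=["chrom", "pos"])
        assert (merged["nt"] == merged["ref"]).all()

    def test_sister_cells_share_genotype(self):
        truth = generate_cells(small_config()).truth
        per_locus = truth.pivot_table(index=["embryo_id", "pos"],
                                      columns="cell_id", values="genotype",
                                      aggfunc="first")
        assert (per_locus.nunique(axis=1) == 1).all()

    def test_non_ai_het_loci_share_skew(self):
        truth = generate_cells(small_config(ase_fraction=0.6)).truth
        shared = truth[(truth.genotype == "het") & ~truth.is_ai]
        spread = shared.groupby(["embryo_id", "pos"])["log2_skew"].nunique()
        assert (spread == 1).all()

    def test_count_conservation(self):
        """Summed ref+alt counts across strands equal simulated coverage
        implicitly: per locus the table's total equals the per-locus tally."""
        result = generate_cells(small_config())
        by_cell = counts_from_frame(result.counts)
        table_totals = result.counts.groupby(["cell_id", "chrom", "pos"])["count"].sum()
        for (cell_id, chrom, pos), total in table_totals.items():
            assert by_cell[cell_id][(chrom, pos)].coverage == total

    def test_skew_mean_recovered_at_high_coverage(self):
        """Law of large numbers: constant true log2 skew of 2 is recovered
        by the brute-force mean of observed log2 ratios at coverage >= 100."""
        config = SimulationConfig(
            seed=3, n_embryos=1, cells_per_embryo=1, n_loci=2000,
            ase_fraction=1.0, ai_fraction=0.0,
            ase_log2_skew_law={"name": "constant", "value": 2.0},
            genotype_probs=dict(ALL_HET),
            coverage_law={"name": "negative_binomial", "mean": 150,
                          "dispersion": 8, "min": 100})
        result = generate_cells(config)
        cell = next(iter(counts_from_frame(result.counts).values()))
        ratios = []
        for key, sac in cell.items():
            locus = result.loci[key]
            ref, alt = sac.ref_alt(locus)
            ratios.append(np.log2((ref + 1) / (alt + 1)))
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.1)

    def test_dup_fraction_within_bounds(self):
        counts = generate_cells(small_config(dup_rate=0.5)).counts
        assert counts["max_dup_frac"].between(0, 1).all()
        # high duplication must produce some heavy identical-position groups
        assert (counts["max_dup_frac"] > 0.5).any()


class TestControlCells:
    def test_zero_error_gives_all_ref_or_alt(self):
        config = small_config(
            error_rate=0.0,
            control_genotype_probs={"hom_ref": 0.6, "hom_alt": 0.4, "het": 0.0})
        control = generate_control_cells(config, 4)
        by_cell = counts_from_frame(control.counts)
        for cell in by_cell.values():
            for key, sac in cell.items():
                assert len(sac.observed_nts()) == 1

    def test_warns_on_heterozygous_mass(self, caplog):
        config = small_config(
            control_genotype_probs={"hom_ref": 0.5, "hom_alt": 0.45, "het": 0.05})
        with caplog.at_level("WARNING", logger="scallele.simulate"):
            generate_control_cells(config, 2)
        assert "calibration validity" in caplog.text

    def test_loci_shared_with_experiment(self):
        config = small_config()
        assert generate_cells(config).loci == generate_control_cells(config, 2).loci


class TestUtrCoverage:
    def test_deterministic_and_cells_independent(self):
        config = small_config(utr_params={"n_genes": 5})
        a, truth_a, seq_a = generate_utr_coverage(config, ["c1", "c2"])
        b, truth_b, seq_b = generate_utr_coverage(config, ["c1", "c2"])
        pd.testing.assert_frame_equal(a["c1"], b["c1"])
        pd.testing.assert_frame_equal(truth_a, truth_b)
        assert seq_a == seq_b
        assert not a["c1"].equals(a["c2"])  # independent noise per cell

    def test_two_isoform_closed_form_levels(self):
        """Noise-free: coverage just upstream of each site matches the sum
        of the isoform decay profiles."""
        config = small_config(utr_params={
            "n_genes": 1, "position_jitter": 0, "noise": False,
            "abundance_ratio": 5.0, "base_abundance": 1.0,
            "proximal_end": 1000, "distal_end": 2500, "decay_length": 600})
        bedgraphs, truth, _ = generate_utr_coverage(config, ["c1"])
        from scallele.utr import track_from_bedgraph
        track = track_from_bedgraph(bedgraphs["c1"], truth.transcript_id[0])
        near_prox = track.values[995:1000].mean()
        near_dist = track.values[2495:2500].mean()
        expected_prox = 5.0 + 1.0 * np.exp(-(2500 - 997.5) / 600)
        assert near_prox == pytest.approx(expected_prox, rel=0.02)
        assert near_dist == pytest.approx(1.0, rel=0.02)

    def test_truth_columns(self):
        config = small_config(utr_params={"n_genes": 3})
        _, truth, seqs = generate_utr_coverage(config)
        assert len(truth) == 3 and len(seqs) == 3
        assert (truth["proximal_end"] < truth["distal_end"]).all()
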