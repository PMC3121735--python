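"""Strand-balance statistic, empirical null, ASE p-values and concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scallele.ase import (AseCaller, BalanceDistribution, ase_pvalue,
                          build_balance_distribution, call_ase,
                          direction_concordance, strand_balance)
from scallele.counts import counts_from_frame
from scallele.simulate import SimulationConfig, generate_cells

from conftest import ALL_HET, make_counts


class TestStrandBalance:
    def test_balanced_strands_give_one(self, locus):
        sac = make_counts(locus, ref_plus=10, ref_minus=10, alt_plus=10, alt_minus=10)
        assert strand_balance(sac, locus) == pytest.approx(1.0)

    def test_allelic_skew_does_not_move_b(self, locus):
        """A strongly skewed locus with unbiased strands still has B = 1:
        the statistic isolates strand bias from allelic imbalance."""
        sac = make_counts(locus, ref_plus=40, ref_minus=40, alt_plus=5, alt_minus=5)
        assert strand_balance(sac, locus) == pytest.approx(46 / 46)

    def test_extreme_strand_bias_sentinel(self, locus):
        sac = make_counts(locus, ref_plus=20, ref_minus=0, alt_plus=0, alt_minus=20)
        assert strand_balance(sac, locus) == pytest.approx(41.0)

    def test_concentrates_near_one_at_high_coverage(self):
        """With unbiased strands, log2(B) stays near 0 at coverage >= 500
        regardless of the true allelic skew."""
        config = SimulationConfig(
            seed=31, n_embryos=1, cells_per_embryo=1, n_loci=500,
            ase_fraction=1.0, ai_fraction=0.0,
            ase_log2_skew_law={"name": "constant", "value": 2.0},
            genotype_probs=dict(ALL_HET),
            coverage_law={"name": "fixed", "mean": 500, "min": 500})
        result = generate_cells(config)
        cell = next(iter(counts_from_frame(result.counts).values()))
        values = [math.log2(strand_balance(sac, result.loci[k]))
                  for k, sac in sorted(cell.items())]
        assert abs(float(np.median(values))) < 0.1
        assert float(np.std(values)) < 0.25


class TestBalanceDistribution:
    def test_requires_fifty_loci(self, locus):
        het = [(make_counts(locus, ref_plus=10, alt_plus=10), locus)] * 49
        with pytest.raises(ValueError, match="insufficient heterozygous loci"):
            build_balance_distribution(het)

    def test_all_balanced_gives_zero_center(self, locus):
        het = [(make_counts(locus, ref_plus=10, ref_minus=10,
                            alt_plus=10, alt_minus=10), locus)] * 60
        null = build_balance_distribution(het)
        assert null.n == 60
        assert np.all(null.values == 0.0)
        assert null.center == 0.0

    def test_unbiased_cell_median_near_zero(self, balanced_cell):
        null = build_balance_distribution(balanced_cell[:500])
        assert abs(null.center) < 0.1


class TestAsePvalue:
    def _null(self, values):
        arr = np.asarray(values, dtype=float)
        return BalanceDistribution("c", arr, float(np.median(arr)))

    def test_explicit_tail_count_oracle(self):
        """p on a nine-value list equals brute-force two-tailed counting."""
        values = [-0.3, -0.2, -0.1, 0, 0, 0, 0.1, 0.2, 0.3]
        null = self._null(values)
        r = 0.25
        brute = (1 + sum(1 for v in values if abs(v - 0) >= abs(r - 0))) / (len(values) + 1)
        assert brute == pytest.approx(0.3)
        assert ase_pvalue(r, null) == pytest.approx(brute)

    def test_center_value_gives_p_one(self):
        null = self._null([-0.2, -0.1, 0, 0.1, 0.2])
        assert ase_pvalue(0.0, null) == 1.0

    def test_floor_is_one_over_n_plus_one(self):
        null = self._null([-0.2, -0.1, 0, 0.1, 0.2])
        assert ase_pvalue(99.0, null) == pytest.approx(1 / 6)

    @given(st.floats(-8, 8), st.floats(-8, 8))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_deviation(self, r1, r2):
        rng = np.random.default_rng(0)
        null = self._null(rng.normal(0, 0.4, 201))
        if abs(r1 - null.center) <= abs(r2 - null.center):
            assert ase_pvalue(r1, null) >= ase_pvalue(r2, null)


class TestAseCalls:
    def test_type_one_error_near_alpha(self, balanced_cell):
        """With no true ASE the call rate at alpha=0.01 stays within
        binomial tolerance of alpha."""
        caller = AseCaller(alpha=0.01).fit(balanced_cell)
        rate = float(caller.predict(balanced_cell).mean())
        assert 0.002 <= rate <= 0.03

    def test_power_at_strong_skew(self):
        """True log2 skew of 2 at coverage >= 50 is detected >= 80% of the
        time against a null fitted on the same loci."""
        config = SimulationConfig(
            seed=32, n_embryos=1, cells_per_embryo=1, n_loci=2000,
            ase_fraction=1.0, ai_fraction=0.0,
            ase_log2_skew_law={"name": "constant", "value": 2.0},
            genotype_probs=dict(ALL_HET),
            coverage_law={"name": "negative_binomial", "mean": 60,
                          "dispersion": 5, "min": 50})
        result = generate_cells(config)
        cell = next(iter(counts_from_frame(result.counts).values()))
        het = [(sac, result.loci[k]) for k, sac in sorted(cell.items())]
        caller = AseCaller().fit(het)
        assert float(caller.predict(het).mean()) >= 0.80

    def test_summary_percentage_convention(self, balanced_cell):
        calls, summary = call_ase(balanced_cell[:1042], n_selected=1500)
        assert summary["n_het"] == 1042
        assert summary["ase_pct"] == pytest.approx(
            100.0 * summary["n_ase"] / 1042)
        assert summary["expected_ase_fp"] == pytest.approx(1042 * 0.01)

    def test_alpha_one_calls_every_locus(self, balanced_cell):
        _, summary = call_ase(balanced_cell[:200], alpha=1.0)
        assert summary["n_ase"] == summary["n_het"]


class TestDirectionConcordance:
    @staticmethod
    def _calls(cell, entries):
        from scallele.ase import AseCall
        return {("chr1", pos): AseCall(cell, "chr1", pos, 10, 5, lr, 0.5, False)
                for pos, lr in entries}

    def test_same_sign_concordant_opposite_discordant(self):
        calls = {"b1": self._calls("b1", [(100, 0.8), (200, 0.8)]),
                 "b2": self._calls("b2", [(100, 0.3), (200, -0.3)])}
        df = direction_concordance(calls, {"E1": ["b1", "b2"]})
        assert df.loc[0, "n_loci"] == 2
        assert df.loc[0, "concordance"] == pytest.approx(0.5)

    def test_zero_ratio_excluded(self):
        calls = {"b1": self._calls("b1", [(100, 0.0)]),
                 "b2": self._calls("b2", [(100, 0.4)])}
        df = direction_concordance(calls, {"E1": ["b1", "b2"]})
        assert df.loc[0, "n_loci"] == 0
        assert np.isnan(df.loc[0, "concordance"])

    def test_shared_skew_sisters_mostly_concordant(self):
        """Sister cells sharing every true skew at high coverage agree in
        direction for >90% of loci."""
        config = SimulationConfig(
            seed=33, n_embryos=1, cells_per_embryo=2, n_loci=600,
            ase_fraction=1.0, ai_fraction=0.0,
            genotype_probs=dict(ALL_HET),
            coverage_law={"name": "negative_binomial", "mean": 150,
                          "dispersion": 5, "min": 100})
        result = generate_cells(config)
        by_cell = counts_from_frame(result.counts)
        calls_by_cell = {}
        for cell_id, cell in by_cell.items():
            het = [(sac, result.loci[k]) for k, sac in sorted(cell.items())]
            calls, _ = call_ase(het)
            calls_by_cell[cell_id] = {(c.chrom, c.pos): c for c in calls}
        df = direction_concordance(calls_by_cell, {"E1": sorted(by_cell)})
        assert df.loc[0, "concordance"] > 0.9
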