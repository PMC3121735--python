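"""Paired-blastomere allelic imbalance: chi-square, FC filter, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scallele.counts import counts_from_frame
from scallele.imbalance import ai_summary, call_ai, call_ai_embryo, expected_ai_fp
from scallele.io import SnpLocus
from scallele.simulate import SimulationConfig, generate_cells

from conftest import ALL_HET, make_counts


def pearson_chi2_oracle(table):
    """Closed-form Pearson chi-square for a 2x2 table: N(ad-bc)^2 over the
    product of the margins."""
    (a, b), (c, d) = table
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


class TestCallAi:
    def test_identical_counts_null(self, locus):
        c1 = make_counts(locus, ref_plus=20, alt_plus=20, cell_id="b1")
        c2 = make_counts(locus, ref_plus=20, alt_plus=20, cell_id="b2")
        call = call_ai(c1, c2, locus)
        assert call.ai_value == pytest.approx(1.0)
        assert call.chi2_stat == pytest.approx(0.0)
        assert not call.is_ai

    def test_strong_flip_detected(self, locus):
        """ref/alt 40:10 vs 10:40 gives chi2 = 36 (hand-computed) and
        AI = (41/11)/(11/41) ~ 13.9 -> called AI."""
        c1 = make_counts(locus, ref_plus=40, alt_plus=10, cell_id="b1")
        c2 = make_counts(locus, ref_plus=10, alt_plus=40, cell_id="b2")
        call = call_ai(c1, c2, locus)
        assert call.chi2_stat == pytest.approx(36.0)
        assert call.ai_value == pytest.approx((41 / 11) / (11 / 41))
        assert call.is_ai

    def test_borderline_depends_on_alpha(self, locus):
        """30:20 vs 20:30 has chi2 = 4.0, p ~ 0.0455: AI at alpha=0.05 but
        not at alpha=0.01."""
        c1 = make_counts(locus, ref_plus=30, alt_plus=20, cell_id="b1")
        c2 = make_counts(locus, ref_plus=20, alt_plus=30, cell_id="b2")
        call = call_ai(c1, c2, locus)
        assert call.chi2_stat == pytest.approx(4.0)
        assert call.p_value == pytest.approx(0.0455, abs=2e-4)
        assert call.ai_value == pytest.approx((31 / 21) / (21 / 31))
        assert call.is_ai
        assert not call_ai(c1, c2, locus, alpha=0.01).is_ai

    def test_fc_required_as_well_as_p(self, locus):
        """A significant chi-square without a >2 or <0.5 fold change is not
        called AI."""
        c1 = make_counts(locus, ref_plus=560, alt_plus=440, cell_id="b1")
        c2 = make_counts(locus, ref_plus=440, alt_plus=560, cell_id="b2")
        call = call_ai(c1, c2, locus)
        assert call.p_value < 0.05
        assert not call.fc_pass and not call.is_ai

    def test_chi2_matches_oracle_on_random_tables(self, locus):
        """Pipeline chi-square equals the closed-form contingency oracle to
        1e-9 over 200 random tables."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(1, 200, size=4)
            c1 = make_counts(locus, ref_plus=int(a), alt_plus=int(b), cell_id="b1")
            c2 = make_counts(locus, ref_plus=int(c), alt_plus=int(d), cell_id="b2")
            call = call_ai(c1, c2, locus)
            assert call.chi2_stat == pytest.approx(
                pearson_chi2_oracle(((a, b), (c, d))), abs=1e-9)
            checked += 1

    @given(a=st.integers(0, 100), b=st.integers(0, 100),
           c=st.integers(0, 100), d=st.integers(0, 100))
    @settings(deadline=None, max_examples=60)
    def test_symmetric_under_cell_swap(self, a, b, c, d):
        locus = SnpLocus("chr1", 100, "A", "G")
        if a + b == 0 or c + d == 0:
            return
        c1 = make_counts(locus, ref_plus=a, alt_plus=b, cell_id="b1")
        c2 = make_counts(locus, ref_plus=c, alt_plus=d, cell_id="b2")
        fwd = call_ai(c1, c2, locus)
        rev = call_ai(c2, c1, locus)
        assert fwd.log2_ai == pytest.approx(-rev.log2_ai)
        assert fwd.chi2_stat == pytest.approx(rev.chi2_stat, abs=1e-9)
        assert fwd.is_ai == rev.is_ai

    def test_degenerate_margin_is_null(self, locus):
        c1 = make_counts(locus, ref_plus=30, cell_id="b1")
        c2 = make_counts(locus, ref_plus=25, cell_id="b2")
        call = call_ai(c1, c2, locus)
        assert call.chi2_stat == 0.0 and call.p_value == 1.0


def _simulate_pair(seed, ai_fraction, ase_fraction=0.0, n_loci=2000):
    config = SimulationConfig(
        seed=seed, n_embryos=1, cells_per_embryo=2, n_loci=n_loci,
        ase_fraction=ase_fraction, ai_fraction=ai_fraction,
        genotype_probs=dict(ALL_HET),
        coverage_law={"name": "negative_binomial", "mean": 60,
                      "dispersion": 5, "min": 50})
    result = generate_cells(config)
    return result, counts_from_frame(result.counts)


class TestAiRecovery:
    def test_true_ai_detected_null_controlled(self):
        """Loci with per-cell skews are called AI >= 60% of the time while
        shared-skew loci stay below 7%."""
        result, by_cell = _simulate_pair(seed=41, ai_fraction=0.5, ase_fraction=0.3)
        cells = sorted(by_cell)
        truth = result.truth[result.truth.cell_id == cells[0]].set_index("pos")
        det = {True: [0, 0], False: [0, 0]}
        for key in sorted(by_cell[cells[0]]):
            call = call_ai(by_cell[cells[0]][key], by_cell[cells[1]][key],
                           result.loci[key])
            bucket = det[bool(truth.loc[key[1], "is_ai"])]
            bucket[0] += 1
            bucket[1] += int(call.is_ai)
        assert det[True][1] / det[True][0] >= 0.60
        assert det[False][1] / det[False][0] <= 0.07

    def test_null_pair_rate_bounded(self):
        """Sister cells with fully shared skews: AI calls stay below the
        alpha=0.05 level plus binomial slack."""
        result, by_cell = _simulate_pair(seed=42, ai_fraction=0.0, ase_fraction=0.45)
        cells = sorted(by_cell)
        calls = [call_ai(by_cell[cells[0]][k], by_cell[cells[1]][k], result.loci[k])
                 for k in sorted(by_cell[cells[0]])]
        rate = np.mean([c.is_ai for c in calls])
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(calls))


class TestSummary:
    def test_embryo_counts_shared_by_pair(self):
        result, by_cell = _simulate_pair(seed=43, ai_fraction=0.2, n_loci=400)
        cells = sorted(by_cell)
        het_keys = {c: set(by_cell[c]) for c in cells}
        calls = call_ai_embryo(by_cell, het_keys, result.loci, "E1", cells)
        df = ai_summary(calls, estimate_fp=False)
        assert df.loc[0, "embryo_id"] == "E1"
        assert df.loc[0, "n_tested"] == len(set(by_cell[cells[0]]) & set(by_cell[cells[1]]))
        assert df.loc[0, "ai_pct"] == pytest.approx(
            100 * df.loc[0, "n_ai"] / df.loc[0, "n_tested"])

    def test_expected_fp_tracks_null_call_count(self):
        """The permutation-based expected-false-positive estimate is close
        to the realised null AI count when no locus is truly imbalanced."""
        result, by_cell = _simulate_pair(seed=44, ai_fraction=0.0, n_loci=1000)
        cells = sorted(by_cell)
        calls = [call_ai(by_cell[cells[0]][k], by_cell[cells[1]][k], result.loci[k],
                         embryo_id="E1")
                 for k in sorted(by_cell[cells[0]])]
        n_called = sum(c.is_ai for c in calls)
        fp = expected_ai_fp(calls, seed=1)
        assert fp == pytest.approx(n_called, abs=max(12, 0.8 * n_called))

    def test_empty_input(self):
        assert ai_summary([], estimate_fp=False).empty
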