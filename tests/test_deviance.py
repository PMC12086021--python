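"""OEI / MI definitions, population tests, controls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oddball import studies
from oddball.deviance import (
    adaptation_control,
    compute_mi,
    compute_oei,
    matched_resampling,
    modulation_index_table,
    oddball_summary,
    population_tests,
    early_late_effect_comparison,
)

positive = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestIndices:
    def test_oei_direct_formula(self):
        assert compute_oei(10.0, 5.0) == pytest.approx(1 / 3)
        assert compute_oei(7.0, 7.0) == 0.0

    def test_mi_direct_formula(self):
        assert compute_mi(10.0, 5.0) == pytest.approx(-1 / 3)
        assert compute_mi(4.0, 4.0) == 0.0

    def test_zero_denominator_undefined(self):
        assert math.isnan(compute_oei(0.0, 0.0))
        assert math.isnan(compute_mi(0.0, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(o=positive, s=positive)
    def test_oei_bounded_and_antisymmetric(self, o, s):
        oei = compute_oei(o, s)
        if math.isnan(oei):
            assert o + s == 0
        else:
            assert -1.0 <= oei <= 1.0
            assert compute_oei(s, o) == pytest.approx(-oei, abs=1e-12)


class TestOeiConvergence:
    @pytest.mark.parametrize("gain", [1.2, 1.5, 2.0])
    def test_population_oei_converges_to_gain_formula(self, gain):
        """For baseline-free tuned units, OEI -> (g-1)/(g+1)."""
        oei = studies.oei_gain_recovery(gain, n_oddballs_per_role=200, n_neurons=60, rng=5)
        assert oei == pytest.approx((gain - 1) / (gain + 1), abs=0.02)


class TestSummaryTables:
    def test_oddball_summary_means_and_oei(self, medium_responses):
        summary = oddball_summary(medium_responses)
        assert {"O", "S", "oei"} <= set(summary.columns)
        row = summary.iloc[0]
        assert row["oei"] == pytest.approx((row["O"] - row["S"]) / (row["O"] + row["S"]))
        assert (summary["n_oddball"] >= 30).all()

    def test_first_standard_exclusion_reduces_standard_count(self, medium_responses):
        """Dropping the standard right after each oddball removes exactly one
        standard trial per oddball from S."""
        full = oddball_summary(medium_responses)
        trimmed = oddball_summary(medium_responses, exclude_first_standard=True)
        merged = full.merge(trimmed, on=["neuron_id", "stimulus_id", "period"], suffixes=("", "_t"))
        assert (merged["n_oddball"] == merged["n_oddball_t"]).all()
        # each oddball of stimulus A precedes a standard of the *other*
        # stimulus, so the removed standards belong to the companion block
        per_period = merged.groupby(["neuron_id", "period"])[["n_standard", "n_standard_t"]].sum()
        odd_per_period = merged.groupby(["neuron_id", "period"])["n_oddball"].sum()
        removed = per_period["n_standard"] - per_period["n_standard_t"]
        # every oddball except the last of each of the 4 blocks precedes a
        # standard, so exactly (n_oddballs - n_blocks) standards are removed
        assert (removed == odd_per_period - 4).all()

    def test_baseline_subtraction_changes_oei_scale(self, medium_responses):
        raw = oddball_summary(medium_responses)
        sub = oddball_summary(medium_responses, baseline_subtract=True)
        assert (sub["O"] <= raw["O"] + 1e-9).all()

    def test_modulation_index_roles(self, medium_responses):
        summary = oddball_summary(medium_responses)
        mi = modulation_index_table(summary)
        assert set(mi["role"]) == {"oddball", "standard"}
        valid = mi["mi"].dropna()
        assert ((valid >= -1) & (valid <= 1)).all()


class TestPopulationTests:
    def _summary(self, oei_sal, oei_doi, oei_pre=None):
        oei_pre = oei_sal if oei_pre is None else oei_pre
        rows = []
        for i, (a, b, c) in enumerate(zip(oei_pre, oei_sal, oei_doi)):
            for period, oei in (("pre", a), ("saline", b), ("doi", c)):
                rows.append(
                    {
                        "neuron_id": f"n{i}", "stimulus_id": "chord_8kHz",
                        "period": period, "O": 1 + oei, "S": 1 - oei,
                        "n_oddball": 50, "n_standard": 500, "oei": oei,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_periods_give_p_one(self):
        oei = np.linspace(0.1, 0.4, 20)
        out = population_tests(self._summary(oei, oei))
        assert out["p"].iloc[0] == 1.0

    def test_three_neurons_give_undefined_p(self):
        oei = np.array([0.1, 0.2, 0.3])
        out = population_tests(self._summary(oei, oei * 0.5))
        assert math.isnan(out["p"].iloc[0])

    def test_oei_reduction_detected(self):
        rng = np.random.default_rng(3)
        sal = rng.normal(0.3, 0.05, 50)
        out = population_tests(self._summary(sal, sal - 0.15))
        assert out["p"].iloc[0] < 1e-4
        assert out["median_oei_doi"].iloc[0] < out["median_oei_saline"].iloc[0]


class TestAdaptationControl:
    def test_drift_only_change_is_symmetric_across_transitions(self):
        """Equal multiplicative decay each period: MI(Pre-Sal) equals
        MI(Sal-DOI) and the paired comparison stays null."""
        rng = np.random.default_rng(6)
        rows = []
        for i in range(60):
            o0 = rng.uniform(5, 20)
            decay = 0.9
            for k, period in enumerate(("pre", "saline", "doi")):
                o = o0 * decay**k * rng.normal(1, 0.02)
                rows.append(
                    {
                        "neuron_id": f"n{i}", "stimulus_id": "chord_8kHz",
                        "period": period, "O": o, "S": o * 0.8,
                        "n_oddball": 50, "n_standard": 500,
                        "oei": (o - o * 0.8) / (o + o * 0.8),
                    }
                )
        out = adaptation_control(pd.DataFrame(rows))
        row = out.iloc[0]
        assert row["median_mi_pre_sal"] == pytest.approx(row["median_mi_sal_doi"], abs=0.02)
        assert row["p_mi_comparison"] > 0.05

    def test_doi_only_effect_detected(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(200):
            o0 = rng.uniform(5, 20)
            for period, scale in (("pre", 1.0), ("saline", 1.0), ("doi", 0.7)):
                o = o0 * scale * rng.normal(1, 0.05)
                rows.append(
                    {
                        "neuron_id": f"n{i}", "stimulus_id": "chord_8kHz",
                        "period": period, "O": o, "S": o * 0.8,
                        "n_oddball": 50, "n_standard": 500, "oei": 0.1,
                    }
                )
        out = adaptation_control(pd.DataFrame(rows))
        row = out.iloc[0]
        assert row["p_oddball_pre_sal"] > 0.05
        assert row["p_oddball_sal_doi"] < 1e-6
        assert row["median_mi_sal_doi"] < row["median_mi_pre_sal"]
        assert row["p_mi_comparison"] < 0.001


class TestMatchedResampling:
    def test_identity_late_set_returns_full_subsets(self):
        rng = np.random.default_rng(1)
        sal = rng.normal(0.3, 0.1, 50)
        doi = sal - 0.1
        out = matched_resampling(sal, sal, doi, n_resamples=5, rng=2)
        assert all(len(idx) == 50 for idx in out.subsets)
        assert out.fraction_saline_gt_doi == 1.0

    def test_fixed_seed_reproduces_subsets(self):
        rng = np.random.default_rng(4)
        early = rng.normal(0.25, 0.1, 80)
        late = rng.normal(0.15, 0.1, 120)
        doi = late - 0.1
        a = matched_resampling(early, late, doi, n_resamples=10, rng=7)
        b = matched_resampling(early, late, doi, n_resamples=10, rng=7)
        for i1, i2 in zip(a.subsets, b.subsets):
            np.testing.assert_array_equal(np.sort(i1), np.sort(i2))

    def test_subset_means_match_target_within_tolerance(self):
        out = studies.resampling_control(n_resamples=20, rng=3)
        assert np.all(np.abs(out.subset_mean_saline_oei - out.target_mean) <= 0.01 + 1e-12)

    def test_unreachable_target_raises(self):
        late = np.full(30, 0.0)
        with pytest.raises(ValueError):
            matched_resampling(np.full(10, 0.9), late, late - 0.1, n_resamples=2,
                               rng=0, subset_size=25)


def test_early_late_effect_comparison_null_and_effect():
    rng = np.random.default_rng(11)
    early_sal = rng.normal(0.3, 0.1, 80)
    late_sal = rng.normal(0.2, 0.1, 80)
    effect = 0.12
    same = early_late_effect_comparison(early_sal, early_sal - effect, late_sal, late_sal - effect)
    assert same["p"] > 0.05
    assert same["median_effect_early"] == pytest.approx(effect, abs=0.02)
    diff = early_late_effect_comparison(early_sal, early_sal - effect, late_sal, late_sal - 0.01)
    assert diff["p"] < 1e-6
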