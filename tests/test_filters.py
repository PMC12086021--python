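"""Inclusion criteria: stability, responsiveness, evoked floor, locomotion."""

import math

import numpy as np
import pandas as pd
import pytest

from oddball.filters import (
    classify_locomotion,
    evoked_floor,
    oei_stability_filter,
    otsu_threshold,
    responsiveness_test,
    smooth_boxcar,
    stability_filter,
)


def _resp(evoked, baseline=None, stimulus="s1", period="pre"):
    evoked = np.asarray(evoked, dtype=float)
    baseline = np.zeros_like(evoked) if baseline is None else np.asarray(baseline, dtype=float)
    return pd.DataFrame(
        {
            "stimulus_id": stimulus,
            "period": period,
            "evoked_rate": evoked,
            "baseline_rate": baseline,
        }
    )


class TestStability:
    @pytest.mark.parametrize(
        "pre,sal,expect_stable",
        [
            (10.0, 12.0, True),    # 20% change
            (10.0, 14.0, False),   # 40% change
            (10.0, 13.0, True),    # exactly 30%: criterion is "did not change >30%"
        ],
    )
    def test_evoked_change_thresholds(self, pre, sal, expect_stable):
        stable, diag = stability_filter(_resp([pre] * 4), _resp([sal] * 4))
        assert stable is expect_stable
        assert diag["evoked_change"] == pytest.approx(abs(sal - pre) / pre)

    def test_spontaneous_change_also_screened(self):
        pre = _resp([10.0] * 4, baseline=[5.0] * 4)
        sal = _resp([10.0] * 4, baseline=[8.0] * 4)  # 60% spontaneous change
        stable, _ = stability_filter(pre, sal)
        assert not stable

    def test_per_stimulus_screen_is_stricter_than_pooled(self):
        """Two stimuli drifting in opposite directions cancel in the pooled
        mean but fail the per-stimulus screen."""
        pre = pd.concat([_resp([10.0] * 4, stimulus="s1"), _resp([10.0] * 4, stimulus="s2")])
        sal = pd.concat([_resp([14.0] * 4, stimulus="s1"), _resp([6.0] * 4, stimulus="s2")])
        pooled, _ = stability_filter(pre, sal)
        per_stim, diag = stability_filter(pre, sal, pool_stimuli=False)
        assert pooled
        assert not per_stim
        assert diag["evoked_change"] == pytest.approx(0.4)

    def test_zero_pre_rate(self):
        stable, _ = stability_filter(_resp([0.0] * 4), _resp([1.0] * 4))
        assert not stable
        stable, _ = stability_filter(_resp([0.0] * 4), _resp([0.0] * 4))
        assert stable


class TestResponsiveness:
    def test_identical_evoked_and_baseline_not_responsive(self):
        r = _resp([5.0] * 10, baseline=[5.0] * 10)
        flag, p = responsiveness_test(r)
        assert not flag and p == 1.0

    def test_bonferroni_correction_blocks_marginal_stimulus(self):
        """With 7 trials all shifted the same way, the exact signed-rank
        two-sided p is 2/2^7 = 0.015625: significant alone, but not after
        Bonferroni correction over 16 stimuli (0.25 > 0.05)."""
        frames = [_resp([5.0] * 7, baseline=[5.0] * 7, stimulus=f"s{k}") for k in range(15)]
        frames.append(_resp([6.0] * 7, baseline=[5.0] * 7, stimulus="hot"))
        many = pd.concat(frames, ignore_index=True)
        flag_many, p_many = responsiveness_test(many)
        assert p_many == pytest.approx(0.015625 * 16)
        assert not flag_many
        flag_one, p_one = responsiveness_test(frames[-1])
        assert p_one == pytest.approx(0.015625)
        assert flag_one

    def test_strong_response_detected(self, rng):
        evoked = rng.poisson(30 * 0.1, 20) / 0.1
        baseline = rng.poisson(10 * 0.2, 20) / 0.2
        flag, _ = responsiveness_test(_resp(evoked, baseline))
        assert flag

    def test_power_on_simulated_3x_response(self, rng):
        """A neuron with evoked = 3x baseline and 20 trials is detected
        essentially always."""
        hits = 0
        for _ in range(50):
            evoked = rng.poisson(30 * 0.1, 20) / 0.1
            baseline = rng.poisson(10 * 0.2, 20) / 0.2
            flag, _ = responsiveness_test(_resp(evoked, baseline))
            hits += flag
        assert hits >= 49

    def test_adding_silent_stimuli_never_creates_responsiveness(self):
        base = _resp([6.0] * 7, baseline=[5.0] * 7, stimulus="hot")
        assert responsiveness_test(base)[0]
        grown = pd.concat(
            [base] + [_resp([5.0] * 7, baseline=[5.0] * 7, stimulus=f"s{k}") for k in range(20)],
            ignore_index=True,
        )
        flag, _ = responsiveness_test(grown)
        assert not flag  # Bonferroni only grows the corrected p


class TestEvokedFloor:
    def _by_period(self, rates):
        return {
            p: _resp([r] * 4, period=p)
            for p, r in zip(("pre", "saline", "doi"), rates)
        }

    @pytest.mark.parametrize(
        "rates,expected",
        [((8, 6, 5.5), True), ((8, 6, 4), False), ((8, 6, 5.0), False)],
    )
    def test_floor_is_strict(self, rates, expected):
        flag, _ = evoked_floor(self._by_period(rates))
        assert flag is expected

    def test_missing_period_fails(self):
        by = self._by_period((8, 6, 7))
        del by["doi"]
        flag, _ = evoked_floor(by)
        assert not flag


class TestOeiStability:
    @pytest.mark.parametrize(
        "pre,sal,keep",
        [
            (0.40, 0.45, True),   # 12.5% change
            (0.40, 0.20, False),  # 50% change
            (0.40, 0.52, False),  # exactly 30%: criterion is "<30%"
        ],
    )
    def test_thresholds(self, pre, sal, keep):
        assert oei_stability_filter(pre, sal) is keep

    def test_zero_and_nan_pre(self):
        assert oei_stability_filter(0.0, 0.0)
        assert not oei_stability_filter(0.0, 0.1)
        assert not oei_stability_filter(math.nan, 0.1)


class TestLocomotion:
    def test_boxcar_impulse_plateau(self):
        trace = np.zeros(100)
        trace[50] = 1.0
        sm = smooth_boxcar(trace, 10)
        assert np.isclose(sm.max(), 0.1)
        assert np.sum(np.isclose(sm, 0.1)) == 10

    def test_constant_zero_trace_all_stationary(self):
        flags = classify_locomotion(np.zeros(300), np.array([1.0, 5.0]), threshold=0.5)
        assert list(flags.to_numpy(na_value=False)) == [False, False]

    def test_onset_outside_trace_is_unknown(self):
        flags = classify_locomotion(np.ones(30), np.array([0.5, 99.0]), threshold=0.5)
        assert bool(flags[0]) is True
        assert flags[1] is pd.NA

    def test_otsu_separates_bimodal(self, rng):
        values = np.concatenate([rng.normal(0.05, 0.01, 500), rng.normal(1.0, 0.05, 500)])
        th = otsu_threshold(values)
        assert 0.1 < th < 0.95
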