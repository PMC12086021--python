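"""Generative model: count process calibration, determinism, role symmetry."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oddball.filters import classify_locomotion
from oddball.session import ResponseWindows, align_and_count
from oddball.simulate import (
    PopulationPriors,
    SimConfig,
    SimNeuron,
    draw_neurons,
    sample_counts,
    simulate_motion_trace,
    simulate_session,
    simulate_spikes,
    simulate_trial_responses,
    stimulus_log2khz,
)
from oddball.stimuli import PERIODS, build_oddball_block, chord


def _flat_neuron(baseline=0.0, amp=20.0, gain=1.0, phi=1.0, nid="n0"):
    return SimNeuron(
        neuron_id=nid,
        baseline_rate={p: baseline for p in PERIODS},
        bf_log2khz={p: math.log2(10.0) for p in PERIODS},
        sigma_octaves={p: 3.0 for p in PERIODS},
        amplitude={p: amp for p in PERIODS},
        oddball_gain={p: gain for p in PERIODS},
        dispersion={p: phi for p in PERIODS},
    )


class TestCountProcess:
    def test_poisson_fano_is_one(self, rng):
        counts = sample_counts(rng, np.full(10_000, 2.0), 1.0)
        ff = counts.var(ddof=1) / counts.mean()
        assert ff == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("phi", [1.3, 2.0])
    def test_overdispersion_target_recovered(self, phi, rng):
        counts = sample_counts(rng, np.full(10_000, 2.0), phi)
        ff = counts.var(ddof=1) / counts.mean()
        assert ff == pytest.approx(phi, rel=0.05)

    def test_underdispersion_via_binomial_thinning(self, rng):
        counts = sample_counts(rng, np.full(20_000, 2.0), 0.7)
        assert counts.mean() == pytest.approx(2.0, rel=0.03)
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(0.7, rel=0.08)

    def test_mean_preserved_across_regimes(self, rng):
        for phi in (0.6, 1.0, 1.7):
            counts = sample_counts(rng, np.full(20_000, 3.0), phi)
            assert counts.mean() == pytest.approx(3.0, rel=0.03)

    def test_invalid_dispersion_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_counts(rng, np.array([1.0]), 0.0)


class TestSpikeSimulation:
    def test_zero_amplitude_means_evoked_equals_baseline(self, rng):
        neuron = _flat_neuron(baseline=10.0, amp=0.0)
        trials = build_oddball_block(chord(8.0), chord(13.0), 100, rng)
        stim_x = stimulus_log2khz({s.stimulus_id: s for s in (chord(8.0), chord(13.0))})
        rec = simulate_spikes(neuron, trials, stim_x, rng)
        out = align_and_count(rec, trials)
        assert out["evoked_rate"].mean() == pytest.approx(out["baseline_rate"].mean(), rel=0.1)

    def test_unity_gain_gives_zero_population_oei(self, rng):
        """With oddball_gain = 1 the two roles are exchangeable, so the
        mean OEI over many trials is ~0."""
        neuron = _flat_neuron(baseline=0.0, amp=30.0, gain=1.0)
        trials = build_oddball_block(chord(8.0), chord(13.0), 300, rng)
        stim_x = stimulus_log2khz({s.stimulus_id: s for s in (chord(8.0), chord(13.0))})
        resp = simulate_trial_responses([neuron], trials, stim_x, rng)
        means = resp.groupby(["stimulus_id", "role"])["evoked_rate"].mean()
        for sid in ("chord_8kHz", "chord_13kHz"):
            o, s = means[(sid, "oddball")], means[(sid, "standard")]
            assert abs((o - s) / (o + s)) < 0.05

    def test_role_symmetry_of_response_distribution(self, rng):
        """At gain 1, the response distribution to a stimulus is the same
        whether it serves as standard or oddball (rank-sum not rejected)."""
        neuron = _flat_neuron(baseline=0.0, amp=40.0, gain=1.0)
        trials = build_oddball_block(chord(8.0), chord(13.0), 200, rng)
        stim_x = stimulus_log2khz({s.stimulus_id: s for s in (chord(8.0), chord(13.0))})
        resp = simulate_trial_responses([neuron], trials, stim_x, np.random.default_rng(5))
        g = resp[resp["stimulus_id"] == "chord_8kHz"]
        odd = g.loc[g["role"] == "oddball", "evoked_count"]
        std = g.loc[g["role"] == "standard", "evoked_count"]
        assert stats.mannwhitneyu(odd, std).pvalue > 0.01

    def test_oddball_gain_raises_only_oddball_response(self, rng):
        neuron = _flat_neuron(baseline=0.0, amp=30.0, gain=1.5)
        trials = build_oddball_block(chord(8.0), chord(13.0), 400, rng)
        stim_x = stimulus_log2khz({s.stimulus_id: s for s in (chord(8.0), chord(13.0))})
        resp = simulate_trial_responses([neuron], trials, stim_x, rng)
        means = resp.groupby("role")["evoked_rate"].mean()
        assert means["oddball"] / means["standard"] == pytest.approx(1.5, rel=0.05)

    def test_spike_and_count_paths_agree(self):
        """Spike-time placement followed by re-counting reproduces the
        count-level statistics."""
        config = SimConfig(n_neurons=4, tuning_reps=10, min_oddballs=20, seed=3)
        with_spikes = simulate_session(config, spike_times=True, motion=False)
        counts_only = simulate_session(config, spike_times=False, motion=False)
        a = with_spikes.responses.groupby(["neuron_id", "period"])["evoked_rate"].mean()
        b = counts_only.responses.groupby(["neuron_id", "period"])["evoked_rate"].mean()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=0.25, atol=1.0)


class TestDeterminism:
    def test_same_seed_identical_sessions(self):
        config = SimConfig(n_neurons=3, tuning_reps=5, min_oddballs=5, seed=21)
        s1 = simulate_session(config)
        s2 = simulate_session(config)
        pd.testing.assert_frame_equal(s1.trials, s2.trials)
        pd.testing.assert_frame_equal(s1.responses, s2.responses)
        for r1, r2 in zip(s1.recordings, s2.recordings):
            np.testing.assert_array_equal(r1.spike_times_s, r2.spike_times_s)
        np.testing.assert_array_equal(s1.motion_trace, s2.motion_trace)

    def test_neuron_substreams_independent_of_population_size(self):
        config_small = SimConfig(n_neurons=3, seed=5)
        config_large = SimConfig(n_neurons=8, seed=5)
        small = draw_neurons(config_small)
        large = draw_neurons(config_large)
        for a, b in zip(small, large):
            assert a.baseline_rate == b.baseline_rate
            assert a.bf_log2khz == b.bf_log2khz


class TestMotionTrace:
    def test_all_stationary_recovered(self, rng):
        trials = build_oddball_block(chord(8.0), chord(13.0), 20, rng)
        trials["running"] = pd.array([False] * len(trials), dtype="boolean")
        trace = simulate_motion_trace(trials, rng=rng)
        flags = classify_locomotion(trace, trials["onset_s"].to_numpy(), threshold=0.5)
        assert not flags.to_numpy(na_value=False).any()

    def test_mixed_labels_recovered(self, rng):
        trials = build_oddball_block(chord(8.0), chord(13.0), 60, rng)
        trials["running"] = pd.array(rng.random(len(trials)) < 0.4, dtype="boolean")
        trace = simulate_motion_trace(trials, rng=rng)
        flags = classify_locomotion(trace, trials["onset_s"].to_numpy())
        truth = trials["running"].to_numpy(na_value=False)
        got = flags.to_numpy(na_value=False)
        assert (truth == got).mean() >= 0.99

    def test_same_seed_identical_trace(self, rng):
        trials = build_oddball_block(chord(8.0), chord(13.0), 10, np.random.default_rng(0))
        trials["running"] = pd.array([True, False] * (len(trials) // 2) + [True] * (len(trials) % 2), dtype="boolean")
        a = simulate_motion_trace(trials, rng=np.random.default_rng(9))
        b = simulate_motion_trace(trials, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


def test_priors_validation():
    with pytest.raises(ValueError):
        SimConfig(running_prob={"pre": 1.5, "saline": 0.2, "doi": 0.2})
    with pytest.raises(ValueError):
        _flat_neuron(baseline=-1.0)
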