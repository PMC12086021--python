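"""Generative model of oddball-session spike trains.

The generator emulates a three-period pharmacology session (pre-injection,
saline, DOI) in which each period presents the same three stimulus ensembles:
a 16-frequency pure-tone tuning block, a chord oddball paradigm and an FM
oddball paradigm (see :mod:`oddball.stimuli`).  Neurons are log-frequency
Gaussian-tuned rate units:

    rate(trial) = baseline + A * exp(-(x - bf)^2 / (2 sigma^2))
                  * g_oddball(role) * g_running(state)

with ``x`` the stimulus log2 frequency, ``A`` the tuning amplitude (spk/s),
``g_oddball`` a multiplicative gain applied on oddball trials only (deviance
detection is modeled as extra gain on rare stimuli), and ``g_running`` a gain
applied while the animal runs.  All parameters may differ between periods,
which is how drug effects are expressed: the default configuration reduces
evoked and spontaneous rates by 20 %, drops the oddball gain from 1.5 to 1.1
and raises count dispersion from 1.0 to 1.3 under DOI, leaving the
pre-injection and saline periods statistically identical.

Spike counts in the evoked window follow a count process with controllable
Fano factor ``phi`` (variance = phi * mean): Poisson for phi = 1, a
gamma-mixed Poisson (negative binomial) for phi > 1 and a binomial thinning
construction for phi < 1.  Spike times are placed uniformly within windows;
background spiking between windows is homogeneous Poisson at the baseline
rate.  All randomness flows from a single seeded generator hierarchy with
per-neuron substreams, so a given neuron is reproducible independently of
population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stimuli
from .session import NeuronRecording, ResponseWindows
from .stimuli import (
    PERIODS,
    StimulusSpec,
    build_oddball_block,
    build_tuning_block,
    chord,
    fm_sweep,
    pure_tone,
    tuning_frequencies_khz,
)

log = logging.getLogger(__name__)


def sample_counts(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Draw spike counts with E[N] = mean and Var[N] = phi * mean.

    phi = 1 gives Poisson; phi > 1 a gamma-mixed Poisson (negative binomial
    with shape r = mean / (phi - 1)); phi < 1 a binomial Binomial(n, 1 - phi)
    with randomized rounding of n = mean / (1 - phi).
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape).copy()
    if np.any(phi <= 0):
        raise ValueError("dispersion phi must be > 0")
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = np.isclose(phi, 1.0) | (mean == 0)
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    over = (~pois) & (phi > 1)
    if np.any(over):
        r = mean[over] / (phi[over] - 1.0)
        lam = rng.gamma(shape=r, scale=(phi[over] - 1.0))
        out[over] = rng.poisson(lam)
    under = (~pois) & (phi < 1)
    if np.any(under):
        p = 1.0 - phi[under]
        n_exact = mean[under] / p
        n_floor = np.floor(n_exact)
        n = (n_floor + (rng.random(n_exact.shape) < (n_exact - n_floor))).astype(np.int64)
        out[under] = rng.binomial(n, p)
    return out


@dataclass
class SimNeuron:
    """Generative parameters of one simulated unit.

    Per-period dictionaries are keyed by ``"pre"``, ``"saline"``, ``"doi"``.
    ``dispersion`` entries may be a scalar (used in both locomotion states) or
    a ``(stationary, running)`` pair.
    """

    neuron_id: str
    baseline_rate: dict[str, float]
    bf_log2khz: dict[str, float]
    sigma_octaves: dict[str, float]
    amplitude: dict[str, float]
    oddball_gain: dict[str, float]
    dispersion: dict[str, float | tuple[float, float]]
    running_gain: float = 1.0

    def __post_init__(self) -> None:
        for p, v in self.baseline_rate.items():
            if v < 0:
                raise ValueError(f"baseline_rate[{p}] must be >= 0")
        for p, v in self.amplitude.items():
            if v < 0:
                raise ValueError(f"amplitude[{p}] must be >= 0")
        for p, v in self.oddball_gain.items():
            if v < 0:
                raise ValueError(f"oddball_gain[{p}] must be >= 0")

    def phi(self, period: str, running: bool) -> float:
        d = self.dispersion[period]
        if np.isscalar(d):
            return float(d)  # type: ignore[arg-type]
        return float(d[1] if running else d[0])  # type: ignore[index]

    def evoked_component(self, period: str, x_log2khz: np.ndarray) -> np.ndarray:
        """Tuned evoked rate (spk/s above baseline) at log2 frequency x."""
        bf = self.bf_log2khz[period]
        sig = self.sigma_octaves[period]
        return self.amplitude[period] * np.exp(-((x_log2khz - bf) ** 2) / (2.0 * sig**2))


@dataclass
class PopulationPriors:
    """Population distributions from which neurons are drawn.

    Rates are lognormal (median, sigma of log); best frequencies uniform on
    the log2 tuning range; tuning widths uniform.  The saline oddball gain
    carries lognormal population spread (``gain_jitter_sd``); DOI effects are
    expressed as per-neuron ratios to saline with lognormal heterogeneity
    ``effect_jitter_sd`` -- zero heterogeneity plus unit ratios makes the DOI
    period identical to saline neuron by neuron.
    """

    baseline_rate_median: float = 3.0
    baseline_rate_logsd: float = 0.6
    amplitude_median: float = 20.0
    amplitude_logsd: float = 0.5
    bf_range_log2khz: tuple[float, float] = (np.log2(2.0), np.log2(40.0))
    sigma_range_octaves: tuple[float, float] = (0.3, 1.0)
    oddball_gain_saline: float = 1.5
    oddball_gain_doi: float = 1.1
    rate_scale_doi: float = 0.8
    dispersion_saline: float = 1.0
    dispersion_doi: float = 1.3
    running_gain: float = 1.2
    gain_jitter_sd: float = 0.08
    effect_jitter_sd: float = 0.08

    @classmethod
    def null(cls) -> "PopulationPriors":
        """Priors with no drug effect: each neuron's DOI-period parameters
        equal its saline parameters exactly (no effect also means no
        per-neuron effect heterogeneity)."""
        return cls(
            oddball_gain_doi=1.5, rate_scale_doi=1.0, dispersion_doi=1.0,
            effect_jitter_sd=0.0,
        )


@dataclass
class SimConfig:
    """Full parameterization of a simulated session.

    Defaults mirror the experimental design: 16 tuning frequencies at >= 20
    repetitions with 1-1.4 s interstimulus intervals; chord (8 / 13 kHz
    centers, 550 ms onset asynchrony) and FM (8-13 kHz sweeps, 600 ms onset
    asynchrony) oddball paradigms with 9-11 standards per oddball and at
    least 50 oddballs per block; running probabilities per period of
    0.44 / 0.20 / 0.72 (pre / saline / DOI).
    """

    n_neurons: int = 100
    tuning_reps: int = 20
    min_oddballs: int = 50
    isi_range_s: tuple[float, float] = (1.0, 1.4)
    chord_centers_khz: tuple[float, float] = (8.0, 13.0)
    chord_soa_s: float = stimuli.CHORD_SOA_S
    fm_range_khz: tuple[float, float] = (8.0, 13.0)
    fm_soa_s: float = stimuli.FM_SOA_S
    running_prob: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.44, "saline": 0.20, "doi": 0.72}
    )
    priors: PopulationPriors = field(default_factory=PopulationPriors)
    include_tuning: bool = True
    include_chords: bool = True
    include_fm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p, v in self.running_prob.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"running_prob[{p}] must be in [0, 1]")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["isi_range_s"] = list(d["isi_range_s"])
        d["chord_centers_khz"] = list(d["chord_centers_khz"])
        d["fm_range_khz"] = list(d["fm_range_khz"])
        d["priors"]["bf_range_log2khz"] = [float(v) for v in d["priors"]["bf_range_log2khz"]]
        d["priors"]["sigma_range_octaves"] = list(d["priors"]["sigma_range_octaves"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("isi_range_s", "chord_centers_khz", "fm_range_khz"):
            if key in d:
                d[key] = tuple(d[key])
        if "priors" in d and not isinstance(d["priors"], PopulationPriors):
            pr = dict(d["priors"])
            for key in ("bf_range_log2khz", "sigma_range_octaves"):
                if key in pr:
                    pr[key] = tuple(pr[key])
            d["priors"] = PopulationPriors(**pr)
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def stimulus_specs(self) -> dict[str, StimulusSpec]:
        """All stimuli of the session, keyed by stimulus id."""
        specs: dict[str, StimulusSpec] = {}
        if self.include_tuning:
            for f in tuning_frequencies_khz():
                s = pure_tone(f)
                specs[s.stimulus_id] = s
        if self.include_chords:
            for f in self.chord_centers_khz:
                s = chord(f)
                specs[s.stimulus_id] = s
        if self.include_fm:
            lo, hi = self.fm_range_khz
            for s in (fm_sweep(lo, hi), fm_sweep(hi, lo)):
                specs[s.stimulus_id] = s
        return specs


def stimulus_log2khz(specs: Mapping[str, StimulusSpec]) -> dict[str, float]:
    return {sid: spec.effective_log2khz() for sid, spec in specs.items()}


def draw_neurons(config: SimConfig, rng: np.random.Generator | int | None = None) -> list[SimNeuron]:
    """Draw a reproducible population of :class:`SimNeuron` from the priors.

    Each neuron uses its own substream spawned from ``rng``, so neuron ``i``
    is identical regardless of ``n_neurons``.
    """
    pr = config.priors
    base = np.random.default_rng(rng if rng is not None else config.seed)
    streams = base.spawn(config.n_neurons)
    neurons = []
    for i, sub in enumerate(streams):
        baseline = pr.baseline_rate_median * np.exp(sub.normal(0, pr.baseline_rate_logsd))
        amp = pr.amplitude_median * np.exp(sub.normal(0, pr.amplitude_logsd))
        bf = sub.uniform(*pr.bf_range_log2khz)
        sigma = sub.uniform(*pr.sigma_range_octaves)
        # Population spread of the saline-period gain, then per-neuron
        # heterogeneity of the DOI effect expressed as ratios to saline; with
        # effect_jitter_sd = 0 the DOI parameters equal saline exactly.
        gain_sal = pr.oddball_gain_saline * np.exp(sub.normal(0, pr.gain_jitter_sd))
        effect_jitter = lambda: np.exp(sub.normal(0, pr.effect_jitter_sd))
        gain_doi = gain_sal * (pr.oddball_gain_doi / pr.oddball_gain_saline) * effect_jitter()
        scale_doi = pr.rate_scale_doi * effect_jitter()
        neurons.append(
            SimNeuron(
                neuron_id=f"sim{i:04d}",
                baseline_rate={"pre": baseline, "saline": baseline, "doi": baseline * scale_doi},
                bf_log2khz={p: bf for p in PERIODS},
                sigma_octaves={p: sigma for p in PERIODS},
                amplitude={"pre": amp, "saline": amp, "doi": amp * scale_doi},
                oddball_gain={"pre": gain_sal, "saline": gain_sal, "doi": gain_doi},
                dispersion={
                    "pre": pr.dispersion_saline,
                    "saline": pr.dispersion_saline,
                    "doi": pr.dispersion_doi,
                },
                running_gain=pr.running_gain,
            )
        )
    return neurons


def _trial_arrays(trials: pd.DataFrame, stim_x: Mapping[str, float]):
    x = trials["stimulus_id"].map(stim_x)
    if x.isna().any():
        missing = sorted(trials.loc[x.isna(), "stimulus_id"].unique())
        raise KeyError(f"no frequency mapping for stimulus id(s) {missing}")
    running = trials["running"].fillna(False).to_numpy(dtype=bool)
    is_odd = (trials["role"] == "oddball").to_numpy()
    return x.to_numpy(dtype=float), running, is_odd


def evoked_rate_matrix(
    neurons: Sequence[SimNeuron],
    trials: pd.DataFrame,
    stim_x: Mapping[str, float],
) -> np.ndarray:
    """Expected evoked-window firing rate, shape ``(n_trials, n_neurons)``.

    The rate is baseline plus the tuned component scaled by the oddball and
    running gains; negative values cannot arise (all factors nonnegative).
    """
    x, running, is_odd = _trial_arrays(trials, stim_x)
    periods = trials["period"].to_numpy()
    out = np.zeros((len(trials), len(neurons)))
    for period in np.unique(periods):
        sel = periods == period
        xs = x[sel]
        for j, nrn in enumerate(neurons):
            ev = nrn.evoked_component(period, xs)
            gain = np.where(is_odd[sel], nrn.oddball_gain[period], 1.0)
            gain = gain * np.where(running[sel], nrn.running_gain, 1.0)
            out[sel, j] = nrn.baseline_rate[period] + ev * gain
    return out


def dispersion_matrix(
    neurons: Sequence[SimNeuron], trials: pd.DataFrame
) -> np.ndarray:
    periods = trials["period"].to_numpy()
    running = trials["running"].fillna(False).to_numpy(dtype=bool)
    out = np.ones((len(trials), len(neurons)))
    for period in np.unique(periods):
        sel = periods == period
        run_sel = running[sel]
        for j, nrn in enumerate(neurons):
            out[sel, j] = np.where(run_sel, nrn.phi(period, True), nrn.phi(period, False))
    return out


def simulate_trial_responses(
    neurons: Sequence[SimNeuron],
    trials: pd.DataFrame,
    stim_x: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
    windows: ResponseWindows | None = None,
) -> pd.DataFrame:
    """Count-level fast path: per-trial responses without spike timestamps.

    Draws the evoked-window and baseline-window counts directly from the
    count process; statistically identical to placing spikes and re-counting
    them, and the form the analysis consumes.  Returns a tidy frame with one
    row per trial x neuron.
    """
    rng = np.random.default_rng(rng)
    windows = windows or ResponseWindows()
    mean_rate = evoked_rate_matrix(neurons, trials, stim_x)
    phi = dispersion_matrix(neurons, trials)
    ev_len = trials["duration_s"].to_numpy(dtype=float)[:, None]
    ev_counts = sample_counts(rng, mean_rate * ev_len, phi)
    period_cat = pd.Categorical(trials["period"])
    base_by_period = np.array(
        [[nrn.baseline_rate[p] for nrn in neurons] for p in period_cat.categories]
    )
    base_rates = base_by_period[period_cat.codes]
    b_len = windows.baseline_length_s
    base_counts = rng.poisson(base_rates * b_len)

    n_trials, n_neurons = ev_counts.shape
    rep = trials.loc[trials.index.repeat(n_neurons)].reset_index(drop=True)
    rep.insert(0, "neuron_id", np.tile([nrn.neuron_id for nrn in neurons], n_trials))
    rep["evoked_count"] = ev_counts.ravel()
    rep["evoked_rate"] = (ev_counts / ev_len).ravel()
    rep["baseline_count"] = base_counts.ravel()
    rep["baseline_rate"] = base_counts.ravel() / b_len
    return rep


def simulate_spikes(
    neuron: SimNeuron,
    trials: pd.DataFrame,
    stim_x: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
    windows: ResponseWindows | None = None,
) -> NeuronRecording:
    """Generate a full spike-time vector for one neuron over the session.

    Evoked-window counts come from the dispersed count process with spikes
    placed uniformly within the window; everywhere else the neuron fires as a
    homogeneous Poisson process at its per-period baseline rate.
    """
    if trials.empty:
        raise ValueError("trials table is empty")
    rng = np.random.default_rng(rng)
    windows = windows or ResponseWindows()
    onsets = trials["onset_s"].to_numpy(dtype=float)
    durations = trials["duration_s"].to_numpy(dtype=float)
    e0, e1 = windows.evoked_edges(onsets, durations)

    mean_rate = evoked_rate_matrix([neuron], trials, stim_x)[:, 0]
    phi = dispersion_matrix([neuron], trials)[:, 0]
    counts = sample_counts(rng, mean_rate * (e1 - e0), phi)
    evoked_spikes = np.concatenate(
        [rng.uniform(a, b, size=c) for a, b, c in zip(e0, e1, counts)]
    ) if counts.sum() else np.array([])

    # Background Poisson per period span, thinned out of the evoked windows.
    bg_parts = []
    periods = trials["period"].to_numpy()
    for period in np.unique(periods):
        sel = periods == period
        t0 = onsets[sel].min() - 0.5
        t1 = (onsets[sel] + durations[sel]).max() + 0.5
        rate = neuron.baseline_rate[period]
        n_bg = rng.poisson(rate * (t1 - t0))
        bg_parts.append(rng.uniform(t0, t1, size=n_bg))
    bg = np.concatenate(bg_parts) if bg_parts else np.array([])
    if bg.size:
        edges = np.column_stack([e0, e1]).ravel()
        inside = np.searchsorted(edges, bg, side="right") % 2 == 1
        bg = bg[~inside]
    return NeuronRecording(neuron.neuron_id, np.sort(np.concatenate([bg, evoked_spikes])))


def simulate_motion_trace(
    trials: pd.DataFrame,
    frame_rate_hz: float = 30.0,
    rng: np.random.Generator | int | None = None,
    *,
    high: float = 1.0,
    low: float = 0.05,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Synthetic motion-energy series consistent with the trial running flags.

    The series is piecewise constant at a high (running) or low (stationary)
    level, switching state midway between trial onsets, with additive
    truncated Gaussian noise; after 10-frame boxcar smoothing the value at
    each onset separates the two states cleanly.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    rng = np.random.default_rng(rng)
    onsets = trials["onset_s"].to_numpy(dtype=float)
    running = trials["running"].fillna(False).to_numpy(dtype=bool)
    t_end = onsets.max() + trials["duration_s"].iloc[-1] + 1.0
    n_frames = int(np.ceil(t_end * frame_rate_hz)) + 1
    frame_t = np.arange(n_frames) / frame_rate_hz
    nearest = np.clip(np.searchsorted(onsets, frame_t), 1, len(onsets) - 1) if len(onsets) > 1 else np.zeros(n_frames, dtype=int)
    if len(onsets) > 1:
        left = onsets[nearest - 1]
        right = onsets[nearest]
        nearest = np.where(frame_t - left <= right - frame_t, nearest - 1, nearest)
    levels = np.where(running[nearest], high, low)
    trace = np.maximum(levels + rng.normal(0, noise_sd, size=n_frames), 0.0)
    return trace


@dataclass
class Session:
    """One simulated session: paradigm, ground-truth neurons and responses."""

    config: SimConfig
    trials: pd.DataFrame
    neurons: list[SimNeuron]
    responses: pd.DataFrame
    recordings: list[NeuronRecording] | None = None
    motion_trace: np.ndarray | None = None
    frame_rate_hz: float = 30.0

    @property
    def stim_x(self) -> dict[str, float]:
        return stimulus_log2khz(self.config.stimulus_specs())


def build_session_trials(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial table for the whole session: identical paradigm in each period."""
    period_tables = []
    block_counter = 0
    lo, hi = config.fm_range_khz
    for period in PERIODS:
        blocks = []
        if config.include_tuning:
            blocks.append(
                build_tuning_block(
                    config.tuning_reps, period, rng,
                    isi_range_s=config.isi_range_s, block_id=block_counter,
                )
            )
            block_counter += 1
        if config.include_chords:
            blocks.append(
                build_oddball_block(
                    chord(config.chord_centers_khz[0]), chord(config.chord_centers_khz[1]),
                    config.min_oddballs, rng, period=period, soa_s=config.chord_soa_s,
                    block_ids=(block_counter, block_counter + 1),
                )
            )
            block_counter += 2
        if config.include_fm:
            blocks.append(
                build_oddball_block(
                    fm_sweep(lo, hi), fm_sweep(hi, lo),
                    config.min_oddballs, rng, period=period, soa_s=config.fm_soa_s,
                    block_ids=(block_counter, block_counter + 1),
                )
            )
            block_counter += 2
        period_tables.append(stimuli.concat_blocks(blocks))
    trials = stimuli.concat_blocks(period_tables, gap_s=30.0)
    # Locomotion state per trial.
    p_run = trials["period"].map(config.running_prob).to_numpy(dtype=float)
    trials["running"] = pd.array(rng.random(len(trials)) < p_run, dtype="boolean")
    return trials


def simulate_session(
    config: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    spike_times: bool = True,
    motion: bool = True,
) -> Session:
    """Simulate a full session under ``config``.

    With ``spike_times=True`` every neuron gets a spike-time vector and the
    responses are obtained by aligning and counting those spikes; with
    ``spike_times=False`` responses are drawn at the count level directly
    (statistically equivalent and much faster for replicate studies).
    """
    from .session import align_population  # local import to avoid cycle at module load

    config = config or SimConfig()
    base = np.random.default_rng(config.seed if rng is None else rng)
    trial_rng, neuron_rng, spike_rng, motion_rng = base.spawn(4)
    trials = build_session_trials(config, trial_rng)
    neurons = draw_neurons(config, neuron_rng)
    stim_x = stimulus_log2khz(config.stimulus_specs())
    windows = ResponseWindows()

    recordings = None
    if spike_times:
        recordings = [
            simulate_spikes(nrn, trials, stim_x, sub, windows)
            for nrn, sub in zip(neurons, spike_rng.spawn(len(neurons)))
        ]
        responses = align_population(recordings, trials, windows)
    else:
        responses = simulate_trial_responses(neurons, trials, stim_x, spike_rng, windows)

    trace = simulate_motion_trace(trials, rng=motion_rng) if motion else None
    return Session(
        config=config, trials=trials, neurons=neurons, responses=responses,
        recordings=recordings, motion_trace=trace,
    )
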