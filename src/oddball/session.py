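"""Session data model: spike recordings, response windows, trial alignment, CSV I/O.

A session pairs a trial table (one row per stimulus presentation, see
:mod:`oddball.stimuli`) with one spike-time vector per isolated unit.  The
central operation is :func:`align_and_count`, which converts spike timestamps
into per-trial baseline and evoked firing rates.

Windows follow the convention used for awake auditory-cortex recordings:
baseline activity is counted from -200 ms to 0 ms relative to sound onset,
and evoked activity from 15 ms after onset to 15 ms after offset, the 15 ms
compensating the ear-to-cortex transmission delay.  All windows are half-open
``[start, end)`` so a spike on a boundary is counted exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import PERIODS, ROLES, TRIAL_COLUMNS

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """An input file does not conform to the documented CSV schema."""


@dataclass
class NeuronRecording:
    """Spike timestamps of one isolated unit across a session."""

    neuron_id: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        self.spike_times_s = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass(frozen=True)
class ResponseWindows:
    """Baseline and evoked counting windows relative to stimulus onset.

    The evoked window is ``[onset + latency, onset + duration + latency)``;
    its length always equals the stimulus duration.
    """

    baseline: tuple[float, float] = (-0.200, 0.0)
    latency_s: float = 0.015

    def evoked_edges(self, onsets: np.ndarray, durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        start = onsets + self.latency_s
        return start, start + durations

    def baseline_edges(self, onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return onsets + self.baseline[0], onsets + self.baseline[1]

    @property
    def baseline_length_s(self) -> float:
        return self.baseline[1] - self.baseline[0]


def _count_in_windows(spike_times: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Spike counts in half-open windows ``[start, end)`` via binary search."""
    left = np.searchsorted(spike_times, starts, side="left")
    right = np.searchsorted(spike_times, ends, side="left")
    return (right - left).astype(int)


def align_and_count(
    rec: NeuronRecording,
    trials: pd.DataFrame,
    windows: ResponseWindows | None = None,
) -> pd.DataFrame:
    """Per-trial baseline and evoked spike counts and rates for one neuron.

    Returns the trial table joined with ``baseline_count``, ``baseline_rate``,
    ``evoked_count`` and ``evoked_rate`` columns (rates in spikes/s).
    Spikes outside every window are ignored.
    """
    windows = windows or ResponseWindows()
    if trials.empty:
        out = trials.copy()
        for col in ("baseline_count", "evoked_count", "baseline_rate", "evoked_rate"):
            out[col] = pd.Series(dtype=float)
        out.insert(0, "neuron_id", pd.Series(dtype=object))
        return out
    onsets = trials["onset_s"].to_numpy(dtype=float)
    durations = trials["duration_s"].to_numpy(dtype=float)
    b0, b1 = windows.baseline_edges(onsets)
    e0, e1 = windows.evoked_edges(onsets, durations)
    out = trials.copy()
    out["baseline_count"] = _count_in_windows(rec.spike_times_s, b0, b1)
    out["evoked_count"] = _count_in_windows(rec.spike_times_s, e0, e1)
    out["baseline_rate"] = out["baseline_count"] / windows.baseline_length_s
    out["evoked_rate"] = out["evoked_count"] / (e1 - e0)
    out.insert(0, "neuron_id", rec.neuron_id)
    return out


def align_population(
    recordings: list[NeuronRecording],
    trials: pd.DataFrame,
    windows: ResponseWindows | None = None,
) -> pd.DataFrame:
    """Stack :func:`align_and_count` over a list of recordings."""
    if not recordings:
        return align_and_count(NeuronRecording("none", np.array([])), trials.iloc[:0], windows)
    return pd.concat(
        [align_and_count(rec, trials, windows) for rec in recordings], ignore_index=True
    )


# ---------------------------------------------------------------------------
# CSV I/O.  spikes.csv: neuron_id, spike_time_s.  trials.csv: the trial-table
# columns documented in the README (schema version 1).
# ---------------------------------------------------------------------------

def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table against the schema; raise :class:`SchemaError` naming the field."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trials table missing column(s): {', '.join(missing)}")
    onsets = trials["onset_s"].to_numpy(dtype=float)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise SchemaError("column 'onset_s': onsets must be strictly increasing")
    bad_roles = set(trials["role"].unique()) - set(ROLES)
    if bad_roles:
        raise SchemaError(f"column 'role': unknown value(s) {sorted(bad_roles)}")
    bad_periods = set(trials["period"].unique()) - set(PERIODS)
    if bad_periods:
        raise SchemaError(f"column 'period': unknown value(s) {sorted(bad_periods)}")
    return trials


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.loc[:, TRIAL_COLUMNS].copy()
    running = out["running"].astype(object)
    out["running"] = running.where(running.notna(), "unknown").replace(
        {True: "true", False: "false"}
    )
    out.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"stimulus_id": str, "role": str, "period": str})
    if "running" in raw.columns:
        mapping = {"true": True, "false": False, "unknown": pd.NA,
                   "True": True, "False": False}
        raw["running"] = pd.array(
            [mapping.get(str(v), pd.NA) for v in raw["running"]], dtype="boolean"
        )
    return validate_trials(raw)


def write_spikes(recordings: list[NeuronRecording], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"neuron_id": rec.neuron_id, "spike_time_s": rec.spike_times_s})
        for rec in recordings
    ]
    header = pd.DataFrame({"neuron_id": pd.Series(dtype=object),
                           "spike_time_s": pd.Series(dtype=float)})
    pd.concat([header, *frames], ignore_index=True).to_csv(path, index=False)


def read_spikes(path: str | Path, neuron_ids: list[str] | None = None) -> list[NeuronRecording]:
    """Read spikes.csv; a neuron listed in ``neuron_ids`` but absent from the
    file is retained with zero spikes (a warning is logged)."""
    df = pd.read_csv(path, dtype={"neuron_id": str})
    if "neuron_id" not in df.columns or "spike_time_s" not in df.columns:
        raise SchemaError("spikes file must have columns 'neuron_id', 'spike_time_s'")
    grouped = {nid: g["spike_time_s"].to_numpy(dtype=float) for nid, g in df.groupby("neuron_id")}
    ids = neuron_ids if neuron_ids is not None else sorted(grouped)
    recordings = []
    for nid in ids:
        times = grouped.get(nid)
        if times is None:
            log.warning("neuron %s has no spikes in %s; retained with zero spikes", nid, path)
            times = np.array([])
        recordings.append(NeuronRecording(nid, times))
    return recordings


def write_session(
    directory: str | Path,
    recordings: list[NeuronRecording],
    trials: pd.DataFrame,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trials(trials, directory / "trials.csv")
    write_spikes(recordings, directory / "spikes.csv")


def read_session(directory: str | Path) -> tuple[list[NeuronRecording], pd.DataFrame]:
    directory = Path(directory)
    trials = read_trials(directory / "trials.csv")
    recordings = read_spikes(directory / "spikes.csv")
    return recordings, trials
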