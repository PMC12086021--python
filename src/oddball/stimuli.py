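"""Stimulus specifications and trial-table builders for the experimental paradigms.

Three stimulus ensembles are supported, mirroring a standard awake-rodent
auditory-cortex protocol:

* a frequency-tuning block of pure-tone pips, 16 frequencies logarithmically
  spaced between 2 and 40 kHz, presented in random order with interstimulus
  intervals drawn uniformly from 1-1.4 s;
* an oddball paradigm built from two narrowband chords (12 components each,
  centered at 8 and 13 kHz, 50 ms duration, 550 ms onset asynchrony);
* an oddball paradigm built from two frequency-modulated sweeps (8-13 kHz
  upsweep and 13-8 kHz downsweep, 100 ms duration, 600 ms onset asynchrony).

In an oddball sequence one stimulus (the standard) repeats 9-11 times between
single presentations of the other (the oddball); after at least 50 oddballs
the roles are exchanged in a companion block so that each stimulus is measured
in both roles.

A trial table is a :class:`pandas.DataFrame` with one row per stimulus
presentation; see :data:`TRIAL_COLUMNS`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns of a trial table, in canonical order.
TRIAL_COLUMNS = [
    "onset_s",
    "stimulus_id",
    "role",
    "period",
    "block_id",
    "running",
    "duration_s",
]

ROLES = ("standard", "oddball", "tuning")
PERIODS = ("pre", "saline", "doi")

#: Default tuning-ensemble parameters.
N_TUNING_FREQS = 16
TUNING_FREQ_RANGE_KHZ = (2.0, 40.0)
TONE_DURATION_S = 0.100
TUNING_ISI_RANGE_S = (1.0, 1.4)

#: Default oddball-ensemble parameters.
CHORD_DURATION_S = 0.050
CHORD_SOA_S = 0.550  # 50 ms sound + 500 ms silence
FM_DURATION_S = 0.100
FM_SOA_S = 0.600  # 100 ms sound + 500 ms silence
RUN_LENGTHS = (9, 10, 11)

_TONE_ID_RE = re.compile(r"^tone_([0-9.]+)kHz$")


@dataclass(frozen=True)
class StimulusSpec:
    """Description of one sound used in the paradigms.

    Parameters
    ----------
    kind:
        ``"pure_tone"``, ``"chord"`` or ``"fm_sweep"``.
    center_or_range:
        Frequency in kHz: a scalar for tones and chord centers, or a
        ``(start, end)`` pair for FM sweeps.
    duration_s:
        Sound duration in seconds.
    level_db:
        Presentation level in dB SPL.
    n_components:
        Number of simultaneous tone components (chords only).
    """

    kind: str
    center_or_range: float | tuple[float, float]
    duration_s: float
    level_db: float = 70.0
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("pure_tone", "chord", "fm_sweep"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.kind == "fm_sweep":
            start, end = self.center_or_range  # type: ignore[misc]
            if start == end:
                raise ValueError("fm_sweep start and end frequencies must differ")
        if self.kind == "chord" and self.n_components is None:
            object.__setattr__(self, "n_components", 12)

    @property
    def stimulus_id(self) -> str:
        if self.kind == "pure_tone":
            return f"tone_{float(self.center_or_range):.3f}kHz"
        if self.kind == "chord":
            return f"chord_{float(self.center_or_range):g}kHz"
        start, end = self.center_or_range  # type: ignore[misc]
        direction = "up" if end > start else "down"
        return f"fm_{direction}_{start:g}-{end:g}kHz"

    def component_frequencies_khz(self) -> np.ndarray:
        """Component frequencies of the sound.

        Chords contain ``n_components`` tones logarithmically spaced in
        ``[f/1.2, f*1.2]`` around the center frequency ``f``; tones return
        their single frequency; sweeps return their start/end frequencies.
        """
        if self.kind == "pure_tone":
            return np.array([float(self.center_or_range)])
        if self.kind == "chord":
            f = float(self.center_or_range)
            return np.geomspace(f / 1.2, f * 1.2, self.n_components or 12)
        return np.asarray(self.center_or_range, dtype=float)

    def effective_log2khz(self) -> float:
        """Log2 frequency (kHz) at which a tuning curve is evaluated.

        Tones and chords use their (center) frequency; FM sweeps use the
        geometric mean of the traversed range.
        """
        comps = self.component_frequencies_khz()
        if self.kind == "chord":
            comps = np.array([float(self.center_or_range)])
        return float(np.mean(np.log2(comps)))


def pure_tone(freq_khz: float, duration_s: float = TONE_DURATION_S) -> StimulusSpec:
    return StimulusSpec("pure_tone", freq_khz, duration_s, level_db=70.0)


def chord(center_khz: float, duration_s: float = CHORD_DURATION_S) -> StimulusSpec:
    return StimulusSpec("chord", center_khz, duration_s, level_db=50.0, n_components=12)


def fm_sweep(start_khz: float, end_khz: float, duration_s: float = FM_DURATION_S) -> StimulusSpec:
    return StimulusSpec("fm_sweep", (start_khz, end_khz), duration_s, level_db=70.0)


def tuning_frequencies_khz(
    n: int = N_TUNING_FREQS,
    lo_khz: float = TUNING_FREQ_RANGE_KHZ[0],
    hi_khz: float = TUNING_FREQ_RANGE_KHZ[1],
) -> np.ndarray:
    """The logarithmically spaced pure-tone frequencies of the tuning block."""
    return np.geomspace(lo_khz, hi_khz, n)


def parse_tone_khz(stimulus_id: str) -> float:
    """Frequency in kHz encoded in a tuning-stimulus id, e.g. ``tone_8.000kHz``."""
    m = _TONE_ID_RE.match(stimulus_id)
    if m is None:
        raise ValueError(f"not a tuning-stimulus id: {stimulus_id!r}")
    return float(m.group(1))


def _empty_trials() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": pd.Series(dtype=float),
            "stimulus_id": pd.Series(dtype=object),
            "role": pd.Series(dtype=object),
            "period": pd.Series(dtype=object),
            "block_id": pd.Series(dtype=int),
            "running": pd.Series(dtype="boolean"),
            "duration_s": pd.Series(dtype=float),
        }
    )


def build_tuning_block(
    n_reps: int,
    period: str = "pre",
    rng: np.random.Generator | int | None = None,
    *,
    frequencies_khz: Sequence[float] | None = None,
    duration_s: float = TONE_DURATION_S,
    isi_range_s: tuple[float, float] = TUNING_ISI_RANGE_S,
    start_s: float = 0.0,
    block_id: int = 0,
) -> pd.DataFrame:
    """Build the pure-tone frequency-tuning block.

    Each of the 16 frequencies appears ``n_reps`` times in globally randomized
    order; successive onsets are separated by the stimulus duration plus an
    interstimulus interval drawn uniformly from ``isi_range_s``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    freqs = np.asarray(
        tuning_frequencies_khz() if frequencies_khz is None else frequencies_khz, dtype=float
    )
    ids = [pure_tone(f, duration_s).stimulus_id for f in freqs]
    order = rng.permutation(np.repeat(np.arange(len(freqs)), n_reps))
    isis = rng.uniform(*isi_range_s, size=order.size)
    onsets = start_s + np.concatenate(([0.0], np.cumsum(duration_s + isis[:-1])))
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "stimulus_id": [ids[i] for i in order],
            "role": "tuning",
            "period": period,
            "block_id": block_id,
            "running": pd.array([pd.NA] * order.size, dtype="boolean"),
            "duration_s": duration_s,
        }
    )


def _oddball_sequence(
    min_oddballs: int, rng: np.random.Generator, run_lengths: Sequence[int] = RUN_LENGTHS
) -> np.ndarray:
    """Boolean array, True where the oddball occurs.

    Runs of consecutive standards between oddballs have lengths drawn
    uniformly from ``run_lengths``; the sequence ends at the oddball that
    reaches ``min_oddballs``.
    """
    flags: list[bool] = []
    for _ in range(min_oddballs):
        flags.extend([False] * int(rng.choice(run_lengths)))
        flags.append(True)
    return np.asarray(flags, dtype=bool)


def build_oddball_block(
    stim_a: StimulusSpec,
    stim_b: StimulusSpec,
    min_oddballs: int = 50,
    rng: np.random.Generator | int | None = None,
    *,
    period: str = "pre",
    soa_s: float | None = None,
    start_s: float = 0.0,
    block_ids: tuple[int, int] = (0, 1),
    inter_block_gap_s: float = 2.0,
) -> pd.DataFrame:
    """Build an oddball sequence and its role-swapped companion.

    The first block presents ``stim_a`` as the standard and ``stim_b`` as the
    oddball; the second block exchanges the roles. Within each block every run
    of standards between oddballs has length 9, 10 or 11 (uniform), and the
    block contains at least ``min_oddballs`` oddball presentations.
    """
    if stim_a.stimulus_id == stim_b.stimulus_id:
        raise ValueError("standard and oddball stimuli must differ")
    if min_oddballs < 1:
        raise ValueError("min_oddballs must be >= 1")
    rng = np.random.default_rng(rng)
    if soa_s is None:
        soa_s = stim_a.duration_s + 0.5

    frames = []
    t = start_s
    for (std, odd), block_id in zip(((stim_a, stim_b), (stim_b, stim_a)), block_ids):
        is_odd = _oddball_sequence(min_oddballs, rng)
        onsets = t + soa_s * np.arange(is_odd.size)
        frames.append(
            pd.DataFrame(
                {
                    "onset_s": onsets,
                    "stimulus_id": np.where(is_odd, odd.stimulus_id, std.stimulus_id),
                    "role": np.where(is_odd, "oddball", "standard"),
                    "period": period,
                    "block_id": block_id,
                    "running": pd.array([pd.NA] * is_odd.size, dtype="boolean"),
                    "duration_s": std.duration_s,
                }
            )
        )
        t = onsets[-1] + soa_s + inter_block_gap_s
    return pd.concat(frames, ignore_index=True)


def concat_blocks(blocks: Sequence[pd.DataFrame], gap_s: float = 5.0) -> pd.DataFrame:
    """Concatenate trial blocks in time, shifting onsets so they never overlap."""
    parts = []
    t = 0.0
    for block in blocks:
        if block.empty:
            continue
        shifted = block.copy()
        shifted["onset_s"] = block["onset_s"] - block["onset_s"].iloc[0] + t
        parts.append(shifted)
        t = shifted["onset_s"].iloc[-1] + shifted["duration_s"].iloc[-1] + gap_s
    if not parts:
        return _empty_trials()
    return pd.concat(parts, ignore_index=True)
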