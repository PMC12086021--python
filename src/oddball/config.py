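"""Analysis configuration: the thresholds and windows used across the pipeline.

All printed constants of the analysis live here as defaults: the 30 %
stability criterion, the 5 spk/s evoked floor, alpha = 0.05 with Bonferroni
correction, the R^2 > 0.05 tuning-fit gate, the -200-0 ms baseline and
15 ms latency windows, the 10-frame locomotion smoothing, the >= 4-trials
rule for running-split Fano factors and the 100-resample matching control.
Configurations round-trip losslessly through YAML (JSON-compatible).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    baseline_window_s: tuple[float, float] = (-0.200, 0.0)
    latency_s: float = 0.015
    stability_max_change: float = 0.30
    evoked_floor_spk_s: float = 5.0
    alpha: float = 0.05
    r2_gate: float = 0.05
    locomotion_smooth_frames: int = 10
    locomotion_threshold: float | None = None  # None -> Otsu threshold
    frame_rate_hz: float = 30.0
    ff_min_trials_split: int = 4
    ff_min_trials_all: int = 2
    n_resamples: int = 100
    resample_tol: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.stability_max_change < 0:
            raise ValueError("stability_max_change must be >= 0")
        if self.locomotion_smooth_frames < 1:
            raise ValueError("locomotion_smooth_frames must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_window_s"] = list(d["baseline_window_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "baseline_window_s" in d:
            d["baseline_window_s"] = tuple(d["baseline_window_s"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
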