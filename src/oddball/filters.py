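"""Neuron-inclusion criteria and locomotion-state classification.

A neuron enters the population analyses only if it is *stable* (its
spontaneous and evoked firing change by no more than 30 % between the
pre-injection and saline periods, ruling out time-in-rig confounds),
*responsive* (signed-rank test of evoked vs baseline rate, Bonferroni
corrected over stimuli, in every period) and above the *evoked floor*
(maximum mean evoked rate above 5 spk/s in every period).  An additional
30 % stability screen on the oddball enhancement index gates the
deviance-detection analyses.

Locomotion state is classified from a motion-energy trace: the trace is
smoothed with a 10-frame square window and the smoothed value at the frame
nearest each stimulus onset is thresholded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import MIN_PAIRS
from .stimuli import PERIODS

log = logging.getLogger(__name__)

STABILITY_MAX_CHANGE = 0.30
EVOKED_FLOOR_SPK_S = 5.0
RESPONSIVE_ALPHA = 0.05
SMOOTH_FRAMES = 10


def _relative_change(pre: float, post: float) -> float:
    """|post - pre| / pre, with the 0/0 -> 0 and x/0 -> inf conventions."""
    if pre == 0:
        return 0.0 if post == 0 else math.inf
    return abs(post - pre) / abs(pre)


def stability_filter(
    resp_pre: pd.DataFrame,
    resp_sal: pd.DataFrame,
    max_change: float = STABILITY_MAX_CHANGE,
    *,
    pool_stimuli: bool = True,
) -> tuple[bool, dict[str, float]]:
    """Firing-rate stability between pre-injection and saline.

    Both the mean spontaneous (baseline) and the mean evoked rate, pooled
    over all trials of the period, must change by at most ``max_change``
    relative to the pre-injection value (a change of exactly 30 % still
    passes: the criterion is "did not change >30%").  With
    ``pool_stimuli=False`` the evoked change is the worst per-stimulus
    change instead of the pooled one.
    """
    if resp_pre.empty or resp_sal.empty:
        raise ValueError("both periods need at least one trial")
    if pool_stimuli:
        evoked_change = _relative_change(
            resp_pre["evoked_rate"].mean(), resp_sal["evoked_rate"].mean()
        )
    else:
        pre_by_stim = resp_pre.groupby("stimulus_id")["evoked_rate"].mean()
        sal_by_stim = resp_sal.groupby("stimulus_id")["evoked_rate"].mean()
        common = pre_by_stim.index.intersection(sal_by_stim.index)
        evoked_change = max(
            (_relative_change(pre_by_stim[s], sal_by_stim[s]) for s in common),
            default=math.inf,
        )
    changes = {
        "spont_change": _relative_change(
            resp_pre["baseline_rate"].mean(), resp_sal["baseline_rate"].mean()
        ),
        "evoked_change": evoked_change,
    }
    if math.isinf(changes["spont_change"]) or math.isinf(changes["evoked_change"]):
        log.warning("stability filter: division by zero pre-injection rate")
    stable = all(c <= max_change for c in changes.values())
    return stable, changes


def responsiveness_test(
    resp: pd.DataFrame,
    alpha: float = RESPONSIVE_ALPHA,
    min_trials: int = MIN_PAIRS,
) -> tuple[bool, float]:
    """Sound responsiveness within one period.

    For each stimulus, a paired Wilcoxon signed-rank test compares evoked and
    baseline rates across that stimulus's trials; p-values are Bonferroni
    corrected by the number of stimuli tested.  The neuron is responsive if
    any corrected p is below ``alpha``.  Returns ``(flag, min corrected p)``.
    """
    stim_ids = resp["stimulus_id"].unique()
    n_stim = len(stim_ids)
    min_p = 1.0
    for sid in stim_ids:
        g = resp[resp["stimulus_id"] == sid]
        if len(g) < min_trials:
            continue
        d = g["evoked_rate"].to_numpy() - g["baseline_rate"].to_numpy()
        if np.all(d == 0):
            continue  # test undefined; treated as p = 1
        p = stats.wilcoxon(
            d, zero_method="wilcox", correction=True, method="auto"
        ).pvalue
        min_p = min(min_p, min(1.0, float(p) * n_stim))
    return min_p < alpha, min_p


def evoked_floor(
    resp_by_period: dict[str, pd.DataFrame],
    floor_spk_s: float = EVOKED_FLOOR_SPK_S,
    periods: tuple[str, ...] = PERIODS,
) -> tuple[bool, dict[str, float]]:
    """Evoked-rate floor: in every period, the best stimulus must drive the
    neuron strictly above ``floor_spk_s`` (exactly 5.0 fails: "above 5")."""
    max_rates: dict[str, float] = {}
    for period in periods:
        resp = resp_by_period.get(period)
        if resp is None or resp.empty:
            log.warning("evoked floor: missing period %r", period)
            return False, max_rates
        max_rates[period] = float(resp.groupby("stimulus_id")["evoked_rate"].mean().max())
    return all(r > floor_spk_s for r in max_rates.values()), max_rates


def oei_stability_filter(
    oei_pre: float, oei_sal: float, max_change: float = STABILITY_MAX_CHANGE
) -> bool:
    """OEI stability between pre-injection and saline: strict "<30%" change."""
    if math.isnan(oei_pre) or math.isnan(oei_sal):
        return False
    if oei_pre == 0:
        if oei_sal != 0:
            log.warning("OEI stability: pre-injection OEI is zero")
        return oei_sal == 0
    return abs(oei_sal - oei_pre) / abs(oei_pre) < max_change


def smooth_boxcar(trace: np.ndarray, n_frames: int = SMOOTH_FRAMES) -> np.ndarray:
    """Square-window moving average with edge renormalization."""
    trace = np.asarray(trace, dtype=float)
    kernel = np.ones(n_frames)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Threshold between the two modes of a histogram.

    Finds the split maximizing the between-class variance (Otsu) and returns
    the midpoint of the two class means, so the threshold sits between the
    stationary and running modes rather than at the edge of the tighter one.
    """
    values = np.asarray(values, dtype=float)
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        return float(values.mean()) if values.size else 0.0
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_total = cum_m[-1] / total
    w0 = cum_w / total
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cum_m / cum_w
        m1 = (cum_m[-1] - cum_m) / (total - cum_w)
        between = w0 * w1 * (m0 - m1) ** 2
    between[~np.isfinite(between)] = -1.0
    k = int(np.argmax(between))
    if not np.isfinite(m0[k]) or not np.isfinite(m1[k]):
        return float(centers[k])
    return float(0.5 * (m0[k] + m1[k]))


def classify_locomotion(
    trace: np.ndarray,
    trial_onsets_s: np.ndarray,
    frame_rate_hz: float = 30.0,
    smooth_frames: int = SMOOTH_FRAMES,
    threshold: float | None = None,
) -> pd.api.extensions.ExtensionArray:
    """Running / not-running flag per trial from a motion-energy trace.

    The trace is boxcar-smoothed over ``smooth_frames`` frames and the value
    at the frame nearest each onset is compared against ``threshold``
    (default: Otsu threshold of the smoothed trace).  Onsets outside the
    trace span get an unknown (NA) flag.
    """
    trace = np.asarray(trace, dtype=float)
    onsets = np.asarray(trial_onsets_s, dtype=float)
    smoothed = smooth_boxcar(trace, smooth_frames)
    if threshold is None:
        threshold = otsu_threshold(smoothed)
    frames = np.round(onsets * frame_rate_hz).astype(int)
    flags = []
    for fr in frames:
        if fr < 0 or fr >= smoothed.size:
            log.warning("locomotion: onset frame %d outside trace span", fr)
            flags.append(pd.NA)
        else:
            flags.append(bool(smoothed[fr] > threshold))
    return pd.array(flags, dtype="boolean")


@dataclass
class InclusionThresholds:
    max_change: float = STABILITY_MAX_CHANGE
    floor_spk_s: float = EVOKED_FLOOR_SPK_S
    alpha: float = RESPONSIVE_ALPHA


def inclusion_report(
    responses: pd.DataFrame,
    thresholds: InclusionThresholds | None = None,
    stimulus_roles: tuple[str, ...] = ("tuning",),
) -> pd.DataFrame:
    """Per-neuron inclusion audit over a population response table.

    ``responses`` is a tidy frame (one row per trial x neuron) as produced by
    :func:`oddball.session.align_population`.  The stability and evoked-floor
    criteria are evaluated on the ``stimulus_roles`` subset (pure tones by
    default); responsiveness is required in every period.  Returns one row
    per neuron with flags, diagnostics, and the overall ``included`` flag.
    """
    th = thresholds or InclusionThresholds()
    sub = responses[responses["role"].isin(stimulus_roles)]
    rows = []
    for nid, g in sub.groupby("neuron_id", sort=True):
        by_period = {p: gp for p, gp in g.groupby("period")}
        try:
            stable, changes = stability_filter(
                by_period.get("pre", g.iloc[0:0]),
                by_period.get("saline", g.iloc[0:0]),
                th.max_change,
            )
        except ValueError:
            stable, changes = False, {"spont_change": math.nan, "evoked_change": math.nan}
        resp_flags, min_ps = [], []
        for period in PERIODS:
            gp = by_period.get(period)
            if gp is None or gp.empty:
                resp_flags.append(False)
                min_ps.append(math.nan)
            else:
                flag, min_p = responsiveness_test(gp, th.alpha)
                resp_flags.append(flag)
                min_ps.append(min_p)
        responsive = all(resp_flags)
        floor_ok, max_rates = evoked_floor(by_period, th.floor_spk_s)
        included = stable and responsive and floor_ok
        if not included:
            log.info(
                "neuron %s excluded (stable=%s responsive=%s floor=%s)",
                nid, stable, responsive, floor_ok,
            )
        rows.append(
            {
                "neuron_id": nid,
                "stable": stable,
                "responsive": responsive,
                "evoked_floor_ok": floor_ok,
                "included": included,
                "spont_change": changes["spont_change"],
                "evoked_change": changes["evoked_change"],
                "min_corrected_p": np.nanmin(min_ps) if not all(math.isnan(v) for v in min_ps) else math.nan,
                "max_evoked_rate": min(max_rates.values()) if len(max_rates) == len(PERIODS) else math.nan,
            }
        )
    return pd.DataFrame(rows)
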