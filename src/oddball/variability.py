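"""Trial-to-trial variability via the Fano factor.

For each neuron and pure-tone stimulus the Fano factor is the
variance-to-mean ratio of the evoked responses across that stimulus's
trials, FF = sigma^2 / mu (unbiased n-1 variance); a Poisson process has
FF = 1.  The primary statistic is computed on evoked-window spike counts
(the classical count definition); computing it on rates instead divides
every FF by the window length, which is exposed as an option and stated in
all outputs.  A neuron's FF is the mean over its included stimuli, and
saline-vs-DOI comparisons are paired across neurons.

When trials are split by locomotion state, a stimulus enters a neuron's
average only if it has at least four trials in each running condition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._stats import nanmedian, paired_wilcoxon

MIN_TRIALS_SPLIT = 4
MIN_TRIALS_UNSPLIT = 2

SPLITS = ("all", "running", "stationary")


def fano_factor(values, ddof: int = 1) -> float:
    """Variance-to-mean ratio; NaN if fewer than 2 values or zero mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return math.nan
    mu = values.mean()
    if mu == 0:
        return math.nan
    return float(values.var(ddof=ddof) / mu)


def _select_split(responses: pd.DataFrame, split: str) -> pd.DataFrame:
    if split == "all":
        return responses
    if split not in SPLITS:
        raise ValueError(f"unknown split {split!r}")
    want = split == "running"
    running = responses["running"]
    return responses[running.notna() & (running == want)]


def neuron_fano(
    responses: pd.DataFrame,
    split: str = "all",
    *,
    on: str = "evoked_count",
    min_trials: int | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Neuron-level Fano factor per period, averaged over tuning stimuli.

    ``responses`` is a tidy per-trial table; only tuning-role trials are
    used.  With ``split`` of ``running`` or ``stationary``, a stimulus is
    included only if the neuron has at least :data:`MIN_TRIALS_SPLIT` trials
    of it in *each* running state; unsplit analyses require
    :data:`MIN_TRIALS_UNSPLIT` trials.  ``on`` selects counts (default,
    classical definition) or ``evoked_rate``.
    """
    tuning = responses[responses["role"] == "tuning"]
    if min_trials is None:
        min_trials = MIN_TRIALS_SPLIT if split != "all" else MIN_TRIALS_UNSPLIT
    rows = []
    for (nid, period), g in tuning.groupby(["neuron_id", "period"], sort=True):
        ffs = []
        for sid, gs in g.groupby("stimulus_id"):
            if split != "all":
                running = gs["running"]
                n_run = int((running.notna() & (running == True)).sum())  # noqa: E712
                n_stat = int((running.notna() & (running == False)).sum())  # noqa: E712
                if min(n_run, n_stat) < MIN_TRIALS_SPLIT:
                    continue
                gs = _select_split(gs, split)
            if len(gs) < min_trials:
                continue
            ff = fano_factor(gs[on].to_numpy(), ddof=ddof)
            if not math.isnan(ff):
                ffs.append(ff)
        rows.append(
            {
                "neuron_id": nid,
                "period": period,
                "split": split,
                "ff_mean": float(np.mean(ffs)) if ffs else math.nan,
                "n_stimuli_included": len(ffs),
            }
        )
    return pd.DataFrame(
        rows, columns=["neuron_id", "period", "split", "ff_mean", "n_stimuli_included"]
    )


def fano_summary(
    fano: pd.DataFrame, period_a: str = "saline", period_b: str = "doi"
) -> dict:
    """Paired population summary of neuron-level Fano factors.

    Reports the median FF under each period, the two-sided signed-rank
    p-value, and the percentage of paired neurons whose FF increased from
    ``period_a`` to ``period_b``.
    """
    if fano.empty or "ff_mean" not in fano.columns:
        return {"median_a": math.nan, "median_b": math.nan, "p": math.nan,
                "pct_increased": math.nan, "n": 0}
    wide = fano.pivot_table(index="neuron_id", columns="period", values="ff_mean", aggfunc="first")
    if period_a not in wide.columns or period_b not in wide.columns:
        return {"median_a": math.nan, "median_b": math.nan, "p": math.nan,
                "pct_increased": math.nan, "n": 0}
    a = wide[period_a].to_numpy(dtype=float)
    b = wide[period_b].to_numpy(dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    p, n = paired_wilcoxon(a, b)
    return {
        "median_a": nanmedian(a),
        "median_b": nanmedian(b),
        "p": p,
        "pct_increased": float(100.0 * np.mean(b > a)) if n else math.nan,
        "n": n,
    }
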