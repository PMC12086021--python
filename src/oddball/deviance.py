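"""Oddball-enhancement and modulation indices, and their population analyses.

Deviance detection is quantified per neuron and stimulus with the oddball
enhancement index

    OEI = (O - S) / (O + S),

where ``O`` is the neuron's mean evoked rate when the stimulus appears as a
rare oddball and ``S`` its mean evoked rate when the same stimulus appears as
the repeated standard in the companion (role-swapped) block.  Drug effects on
each role are quantified with the modulation index

    MI = (DOI - Sal) / (DOI + Sal),

computed separately for oddball and standard responses.  Both indices lie in
[-1, 1] for nonnegative responses and are undefined (excluded, never
imputed) when the denominator is zero.

Population comparisons are paired Wilcoxon signed-rank tests across neurons,
per stimulus.  Two control analyses accompany them: an adaptation control
comparing pre-injection -> saline changes with saline -> DOI changes, and a
matched-resampling control that re-tests the drug effect on subsets of
late-session neurons whose mean saline OEI matches the early sessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import mannwhitney_u, nanmedian, paired_wilcoxon
from .filters import oei_stability_filter
from .stimuli import PERIODS

log = logging.getLogger(__name__)


def safe_index(a: float, b: float) -> float:
    """(a - b) / (a + b), NaN when the denominator is zero."""
    denom = a + b
    if denom == 0:
        return math.nan
    return (a - b) / denom


def compute_oei(o_mean: float, s_mean: float) -> float:
    """Oddball enhancement index from mean oddball and standard responses."""
    oei = safe_index(o_mean, s_mean)
    if math.isnan(oei):
        log.info("OEI undefined (O + S = 0); excluded")
    return oei


def compute_mi(sal_mean: float, doi_mean: float) -> float:
    """Modulation index (DOI - Sal)/(DOI + Sal) from mean responses."""
    mi = safe_index(doi_mean, sal_mean)
    if math.isnan(mi):
        log.info("MI undefined (Sal + DOI = 0); excluded")
    return mi


def _first_standard_mask(responses: pd.DataFrame) -> pd.Series:
    """True for standard trials that immediately follow an oddball within
    the same neuron and block (candidates for exclusion from S)."""
    ordered = responses.sort_values(["neuron_id", "block_id", "onset_s"])
    prev_odd = (
        ordered.groupby(["neuron_id", "block_id"])["role"]
        .shift(1)
        .eq("oddball")
    )
    mask = prev_odd & (ordered["role"] == "standard")
    return mask.reindex(responses.index, fill_value=False)


def oddball_summary(
    responses: pd.DataFrame,
    *,
    exclude_first_standard: bool = False,
    baseline_subtract: bool = False,
) -> pd.DataFrame:
    """Per neuron x stimulus x period oddball/standard means and OEI.

    ``responses`` is a tidy per-trial frame; only oddball-paradigm trials
    (role ``standard`` or ``oddball``) contribute.  The mean over a
    stimulus's oddball presentations comes from one block and the mean over
    its standard presentations from the role-swapped companion block.

    Options (both off by default): ``exclude_first_standard`` drops the
    standard presentation immediately following each oddball from S;
    ``baseline_subtract`` computes the indices on evoked minus baseline
    rate instead of the raw evoked rate.
    """
    sub = responses[responses["role"].isin(("standard", "oddball"))]
    if exclude_first_standard:
        sub = sub[~_first_standard_mask(sub)]
    if baseline_subtract:
        sub = sub.assign(evoked_rate=sub["evoked_rate"] - sub["baseline_rate"])
    agg = (
        sub.groupby(["neuron_id", "stimulus_id", "period", "role"], sort=True)["evoked_rate"]
        .agg(["mean", "size"])
        .unstack("role")
    )
    out = pd.DataFrame(
        {
            "O": agg[("mean", "oddball")],
            "S": agg[("mean", "standard")],
            "n_oddball": agg[("size", "oddball")],
            "n_standard": agg[("size", "standard")],
        }
    ).reset_index()
    denom = out["O"] + out["S"]
    out["oei"] = np.where(denom > 0, (out["O"] - out["S"]) / denom, np.nan)
    n_undef = int((denom == 0).sum())
    if n_undef:
        log.info("OEI undefined for %d neuron x stimulus x period cells", n_undef)
    return out


def modulation_index_table(
    summary: pd.DataFrame, period_ref: str = "saline", period_test: str = "doi"
) -> pd.DataFrame:
    """Per neuron x stimulus x role modulation index between two periods."""
    ref = summary[summary["period"] == period_ref].set_index(["neuron_id", "stimulus_id"])
    test = summary[summary["period"] == period_test].set_index(["neuron_id", "stimulus_id"])
    common = ref.index.intersection(test.index)
    ref, test = ref.loc[common], test.loc[common]
    rows = []
    for role, col in (("oddball", "O"), ("standard", "S")):
        denom = test[col] + ref[col]
        mi = np.where(denom > 0, (test[col] - ref[col]) / denom, np.nan)
        frame = pd.DataFrame(
            {"role": role, "mi": mi}, index=common
        ).reset_index()
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def oei_stable_mask(summary: pd.DataFrame, max_change: float = 0.30) -> pd.Series:
    """Neuron x stimulus mask: OEI varied by <30% between pre and saline."""
    wide = summary.pivot_table(
        index=["neuron_id", "stimulus_id"], columns="period", values="oei", aggfunc="first"
    )
    pre = wide.get("pre")
    sal = wide.get("saline")
    if pre is None or sal is None:
        return pd.Series(True, index=wide.index)
    return pd.Series(
        [oei_stability_filter(p, s, max_change) for p, s in zip(pre, sal)],
        index=wide.index,
    )


def paired_oei_test(oei_a, oei_b) -> dict:
    """Paired saline-vs-DOI style comparison of per-neuron OEIs."""
    p, n = paired_wilcoxon(oei_a, oei_b)
    return {
        "median_a": nanmedian(oei_a),
        "median_b": nanmedian(oei_b),
        "p": p,
        "n": n,
    }


def population_tests(
    summary: pd.DataFrame,
    period_a: str = "saline",
    period_b: str = "doi",
    *,
    apply_oei_stability: bool = True,
    neuron_filter: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-stimulus paired comparison of OEI between two periods.

    ``neuron_filter``, when given, restricts to those neuron ids (e.g. the
    responsive set from the inclusion report).  With
    ``apply_oei_stability=True`` only neuron x stimulus cells whose OEI was
    stable between pre-injection and saline enter the test.
    """
    stable = oei_stable_mask(summary) if apply_oei_stability else None
    rows = []
    for sid, g in summary.groupby("stimulus_id", sort=True):
        wide = g.pivot_table(
            index="neuron_id", columns="period", values="oei", aggfunc="first"
        )
        if period_a not in wide.columns or period_b not in wide.columns:
            continue
        if neuron_filter is not None:
            wide = wide.loc[wide.index.intersection(neuron_filter)]
        if stable is not None:
            idx = pd.MultiIndex.from_product([wide.index, [sid]])
            ok = stable.reindex(idx).fillna(False).to_numpy()
            wide = wide.loc[ok]
        res = paired_oei_test(wide[period_a], wide[period_b])
        rows.append(
            {
                "stimulus_id": sid,
                f"median_oei_{period_a}": res["median_a"],
                f"median_oei_{period_b}": res["median_b"],
                "p": res["p"],
                "n": res["n"],
            }
        )
    return pd.DataFrame(rows)


def mi_role_comparison(summary: pd.DataFrame, neuron_filter: pd.Index | None = None) -> pd.DataFrame:
    """Per-stimulus comparison of oddball-response vs standard-response MI.

    Tests, across neurons, whether the drug changed oddball responses more
    than standard responses (paired signed-rank on the two MIs).
    """
    mi = modulation_index_table(summary)
    if neuron_filter is not None:
        mi = mi[mi["neuron_id"].isin(neuron_filter)]
    rows = []
    for sid, g in mi.groupby("stimulus_id", sort=True):
        wide = g.pivot_table(index="neuron_id", columns="role", values="mi", aggfunc="first")
        if "oddball" not in wide.columns or "standard" not in wide.columns:
            continue
        p, n = paired_wilcoxon(wide["oddball"], wide["standard"])
        rows.append(
            {
                "stimulus_id": sid,
                "median_mi_oddball": nanmedian(wide["oddball"]),
                "median_mi_standard": nanmedian(wide["standard"]),
                "p": p,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def adaptation_control(summary: pd.DataFrame, neuron_filter: pd.Index | None = None) -> pd.DataFrame:
    """Adaptation control: pre -> saline vs saline -> DOI changes in oddball
    responses.

    Uses all neurons responsive to the stimulus regardless of OEI stability.
    Per stimulus, reports the signed-rank p for the change in oddball
    response across each period transition, and the paired comparison of the
    per-neuron modulation indices MI(Pre-Sal) vs MI(Sal-DOI).
    """
    rows = []
    for sid, g in summary.groupby("stimulus_id", sort=True):
        wide = g.pivot_table(index="neuron_id", columns="period", values="O", aggfunc="first")
        if not all(p in wide.columns for p in PERIODS):
            continue
        if neuron_filter is not None:
            wide = wide.loc[wide.index.intersection(neuron_filter)]
        p_pre_sal, _ = paired_wilcoxon(wide["pre"], wide["saline"])
        p_sal_doi, _ = paired_wilcoxon(wide["saline"], wide["doi"])
        denom1 = wide["saline"] + wide["pre"]
        denom2 = wide["doi"] + wide["saline"]
        mi_pre_sal = np.where(denom1 > 0, (wide["saline"] - wide["pre"]) / denom1, np.nan)
        mi_sal_doi = np.where(denom2 > 0, (wide["doi"] - wide["saline"]) / denom2, np.nan)
        p_mi, n = paired_wilcoxon(mi_sal_doi, mi_pre_sal)
        rows.append(
            {
                "stimulus_id": sid,
                "p_oddball_pre_sal": p_pre_sal,
                "p_oddball_sal_doi": p_sal_doi,
                "median_mi_pre_sal": nanmedian(mi_pre_sal),
                "median_mi_sal_doi": nanmedian(mi_sal_doi),
                "p_mi_comparison": p_mi,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def early_late_effect_comparison(
    early_sal, early_doi, late_sal, late_doi
) -> dict:
    """Mann-Whitney U comparison of the per-neuron drug effect (saline OEI
    minus DOI OEI) between neurons recorded in early and late sessions."""
    d_early = np.asarray(early_sal, dtype=float) - np.asarray(early_doi, dtype=float)
    d_late = np.asarray(late_sal, dtype=float) - np.asarray(late_doi, dtype=float)
    p, n_early, n_late = mannwhitney_u(d_early, d_late)
    return {"p": p, "n_early": n_early, "n_late": n_late,
            "median_effect_early": nanmedian(d_early), "median_effect_late": nanmedian(d_late)}


@dataclass
class ResampleResult:
    """Outcome of the OEI-matched resampling control."""

    subsets: list[np.ndarray]
    subset_mean_saline_oei: np.ndarray
    median_saline: np.ndarray
    median_doi: np.ndarray
    fraction_saline_gt_doi: float
    target_mean: float


def _target_reachable(sal: np.ndarray, target: float, tol: float, size: int) -> bool:
    """A size-``size`` subset mean can lie within ``tol`` of ``target`` iff the
    target sits between the bottom-k and top-k means."""
    s = np.sort(sal)
    lo = s[:size].mean()
    hi = s[-size:].mean()
    return lo - tol <= target <= hi + tol


def _feasible_subset_size(sal: np.ndarray, target: float, tol: float, max_size: int) -> int:
    """Largest subset size (<= max_size) for which the target mean is reachable."""
    for size in range(max_size, 0, -1):
        if _target_reachable(sal, target, tol, size):
            return size
    raise ValueError(
        f"no subset of any size can reach mean {target:.4f} +/- {tol}"
    )


def _match_subset(
    sal: np.ndarray,
    target_mean: float,
    size: int,
    tol: float,
    rng: np.random.Generator,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Indices of a size-``size`` subset whose mean is within ``tol`` of the
    target, found by random start plus greedy element swaps."""
    n = sal.size
    idx = rng.permutation(n)
    members = set(idx[:size].tolist())
    cur_sum = float(sal[list(members)].sum())
    order = np.argsort(sal, kind="stable")
    for _ in range(max_iter):
        mean = cur_sum / size
        if abs(mean - target_mean) <= tol:
            return np.fromiter(members, dtype=int)
        member_list = np.fromiter(members, dtype=int)
        m = int(rng.choice(member_list))
        want = sal[m] + size * (target_mean - mean)
        pos = int(np.searchsorted(sal[order], want))
        # nearest non-member to the desired value
        candidates = []
        for offset in range(n):
            for j in (pos - offset - 1, pos + offset):
                if 0 <= j < n and int(order[j]) not in members:
                    candidates.append(int(order[j]))
            if candidates:
                break
        if not candidates:
            break
        o = candidates[int(rng.integers(len(candidates)))]
        new_sum = cur_sum - sal[m] + sal[o]
        if abs(new_sum / size - target_mean) < abs(mean - target_mean):
            members.remove(m)
            members.add(o)
            cur_sum = new_sum
    raise RuntimeError(
        f"no subset of size {size} reached mean {target_mean:.4f} +/- {tol} "
        f"(late-set mean {sal.mean():.4f}, n={n})"
    )


def matched_resampling(
    early_sal,
    late_sal,
    late_doi,
    n_resamples: int = 100,
    rng: np.random.Generator | int | None = None,
    *,
    subset_size: int | None = None,
    tol: float = 0.01,
) -> ResampleResult:
    """Repeatedly draw late-session subsets whose mean saline OEI matches the
    early sessions, and re-test the drug effect in each subset.

    ``late_sal`` and ``late_doi`` are aligned per-neuron OEIs.  Each of the
    ``n_resamples`` subsets is drawn without replacement and constrained to
    ``|mean saline OEI - early mean| <= tol``.  Reports the fraction of
    resamples in which the subset's median saline OEI exceeds its median DOI
    OEI (the direction of the deviance-detection drug effect).
    """
    rng = np.random.default_rng(rng)
    early_sal = np.asarray(early_sal, dtype=float)
    late_sal = np.asarray(late_sal, dtype=float)
    late_doi = np.asarray(late_doi, dtype=float)
    keep = ~(np.isnan(late_sal) | np.isnan(late_doi))
    late_sal, late_doi = late_sal[keep], late_doi[keep]
    target = float(np.nanmean(early_sal))
    if math.isnan(target):
        raise ValueError("early saline OEI mean is undefined")
    if subset_size is None:
        subset_size = _feasible_subset_size(late_sal, target, tol, min(early_sal.size, late_sal.size))
    subset_size = min(subset_size, late_sal.size)
    if not _target_reachable(late_sal, target, tol, subset_size):
        raise ValueError(
            f"no subset of size {subset_size} can reach mean {target:.4f} +/- {tol} "
            f"(late-set mean {late_sal.mean():.4f}, n={late_sal.size})"
        )
    subsets, med_sal, med_doi, means = [], [], [], []
    for _ in range(n_resamples):
        if subset_size == late_sal.size:
            idx = np.arange(late_sal.size)
        else:
            idx = _match_subset(late_sal, target, subset_size, tol, rng)
        subsets.append(idx)
        means.append(float(late_sal[idx].mean()))
        med_sal.append(float(np.median(late_sal[idx])))
        med_doi.append(float(np.median(late_doi[idx])))
    med_sal_arr = np.asarray(med_sal)
    med_doi_arr = np.asarray(med_doi)
    return ResampleResult(
        subsets=subsets,
        subset_mean_saline_oei=np.asarray(means),
        median_saline=med_sal_arr,
        median_doi=med_doi_arr,
        fraction_saline_gt_doi=float(np.mean(med_sal_arr > med_doi_arr)),
        target_mean=target,
    )
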