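"""End-to-end analysis: filters -> tuning -> deviance -> variability.

:func:`run_analysis` consumes a tidy per-trial response table (one row per
trial x neuron, as produced by :func:`oddball.session.align_population` or
by the count-level simulator path) and returns every population-level result
the reporting layer needs, keyed by analysis stage.  Numbers in the report
are exactly the module-level outputs; nothing is recomputed downstream.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import deviance, filters, tuning, variability
from .config import AnalysisConfig
from .session import ResponseWindows


def response_windows(config: AnalysisConfig) -> ResponseWindows:
    return ResponseWindows(baseline=config.baseline_window_s, latency_s=config.latency_s)


def run_analysis(
    responses: pd.DataFrame,
    config: AnalysisConfig | None = None,
    *,
    splits: tuple[str, ...] = ("all",),
) -> dict:
    """Run the full population analysis on a per-trial response table."""
    config = config or AnalysisConfig()
    thresholds = filters.InclusionThresholds(
        max_change=config.stability_max_change,
        floor_spk_s=config.evoked_floor_spk_s,
        alpha=config.alpha,
    )
    report = filters.inclusion_report(responses, thresholds)
    included = pd.Index(report.loc[report["included"], "neuron_id"])
    responsive = pd.Index(report.loc[report["responsive"], "neuron_id"])

    results: dict = {
        "config_hash": config.hash(),
        "inclusion": report,
        "n_neurons": int(report.shape[0]),
        "n_included": int(included.size),
    }

    # Frequency tuning per period, compared between saline and DOI.
    fits = tuning.fit_tuning_per_period(responses[responses["neuron_id"].isin(included)])
    results["tuning_fits"] = fits
    if not fits.empty:
        by_period = {p: g for p, g in fits.groupby("period")}
        if "saline" in by_period and "doi" in by_period:
            results["tuning_summary"] = tuning.tuning_change_summary(
                by_period["saline"], by_period["doi"], config.r2_gate
            )

    # Deviance detection.
    summary = deviance.oddball_summary(responses)
    results["oddball_summary"] = summary
    if not summary.empty:
        results["oei_tests"] = deviance.population_tests(
            summary, apply_oei_stability=True, neuron_filter=included
        )
        results["mi_tests"] = deviance.mi_role_comparison(summary, neuron_filter=included)
        results["adaptation_control"] = deviance.adaptation_control(
            summary, neuron_filter=responsive
        )

    # Trial-to-trial variability.
    fano_tables = []
    fano_summaries = {}
    for split in splits:
        table = variability.neuron_fano(
            responses[responses["neuron_id"].isin(included)], split=split
        )
        fano_tables.append(table)
        fano_summaries[split] = variability.fano_summary(table)
    results["fano"] = pd.concat(fano_tables, ignore_index=True) if fano_tables else pd.DataFrame()
    results["fano_summary"] = fano_summaries
    return results


def summary_json(results: dict) -> dict:
    """JSON-serializable digest of :func:`run_analysis` output."""
    out: dict = {
        "config_hash": results.get("config_hash"),
        "n_neurons": results.get("n_neurons"),
        "n_included": results.get("n_included"),
    }
    if "oei_tests" in results:
        out["oei"] = results["oei_tests"].to_dict(orient="records")
    if "mi_tests" in results:
        out["mi"] = results["mi_tests"].to_dict(orient="records")
    if "adaptation_control" in results:
        out["adaptation_control"] = results["adaptation_control"].to_dict(orient="records")
    if "tuning_summary" in results:
        out["tuning"] = results["tuning_summary"]
    if "fano_summary" in results:
        out["fano"] = results["fano_summary"]

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            v = float(obj)
            return None if math.isnan(v) else v
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    return _clean(out)
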