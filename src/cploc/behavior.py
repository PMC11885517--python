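"""Behavioral metrics for the probe-localization reports.

Three trial-level metrics: the absolute estimation error, the reported
response uncertainty (width of the marked interval, degrees), and the prior
bias — how far the response is pulled from the probe's true location toward
the previous sound's location:

    prior_bias = (x_response - x_t) / (x_(t-1) - x_t)

0 means no reliance on the previous sound, 1 means the response sits at the
previous location.  Metrics are summarized per condition (A / AV) and SAC
level 1-6, following the convention that single-sound trials are excluded
(they have no previous sound) and that latent summaries are medians of
within-subject z-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedBiasError",
    "MissingContextError",
    "estimation_error",
    "prior_bias",
    "make_records",
    "summarize_by_sac",
    "error_uncertainty_correlation",
]


class UndefinedBiasError(ValueError):
    """Previous and current locations coincide; bias denominator is zero."""


class MissingContextError(ValueError):
    """Single-sound trial: no previous location to compute prior bias from."""


class DegenerateCorrelationError(ValueError):
    """Zero-variance input to a correlation."""


def estimation_error(response: float, true_location: float) -> float:
    """Absolute difference between response and the probe's true location."""
    return float(abs(np.asarray(response) - np.asarray(true_location)))


def prior_bias(response: float, x_t: float, x_prev: float) -> float:
    """(response - x_t) / (x_prev - x_t); raises on degenerate inputs."""
    if x_prev is None or (isinstance(x_prev, float) and np.isnan(x_prev)):
        raise MissingContextError("single-sound trial has no previous location")
    denom = x_prev - x_t
    if denom == 0:
        raise UndefinedBiasError("previous and current locations coincide")
    return float((response - x_t) / denom)


def make_records(
    trials: pd.DataFrame,
    responses: np.ndarray,
    response_uncertainty: np.ndarray | None = None,
    subject: int | str = 0,
) -> pd.DataFrame:
    """Per-trial behavioral records from a trial table and responses.

    ``trials`` needs columns trial_id, condition, probe_location,
    prev_location (NaN for single-sound trials), probe_sac.  The response
    uncertainty defaults to the width of the observer's credible interval when
    ``ci_low``/``ci_high`` columns are present.
    """
    rec = trials[
        ["trial_id", "condition", "probe_location", "prev_location", "probe_sac"]
    ].copy()
    rec["subject"] = subject
    rec["response"] = np.asarray(responses, float)
    if response_uncertainty is None:
        if {"ci_low", "ci_high"}.issubset(trials.columns):
            response_uncertainty = (trials["ci_high"] - trials["ci_low"]).to_numpy()
        else:
            raise ValueError("response_uncertainty required without ci columns")
    rec["response_uncertainty"] = np.asarray(response_uncertainty, float)
    rec["error"] = np.abs(rec["response"] - rec["probe_location"])
    denom = rec["prev_location"] - rec["probe_location"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = (rec["response"] - rec["probe_location"]) / denom
    bias[denom == 0] = np.nan  # undefined, excluded rather than zeroed
    rec["prior_bias"] = bias
    rec["single_sound"] = rec["prev_location"].isna()
    return rec


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std()  # population convention
    if sd == 0:
        raise DegenerateCorrelationError("zero variance; cannot z-score")
    return (v - v.mean()) / sd


def summarize_by_sac(
    records: pd.DataFrame,
    latents: pd.DataFrame | None = None,
    max_sac: int = 6,
    all_sac: bool = False,
) -> pd.DataFrame:
    """Mean/SEM of the behavioral metrics and median/SEM of z-scored latents
    per condition x SAC level.

    Behavioral rows use the probe's SAC level, excluding single-sound trials
    and (by default) probes with SAC above ``max_sac``.  Latent rows pool
    every non-first sound by its SAC level, z-scoring PU and SU within
    subject over those sounds.  Empty cells are reported with n=0 and NaN
    statistics rather than imputed.
    """
    rows = []
    rec = records[~records["single_sound"]]
    if not all_sac:
        rec = rec[rec["probe_sac"] <= max_sac]
    sac_levels = range(1, (max(rec["probe_sac"].max(), max_sac) if all_sac else max_sac) + 1)
    for cond, grp_c in rec.groupby("condition"):
        for sac in sac_levels:
            cell = grp_c[grp_c["probe_sac"] == sac]
            for metric in ("error", "prior_bias", "response_uncertainty"):
                vals = cell[metric].dropna().to_numpy()
                rows.append(
                    {
                        "condition": cond,
                        "sac": sac,
                        "metric": metric,
                        "mean": vals.mean() if len(vals) else np.nan,
                        "median": np.median(vals) if len(vals) else np.nan,
                        "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
                        "n": len(vals),
                    }
                )
    if latents is not None:
        lat = latents[~latents["is_first"]].copy()
        for col in ("pu", "su"):
            if "subject" in lat.columns:
                lat[f"z_{col}"] = lat.groupby(["subject", "condition"])[col].transform(
                    lambda v: (v - v.mean()) / v.std()
                )
            else:
                lat[f"z_{col}"] = lat.groupby("condition")[col].transform(
                    lambda v: (v - v.mean()) / v.std()
                )
        if not all_sac:
            lat = lat[lat["sac"] <= max_sac]
        for cond, grp_c in lat.groupby("condition"):
            for sac in sac_levels:
                cell = grp_c[grp_c["sac"] == sac]
                for col in ("pu", "su"):
                    vals = cell[f"z_{col}"].to_numpy()
                    raw = cell[col].to_numpy()
                    rows.append(
                        {
                            "condition": cond,
                            "sac": sac,
                            "metric": col,
                            "mean": raw.mean() if len(raw) else np.nan,
                            "median": np.median(vals) if len(vals) else np.nan,
                            "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
                            "n": len(vals),
                        }
                    )
    return pd.DataFrame(rows)


def error_uncertainty_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson r between per-subject SD of absolute errors and per-subject
    mean response uncertainty, with its p-value."""
    per_subj = records.groupby("subject").agg(
        err_sd=("error", "std"), mean_ru=("response_uncertainty", "mean")
    )
    if len(per_subj) < 3:
        raise ValueError("need at least 3 subjects")
    if per_subj["err_sd"].std() == 0 or per_subj["mean_ru"].std() == 0:
        raise DegenerateCorrelationError("zero between-subject variance")
    r, p = stats.pearsonr(per_subj["err_sd"], per_subj["mean_ru"])
    return float(r), float(p)
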