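"""Trial-level link between cluster-averaged probe activity and behavior.

Clusters are defined on non-probe epochs; the held-out probe epochs are then
averaged over each significant cluster's datapoints to give a single scalar
per trial and cluster.  Within each subject that scalar is regressed (both
sides z-scored, so the slope is a correlation) against each behavioral
variable — estimation error, response uncertainty, prior bias — and the
per-subject slopes are tested against zero with a group one-sample t-test at
alpha = 0.05.  Single-sound trials are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .regression import Cluster, ClusterSet

__all__ = ["score_clusters", "link_behavior", "BEHAVIOR_VARS"]

BEHAVIOR_VARS = ("error", "response_uncertainty", "prior_bias")


class CoverageError(ValueError):
    """Cluster datapoints fall outside the probe-epoch window."""


def _time_indices(cluster_times: np.ndarray, probe_times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(probe_times, cluster_times)
    idx = np.clip(idx, 0, len(probe_times) - 1)
    # snap to the nearer neighbor, then insist on an (near-)exact match
    left = np.clip(idx - 1, 0, len(probe_times) - 1)
    use_left = np.abs(probe_times[left] - cluster_times) < np.abs(
        probe_times[idx] - cluster_times
    )
    idx = np.where(use_left, left, idx)
    if np.any(np.abs(probe_times[idx] - cluster_times) > 1e-6):
        raise CoverageError("cluster time points not present in the probe epochs")
    return idx


def score_clusters(
    probe_data: np.ndarray,
    probe_times: np.ndarray,
    clusters: ClusterSet | list[Cluster],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean probe-epoch activity over each cluster's datapoints.

    ``probe_data`` is (channels, [freqs,] times, trials) in the same channel
    (and frequency) space the clusters were defined in.  Returns a tidy frame
    with one row per (trial, cluster).
    """
    cl_list = clusters.clusters if isinstance(clusters, ClusterSet) else clusters
    has_freq = probe_data.ndim == 4
    n_trials = probe_data.shape[-1]
    rows = []
    for ci, c in enumerate(cl_list):
        t_idx = _time_indices(c.times, probe_times)
        if has_freq:
            if c.f_idx is None:
                raise CoverageError("frequency-resolved data but time-only cluster")
            vals = probe_data[c.ch_idx, c.f_idx, t_idx, :]
        else:
            vals = probe_data[c.ch_idx, t_idx, :]
        scores = vals.mean(axis=0)
        for k in range(n_trials):
            rows.append({"trial": k, "cluster": ci, "score": float(scores[k])})
    df = pd.DataFrame(rows)
    if meta is not None:
        meta = meta.reset_index(drop=True)
        for col in meta.columns:
            df[col] = meta[col].to_numpy()[df["trial"].to_numpy()]
    return df


def _safe_z(v: np.ndarray) -> np.ndarray | None:
    s = v.std()
    if s == 0 or not np.isfinite(s):
        return None
    return (v - v.mean()) / s


def link_behavior(
    scores: pd.DataFrame,
    behavior: pd.DataFrame,
    variables: tuple[str, ...] = BEHAVIOR_VARS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject slopes of behavior on cluster score, plus the group test.

    ``scores`` needs columns subject, trial_id, cluster, score; ``behavior``
    needs subject, trial_id, the behavioral variables and ``single_sound``.
    Both sides are z-scored within subject; subjects with degenerate variance
    are dropped with a warning.  Returns ``(slopes, group)`` where ``group``
    has one row per (cluster, variable) with the mean slope, t, df and p.
    """
    beh = behavior.copy()
    if "single_sound" in beh.columns:
        beh = beh[~beh["single_sound"]]
    merged = scores.merge(beh, on=["subject", "trial_id"], how="inner")
    slope_rows = []
    for (subj, cl), grp in merged.groupby(["subject", "cluster"]):
        if len(grp) < 2:
            continue
        zs = _safe_z(grp["score"].to_numpy(float))
        if zs is None:
            warnings.warn(
                f"subject {subj}: degenerate cluster score, dropped", RuntimeWarning
            )
            continue
        for var in variables:
            v = grp[var].to_numpy(float)
            ok = np.isfinite(v)
            if ok.sum() < 2:
                continue
            zv = _safe_z(v[ok])
            if zv is None:
                warnings.warn(
                    f"subject {subj}: degenerate {var}, dropped", RuntimeWarning
                )
                continue
            slope = float(np.mean(zs[ok] * zv))  # OLS slope of z on z
            slope_rows.append(
                {"subject": subj, "cluster": cl, "variable": var, "beta": slope}
            )
    slopes = pd.DataFrame(slope_rows)
    group_rows = []
    if len(slopes):
        for (cl, var), grp in slopes.groupby(["cluster", "variable"]):
            b = grp["beta"].to_numpy()
            t, p = stats.ttest_1samp(b, 0.0)
            group_rows.append(
                {
                    "cluster": cl,
                    "variable": var,
                    "mean_beta": float(b.mean()),
                    "t": float(t),
                    "df": len(b) - 1,
                    "p": float(p),
                    "significant": bool(p < alpha),
                    "n_subjects": len(b),
                }
            )
    return slopes, pd.DataFrame(group_rows)
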