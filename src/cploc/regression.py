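"""Mass-univariate regression of single-trial EEG on observer latents, with
cluster-based permutation inference.

Per subject, every datapoint (channel x time, or channel x frequency x time)
is regressed by OLS on the z-scored PU and SU latents jointly (plus an
intercept); first and probe sounds are excluded.  Group inference thresholds
the across-subject one-sample t-map at a cluster-forming alpha (0.001
two-sided by default), groups adjacency-connected suprathreshold datapoints
of like sign (channel neighbors, +-1 time step, +-1 frequency bin), sums
their t-values into a cluster mass, and compares each mass against the
permutation distribution of the maximum absolute cluster mass under random
sign flips of the subject maps.  Clusters spanning no more than a minimum
duration (5 ms) are dropped.  The smallest attainable p with B permutations
is 1/(B+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "select_epochs",
    "zscore",
    "fit_betas",
    "Cluster",
    "ClusterSet",
    "cluster_test",
    "cluster_test_paired",
    "PU_WINDOW",
    "SU_WINDOW",
]

#: analysis windows (seconds relative to sound onset)
PU_WINDOW = (-0.250, 0.100)
SU_WINDOW = (0.0, 0.500)


class DegeneratePredictorError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


def select_epochs(meta: pd.DataFrame) -> np.ndarray:
    """Inclusion mask: drop first sounds (no prior) and probes (held out for
    the behavioral analysis)."""
    mask = (~meta["is_first"].to_numpy()) & (~meta["is_probe"].to_numpy())
    if not mask.any():
        raise ValueError("epoch selection is empty")
    return mask


def zscore(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    """z-transform with the population-SD convention (ddof=0)."""
    v = np.asarray(values, float)
    m = v.mean(axis=axis, keepdims=axis is not None)
    s = v.std(axis=axis, keepdims=axis is not None)
    if np.any(s == 0):
        raise DegeneratePredictorError("zero variance; cannot z-score")
    return (v - m) / s


def fit_betas(
    data: np.ndarray,
    latents: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-datapoint OLS betas of EEG on z-scored PU and SU.

    ``data`` is (channels, [freqs,] times, epochs); ``latents`` provides
    per-epoch ``pu`` and ``su`` (raw; z-scored here over the included
    epochs).  EEG is z-scored per datapoint over the same epochs.  Returns
    betas with leading axis (pu, su) over the datapoint shape.
    """
    if mask is None:
        mask = select_epochs(latents)
    if data.shape[-1] != len(latents):
        raise ValueError("epoch axis does not match the latent table")
    pu = zscore(latents["pu"].to_numpy(float)[mask])
    su = zscore(latents["su"].to_numpy(float)[mask])
    r = float(np.corrcoef(pu, su)[0, 1])
    if abs(r) > 0.999:
        raise CollinearityError(f"PU and SU are collinear (r={r:.4f})")
    point_shape = data.shape[:-1]
    y = data[..., mask].reshape(-1, int(mask.sum())).T  # (n_inc, P)
    y = zscore(y, axis=0)
    X = np.column_stack([np.ones_like(pu), pu, su])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef[1:].reshape((2,) + point_shape)


@dataclass
class Cluster:
    """One adjacency-connected set of suprathreshold datapoints."""

    ch_idx: np.ndarray
    t_idx: np.ndarray
    f_idx: np.ndarray | None
    times: np.ndarray  # seconds, per member
    sign: int
    mass: float
    duration_ms: float
    p: float = np.nan

    @property
    def n_points(self) -> int:
        return len(self.ch_idx)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    tmap: np.ndarray
    threshold: float
    window: tuple[float, float]
    times: np.ndarray
    freqs: np.ndarray | None = None
    n_perm: int = 0
    null_max_mass: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            rows.append(
                {
                    "cluster_id": i,
                    "sign": c.sign,
                    "n_datapoints": c.n_points,
                    "t_mass": c.mass,
                    "p": c.p,
                    "t_min_ms": 1000.0 * c.times.min(),
                    "t_max_ms": 1000.0 * c.times.max(),
                    "duration_ms": c.duration_ms,
                    "n_channels": len(np.unique(c.ch_idx)),
                }
            )
        return pd.DataFrame(rows)


def _space_adjacency(
    ch_adj: sparse.spmatrix, n_f: int, n_t: int
) -> sparse.csr_matrix:
    """Adjacency over flattened (ch, f, t) points: channel neighbors at the
    same (f, t), +-1 frequency bin, +-1 time step."""
    n_ch = ch_adj.shape[0]
    eye_ch = sparse.identity(n_ch, dtype=bool, format="csr")
    eye_f = sparse.identity(n_f, dtype=bool, format="csr")
    eye_t = sparse.identity(n_t, dtype=bool, format="csr")
    band_f = sparse.diags([True] * (n_f - 1), 1, shape=(n_f, n_f), dtype=bool) if n_f > 1 else sparse.csr_matrix((n_f, n_f), dtype=bool)
    band_f = (band_f + band_f.T).astype(bool)
    band_t = sparse.diags([True] * (n_t - 1), 1, shape=(n_t, n_t), dtype=bool)
    band_t = (band_t + band_t.T).astype(bool)
    adj = (
        sparse.kron(sparse.kron(ch_adj.astype(bool), eye_f), eye_t)
        + sparse.kron(sparse.kron(eye_ch, band_f), eye_t)
        + sparse.kron(sparse.kron(eye_ch, eye_f), band_t)
    )
    return adj.tocsr().astype(bool)


def _components(mask_idx: np.ndarray, adj: sparse.csr_matrix) -> list[np.ndarray]:
    if len(mask_idx) == 0:
        return []
    sub = adj[mask_idx][:, mask_idx]
    n, labels = connected_components(sub, directed=False)
    return [mask_idx[labels == k] for k in range(n)]


def _enumerate_clusters(
    t_flat: np.ndarray,
    threshold: float,
    adj: sparse.csr_matrix,
    shape: tuple[int, ...],
    dt_ms: float,
    min_dur_ms: float,
):
    """Suprathreshold clusters of each sign passing the duration filter.

    Returns (members, signs, masses) with members as flat-index arrays.
    """
    out_members, out_signs, out_mass = [], [], []
    for sign in (1, -1):
        idx = np.flatnonzero(sign * t_flat > threshold)
        for comp in _components(idx, adj):
            t_pos = np.unravel_index(comp, shape)[-1]
            dur = (t_pos.max() - t_pos.min() + 1) * dt_ms
            if dur <= min_dur_ms:
                continue
            out_members.append(comp)
            out_signs.append(sign)
            out_mass.append(float(t_flat[comp].sum()))
    return out_members, out_signs, out_mass


def _tmaps_signed(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t-maps for sign-flipped data, vectorized over draws.

    X is (n_subj, P); signs is (B, n_subj).  Uses the invariance of
    sum(x^2) under sign flips: only the mean changes per draw.
    """
    n = X.shape[0]
    msq = (X**2).mean(axis=0)  # (P,)
    means = signs @ X / n  # (B, P)
    var = (msq - means**2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def cluster_test(
    subject_maps: np.ndarray,
    ch_adjacency: sparse.spmatrix,
    times: np.ndarray,
    window: tuple[float, float],
    freqs: np.ndarray | None = None,
    cf_alpha: float = 0.001,
    n_perm: int = 1000,
    min_dur_ms: float = 5.0,
    seed: int = 0,
) -> ClusterSet:
    """Cluster-based sign-flip permutation test of subject maps against zero.

    ``subject_maps`` is (n_subj, n_ch, [n_f,] n_t); ``times`` (seconds) spans
    the last axis and is cropped to ``window``.  Cluster p-values are
    ``(1 + #{permutation max |mass| >= |observed mass|}) / (n_perm + 1)``;
    the identity assignment contributes the +1.
    """
    X = np.asarray(subject_maps, float)
    has_freq = X.ndim == 4
    if has_freq and freqs is None:
        raise ValueError("freqs required for 4-D maps")
    n_subj = X.shape[0]
    if n_subj < 6:
        raise ValueError("cluster test requires at least 6 subjects")
    tsel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not tsel.any():
        raise ValueError(f"window {window} outside the data time range")
    X = X[..., tsel]
    wtimes = np.asarray(times)[tsel]
    dt_ms = 1000.0 * float(np.median(np.diff(wtimes))) if len(wtimes) > 1 else np.inf
    shape = X.shape[1:]
    n_ch = shape[0]
    n_f = shape[1] if has_freq else 1
    n_t = shape[-1]
    adj = _space_adjacency(sparse.csr_matrix(ch_adjacency), n_f, n_t)

    flat = X.reshape(n_subj, -1)
    threshold = float(stats.t.ppf(1.0 - cf_alpha / 2.0, df=n_subj - 1))
    t_obs = _tmaps_signed(flat, np.ones((1, n_subj)))[0]
    members, signs_list, masses = _enumerate_clusters(
        t_obs, threshold, adj, shape, dt_ms, min_dur_ms
    )

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    t_perm = _tmaps_signed(flat, flips)
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        tb = t_perm[b]
        if np.max(np.abs(tb)) <= threshold:
            continue
        _, _, pm = _enumerate_clusters(tb, threshold, adj, shape, dt_ms, min_dur_ms)
        if pm:
            null_max[b] = np.max(np.abs(pm))

    clusters = []
    for comp, sign, mass in zip(members, signs_list, masses):
        coords = np.unravel_index(comp, shape)
        ch_idx = coords[0]
        f_idx = coords[1] if has_freq else None
        t_idx = coords[-1]
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        clusters.append(
            Cluster(
                ch_idx=ch_idx,
                t_idx=t_idx,
                f_idx=f_idx,
                times=wtimes[t_idx],
                sign=sign,
                mass=mass,
                duration_ms=(t_idx.max() - t_idx.min() + 1) * dt_ms,
                p=float(p),
            )
        )
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterSet(
        clusters=clusters,
        tmap=t_obs.reshape(shape),
        threshold=threshold,
        window=window,
        times=wtimes,
        freqs=None if not has_freq else np.asarray(freqs),
        n_perm=n_perm,
        null_max_mass=null_max,
    )


def cluster_test_paired(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    ch_adjacency: sparse.spmatrix,
    times: np.ndarray,
    window: tuple[float, float],
    **kwargs,
) -> ClusterSet:
    """Paired contrast (e.g. AV - A): one-sample cluster test on the
    per-subject difference maps; sign flips realize condition swaps."""
    a, b = np.asarray(maps_a, float), np.asarray(maps_b, float)
    if a.shape != b.shape:
        raise ValueError("paired maps must have matching shapes")
    return cluster_test(a - b, ch_adjacency, times, window, **kwargs)
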