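"""Synthetic epoched EEG with implanted latent-variable effects.

Generates multichannel sound-locked epochs whose components are modulated by
the observer latents (prior uncertainty, surprisal), on top of a 1/f
background with shared low-rank spatial mixing and white sensor noise.  Each
implanted component has a dipolar spatial map (one positive and one negative
pole), a Gaussian temporal kernel, and either a DC carrier (an ERP-like
deflection) or an oscillatory carrier with random phase per epoch (an induced
effect invisible in the evoked average).  Ground-truth masks record where
each component lives, so downstream regression and cluster inference can be
validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import Delaunay

__all__ = [
    "ChannelLayout",
    "EffectSpec",
    "EpochSet",
    "make_layout",
    "simulate_subject_epochs",
    "pink_noise",
]


@dataclass
class ChannelLayout:
    """Channel names, 2-D positions on the unit disk, and adjacency."""

    names: list[str]
    pos: np.ndarray
    adjacency: sparse.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.names)
        adj = self.adjacency
        if adj.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")

    @property
    def n_channels(self) -> int:
        return len(self.names)


def make_layout(n_channels: int, rng: np.random.Generator | None = None) -> ChannelLayout:
    """Quasi-uniform sunflower layout on the unit disk with Delaunay adjacency.

    Deterministic without an ``rng``; passing one adds a small positional
    jitter (useful to randomize montages across simulated datasets).
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    k = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt((k + 0.5) / n_channels)
    theta = k * golden
    pos = np.c_[r * np.cos(theta), r * np.sin(theta)]
    if rng is not None:
        pos = pos + rng.normal(0.0, 0.01, size=pos.shape)
    tri = Delaunay(pos)
    rows, cols = [], []
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = simplex[a], simplex[b]
                rows += [i, j]
                cols += [j, i]
    adj = sparse.csr_matrix(
        (np.ones(len(rows), bool), (rows, cols)), shape=(n_channels, n_channels)
    )
    adj.setdiag(False)
    adj.eliminate_zeros()
    adj.data[:] = True
    names = [f"ch{i:03d}" for i in range(n_channels)]
    return ChannelLayout(names=names, pos=pos, adjacency=adj)


@dataclass(frozen=True)
class EffectSpec:
    """One implanted component.

    ``latent`` is ``"pu"``, ``"su"`` or ``None`` (latent-independent).  The
    per-epoch amplitude is ``base + beta * z(latent)``; the spatial map is a
    dipole built from Gaussian bumps at ``pos_pole`` / ``neg_pole`` channel
    indices (max |weight| normalized to 1); the temporal kernel is a Gaussian
    centered at ``center_ms`` with SD ``width_ms``; ``freq_hz=None`` gives a
    DC (ERP-like) carrier, otherwise a random-phase oscillation.
    """

    name: str
    latent: str | None
    center_ms: float
    width_ms: float
    beta: float
    base: float = 0.0
    freq_hz: float | None = None
    pos_pole: int = 0
    neg_pole: int | None = None
    spatial_sigma: float = 0.4

    def spatial_map(self, layout: ChannelLayout) -> np.ndarray:
        d_pos = np.linalg.norm(layout.pos - layout.pos[self.pos_pole], axis=1)
        w = np.exp(-0.5 * (d_pos / self.spatial_sigma) ** 2)
        if self.neg_pole is not None:
            d_neg = np.linalg.norm(layout.pos - layout.pos[self.neg_pole], axis=1)
            w = w - np.exp(-0.5 * (d_neg / self.spatial_sigma) ** 2)
        return w / np.max(np.abs(w))

    def kernel(self, times: np.ndarray) -> np.ndarray:
        c, s = self.center_ms / 1000.0, self.width_ms / 1000.0
        return np.exp(-0.5 * ((times - c) / s) ** 2)


@dataclass
class EpochSet:
    """Epoched data: channels x time x epochs, with per-epoch metadata."""

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    meta: pd.DataFrame
    baseline: tuple[float, float] | None = (-0.1, 0.0)

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.data.shape[2] != len(self.meta):
            raise ValueError("metadata rows must match epoch count")
        dt = np.diff(self.times)
        if not np.allclose(dt, 1.0 / self.sfreq, atol=1e-9):
            raise ValueError("time vector must be regular at sfreq")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.sfreq, self.times.copy(), self.meta.copy(),
            self.baseline,
        )


def pink_noise(
    shape: tuple[int, ...], n_times: int, sfreq: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f-power noise along the last axis, unit variance."""
    freqs = np.fft.rfftfreq(n_times, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.standard_normal(shape + (len(freqs),))
        + 1j * rng.standard_normal(shape + (len(freqs),))
    ) * amp
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _zscore_included(values: np.ndarray, included: np.ndarray) -> np.ndarray:
    """z-score all epochs using the mean/SD of the included ones."""
    m = values[included].mean()
    s = values[included].std()
    if s == 0:
        raise ValueError("latent has zero variance over included epochs")
    return (values - m) / s


def simulate_subject_epochs(
    latents: pd.DataFrame,
    layout: ChannelLayout,
    effects: list[EffectSpec],
    rng: np.random.Generator,
    sfreq: float = 250.0,
    tmin: float = -0.3,
    tmax: float = 0.5,
    pink_scale: float = 1.0,
    sensor_scale: float = 0.2,
    n_shared: int = 5,
    shared_scale: float = 0.5,
    baseline: tuple[float, float] | None = (-0.1, 0.0),
) -> tuple[EpochSet, dict[str, dict]]:
    """One subject's epochs (one per sound in ``latents``) plus ground truth.

    ``latents`` must carry columns ``pu``, ``su``, ``is_first``, ``is_probe``
    (plus any identifiers, which are passed through to the metadata).
    Latents are z-scored within subject over the included (non-first,
    non-probe) epochs, matching the regression convention; the same z-map is
    applied to probe epochs so brain-behavior effects carry over.  Epochs are
    baseline-corrected by subtracting the per-channel, per-epoch mean of the
    baseline window.
    """
    n_ep = len(latents)
    n_ch = layout.n_channels
    n_t = int(round((tmax - tmin) * sfreq)) + 1
    times = tmin + np.arange(n_t) / sfreq
    included = (~latents["is_first"].to_numpy()) & (~latents["is_probe"].to_numpy())
    if included.sum() < 2:
        raise ValueError("need at least two included epochs")
    z = {
        name: _zscore_included(latents[name].to_numpy(float), included)
        for name in ("pu", "su")
    }

    data = pink_scale * pink_noise((n_ch, n_ep), n_t, sfreq, rng)
    if n_shared > 0 and shared_scale > 0:
        shared = pink_noise((n_shared, n_ep), n_t, sfreq, rng)
        mix = rng.standard_normal((n_ch, n_shared)) / np.sqrt(n_shared)
        data = data + shared_scale * np.einsum("cs,set->cet", mix, shared)
    if sensor_scale > 0:
        data = data + sensor_scale * rng.standard_normal((n_ch, n_ep, n_t))
    data = np.moveaxis(data, 1, 2)  # -> (ch, time, epoch)

    truth: dict[str, dict] = {}
    for eff in effects:
        w = eff.spatial_map(layout)
        k = eff.kernel(times)
        if eff.latent is None:
            amp = np.full(n_ep, eff.base)
        else:
            amp = eff.base + eff.beta * z[eff.latent]
        if eff.freq_hz is None:
            carrier = np.ones((n_t, n_ep))
        else:
            phase = rng.uniform(0, 2 * np.pi, size=n_ep)
            carrier = np.cos(2 * np.pi * eff.freq_hz * times[:, None] + phase[None, :])
        data += w[:, None, None] * (k[:, None] * carrier) * amp[None, None, :]

        ch_mask = np.abs(w) >= 0.5
        t_mask = k >= 0.5
        mask = ch_mask[:, None] & t_mask[None, :]
        sign_map = np.zeros((n_ch, n_t), dtype=int)
        sign_map[mask] = (
            np.sign(eff.beta) * np.sign(w)[:, None] * np.ones(n_t)[None, :]
        )[mask].astype(int)
        truth[eff.name] = {
            "latent": eff.latent,
            "mask": mask,
            "sign_map": sign_map,
            "freq_hz": eff.freq_hz,
            "beta": eff.beta,
            "spatial_map": w,
            "kernel": k,
        }

    if baseline is not None:
        b = (times >= baseline[0]) & (times <= baseline[1])
        data = data - data[:, b, :].mean(axis=1, keepdims=True)

    meta = latents.reset_index(drop=True).copy()
    meta["z_pu"] = z["pu"]
    meta["z_su"] = z["su"]
    return (
        EpochSet(data=data, sfreq=sfreq, times=times, meta=meta, baseline=baseline),
        truth,
    )
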