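"""Time-frequency decomposition of epoched data.

Induced power is isolated by subtracting the across-epoch (evoked) mean
before decomposition.  The low band (4-30 Hz, 1 Hz spacing) uses a single
Hanning taper with a fixed 300 ms window stepped every 16 ms; the high band
(40-100 Hz, 2 Hz spacing) uses DPSS multitapers with the window length
shrinking linearly from 250 ms at 40 Hz to 100 ms at 100 Hz.  Raw power is
expressed as relative signal change against the per-epoch mean over the
0-500 ms interval (the full stimulus-onset asynchrony).

Output time points are aligned to the sample closest to stimulus onset and
include only centers whose analysis window is fully supported by the epoch;
edge samples are omitted rather than zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss, hann

from .synth_eeg import EpochSet

__all__ = [
    "TFRSet",
    "subtract_evoked",
    "tfr_low",
    "tfr_high",
    "baseline_relchange",
    "LOW_BAND",
    "HIGH_BAND",
]

LOW_BAND = dict(fmin=4.0, fmax=30.0, df=1.0, win_ms=300.0, step_ms=16.0)
HIGH_BAND = dict(
    fmin=40.0, fmax=100.0, df=2.0, win_ms_low=250.0, win_ms_high=100.0, step_ms=16.0
)


class WindowError(ValueError):
    """Epoch too short for the requested analysis window."""


@dataclass
class TFRSet:
    """Time-frequency power: channels x frequencies x times x epochs."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    band: str
    kind: str = "raw"  # "raw" | "relchange"
    params: dict | None = None

    def __post_init__(self) -> None:
        if self.power.shape[1] != len(self.freqs):
            raise ValueError("frequency axis mismatch")
        if self.power.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.kind == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")
        if self.kind == "relchange" and np.any(self.power < -1):
            raise ValueError("relative change cannot fall below -1")


def subtract_evoked(epochs: EpochSet) -> EpochSet:
    """Remove the across-epoch mean (the evoked response) from every epoch."""
    if epochs.data.shape[2] < 2:
        raise ValueError("need at least 2 epochs to estimate the evoked response")
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=2, keepdims=True)
    return out


def _centers(n_times: int, times: np.ndarray, L: int, step: int) -> np.ndarray:
    """Window-center sample indices: aligned to the sample nearest t=0,
    stepped every ``step`` samples, full window support required."""
    half = L // 2
    lo, hi = half, n_times - (L - 1 - half) - 1
    if lo > hi:
        raise WindowError(
            f"epoch of {n_times} samples cannot support a {L}-sample window"
        )
    i0 = int(np.argmin(np.abs(times)))
    k_lo = int(np.ceil((lo - i0) / step))
    k_hi = int(np.floor((hi - i0) / step))
    if k_lo > k_hi:
        raise WindowError(
            f"no valid window centers; valid sample range is [{lo}, {hi}]"
        )
    return i0 + step * np.arange(k_lo, k_hi + 1)


def _stft_power(
    data: np.ndarray,
    sfreq: float,
    freqs: np.ndarray,
    centers: np.ndarray,
    tapers_per_freq: list[np.ndarray],
    lengths: np.ndarray,
) -> np.ndarray:
    """Tapered DFT power at arbitrary frequencies.

    ``tapers_per_freq[i]`` has shape (K_i, L_i); power is averaged over
    tapers and normalized per taper energy so that a unit-amplitude sinusoid
    yields comparable power across window lengths.
    """
    n_ch, _, n_ep = data.shape
    out = np.empty((n_ch, len(freqs), len(centers), n_ep))
    for fi, f in enumerate(freqs):
        L = int(lengths[fi])
        half = L // 2
        tap = tapers_per_freq[fi]  # (K, L)
        n = np.arange(L) / sfreq
        phasor = np.exp(-2j * np.pi * f * n)  # (L,)
        kernels = tap * phasor[None, :]  # (K, L)
        # per-taper energy times window length: a unit-amplitude sinusoid
        # yields comparable power across the varying window lengths
        norm = (tap**2).sum(axis=1) * L
        for ci, c in enumerate(centers):
            seg = data[:, c - half : c - half + L, :]  # (ch, L, ep)
            X = np.einsum("kl,cle->kce", kernels, seg)
            p = (np.abs(X) ** 2 / norm[:, None, None]).mean(axis=0)
            out[:, fi, ci, :] = p
    return out


def tfr_low(epochs: EpochSet) -> TFRSet:
    """Single-Hanning-taper power, 4-30 Hz at 1 Hz spacing, 300 ms windows
    stepped every 16 ms."""
    p = LOW_BAND
    sf = epochs.sfreq
    L = int(round(p["win_ms"] / 1000.0 * sf))
    step = max(int(round(p["step_ms"] / 1000.0 * sf)), 1)
    freqs = np.arange(p["fmin"], p["fmax"] + 0.5 * p["df"], p["df"])
    centers = _centers(epochs.data.shape[1], epochs.times, L, step)
    taper = hann(L, sym=False)
    power = _stft_power(
        epochs.data, sf, freqs, centers,
        [taper[None, :]] * len(freqs), np.full(len(freqs), L),
    )
    return TFRSet(
        power=power,
        freqs=freqs,
        times=epochs.times[centers],
        band="low",
        kind="raw",
        params={"win_ms": p["win_ms"], "step_ms": p["step_ms"], "taper": "hann"},
    )


def _high_band_window_ms(f: float) -> float:
    p = HIGH_BAND
    frac = (f - p["fmin"]) / (p["fmax"] - p["fmin"])
    return p["win_ms_low"] + frac * (p["win_ms_high"] - p["win_ms_low"])


def _high_band_n_tapers(f: float) -> int:
    # 3 DPSS tapers at 40 Hz shrinking to 1 at 100 Hz as windows shorten
    p = HIGH_BAND
    frac = (f - p["fmin"]) / (p["fmax"] - p["fmin"])
    return int(np.clip(round(3 - 2 * frac), 1, 3))


def tfr_high(epochs: EpochSet) -> TFRSet:
    """DPSS multitaper power, 40-100 Hz at 2 Hz spacing, window length
    shrinking linearly from 250 ms (40 Hz) to 100 ms (100 Hz)."""
    p = HIGH_BAND
    sf = epochs.sfreq
    step = max(int(round(p["step_ms"] / 1000.0 * sf)), 1)
    freqs = np.arange(p["fmin"], p["fmax"] + 0.5 * p["df"], p["df"])
    lengths = np.array(
        [int(round(_high_band_window_ms(f) / 1000.0 * sf)) for f in freqs]
    )
    # common centers: every frequency's window must fit
    centers = _centers(epochs.data.shape[1], epochs.times, int(lengths.max()), step)
    tapers = []
    for f, L in zip(freqs, lengths):
        K = _high_band_n_tapers(f)
        nw = (K + 1) / 2.0
        tap = dpss(int(L), nw, Kmax=K)
        tapers.append(np.atleast_2d(tap))
    power = _stft_power(epochs.data, sf, freqs, centers, tapers, lengths)
    return TFRSet(
        power=power,
        freqs=freqs,
        times=epochs.times[centers],
        band="high",
        kind="raw",
        params={
            "win_ms": [float(_high_band_window_ms(f)) for f in freqs],
            "n_tapers": [_high_band_n_tapers(f) for f in freqs],
            "step_ms": p["step_ms"],
        },
    )


def baseline_relchange(
    tfr: TFRSet, window: tuple[float, float] = (0.0, 0.5)
) -> TFRSet:
    """Relative signal change: (power - m) / m, m the per-channel,
    per-frequency, per-epoch mean over ``window`` (default 0-500 ms)."""
    if tfr.kind != "raw":
        raise ValueError("baseline expects raw power")
    sel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    if not sel.any():
        raise WindowError(f"baseline window {window} outside TFR time range")
    m = tfr.power[:, :, sel, :].mean(axis=2, keepdims=True)
    if np.any(m <= 0):
        raise FloatingPointError("degenerate (zero) baseline power")
    return TFRSet(
        power=(tfr.power - m) / m,
        freqs=tfr.freqs,
        times=tfr.times,
        band=tfr.band,
        kind="relchange",
        params=tfr.params,
    )
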