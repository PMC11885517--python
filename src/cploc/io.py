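"""HDF5 serialization for epoched and time-frequency data.

Layout: ``/data`` (channels x time x epochs, or channels x freqs x times x
epochs for TFR), ``/times``, ``/freqs`` (TFR only), and the per-epoch
metadata table under ``/meta/<column>``.  Scalar attributes carry the
sampling rate, baseline window and band labels.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .spectral import TFRSet
from .synth_eeg import EpochSet

__all__ = ["save_epochs", "load_epochs", "save_tfr", "load_tfr"]


def _write_meta(f: h5py.File, meta: pd.DataFrame) -> None:
    grp = f.create_group("meta")
    for col in meta.columns:
        v = meta[col].to_numpy()
        if v.dtype == object:
            v = v.astype("S")
        grp.create_dataset(col, data=v)
    grp.attrs["columns"] = list(meta.columns)


def _read_meta(f: h5py.File) -> pd.DataFrame:
    grp = f["meta"]
    cols = list(grp.attrs["columns"])
    data = {}
    for col in cols:
        v = grp[col][()]
        if v.dtype.kind == "S":
            v = v.astype(str)
        data[col] = v
    return pd.DataFrame(data)


def save_epochs(path: str, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        if epochs.baseline is not None:
            f.attrs["baseline"] = list(epochs.baseline)
        _write_meta(f, epochs.meta)


def load_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        baseline = tuple(f.attrs["baseline"]) if "baseline" in f.attrs else None
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            meta=_read_meta(f),
            baseline=baseline,
        )


def save_tfr(path: str, tfr: TFRSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power)
        f.create_dataset("times", data=tfr.times)
        f.create_dataset("freqs", data=tfr.freqs)
        f.attrs["band"] = tfr.band
        f.attrs["kind"] = tfr.kind


def load_tfr(path: str) -> TFRSet:
    with h5py.File(path, "r") as f:
        return TFRSet(
            power=f["power"][()],
            times=f["times"][()],
            freqs=f["freqs"][()],
            band=str(f.attrs["band"]),
            kind=str(f.attrs["kind"]),
        )
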