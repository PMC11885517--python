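"""Simulate one subject's epoched EEG with implanted latent effects.

Builds a 32-channel montage, runs the observer over a session, and implants
the default component set (pre-stimulus PU dipole, P3-like SU dipole,
PU-linked alpha desynchronization, SU-linked gamma increase) on a 1/f
background.  Epochs go to scratch/ as HDF5 (they are bulky); a per-channel
summary and the ground-truth extents go to results/.

Writes scratch/subject0_epochs.h5 and results/eeg_ground_truth.csv.
"""

import os

import numpy as np
import pandas as pd

from cploc import io, pipeline

ROOT = os.path.join(os.path.dirname(__file__), "..")
SEED = 20260922


def main() -> None:
    os.makedirs(os.path.join(ROOT, "results"), exist_ok=True)
    os.makedirs(os.path.join(ROOT, "scratch"), exist_ok=True)
    cohort = pipeline.simulate_cohort(SEED, n_subjects=1, n_pairs=60)
    sub = cohort.subjects[0]
    ep = sub.epochs["A"]
    io.save_epochs(os.path.join(ROOT, "scratch", "subject0_epochs.h5"), ep)
    print(
        f"subject 0 (A): {ep.data.shape[2]} epochs, {ep.data.shape[0]} channels, "
        f"{ep.data.shape[1]} samples at {ep.sfreq:.0f} Hz "
        f"({ep.times[0]:.2f}..{ep.times[-1]:.2f} s)"
    )
    rows = []
    for name, tr in sub.truth["A"].items():
        mask = tr["mask"]
        t_any = mask.any(axis=0)
        rows.append(
            {
                "component": name,
                "latent": tr["latent"],
                "beta": tr["beta"],
                "carrier_hz": tr["freq_hz"] if tr["freq_hz"] else 0.0,
                "n_channels": int(mask.any(axis=1).sum()),
                "t_min_ms": 1000 * ep.times[t_any].min(),
                "t_max_ms": 1000 * ep.times[t_any].max(),
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(os.path.join(ROOT, "results", "eeg_ground_truth.csv"), index=False)
    print(truth.to_string(index=False))
    b = (ep.times >= -0.1) & (ep.times <= 0.0)
    print(
        "baseline check: max |mean over -100..0 ms| = "
        f"{np.abs(ep.data[:, b, :].mean(axis=1)).max():.2e}"
    )


if __name__ == "__main__":
    main()
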