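"""Time-domain mass-univariate regression and cluster permutation tests.

For an 8-subject simulated cohort: per subject and condition, every
(channel, time) point of the epoched EEG is regressed on z-scored PU and SU
(first and probe sounds excluded).  Group-level cluster tests (cluster-
forming alpha 0.001, 1000 sign-flip permutations, clusters > 5 ms) run in
the PU window (-250..100 ms) and SU window (0..500 ms), per condition and
for the AV-A contrast.

Writes results/clusters_time_domain.csv.
"""

import os

import numpy as np
import pandas as pd

from cploc import pipeline, regression

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 20260922
WINDOWS = {"pu": regression.PU_WINDOW, "su": regression.SU_WINDOW}


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cohort = pipeline.simulate_cohort(SEED, n_subjects=8, n_pairs=60)
    maps = {}
    times = None
    for cond in ("A", "AV"):
        maps[cond], times = pipeline.subject_beta_maps(cohort, cond)
        print(f"{cond}: betas for {maps[cond].shape[0]} subjects, "
              f"{maps[cond].shape[2]} channels x {maps[cond].shape[3]} samples")

    frames = []
    for li, latent in enumerate(("pu", "su")):
        win = WINDOWS[latent]
        for label, arg in (
            ("A", maps["A"][:, li]),
            ("AV", maps["AV"][:, li]),
            ("AV-A", maps["AV"][:, li] - maps["A"][:, li]),
        ):
            cs = regression.cluster_test(
                arg, cohort.layout.adjacency, times, win, n_perm=1000, seed=SEED % 1000
            )
            tab = cs.to_frame()
            tab.insert(0, "latent", latent.upper())
            tab.insert(1, "contrast", label)
            frames.append(tab)
            sig = tab[tab.p < 0.05]
            print(
                f"{latent.upper():3s} {label:5s} window {win}: "
                f"{len(sig)} significant cluster(s)"
                + (f", min p = {sig.p.min():.3f}" if len(sig) else "")
            )
    allc = pd.concat(frames, ignore_index=True)
    allc.to_csv(os.path.join(OUT, "clusters_time_domain.csv"), index=False)


if __name__ == "__main__":
    main()
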