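"""Simulate one main-task session and verify its generative statistics.

Generates 150 trial pairs (300 presentations) of the change-point
localization task and a large pooled sample of sequences, then checks the
printed task parameters: experimental noise SD 10 deg, change-point hazard
1/6, per-sound probe probability 1/12, generative means within +-60 deg.

Writes results/session_sounds.csv (one row per presented sound) and
results/task_statistics.csv.
"""

import os

import numpy as np
import pandas as pd

from cploc import task

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 20260922


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    rng = np.random.default_rng(SEED)
    cfg = task.TaskConfig()

    sess = task.generate_session(cfg, 150, rng)
    df = sess.to_frame()
    df.to_csv(os.path.join(OUT, "session_sounds.csv"), index=False)
    print(f"session: {sess.n_presentations} presentations, {len(df)} sounds")

    seqs, n = [], 0
    while n < 200_000:
        s = task.generate_sequence(cfg, rng, len(seqs))
        seqs.append(s)
        n += len(s)
    resid = np.concatenate([s.locations - s.gen_means for s in seqs])
    cps = np.concatenate([s.is_change[1:] for s in seqs])
    free, ended = 0, 0
    for s in seqs:
        for i in range(len(s)):
            if i < cfg.max_len - 1:
                free += 1
                ended += i == s.probe_index
    lens = np.array([len(s) for s in seqs])
    stats = pd.DataFrame(
        [
            {"quantity": "exp_noise_sd_deg", "value": resid.std(), "target": 10.0},
            {"quantity": "change_point_fraction", "value": cps.mean(), "target": 1 / 6},
            {"quantity": "probe_probability", "value": ended / free, "target": 1 / 12},
            {"quantity": "min_gen_mean_deg",
             "value": min(s.gen_means.min() for s in seqs), "target": -60.0},
            {"quantity": "max_gen_mean_deg",
             "value": max(s.gen_means.max() for s in seqs), "target": 60.0},
            {"quantity": "min_len", "value": lens.min(), "target": 1},
            {"quantity": "max_len", "value": lens.max(), "target": cfg.max_len},
        ]
    )
    stats.to_csv(os.path.join(OUT, "task_statistics.csv"), index=False)
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
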