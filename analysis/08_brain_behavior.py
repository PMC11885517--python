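"""Trial-level brain-behavior link at the probe sound.

Recomputes the time-domain SU regression clusters (from non-probe epochs;
same cohort seed as 06_regression_clusters.py), averages each significant
cluster over the held-out probe epochs to get one scalar per trial, and
regresses estimation error, response uncertainty and prior bias on that
scalar within subject, testing the slopes against zero at the group level.

Writes results/brain_behavior_slopes.csv and
results/brain_behavior_group.csv.
"""

import os

import pandas as pd

from cploc import brain_behavior, pipeline, regression

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 20260922


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cohort = pipeline.simulate_cohort(SEED, n_subjects=8, n_pairs=60)
    slope_frames, group_frames = [], []
    for cond in ("A", "AV"):
        maps, times = pipeline.subject_beta_maps(cohort, cond)
        cs = regression.cluster_test(
            maps[:, 1], cohort.layout.adjacency, times, regression.SU_WINDOW,
            n_perm=1000, seed=SEED % 1000,
        )
        sig = cs.significant()
        print(f"{cond}: {len(sig)} significant SU cluster(s) from non-probe epochs")
        if not sig:
            continue
        probe_data, probe_meta = pipeline.probe_epoch_stack(cohort, cond)
        scores = brain_behavior.score_clusters(probe_data, times, sig, meta=probe_meta)
        records = cohort.records
        beh = records[records.condition == cond][
            ["subject", "trial_id", "error", "response_uncertainty", "prior_bias",
             "single_sound"]
        ]
        slopes, group = brain_behavior.link_behavior(scores, beh)
        for df in (slopes, group):
            df.insert(0, "condition", cond)
        slope_frames.append(slopes)
        group_frames.append(group)
        for _, row in group.iterrows():
            print(
                f"  cluster {row.cluster} ~ {row.variable}: mean beta "
                f"{row.mean_beta:+.3f}, t({row.df}) = {row.t:.2f}, p = {row.p:.3f}"
                + ("  *" if row.significant else "")
            )
    if slope_frames:
        pd.concat(slope_frames, ignore_index=True).to_csv(
            os.path.join(OUT, "brain_behavior_slopes.csv"), index=False
        )
        pd.concat(group_frames, ignore_index=True).to_csv(
            os.path.join(OUT, "brain_behavior_group.csv"), index=False
        )


if __name__ == "__main__":
    main()
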