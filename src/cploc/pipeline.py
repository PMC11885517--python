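"""Convenience assembly of the full simulated study.

Builds a deterministic multi-subject "cohort": per subject a paired A/AV
session, observer latents under condition-specific sensory noise, simulated
responses, and synthetic epochs with implanted latent-driven components.
The analysis drivers and the acceptance script share this assembly so every
stage recomputes from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, observer, regression, synth_eeg, task

__all__ = ["SubjectData", "Cohort", "default_effects", "simulate_cohort"]

CONDITIONS = ("A", "AV")


def default_effects(
    av_gain: float = 1.0, n_channels: int = 32
) -> list[synth_eeg.EffectSpec]:
    """Canonical implanted components, shaped after motifs typical of
    predictive-processing EEG studies: a pre-stimulus PU-driven dipole, a
    P3-like SU-driven dipole, a PU-linked alpha desynchronization and an
    SU-linked gamma increase (both induced, random phase).  Pole indices
    scale with the montage size."""
    g = av_gain

    def pole(frac: float) -> int:
        return int(frac * (n_channels - 1))

    return [
        synth_eeg.EffectSpec(
            name="pu_prestim", latent="pu", center_ms=-175.0, width_ms=50.0,
            beta=0.6 * g, pos_pole=pole(0.10), neg_pole=pole(0.68),
        ),
        synth_eeg.EffectSpec(
            name="su_p3", latent="su", center_ms=300.0, width_ms=60.0,
            beta=0.6 * g, pos_pole=pole(0.0), neg_pole=pole(0.55),
        ),
        synth_eeg.EffectSpec(
            name="pu_alpha_desync", latent="pu", center_ms=0.0, width_ms=80.0,
            beta=-0.5 * g, base=1.5, freq_hz=10.0, pos_pole=pole(0.26),
        ),
        synth_eeg.EffectSpec(
            name="su_gamma", latent="su", center_ms=200.0, width_ms=60.0,
            beta=0.5 * g, base=1.0, freq_hz=70.0, pos_pole=pole(0.39),
        ),
    ]


@dataclass
class SubjectData:
    subject: int
    session: task.Session
    latents: pd.DataFrame          # per-sound, both conditions
    trials: pd.DataFrame           # per-presentation probe reports
    records: pd.DataFrame          # behavioral records (responses + metrics)
    epochs: dict[str, synth_eeg.EpochSet] = field(default_factory=dict)
    truth: dict[str, dict] = field(default_factory=dict)


@dataclass
class Cohort:
    layout: synth_eeg.ChannelLayout
    subjects: list[SubjectData]
    sigma_s: float
    sigma_m: float

    @property
    def records(self) -> pd.DataFrame:
        return pd.concat([s.records for s in self.subjects], ignore_index=True)

    @property
    def latents(self) -> pd.DataFrame:
        return pd.concat([s.latents for s in self.subjects], ignore_index=True)


def simulate_cohort(
    seed: int,
    n_subjects: int = 8,
    n_pairs: int = 60,
    n_channels: int = 32,
    sigma_s: float = 10.0,
    sigma_m: float = 3.0,
    av_sigma_s: float = 1.0,
    av_gain: float = 1.3,
    with_eeg: bool = True,
    effects: list[synth_eeg.EffectSpec] | None = None,
) -> Cohort:
    """Simulate ``n_subjects`` paired-session subjects from one seed.

    All subjects share the generative task configuration; each draws an
    independent session (the real study reused one trial set across
    participants, but independent sessions give the group statistics an
    honest between-subject variability).  ``av_gain`` scales the implanted
    effect sizes in the AV condition, mimicking the stronger audio-visual
    coefficient patterns.
    """
    cfg = task.TaskConfig()
    layout = synth_eeg.make_layout(n_channels)
    pa = observer.ObserverParams(sensory_noise_sd=sigma_s)
    pav = observer.av_params(pa, av_sigma_s)
    params = {"A": pa, "AV": pav}
    subjects = []
    for s in range(n_subjects):
        rng = np.random.default_rng((seed * 1009 + s) % (2**31 - 1))
        sess = task.generate_session(cfg, n_pairs, rng)
        latents, trials = observer.run_session(sess, params, rng=rng)
        latents = latents.copy()
        latents["subject"] = s
        responses = trials["estimate"].to_numpy() + rng.normal(
            0.0, sigma_m, len(trials)
        )
        records = behavior.make_records(trials, responses, subject=s)
        sub = SubjectData(
            subject=s, session=sess, latents=latents, trials=trials, records=records
        )
        if with_eeg:
            for cond in CONDITIONS:
                eff = default_effects(
                    av_gain if cond == "AV" else 1.0, n_channels=n_channels
                )
                if effects is not None:
                    eff = effects
                lat_c = latents[latents.condition == cond].reset_index(drop=True)
                ep, truth = synth_eeg.simulate_subject_epochs(
                    lat_c, layout, eff, rng
                )
                sub.epochs[cond] = ep
                sub.truth[cond] = truth
        subjects.append(sub)
    return Cohort(layout=layout, subjects=subjects, sigma_s=sigma_s, sigma_m=sigma_m)


def subject_beta_maps(cohort: Cohort, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (PU, SU) beta maps for one condition.

    Returns ``(maps, times)`` with maps shaped
    (n_subjects, 2, n_channels, n_times).
    """
    maps = []
    times = None
    for sub in cohort.subjects:
        ep = sub.epochs[condition]
        maps.append(regression.fit_betas(ep.data, ep.meta))
        times = ep.times
    return np.array(maps), times


def probe_epoch_stack(cohort: Cohort, condition: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Probe epochs for one condition, stacked as (ch, time, trials), with
    per-trial metadata (subject, trial_id)."""
    blocks, meta_rows = [], []
    for sub in cohort.subjects:
        ep = sub.epochs[condition]
        probe = ep.meta["is_probe"].to_numpy()
        blocks.append(ep.data[:, :, probe])
        for tid in ep.meta.loc[probe, "trial_id"]:
            meta_rows.append({"subject": sub.subject, "trial_id": tid})
    return np.concatenate(blocks, axis=2), pd.DataFrame(meta_rows)
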