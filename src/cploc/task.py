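"""Generative model of the change-point sound-localization task.

A trial is a sequence of sound locations (azimuth, degrees).  The generative
mean of the sounds is resampled from a bounded uniform distribution at random
change-points (per-sound hazard), each sound scatters around the current mean
with Gaussian experimental noise, and each sound has a fixed probability of
being the final "probe" sound whose location the listener must report.  Every
sequence is presented twice, once audio-only (A) and once audio-visual (AV),
with the two presentations never adjacent in the session order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "SoundSequence",
    "TrialPair",
    "Session",
    "generate_sequence",
    "generate_session",
    "sac_from_changes",
]


class ConfigurationError(ValueError):
    """Raised for invalid task or observer configuration."""


class ArrangementError(RuntimeError):
    """Raised when no valid non-adjacent session ordering exists."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the generative task.

    hazard
        Per-sound probability that the generative mean is resampled.
    probe_prob
        Per-sound probability that the sequence terminates (the sound is the
        probe).
    exp_noise_sd
        SD (degrees) of sound locations around the generative mean
        ("experimental noise").
    mean_low, mean_high
        Bounds (degrees) of the uniform distribution of generative means.
    max_len
        Hard cap on sequence length; the probe is forced at this length.
    """

    hazard: float = 1.0 / 6.0
    probe_prob: float = 1.0 / 12.0
    exp_noise_sd: float = 10.0
    mean_low: float = -60.0
    mean_high: float = 60.0
    max_len: int = 43

    def __post_init__(self) -> None:
        if not (0.0 < self.hazard < 1.0):
            raise ConfigurationError(f"hazard must be in (0, 1), got {self.hazard}")
        if not (0.0 < self.probe_prob <= 1.0):
            raise ConfigurationError(
                f"probe_prob must be in (0, 1], got {self.probe_prob}"
            )
        if self.exp_noise_sd <= 0:
            raise ConfigurationError("exp_noise_sd must be positive")
        if self.mean_low >= self.mean_high:
            raise ConfigurationError("mean_low must be below mean_high")
        if self.max_len < 1:
            raise ConfigurationError("max_len must be >= 1")


def sac_from_changes(is_change: np.ndarray) -> np.ndarray:
    """Stimulus-after-change-point level per sound.

    The change-point sound itself (first draw from the new mean) has SAC 1;
    the level then increments by one per sound until the next change-point.
    The first sound of a sequence is a change by construction.
    """
    is_change = np.asarray(is_change, dtype=bool)
    sac = np.empty(len(is_change), dtype=int)
    level = 0
    for i, ch in enumerate(is_change):
        level = 1 if (ch or i == 0) else level + 1
        sac[i] = level
    return sac


@dataclass
class SoundSequence:
    """One trial's sound locations with its generative bookkeeping."""

    locations: np.ndarray
    gen_means: np.ndarray
    is_change: np.ndarray
    sac: np.ndarray
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.gen_means = np.asarray(self.gen_means, dtype=float)
        self.is_change = np.asarray(self.is_change, dtype=bool)
        self.sac = np.asarray(self.sac, dtype=int)
        n = len(self.locations)
        if n < 1:
            raise ValueError("sequence must contain at least one sound")
        if not (len(self.gen_means) == len(self.is_change) == len(self.sac) == n):
            raise ValueError("sequence fields must have equal length")
        if not np.array_equal(self.sac, sac_from_changes(self.is_change)):
            raise ValueError("sac inconsistent with is_change flags")

    def __len__(self) -> int:
        return len(self.locations)

    @property
    def probe_index(self) -> int:
        """Index of the probe (always the final sound)."""
        return len(self.locations) - 1

    def to_frame(self, condition: str | None = None) -> pd.DataFrame:
        n = len(self)
        df = pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "sound_index": np.arange(n),
                "location_deg": self.locations,
                "gen_mean_deg": self.gen_means,
                "is_change": self.is_change,
                "sac": self.sac,
                "is_probe": np.arange(n) == self.probe_index,
            }
        )
        if condition is not None:
            df.insert(1, "condition", condition)
        return df


@dataclass
class TrialPair:
    """A sequence together with its two session positions (A and AV)."""

    sequence: SoundSequence
    a_position: int
    av_position: int

    def __post_init__(self) -> None:
        if abs(self.a_position - self.av_position) < 2:
            raise ArrangementError("paired presentations must not be adjacent")


@dataclass
class Session:
    """Ordered presentations of paired A/AV trials."""

    pairs: list[TrialPair]
    # (sequence, condition) in presentation order
    order: list[tuple[SoundSequence, str]] = field(repr=False, default_factory=list)

    @property
    def n_presentations(self) -> int:
        return len(self.order)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per presented sound."""
        frames = []
        for pos, (seq, cond) in enumerate(self.order):
            df = seq.to_frame(condition=cond)
            df.insert(0, "position", pos)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def generate_sequence(
    cfg: TaskConfig, rng: np.random.Generator, trial_id: int = 0
) -> SoundSequence:
    """Draw one sound sequence from the generative model.

    The first sound always samples a fresh generative mean (flagged as a
    change, SAC 1).  After each sound the sequence terminates with probability
    ``probe_prob``; a probe is forced at ``max_len``.
    """
    locs: list[float] = []
    means: list[float] = []
    changes: list[bool] = []
    mean = rng.uniform(cfg.mean_low, cfg.mean_high)
    while True:
        i = len(locs)
        if i == 0:
            change = True
        else:
            change = rng.random() < cfg.hazard
            if change:
                mean = rng.uniform(cfg.mean_low, cfg.mean_high)
        locs.append(mean + rng.normal(0.0, cfg.exp_noise_sd))
        means.append(mean)
        changes.append(change)
        if len(locs) >= cfg.max_len or rng.random() < cfg.probe_prob:
            break
    changes_arr = np.array(changes, dtype=bool)
    return SoundSequence(
        locations=np.array(locs),
        gen_means=np.array(means),
        is_change=changes_arr,
        sac=sac_from_changes(changes_arr),
        trial_id=trial_id,
    )


def _nonadjacent_order(n_pairs: int, rng: np.random.Generator, max_tries: int = 10000):
    """Shuffle 2*n_pairs presentation labels so no pair occupies adjacent slots."""
    labels = [(t, c) for t in range(n_pairs) for c in ("A", "AV")]
    for _ in range(max_tries):
        perm = rng.permutation(len(labels))
        ordered = [labels[i] for i in perm]
        ok = all(ordered[i][0] != ordered[i + 1][0] for i in range(len(ordered) - 1))
        if ok:
            return ordered
    raise ArrangementError(
        f"could not find a non-adjacent arrangement for n_pairs={n_pairs}"
    )


def generate_session(
    cfg: TaskConfig, n_pairs: int, rng: np.random.Generator
) -> Session:
    """Generate ``n_pairs`` sequences, each presented once as A and once as AV.

    The presentation order is a uniform shuffle conditioned on the two members
    of a pair never being adjacent; deterministic under a seeded ``rng``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_pairs == 1:
        # two presentations of the same trial are necessarily adjacent
        raise ArrangementError("n_pairs=1 admits no non-adjacent arrangement")
    seqs = [generate_sequence(cfg, rng, trial_id=t) for t in range(n_pairs)]
    ordered = _nonadjacent_order(n_pairs, rng)
    positions: dict[tuple[int, str], int] = {
        lab: pos for pos, lab in enumerate(ordered)
    }
    pairs = [
        TrialPair(
            sequence=seqs[t],
            a_position=positions[(t, "A")],
            av_position=positions[(t, "AV")],
        )
        for t in range(n_pairs)
    ]
    order = [(seqs[t], c) for (t, c) in ordered]
    return Session(pairs=pairs, order=order)
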