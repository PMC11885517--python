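"""Grid-based Bayesian observer for the change-point localization task.

The observer tracks a posterior over the current generative mean location on
an explicit grid of azimuth values.  Before each sound the belief is mixed
with the bounded-uniform reset distribution according to the assumed hazard
rate (the "full prior").  Each observed location multiplies the prior by a
Gaussian likelihood whose SD combines the assumed experimental noise with the
observer's own sensory noise.

Two per-sound latent variables are extracted:

* prior uncertainty (PU): the SD, in degrees, of the belief carried into the
  current sound (by default the preceding posterior, before hazard mixing);
* surprisal (SU): the negative natural log of the density of the full prior,
  evaluated at the (noisy) observation.  How much observation noise the
  evaluated density is convolved with is a policy choice, see
  :class:`ObserverParams.surprisal_obs_noise`.

At the probe the observer reports the mean of its posterior over the probe
sound's true location, together with a central credible interval — the model
analog of the participants' response and marked 80% uncertainty range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import ConfigurationError, SoundSequence

__all__ = [
    "ObserverParams",
    "PosteriorGrid",
    "LatentTrace",
    "init_posterior",
    "apply_hazard",
    "surprisal",
    "bayes_update",
    "prior_uncertainty",
    "location_posterior",
    "report",
    "run_observer",
    "run_session",
]

_DENSITY_FLOOR = 1e-300

#: recognised surprisal observation-noise policies
SU_NOISE_POLICIES = ("sensory", "sensory+experimental", "none")


@dataclass(frozen=True)
class ObserverParams:
    """Observer configuration.

    sensory_noise_sd
        SD (degrees) of the observer's internal noise on each observed
        location; the free parameter fitted per participant for the A
        condition and fixed at 1 degree for AV.
    assumed_hazard, assumed_exp_noise_sd, assumed_mean_low/high
        The observer's model of the generative process.  A "near-optimal"
        observer assumes the true task parameters.
    grid_low, grid_high, grid_step
        Discretization of the belief over the mean (degrees).
    probe_sensory_noise_sd
        Sensory noise applied to the probe sound.  The probe is auditory-only
        in both conditions, so this defaults to the auditory sensory noise
        (i.e. ``sensory_noise_sd`` unless overridden).
    surprisal_obs_noise
        Which observation noise the full-prior density is convolved with
        before evaluating surprisal: ``"sensory"`` (default), the sensory
        noise only; ``"sensory+experimental"``, the full predictive noise;
        ``"none"``, the raw prior density over the mean.
    """

    sensory_noise_sd: float = 10.0
    assumed_hazard: float = 1.0 / 6.0
    assumed_exp_noise_sd: float = 10.0
    assumed_mean_low: float = -60.0
    assumed_mean_high: float = 60.0
    grid_low: float = -90.0
    grid_high: float = 90.0
    grid_step: float = 0.5
    probe_sensory_noise_sd: float | None = None
    surprisal_obs_noise: str = "sensory"
    pu_after_hazard: bool = False

    def __post_init__(self) -> None:
        if self.sensory_noise_sd < 0 or self.assumed_exp_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if self.sensory_noise_sd + self.assumed_exp_noise_sd <= 0:
            raise ConfigurationError("total observation noise must be positive")
        if not (0.0 <= self.assumed_hazard <= 1.0):
            raise ConfigurationError("assumed_hazard must be in [0, 1]")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be positive")
        if self.grid_low > self.assumed_mean_low or self.grid_high < self.assumed_mean_high:
            raise ConfigurationError("grid must span the assumed mean bounds")
        if self.assumed_mean_low >= self.assumed_mean_high:
            raise ConfigurationError("assumed mean bounds must be ordered")
        if self.surprisal_obs_noise not in SU_NOISE_POLICIES:
            raise ConfigurationError(
                f"surprisal_obs_noise must be one of {SU_NOISE_POLICIES}"
            )

    @property
    def probe_noise_sd(self) -> float:
        return (
            self.sensory_noise_sd
            if self.probe_sensory_noise_sd is None
            else self.probe_sensory_noise_sd
        )

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_low + self.grid_step * np.arange(n)


@dataclass
class PosteriorGrid:
    """Discrete probability distribution over a regular grid of degrees."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.support.ndim != 1 or self.support.shape != self.mass.shape:
            raise ValueError("support and mass must be matching 1-D arrays")
        steps = np.diff(self.support)
        if len(steps) and not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("support must be regularly spaced")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-10:
            raise ValueError("mass must sum to 1")

    @property
    def step(self) -> float:
        return float(self.support[1] - self.support[0])

    def mean(self) -> float:
        return float(self.mass @ self.support)

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(self.mass @ (self.support - m) ** 2))


def init_posterior(params: ObserverParams) -> PosteriorGrid:
    """Uniform belief over the assumed mean bounds, zero outside."""
    g = params.grid()
    inside = (g >= params.assumed_mean_low - 1e-9) & (
        g <= params.assumed_mean_high + 1e-9
    )
    if not inside.any():
        raise ConfigurationError("grid does not intersect the assumed mean bounds")
    mass = inside / inside.sum()
    return PosteriorGrid(support=g, mass=mass)


def apply_hazard(post: PosteriorGrid, params: ObserverParams) -> PosteriorGrid:
    """Hazard mixture: ``(1 - H) * posterior + H * uniform`` (the full prior)."""
    h = params.assumed_hazard
    uniform = init_posterior(params).mass
    return PosteriorGrid(post.support, (1.0 - h) * post.mass + h * uniform)


def _gauss(x: np.ndarray, sd: float) -> np.ndarray:
    return np.exp(-0.5 * (x / sd) ** 2) / (np.sqrt(2.0 * np.pi) * sd)


def _su_conv_sd(params: ObserverParams, sensory_sd: float) -> float:
    if params.surprisal_obs_noise == "sensory":
        return sensory_sd
    if params.surprisal_obs_noise == "sensory+experimental":
        return float(np.hypot(sensory_sd, params.assumed_exp_noise_sd))
    return 0.0


def _prior_density_at(
    prior: PosteriorGrid, x: float, conv_sd: float
) -> float:
    """Density of ``prior`` convolved with ``N(0, conv_sd^2)`` at ``x``."""
    if conv_sd > 0:
        dens = float(prior.mass @ _gauss(x - prior.support, conv_sd))
    else:
        # raw grid density (mass per degree), linearly interpolated
        if x < prior.support[0] or x > prior.support[-1]:
            warnings.warn(
                "observation outside grid support; clamped for density evaluation",
                RuntimeWarning,
                stacklevel=3,
            )
            x = float(np.clip(x, prior.support[0], prior.support[-1]))
        dens = float(np.interp(x, prior.support, prior.mass / prior.step))
    return max(dens, _DENSITY_FLOOR)


def surprisal(
    prior: PosteriorGrid,
    x: float,
    params: ObserverParams,
    sensory_sd: float | None = None,
) -> float:
    """Negative natural log (nats) of the full-prior density at observation x.

    The prior over the generative mean is convolved with Gaussian observation
    noise per ``params.surprisal_obs_noise`` before evaluation; densities are
    floored at 1e-300 so the result is always finite.
    """
    if sensory_sd is None:
        sensory_sd = params.sensory_noise_sd
    conv_sd = _su_conv_sd(params, sensory_sd)
    return -float(np.log(_prior_density_at(prior, x, conv_sd)))


def bayes_update(
    prior: PosteriorGrid,
    x: float,
    params: ObserverParams,
    sensory_sd: float | None = None,
) -> PosteriorGrid:
    """Posterior over the mean after observing x.

    Likelihood is Gaussian with SD ``sqrt(exp_noise^2 + sensory_noise^2)``.
    """
    if sensory_sd is None:
        sensory_sd = params.sensory_noise_sd
    tot = float(np.hypot(params.assumed_exp_noise_sd, sensory_sd))
    w = prior.mass * _gauss(x - prior.support, tot)
    s = w.sum()
    if s <= 0 or not np.isfinite(s):
        raise FloatingPointError(
            f"degenerate posterior: observation x={x:.2f} has zero likelihood mass"
        )
    return PosteriorGrid(prior.support, w / s)


def prior_uncertainty(post: PosteriorGrid) -> float:
    """SD (degrees) of a grid belief."""
    return post.sd()


def location_posterior(
    prior: PosteriorGrid,
    x: float,
    params: ObserverParams,
    sensory_sd: float | None = None,
) -> PosteriorGrid:
    """Posterior over the *sound location* of the current observation.

    The generative chain is mean -> location (experimental noise) ->
    observation (sensory noise).  Marginalizing the mean gives a Gaussian
    mixture over the location, evaluated on the same grid.  This is the belief
    participants report from at the probe.
    """
    if sensory_sd is None:
        sensory_sd = params.sensory_noise_sd
    se2 = params.assumed_exp_noise_sd**2
    ss2 = sensory_sd**2
    g = prior.support
    post_mu = bayes_update(prior, x, params, sensory_sd)
    if ss2 == 0:
        # exact observation: belief over the location is a point mass at x
        mass = np.zeros_like(g)
        mass[int(np.argmin(np.abs(g - x)))] = 1.0
        return PosteriorGrid(g, mass)
    rho = se2 / (se2 + ss2)
    comp_means = prior.support + rho * (x - prior.support)
    comp_sd = float(np.sqrt(rho * ss2))
    dens = _gauss(g[:, None] - comp_means[None, :], comp_sd) @ post_mu.mass
    s = dens.sum()
    if s <= 0:
        raise FloatingPointError("degenerate location posterior")
    return PosteriorGrid(g, dens / s)


def report(post: PosteriorGrid, level: float = 0.8) -> tuple[float, float, float]:
    """Point estimate (posterior mean) and central credible interval.

    Quantiles are linearly interpolated on the grid CDF (mass treated as
    located at cell centers).
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    point = post.mean()
    cdf = np.cumsum(post.mass) - 0.5 * post.mass
    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    lo = float(np.interp(lo_q, cdf, post.support))
    hi = float(np.interp(hi_q, cdf, post.support))
    return point, lo, hi


@dataclass
class LatentTrace:
    """Per-sound observer latents for one presented sequence."""

    trial_id: int
    condition: str
    pu: np.ndarray
    su: np.ndarray
    observation: np.ndarray
    sac: np.ndarray
    is_change: np.ndarray
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.8
    posteriors: list[PosteriorGrid] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.pu)

    @property
    def probe_index(self) -> int:
        return len(self.pu) - 1

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        idx = np.arange(n)
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "condition": self.condition,
                "sound_index": idx,
                "pu": self.pu,
                "su": self.su,
                "observation": self.observation,
                "sac": self.sac,
                "is_change": self.is_change,
                "is_first": idx == 0,
                "is_probe": idx == self.probe_index,
            }
        )


def run_observer(
    seq: SoundSequence,
    params: ObserverParams,
    rng: np.random.Generator | None = None,
    noisefree: bool = False,
    condition: str = "A",
    ci_level: float = 0.8,
    keep_posteriors: bool = False,
) -> LatentTrace:
    """Run the observer over one sequence, returning per-sound PU and SU.

    For each sound t: PU_t is the SD of the belief carried into the sound
    (default: the preceding posterior, before hazard mixing); the full prior
    is the hazard mixture; the observation is the true location plus sensory
    noise (exact in ``noisefree`` mode); SU_t evaluates the full prior at the
    observation; the posterior is the Bayes update.  At the probe the point
    estimate and the central ``ci_level`` interval of the posterior over the
    probe's location are recorded.
    """
    if rng is None and not noisefree:
        raise ValueError("rng is required unless noisefree=True")
    n = len(seq)
    pu = np.empty(n)
    su = np.empty(n)
    obs = np.empty(n)
    post = init_posterior(params)
    posteriors: list[PosteriorGrid] = []
    estimate = ci_lo = ci_hi = np.nan
    for t in range(n):
        full_prior = apply_hazard(post, params)
        pu[t] = (full_prior if params.pu_after_hazard else post).sd()
        sens_sd = params.probe_noise_sd if t == seq.probe_index else params.sensory_noise_sd
        x = float(seq.locations[t])
        if not noisefree and sens_sd > 0:
            x += float(rng.normal(0.0, sens_sd))
        obs[t] = x
        su[t] = surprisal(full_prior, x, params, sens_sd)
        if t == seq.probe_index:
            loc_post = location_posterior(full_prior, x, params, sens_sd)
            estimate, ci_lo, ci_hi = report(loc_post, ci_level)
        post = bayes_update(full_prior, x, params, sens_sd)
        if keep_posteriors:
            posteriors.append(post)
    return LatentTrace(
        trial_id=seq.trial_id,
        condition=condition,
        pu=pu,
        su=su,
        observation=obs,
        sac=seq.sac.copy(),
        is_change=seq.is_change.copy(),
        estimate=float(estimate),
        ci_low=float(ci_lo),
        ci_high=float(ci_hi),
        ci_level=ci_level,
        posteriors=posteriors if keep_posteriors else None,
    )


def run_session(
    session,
    params_by_condition: dict[str, ObserverParams],
    rng: np.random.Generator | None = None,
    noisefree: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the observer over every presentation of a session.

    Returns ``(latents, trials)``: a per-sound tidy table of PU/SU and a
    per-presentation table with the probe estimate and credible interval.
    """
    latent_frames = []
    trial_rows = []
    for seq, cond in session.order:
        trace = run_observer(
            seq, params_by_condition[cond], rng=rng, noisefree=noisefree,
            condition=cond,
        )
        latent_frames.append(trace.to_frame())
        trial_rows.append(
            {
                "trial_id": seq.trial_id,
                "condition": cond,
                "n_sounds": len(seq),
                "probe_sac": int(seq.sac[seq.probe_index]),
                "probe_location": float(seq.locations[seq.probe_index]),
                "prev_location": float(seq.locations[-2]) if len(seq) > 1 else np.nan,
                "estimate": trace.estimate,
                "ci_low": trace.ci_low,
                "ci_high": trace.ci_high,
            }
        )
    return pd.concat(latent_frames, ignore_index=True), pd.DataFrame(trial_rows)


def av_params(a_params: ObserverParams, av_sensory_sd: float = 1.0) -> ObserverParams:
    """AV-condition parameters: sensory noise fixed (1 degree by default), the
    auditory-only probe keeps the A-condition sensory noise."""
    return replace(
        a_params,
        sensory_noise_sd=av_sensory_sd,
        probe_sensory_noise_sd=a_params.probe_noise_sd,
    )
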