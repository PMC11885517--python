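"""Maximum-likelihood fitting of observer parameters to localization responses.

The response model is: response = posterior-mean estimate of the probe
location + Gaussian motor noise.  The marginal likelihood of a response
integrates over the unobserved sensory noise of the whole sequence; that
integral is approximated by common-random-number Monte Carlo (the same
standard-normal draws are reused at every candidate sensory noise, so the
likelihood surface is smooth in the parameters and deterministic given the
seed).

Free parameters: the sensory noise SD (degrees) and the motor/response noise
SD (degrees).  The optimizer is a coarse log-spaced grid over the sensory
noise with the motor noise profiled out by bounded 1-D search, followed by
bounded scalar refinement of the sensory noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .observer import ObserverParams, init_posterior
from .task import SoundSequence

__all__ = [
    "FitSpec",
    "FitResult",
    "probe_estimates",
    "response_loglik",
    "fit_observer",
    "simulate_responses",
]


@dataclass(frozen=True)
class FitSpec:
    """Search strategy for the observer fit."""

    sensory_bounds: tuple[float, float] = (0.5, 40.0)
    response_bounds: tuple[float, float] = (0.1, 30.0)
    n_sensory_grid: int = 12
    n_response_grid: int = 10
    n_noise_draws: int = 32
    refine_xtol: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.sensory_bounds, self.response_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive and ordered")
        if self.n_noise_draws < 1:
            raise ValueError("n_noise_draws must be >= 1")


@dataclass
class FitResult:
    sensory_noise_sd: float
    response_noise_sd: float
    loglik: float
    n_evals: int
    converged: bool
    grid_logliks: np.ndarray | None = None
    degenerate: bool = False


def _draw_noise(
    sequences: list[SoundSequence], n_draws: int, seed: int
) -> list[np.ndarray]:
    """Standard-normal draws, one (len(seq), n_draws) block per trial."""
    rng = np.random.default_rng(seed)
    return [rng.standard_normal((len(s), n_draws)) for s in sequences]


def probe_estimates(
    sequences: list[SoundSequence],
    params: ObserverParams,
    sensory_sd: float,
    noise: list[np.ndarray],
) -> np.ndarray:
    """Posterior-mean probe estimates, (n_trials, n_draws).

    Vectorized over noise draws: the grid belief is carried as a
    (n_draws, n_grid) matrix through hazard mixing and Bayes updates.  The
    posterior mean over the probe *location* has the closed form
    ``rho * x + (1 - rho) * E[mean | x]`` with
    ``rho = exp_noise^2 / (exp_noise^2 + sensory^2)``, so no extra grid
    convolution is needed in the fitting loop.
    """
    g = params.grid()
    uniform = init_posterior(params).mass
    h = params.assumed_hazard
    se2 = params.assumed_exp_noise_sd**2
    ss2 = sensory_sd**2
    tot2 = se2 + ss2
    rho = se2 / tot2 if tot2 > 0 else 0.0
    out = np.empty((len(sequences), noise[0].shape[1]))
    for k, (seq, z) in enumerate(zip(sequences, noise)):
        post = np.tile(uniform, (z.shape[1], 1))  # (draws, grid)
        for t in range(len(seq)):
            prior = (1.0 - h) * post + h * uniform
            x = seq.locations[t] + sensory_sd * z[t]  # (draws,)
            w = prior * np.exp(-0.5 * (x[:, None] - g[None, :]) ** 2 / tot2)
            s = w.sum(axis=1, keepdims=True)
            post = w / s
            if t == len(seq) - 1:
                post_mean = post @ g
                out[k] = rho * x + (1.0 - rho) * post_mean
    return out


def response_loglik(
    responses: np.ndarray,
    estimates: np.ndarray,
    response_noise_sd: float,
) -> float:
    """Sum over trials of ln mean_j N(response; estimate_j, sigma_m^2)."""
    responses = np.asarray(responses, float)
    if responses.shape[0] != estimates.shape[0]:
        raise ValueError("responses and estimates refer to different trial sets")
    sm = response_noise_sd
    ll = (
        -0.5 * ((responses[:, None] - estimates) / sm) ** 2
        - np.log(np.sqrt(2 * np.pi) * sm)
    )
    return float(np.sum(logsumexp(ll, axis=1) - np.log(estimates.shape[1])))


def _profile_response_sd(
    responses: np.ndarray, estimates: np.ndarray, bounds: tuple[float, float]
) -> tuple[float, float]:
    res = minimize_scalar(
        lambda sm: -response_loglik(responses, estimates, sm),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(res.x), float(-res.fun)


def fit_observer(
    responses: np.ndarray,
    sequences: list[SoundSequence],
    spec: FitSpec,
    base_params: ObserverParams | None = None,
) -> FitResult:
    """Fit (sensory noise, response noise) by maximum likelihood.

    Coarse log-spaced grid over the sensory noise with the response noise
    profiled out, then bounded scalar refinement of the sensory noise around
    the grid optimum.  Deterministic for a fixed ``spec.seed``.
    """
    responses = np.asarray(responses, float)
    if len(responses) != len(sequences):
        raise ValueError("one response per sequence is required")
    if base_params is None:
        base_params = ObserverParams()
    if np.ptp(responses) == 0:
        import warnings

        warnings.warn("all responses identical; fit is degenerate", RuntimeWarning)
    noise = _draw_noise(sequences, spec.n_noise_draws, spec.seed)

    n_evals = 0

    def profiled(sig_s: float) -> tuple[float, float]:
        nonlocal n_evals
        n_evals += 1
        est = probe_estimates(sequences, base_params, sig_s, noise)
        return _profile_response_sd(responses, est, spec.response_bounds)

    sens_grid = np.geomspace(*spec.sensory_bounds, spec.n_sensory_grid)
    grid_ll = np.empty(len(sens_grid))
    grid_sm = np.empty(len(sens_grid))
    for i, s in enumerate(sens_grid):
        grid_sm[i], grid_ll[i] = profiled(s)
    best = int(np.argmax(grid_ll))
    lo = sens_grid[max(best - 1, 0)]
    hi = sens_grid[min(best + 1, len(sens_grid) - 1)]
    if lo == hi:  # optimum at a bound
        sig_s, (sig_m, ll) = float(sens_grid[best]), (grid_sm[best], grid_ll[best])
        converged = True
    else:
        res = minimize_scalar(
            lambda s: -profiled(s)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": spec.refine_xtol},
        )
        sig_s = float(res.x)
        sig_m, ll = profiled(sig_s)
        converged = bool(res.success)
        if ll < grid_ll[best]:  # keep the grid optimum if refinement regressed
            sig_s, sig_m, ll = float(sens_grid[best]), grid_sm[best], grid_ll[best]
    return FitResult(
        sensory_noise_sd=sig_s,
        response_noise_sd=float(sig_m),
        loglik=float(ll),
        n_evals=n_evals,
        converged=converged,
        grid_logliks=grid_ll,
        degenerate=bool(np.ptp(responses) == 0),
    )


def simulate_responses(
    sequences: list[SoundSequence],
    params: ObserverParams,
    response_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate observer responses (estimate + motor noise) for recovery tests."""
    noise = [rng.standard_normal((len(s), 1)) for s in sequences]
    est = probe_estimates(sequences, params, params.sensory_noise_sd, noise)[:, 0]
    return est + rng.normal(0.0, response_noise_sd, size=len(sequences))
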