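"""Bayesian observer: grid inference oracles, latent definitions, reports."""

import numpy as np
import pytest
from scipy import stats

from cploc import observer, task
from cploc.observer import (
    ObserverParams,
    PosteriorGrid,
    apply_hazard,
    bayes_update,
    init_posterior,
    location_posterior,
    prior_uncertainty,
    report,
    run_observer,
    surprisal,
)


def gaussian_grid(sd: float, step: float = 0.25, span: float = 90.0, mean: float = 0.0):
    g = np.arange(-span, span + step / 2, step)
    m = np.exp(-0.5 * ((g - mean) / sd) ** 2)
    return PosteriorGrid(g, m / m.sum())


def point_mass(at: float = 0.0, step: float = 0.5, span: float = 90.0):
    g = np.arange(-span, span + step / 2, step)
    m = np.zeros_like(g)
    m[int(np.argmin(np.abs(g - at)))] = 1.0
    return PosteriorGrid(g, m)


class TestInitAndHazard:
    def test_uniform_init(self):
        p = ObserverParams(grid_step=1.0)
        post = init_posterior(p)
        inside = post.mass > 0
        assert inside.sum() == 121  # -60..60 at 1 degree
        assert np.allclose(post.mass[inside], post.mass[inside][0])
        assert post.mass.sum() == pytest.approx(1.0, abs=1e-12)
        # uniform on a 120-degree range: SD ~ 120/sqrt(12)
        assert post.sd() == pytest.approx(120.0 / np.sqrt(12.0), rel=0.015)

    def test_hazard_identities(self):
        p0 = ObserverParams(assumed_hazard=0.0)
        p1 = ObserverParams(assumed_hazard=1.0)
        g = gaussian_grid(5.0, step=0.5)
        assert np.allclose(apply_hazard(g, p0).mass, g.mass)
        assert np.allclose(apply_hazard(g, p1).mass, init_posterior(p1).mass)

    @pytest.mark.parametrize("h", [0.1, 1.0 / 6.0, 0.5, 0.9])
    def test_hazard_preserves_normalization(self, h):
        p = ObserverParams(assumed_hazard=h)
        g = gaussian_grid(8.0, step=0.5)
        assert apply_hazard(g, p).mass.sum() == pytest.approx(1.0, abs=1e-12)


class TestSurprisal:
    def test_point_mass_gaussian_oracle(self):
        """Point-mass prior with total observation SD 10: closed-form density
        gives SU(0) = 0.5*ln(2*pi*100) ~ 3.2215."""
        p = ObserverParams(sensory_noise_sd=10.0, surprisal_obs_noise="sensory")
        su = surprisal(point_mass(0.0), 0.0, p)
        assert su == pytest.approx(0.5 * np.log(2 * np.pi * 100.0), rel=1e-6)

    def test_point_mass_full_predictive_policy(self):
        """Same oracle through the exp+sensory policy: total SD sqrt(36+64)=10."""
        p = ObserverParams(
            sensory_noise_sd=8.0,
            assumed_exp_noise_sd=6.0,
            surprisal_obs_noise="sensory+experimental",
        )
        su = surprisal(point_mass(0.0), 0.0, p)
        assert su == pytest.approx(0.5 * np.log(2 * np.pi * 100.0), rel=1e-6)

    def test_uniform_prior_log_width(self):
        """Uniform prior over 120 degrees, negligible observation noise:
        numerical integration gives -ln(1/120) for interior x."""
        p = ObserverParams(sensory_noise_sd=0.5, grid_step=0.25)
        prior = init_posterior(p)
        for x in (-30.0, 0.0, 42.0):
            assert surprisal(prior, x, p) == pytest.approx(np.log(120.0), rel=1e-3)

    def test_monotone_in_distance_from_mode(self):
        p = ObserverParams(sensory_noise_sd=5.0)
        prior = gaussian_grid(10.0, step=0.5)
        xs = [0.0, 5.0, 12.0, 20.0, 40.0]
        sus = [surprisal(prior, x, p) for x in xs]
        assert np.all(np.diff(sus) > 0)

    def test_floor_keeps_su_finite(self):
        p = ObserverParams(sensory_noise_sd=0.5, surprisal_obs_noise="sensory")
        su = surprisal(point_mass(0.0), 80.0, p)
        assert np.isfinite(su)


class TestBayesUpdate:
    def test_conjugate_gaussian_oracle(self):
        """With no hazard, the grid recursion must match closed-form Gaussian
        updating: posterior SD = (1/s0^2 + 1/sigma^2)^(-1/2)."""
        p = ObserverParams(
            sensory_noise_sd=0.0, assumed_exp_noise_sd=10.0, assumed_hazard=0.0,
            grid_step=0.25,
        )
        prior = gaussian_grid(10.0, step=0.25)
        post = bayes_update(prior, 5.0, p)
        expect_sd = (1 / 100 + 1 / 100) ** -0.5
        expect_mean = 2.5  # equal precision: midpoint of prior mean and x
        assert post.sd() == pytest.approx(expect_sd, rel=0.01)
        assert post.mean() == pytest.approx(expect_mean, abs=0.05)

    def test_conjugate_sequence_oracle(self):
        """20 observations with H=0 track the conjugate recursion within 1%."""
        rng = np.random.default_rng(0)
        p = ObserverParams(
            sensory_noise_sd=0.0, assumed_exp_noise_sd=10.0, assumed_hazard=0.0,
            grid_step=0.25,
        )
        post = gaussian_grid(30.0, step=0.25)
        mu, v = 0.0, 900.0
        for _ in range(20):
            x = rng.normal(8.0, 10.0)
            post = bayes_update(post, x, p)
            k = v / (v + 100.0)
            mu, v = mu + k * (x - mu), v * 100.0 / (v + 100.0)
            assert post.mean() == pytest.approx(mu, abs=max(0.01 * abs(mu), 0.05))
            assert post.sd() == pytest.approx(np.sqrt(v), rel=0.01)

    def test_posterior_sd_decreases_with_repeats(self):
        p = ObserverParams(sensory_noise_sd=0.0, assumed_hazard=0.0)
        post = init_posterior(p)
        sds = []
        for _ in range(5):
            post = bayes_update(post, 10.0, p)
            sds.append(post.sd())
        assert np.all(np.diff(sds) < 0)

    def test_normalized_output(self):
        p = ObserverParams()
        post = bayes_update(init_posterior(p), 20.0, p)
        assert post.mass.sum() == pytest.approx(1.0, abs=1e-12)


class TestPriorUncertainty:
    def test_point_mass_zero(self):
        assert prior_uncertainty(point_mass(10.0)) == pytest.approx(0.0, abs=1e-9)

    def test_discretized_gaussian(self):
        assert prior_uncertainty(gaussian_grid(10.0, step=0.5)) == pytest.approx(
            10.0, abs=0.1
        )


class TestReport:
    def test_symmetric_posterior_centered(self):
        point, lo, hi = report(gaussian_grid(10.0, step=0.25), 0.8)
        assert point == pytest.approx(0.0, abs=1e-9)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_gaussian_quantile_oracle(self):
        """Central 80% interval of a Gaussian: width 2 * 1.2816 * sd."""
        _, lo, hi = report(gaussian_grid(10.0, step=0.25), 0.8)
        expect = 2.0 * stats.norm.ppf(0.9) * 10.0
        assert hi - lo == pytest.approx(expect, rel=0.01)

    def test_level_to_one_reaches_support(self):
        # bounded-uniform belief: the near-total interval reaches the bounds
        g = init_posterior(ObserverParams())
        _, lo, hi = report(g, 0.9999)
        assert lo < -59 and hi > 59

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            report(gaussian_grid(5.0), 1.2)


class TestRunObserver:
    def test_first_sound_pu_is_uniform_sd(self, a_params):
        seq = task.SoundSequence([5.0], [4.0], [True], [1])
        tr = run_observer(seq, a_params, noisefree=True)
        assert tr.pu[0] == pytest.approx(init_posterior(a_params).sd(), rel=1e-9)

    def test_av_probe_uses_auditory_noise(self, a_params):
        av = observer.av_params(a_params, 1.0)
        assert av.sensory_noise_sd == 1.0
        assert av.probe_noise_sd == a_params.sensory_noise_sd

    def test_noisefree_is_deterministic(self, default_cfg, a_params):
        seq = task.generate_sequence(default_cfg, np.random.default_rng(1))
        t1 = run_observer(seq, a_params, noisefree=True)
        t2 = run_observer(seq, a_params, noisefree=True)
        assert np.array_equal(t1.pu, t2.pu) and np.array_equal(t1.su, t2.su)

    def test_grid_refinement_convergence(self, default_cfg):
        """Halving the grid step changes PU and SU by < 0.5%."""
        rng = np.random.default_rng(21)
        seqs = [task.generate_sequence(default_cfg, rng) for _ in range(5)]
        coarse = observer.ObserverParams(sensory_noise_sd=10.0, grid_step=0.5)
        fine = observer.ObserverParams(sensory_noise_sd=10.0, grid_step=0.25)
        for seq in seqs:
            tc = run_observer(seq, coarse, noisefree=True)
            tf = run_observer(seq, fine, noisefree=True)
            assert np.allclose(tc.pu, tf.pu, rtol=5e-3, atol=0.03)
            assert np.allclose(tc.su, tf.su, rtol=5e-3, atol=0.03)

    def test_location_posterior_mean_closed_form(self, a_params):
        """Posterior mean over the probe location equals
        rho*x + (1-rho)*posterior-mean-over-mu."""
        prior = gaussian_grid(8.0, step=0.25)
        x, ss = 12.0, 10.0
        lp = location_posterior(prior, x, a_params, ss)
        mu_post = bayes_update(prior, x, a_params, ss)
        rho = 100.0 / (100.0 + ss**2)
        assert lp.mean() == pytest.approx(
            rho * x + (1 - rho) * mu_post.mean(), abs=0.02
        )
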