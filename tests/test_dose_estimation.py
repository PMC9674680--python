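"""Tests for time priors, inverse dose, and the two dose-posterior routes."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad, trapezoid

from biodose import (
    DosePosterior,
    LaplacePosterior,
    PatientSummary,
    TimePrior,
    dose_given_t,
    dose_posterior_grid,
    sample_time_prior,
    simulate_dose_posterior,
    summarize_posterior,
)
from biodose.dose_estimation import ratio_of_normals_pdf


class TestTimePrior:
    def test_uniform_moments(self):
        draws = sample_time_prior(TimePrior("uniform", 3, 5), 100000, seed=1)
        assert np.all((draws > 3) & (draws < 5))
        assert draws.mean() == pytest.approx(4.0, abs=0.01)

    def test_scaled_beta_sd(self):
        """Beta(100,100) on (0.25, 0.75): SD = 0.5*sqrt(ab/((a+b)^2(a+b+1)))."""
        prior = TimePrior("beta", 0.25, 0.75, 100, 100)
        draws = sample_time_prior(prior, 200000, seed=2)
        expected_sd = 0.5 * np.sqrt(100 * 100 / (200**2 * 201))
        assert draws.std() == pytest.approx(expected_sd, rel=0.02)
        assert np.all((draws > 0.25) & (draws < 0.75))

    def test_beta_5_5_symmetric(self):
        draws = sample_time_prior(TimePrior("beta", 3, 5, 5, 5), 100000, seed=3)
        assert np.all((draws > 3) & (draws < 5))
        assert draws.mean() == pytest.approx(4.0, abs=0.01)

    def test_pdf_normalizes(self):
        for prior in (TimePrior("uniform", 3, 5), TimePrior("beta", 3, 5, 5, 5)):
            mass, _ = quad(prior.pdf, prior.t_lo, prior.t_hi)
            assert mass == pytest.approx(1.0, abs=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            TimePrior("uniform", 5, 3)
        with pytest.raises(ValueError):
            TimePrior("beta", 3, 5, -1, 5)
        with pytest.raises(ValueError):
            TimePrior("triangular", 3, 5)


class TestDoseGivenT:
    @pytest.mark.parametrize(
        "mu, alpha, beta, expected",
        [(1.0, 1.0, 2.0, 0.0), (5.0, 1.0, 2.0, 2.0), (0.5, 1.0, 2.0, -0.25)],
    )
    def test_values(self, mu, alpha, beta, expected):
        assert dose_given_t(mu, alpha, beta) == pytest.approx(expected)

    def test_zero_slope_raises(self):
        with pytest.raises(ZeroDivisionError):
            dose_given_t(1.0, 0.5, 0.0)


class TestPatientSummary:
    def test_validation(self):
        with pytest.raises(ValueError):
            PatientSummary(-1.0, 0.5, 100)
        with pytest.raises(ValueError):
            PatientSummary(1.0, 0.5, 1)

    def test_from_se_round_trip(self):
        p = PatientSummary.from_se(4.072, 0.230, 500)
        assert p.se == pytest.approx(0.230, rel=1e-12)
        assert p.s == pytest.approx(0.230 * np.sqrt(500), rel=1e-12)


class TestRatioDensity:
    def test_constant_denominator_limit(self):
        """var(beta) -> 0: density collapses to the obvious normal."""
        mu1, s1, mu2 = 0.9, 0.3, 1.5
        r = np.linspace(-1, 2.5, 301)
        nearly = ratio_of_normals_pdf(r, mu1, s1, mu2, 1e-9, 0.0)
        exact = stats.norm.pdf(r, mu1 / mu2, s1 / mu2)
        np.testing.assert_allclose(nearly, exact, rtol=1e-4, atol=1e-10)
        degenerate = ratio_of_normals_pdf(r, mu1, s1, mu2, 0.0, 0.0)
        np.testing.assert_allclose(degenerate, exact, rtol=1e-12)

    def test_matches_numerical_integration(self):
        """Closed form vs direct integration of |b| f(rb, b) db (oracle)."""
        mu1, s1, mu2, s2, rho = 0.8, 0.3, 1.6, 0.08, -0.45
        cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
        bvn = stats.multivariate_normal([mu1, mu2], cov)
        for r in (-0.5, 0.0, 0.4, 0.9, 2.0):
            oracle, _ = quad(lambda b: abs(b) * bvn.pdf([r * b, b]),
                             mu2 - 10 * s2, mu2 + 10 * s2, limit=200)
            assert ratio_of_normals_pdf(np.array([r]), mu1, s1, mu2, s2, rho)[0] == pytest.approx(
                oracle, rel=1e-8
            )

    def test_integrates_to_one(self):
        r = np.linspace(-4, 6, 4001)
        pdf = ratio_of_normals_pdf(r, 0.7, 0.25, 1.4, 0.1, 0.3)
        assert trapezoid(pdf, r) == pytest.approx(1.0, abs=1e-4)


class TestSimulation:
    def test_degenerate_inputs_give_point_mass(self, k2_laplace):
        """Zero posterior covariance, s=0, near-point time prior: constant dose."""
        frozen = LaplacePosterior(
            mode=k2_laplace.mode, cov=np.zeros_like(k2_laplace.cov), spec=k2_laplace.spec,
            parametrization=k2_laplace.parametrization,
            log_posterior_at_mode=k2_laplace.log_posterior_at_mode, params=k2_laplace.params,
        )
        patient = PatientSummary(x_bar=2.0, s=0.0, n=500)
        prior = TimePrior("uniform", 4.0 - 1e-9, 4.0 + 1e-9)
        post = simulate_dose_posterior(frozen, patient, prior, m=10000, seed=0)
        from biodose import alpha_beta_point

        alpha, beta = alpha_beta_point(k2_laplace.params, 4.0)
        np.testing.assert_allclose(post.draws, (2.0 - alpha) / beta, rtol=1e-6)
        s = post.summarize()
        assert s.ci_hi - s.ci_lo == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_given_seed(self, k2_laplace):
        patient = PatientSummary(4.0, 2.0, 500)
        prior = TimePrior("uniform", 3, 5)
        d1 = simulate_dose_posterior(k2_laplace, patient, prior, m=10000, seed=5).draws
        d2 = simulate_dose_posterior(k2_laplace, patient, prior, m=10000, seed=5).draws
        np.testing.assert_array_equal(d1, d2)

    def test_minimum_draws_enforced(self, k2_laplace):
        with pytest.raises(ValueError):
            simulate_dose_posterior(k2_laplace, PatientSummary(4.0, 2.0, 500),
                                    TimePrior("uniform", 3, 5), m=100, seed=0)

    def test_monotone_in_observed_mean(self, k2_laplace):
        """Higher observed foci mean shifts the dose posterior stochastically up."""
        prior = TimePrior("uniform", 3, 5)
        qs = [0.1, 0.25, 0.5, 0.75, 0.9]
        lo = simulate_dose_posterior(k2_laplace, PatientSummary(3.0, 2.0, 500),
                                     prior, m=50000, seed=8)
        hi = simulate_dose_posterior(k2_laplace, PatientSummary(5.0, 2.0, 500),
                                     prior, m=50000, seed=8)
        assert np.all(np.quantile(lo.draws, qs) < np.quantile(hi.draws, qs))

    def test_negative_doses_retained_then_truncated(self, k2_laplace):
        """A background-level mean yields raw negative draws; truncation clips."""
        patient = PatientSummary(0.3, 0.6, 500)  # below the spontaneous level
        prior = TimePrior("uniform", 3, 5)
        raw = simulate_dose_posterior(k2_laplace, patient, prior, m=20000, seed=4)
        assert np.any(raw.draws < 0)
        clipped = simulate_dose_posterior(k2_laplace, patient, prior, m=20000, seed=4,
                                          truncate_negative=True)
        assert np.all(clipped.draws >= 0)


class TestGrid:
    def test_point_time_prior_equals_conditional(self, k2_laplace):
        """A near-degenerate time prior reproduces pi(d | t0)."""
        from biodose import alpha_beta_posterior

        patient = PatientSummary(4.0, 2.0, 500)
        t0 = 4.0
        prior = TimePrior("uniform", t0 - 1e-7, t0 + 1e-7)
        post = dose_posterior_grid(k2_laplace, patient, prior)
        ab = alpha_beta_posterior(k2_laplace, t0)
        mu1 = patient.x_bar - ab.mean[0]
        s1 = np.sqrt(patient.se**2 + ab.cov[0, 0])
        s2 = np.sqrt(ab.cov[1, 1])
        rho = -ab.cov[0, 1] / (s1 * s2)
        expected = ratio_of_normals_pdf(post.grid, mu1, s1, ab.mean[1], s2, rho)
        np.testing.assert_allclose(post.density, expected / trapezoid(expected, post.grid),
                                   rtol=1e-6, atol=1e-9)

    def test_grid_matches_simulation_quantiles(self, k2_laplace):
        patient = PatientSummary(4.0, 2.0, 500)
        prior = TimePrior("beta", 3, 5, 5, 5)
        sim = simulate_dose_posterior(k2_laplace, patient, prior, m=100000, seed=12)
        grid = dose_posterior_grid(k2_laplace, patient, prior)
        s_sim, s_grid = sim.summarize(), grid.summarize()
        for attr in ("ci_lo", "median", "ci_hi"):
            assert abs(getattr(s_sim, attr) - getattr(s_grid, attr)) < 0.02

    def test_too_narrow_grid_rejected(self, k2_laplace):
        patient = PatientSummary(4.0, 2.0, 500)
        prior = TimePrior("uniform", 3, 5)
        with pytest.raises(ValueError, match="too narrow"):
            dose_posterior_grid(k2_laplace, patient, prior, d_grid=np.linspace(0.7, 0.75, 50))

    def test_non_increasing_grid_rejected(self, k2_laplace):
        with pytest.raises(ValueError):
            dose_posterior_grid(k2_laplace, PatientSummary(4.0, 2.0, 500),
                                TimePrior("uniform", 3, 5), d_grid=np.array([0.0, 0.0, 1.0]))


class TestSummaries:
    def test_uniform_draws_quantiles(self, rng):
        post = DosePosterior(method="simulate", draws=rng.uniform(0, 1, 200000))
        s = summarize_posterior(post, level=0.95)
        assert s.ci_lo == pytest.approx(0.025, abs=0.005)
        assert s.ci_hi == pytest.approx(0.975, abs=0.005)
        assert s.mean == pytest.approx(s.median, abs=0.005)
        assert s.ci_lo < s.median < s.ci_hi

    def test_grid_summary_matches_closed_form_normal(self):
        grid = np.linspace(-5, 7, 2001)
        dens = stats.norm.pdf(grid, 1.0, 0.8)
        post = DosePosterior(method="integrate", grid=grid, density=dens)
        s = summarize_posterior(post, level=0.9)
        assert s.mean == pytest.approx(1.0, abs=1e-3)
        assert s.median == pytest.approx(1.0, abs=1e-3)
        assert s.ci_lo == pytest.approx(stats.norm.ppf(0.05, 1.0, 0.8), abs=2e-3)
        assert s.ci_hi == pytest.approx(stats.norm.ppf(0.95, 1.0, 0.8), abs=2e-3)

    def test_unnormalized_density_rejected(self):
        grid = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            DosePosterior(method="integrate", grid=grid, density=np.full(100, 3.0))
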