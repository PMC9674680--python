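"""Posterior of the absorbed dose under uncertainty on time since exposure.

A patient sample is summarized by the mean foci count per cell ``x_bar``,
its standard deviation ``s`` and the number of scored cells ``n``.  The
expected foci count mu of the patient is modelled nonparametrically as
mu ~ N(x_bar, s^2/n), independent of the calibration posterior.  Given a
time t the inverse-regression dose is

    d | t = (mu - alpha_t) / beta_t

so d | t is distributed as a ratio of two correlated normals (the numerator
mu - alpha_t and the denominator beta_t share the calibration posterior of
(alpha_t, beta_t)).  Uncertainty on t enters through a prior pi(t) —
uniform or scaled symmetric beta on an interval — and the marginal dose
posterior pi(d | data) is obtained either by Monte-Carlo simulation of the
sampling chain t* -> (alpha, beta) -> mu* -> d*, or by numerical quadrature
of the exact conditional ratio density over the time prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal
import logging
import warnings

import numpy as np
from scipy import stats
from scipy.integrate import trapezoid

from .calibration import LaplacePosterior
from .surface_posterior import alpha_beta_posterior, alpha_beta_posterior_batch

__all__ = [
    "PatientSummary",
    "TimePrior",
    "DosePosterior",
    "PosteriorSummary",
    "sample_time_prior",
    "dose_given_t",
    "ratio_of_normals_pdf",
    "simulate_dose_posterior",
    "simulate_dose_posterior_from_draws",
    "dose_posterior_grid",
    "summarize_posterior",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatientSummary:
    """Aggregate foci data from the test laboratory.

    x_bar : mean foci per cell; s : sample SD of foci per cell;
    n : number of cells scored (>= 2).
    """

    x_bar: float
    s: float
    n: int

    def __post_init__(self) -> None:
        if self.x_bar < 0 or self.s < 0:
            raise ValueError("x_bar and s must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def se(self) -> float:
        """Standard error of the mean, s/sqrt(n)."""
        return self.s / np.sqrt(self.n)

    @classmethod
    def from_se(cls, x_bar: float, se: float, n: int) -> "PatientSummary":
        """Build from a reported mean +- SE (SE = s/sqrt(n))."""
        return cls(x_bar=x_bar, s=se * np.sqrt(n), n=n)


@dataclass(frozen=True)
class TimePrior:
    """Prior on time since exposure: uniform or scaled beta on (t_lo, t_hi).

    The scaled-beta draw is t_lo + (t_hi - t_lo) * Beta(alpha, beta); with
    alpha = beta the prior is symmetric about the interval midpoint, and
    larger shapes concentrate the mass there.
    """

    family: Literal["uniform", "beta"]
    t_lo: float
    t_hi: float
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.t_lo < self.t_hi:
            raise ValueError("need 0 < t_lo < t_hi")
        if self.family not in ("uniform", "beta"):
            raise ValueError(f"unknown time-prior family {self.family!r}")
        if self.family == "beta" and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("beta shapes must be positive")

    @property
    def width(self) -> float:
        return self.t_hi - self.t_lo

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "uniform":
            return stats.uniform.pdf(t, loc=self.t_lo, scale=self.width)
        return stats.beta.pdf(t, self.alpha, self.beta, loc=self.t_lo, scale=self.width)

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.t_lo, self.t_hi, size=m)
        return self.t_lo + self.width * rng.beta(self.alpha, self.beta, size=m)


def sample_time_prior(prior: TimePrior, m: int, seed: int | None = None) -> np.ndarray:
    """Draw m times from the prior; deterministic given seed."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return prior.sample(m, np.random.default_rng(seed))


def dose_given_t(mu, alpha_t, beta_t):
    """Inverse-regression dose (mu - alpha_t) / beta_t; may be negative."""
    beta_t = np.asarray(beta_t, dtype=float)
    if np.any(beta_t == 0):
        raise ZeroDivisionError("beta_t must be nonzero")
    out = (np.asarray(mu, dtype=float) - np.asarray(alpha_t, dtype=float)) / beta_t
    return out if np.ndim(out) else float(out)


@dataclass
class PosteriorSummary:
    mean: float
    median: float
    ci_lo: float
    ci_hi: float
    level: float


@dataclass
class DosePosterior:
    """Marginal dose posterior, as draws (simulation) or a grid density."""

    method: str
    draws: np.ndarray | None = None
    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws is None and (self.grid is None or self.density is None):
            raise ValueError("need either draws or (grid, density)")
        if self.grid is not None:
            total = trapezoid(self.density, self.grid)
            if abs(total - 1.0) > 1e-3:
                raise ValueError(f"density integrates to {total:.6f}, not 1")

    def summarize(self, level: float = 0.95) -> PosteriorSummary:
        return summarize_posterior(self, level)


def summarize_posterior(dose_post: DosePosterior, level: float = 0.95) -> PosteriorSummary:
    """Mean, median and equal-tailed credible interval at ``level``."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    if dose_post.draws is not None:
        draws = dose_post.draws
        lo, med, hi = np.quantile(draws, [tail, 0.5, 1.0 - tail])
        return PosteriorSummary(float(np.mean(draws)), float(med), float(lo), float(hi), level)
    grid, dens = dose_post.grid, dose_post.density
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    # invert the CDF on the grid (cdf is nondecreasing)
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    lo, med, hi = np.interp([tail, 0.5, 1.0 - tail], cdf[keep], grid[keep])
    mean = float(trapezoid(grid * dens, grid))
    return PosteriorSummary(mean, float(med), float(lo), float(hi), level)


def _sample_bivariate(means: np.ndarray, covs: np.ndarray, rng: np.random.Generator):
    """One draw from each of m bivariate normals, via closed-form Cholesky."""
    z1 = rng.standard_normal(len(means))
    z2 = rng.standard_normal(len(means))
    s11 = np.sqrt(np.maximum(covs[:, 0, 0], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        l21 = np.where(s11 > 0, covs[:, 1, 0] / np.where(s11 > 0, s11, 1.0), 0.0)
    s22 = np.sqrt(np.maximum(covs[:, 1, 1] - l21**2, 0.0))
    x1 = means[:, 0] + s11 * z1
    x2 = means[:, 1] + l21 * z1 + s22 * z2
    return x1, x2


def simulate_dose_posterior(
    laplace: LaplacePosterior,
    patient: PatientSummary,
    prior: TimePrior,
    m: int = 10000,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> DosePosterior:
    """Monte-Carlo dose posterior via the sampling chain.

    For each of m replicates: draw t* from the time prior, draw
    (alpha_{t*}, beta_{t*}) from its delta-method bivariate normal, draw
    mu* ~ N(x_bar, s^2/n), and record d* = (mu* - alpha)/beta.  Negative
    doses are retained in the raw draws (the ratio can produce them when
    mu* < alpha); ``truncate_negative`` clips them to 0 for summaries.
    """
    if m < 10000:
        raise ValueError("m must be >= 10000 for a stable posterior sample")
    rng = np.random.default_rng(seed)
    t_star = prior.sample(m, rng)
    means, covs = alpha_beta_posterior_batch(laplace, t_star)
    alpha, beta = _sample_bivariate(means, covs, rng)
    mu_star = rng.normal(patient.x_bar, patient.se, size=m)
    with np.errstate(divide="ignore", invalid="ignore"):
        draws = (mu_star - alpha) / beta
    invalid = ~np.isfinite(draws) | (beta <= 0)
    n_invalid = int(invalid.sum())
    if n_invalid > 0.01 * m:
        warnings.warn(
            f"simulate_dose_posterior: {n_invalid}/{m} draws invalid (beta <= 0 or non-finite)",
            RuntimeWarning,
        )
    draws = draws[~invalid]
    if truncate_negative:
        draws = np.clip(draws, 0.0, None)
    return DosePosterior(
        method="simulate",
        draws=draws,
        seed=seed,
        diagnostics={"n_requested": m, "n_invalid": n_invalid},
    )


def simulate_dose_posterior_from_draws(
    param_draws,
    patient: PatientSummary,
    prior: TimePrior,
    m: int = 10000,
    seed: int | None = None,
) -> DosePosterior:
    """Monte-Carlo dose posterior drawing (alpha, beta) from MCMC output.

    ``param_draws`` is a sequence of :class:`~biodose.model_core.MixtureParams`
    posterior draws (or an :class:`~biodose.calibration.McmcResult`); step 2
    of the sampling chain picks a stored posterior draw instead of the
    Laplace bivariate normal.
    """
    from .calibration import McmcResult
    from .surface_posterior import alpha_beta_point

    if m < 10000:
        raise ValueError("m must be >= 10000 for a stable posterior sample")
    rng = np.random.default_rng(seed)
    t_star = prior.sample(m, rng)
    if isinstance(param_draws, McmcResult):
        idx = rng.integers(0, len(param_draws.draws), size=m)
        alpha = np.empty(m)
        beta = np.empty(m)
        # evaluate per unique stored draw to avoid m full reconstructions
        for i in np.unique(idx):
            sel = idx == i
            params = param_draws.params_at(int(i))
            a, b = alpha_beta_point(params, t_star[sel])
            alpha[sel], beta[sel] = a, b
    else:
        idx = rng.integers(0, len(param_draws), size=m)
        alpha = np.empty(m)
        beta = np.empty(m)
        for i in np.unique(idx):
            sel = idx == i
            a, b = alpha_beta_point(param_draws[int(i)], t_star[sel])
            alpha[sel], beta[sel] = a, b
    mu_star = rng.normal(patient.x_bar, patient.se, size=m)
    draws = (mu_star - alpha) / beta
    draws = draws[np.isfinite(draws)]
    return DosePosterior(method="simulate-mcmc", draws=draws, seed=seed)


def ratio_of_normals_pdf(r, mu1, sigma1, mu2, sigma2, rho):
    """Exact density of W/B for (W, B) bivariate normal (Hinkley's formula).

    W has mean mu1, SD sigma1; B has mean mu2, SD sigma2; corr(W, B) = rho.
    Vectorized over r.  Degenerate denominators (sigma2 = 0) reduce to the
    normal density of W/mu2.
    """
    r = np.asarray(r, dtype=float)
    if sigma2 <= 0:
        if mu2 == 0:
            raise ZeroDivisionError("denominator is identically zero")
        return stats.norm.pdf(r, loc=mu1 / mu2, scale=sigma1 / abs(mu2))
    if sigma1 <= 0:
        # constant numerator: density of mu1/B by change of variables
        out = np.zeros_like(r)
        nz = r != 0
        out[nz] = stats.norm.pdf(mu1 / r[nz], loc=mu2, scale=sigma2) * abs(mu1) / r[nz] ** 2
        return out
    rho = float(np.clip(rho, -0.999999, 0.999999))
    omr2 = 1.0 - rho**2
    a = np.sqrt(r**2 / sigma1**2 - 2.0 * rho * r / (sigma1 * sigma2) + 1.0 / sigma2**2)
    b = mu1 * r / sigma1**2 - rho * (mu1 + mu2 * r) / (sigma1 * sigma2) + mu2 / sigma2**2
    c = mu1**2 / sigma1**2 - 2.0 * rho * mu1 * mu2 / (sigma1 * sigma2) + mu2**2 / sigma2**2
    # cancellation-free form of (b^2 - c a^2) / (2 (1-rho^2) a^2): the naive
    # difference loses all precision when sigma2 is small relative to mu2
    log_d = -((mu2 * r - mu1) ** 2) / (2.0 * sigma1**2 * sigma2**2 * a**2)
    term1 = (
        b
        * np.exp(log_d)
        / (np.sqrt(2.0 * np.pi) * sigma1 * sigma2 * a**3)
        * (2.0 * stats.norm.cdf(b / (np.sqrt(omr2) * a)) - 1.0)
    )
    term2 = np.sqrt(omr2) / (np.pi * sigma1 * sigma2 * a**2) * np.exp(-c / (2.0 * omr2))
    return term1 + term2


def _conditional_dose_pdf(
    d_grid: np.ndarray, laplace: LaplacePosterior, patient: PatientSummary, t: float
) -> np.ndarray:
    """pi(d | t, data): ratio-of-correlated-normals density on the grid.

    The numerator mu - alpha_t folds the patient uncertainty s^2/n into the
    alpha_t marginal; its covariance with the denominator beta_t is
    -cov(alpha_t, beta_t).
    """
    ab = alpha_beta_posterior(laplace, t)
    mu1 = patient.x_bar - ab.mean[0]
    var1 = patient.se**2 + ab.cov[0, 0]
    mu2 = ab.mean[1]
    var2 = ab.cov[1, 1]
    cov12 = -ab.cov[0, 1]
    sigma1 = np.sqrt(var1)
    sigma2 = np.sqrt(var2)
    rho = cov12 / (sigma1 * sigma2) if sigma1 > 0 and sigma2 > 0 else 0.0
    return ratio_of_normals_pdf(d_grid, mu1, sigma1, mu2, sigma2, rho)


def _default_dose_grid(
    laplace: LaplacePosterior, patient: PatientSummary, prior: TimePrior, n_points: int
) -> np.ndarray:
    """Bracket the posterior support from conditional moments at the prior edges."""
    lo_candidates = []
    hi_candidates = []
    for t in np.linspace(prior.t_lo, prior.t_hi, 9):
        ab = alpha_beta_posterior(laplace, float(t))
        alpha_hat, beta_hat = ab.mean
        center = (patient.x_bar - alpha_hat) / beta_hat
        var_num = patient.se**2 + ab.cov[0, 0]
        # first-order ratio variance, inflated as a safety margin
        sd = np.sqrt(var_num / beta_hat**2 + center**2 * ab.cov[1, 1] / beta_hat**2) + 1e-6
        lo_candidates.append(center - 10 * sd)
        hi_candidates.append(center + 10 * sd)
    return np.linspace(min(lo_candidates), max(hi_candidates), n_points)


def dose_posterior_grid(
    laplace: LaplacePosterior,
    patient: PatientSummary,
    prior: TimePrior,
    d_grid: np.ndarray | None = None,
    n_t_nodes: int = 64,
    n_d_points: int = 801,
) -> DosePosterior:
    """Dose posterior by Gauss-Legendre quadrature of pi(d | t) pi(t) over t.

    The conditional density at each quadrature node is the exact
    ratio-of-correlated-normals density; the marginal is normalized on the
    dose grid and an error is raised if more than 1% of the mass falls
    outside it (grid too narrow).
    """
    if d_grid is None:
        d_grid = _default_dose_grid(laplace, patient, prior, n_d_points)
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be strictly increasing")
    nodes, weights = np.polynomial.legendre.leggauss(n_t_nodes)
    t_nodes = 0.5 * (prior.t_hi - prior.t_lo) * nodes + 0.5 * (prior.t_hi + prior.t_lo)
    t_weights = 0.5 * (prior.t_hi - prior.t_lo) * weights * prior.pdf(t_nodes)
    density = np.zeros_like(d_grid)
    for t, wt in zip(t_nodes, t_weights):
        density += wt * _conditional_dose_pdf(d_grid, laplace, patient, float(t))
    total = trapezoid(density, d_grid)
    if abs(total - 1.0) > 0.01:
        raise ValueError(
            f"dose density integrates to {total:.4f}; grid [{d_grid[0]:.3g}, {d_grid[-1]:.3g}] "
            "is too narrow or the quadrature too coarse"
        )
    density /= total
    return DosePosterior(
        method="integrate",
        grid=d_grid,
        density=density,
        diagnostics={"n_t_nodes": n_t_nodes, "raw_mass": float(total)},
    )
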