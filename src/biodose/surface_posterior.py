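"""Posterior of the calibration-line coefficients (alpha_t, beta_t).

At any fixed post-irradiation time t the mixture mean surface is affine in
dose:  mu(d | t) = alpha_t + beta_t * d  with

    alpha_t = sum_k w_k c_k t**u_k      (spontaneous foci level)
    beta_t  = sum_k w_k a_k t**v_k      (foci yield per gray)

The Gaussian (Laplace) posterior over the free parameter vector is pushed
through g = (alpha_t, beta_t) by the first-order delta method, giving a
bivariate normal N2(g(mode), J Sigma J^T) where J is the Jacobian of g in
the unconstrained parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import LaplacePosterior
from .model_core import MixtureParams
from .parametrization import Parametrization

__all__ = [
    "AlphaBetaPosterior",
    "alpha_beta_point",
    "alpha_beta_gradient",
    "alpha_beta_posterior",
    "alpha_beta_posterior_batch",
]


@dataclass
class AlphaBetaPosterior:
    """Bivariate normal posterior of (alpha_t, beta_t) at a fixed time."""

    t: float
    mean: np.ndarray  # (2,): (alpha_hat, beta_hat)
    cov: np.ndarray  # (2, 2)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = 0.5 * (np.asarray(self.cov, dtype=float) + np.asarray(self.cov, dtype=float).T)
        eigs = np.linalg.eigvalsh(self.cov)
        if eigs.min() < -1e-10 * max(eigs.max(), 1.0):
            raise ValueError(f"(alpha, beta) covariance not PSD: eigenvalues {eigs}")


def alpha_beta_point(params: MixtureParams, t) -> tuple:
    """(alpha_t, beta_t) for scalar or array t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t must be strictly positive")
    alpha = (params.weights * params.c) @ np.power.outer(t_arr, params.u).T
    beta = (params.weights * params.a) @ np.power.outer(t_arr, params.v).T
    if np.ndim(t) == 0:
        return float(alpha), float(beta)
    return alpha, beta


def alpha_beta_gradient(
    free: np.ndarray, t, parametrization: Parametrization
) -> np.ndarray:
    """Jacobian of (alpha_t, beta_t) w.r.t. the unconstrained free vector.

    Returns shape (2, p) for scalar t, or (m, 2, p) for an array of m times.
    Closed form via the chain rule through the softmax and log transforms.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise ValueError("t must be strictly positive")
    params = parametrization.to_params(np.asarray(free, dtype=float))
    K = params.K
    p = parametrization.p
    m = len(t_arr)
    w, a, c, u, v = params.weights, params.a, params.c, params.u, params.v

    tu = np.power.outer(t_arr, u)  # (m, K)
    tv = np.power.outer(t_arr, v)
    ctu = c * tu  # per-component alpha contributions / w
    atv = a * tv
    alpha = ctu @ w
    beta = atv @ w
    logt = np.log(t_arr)[:, None]

    J = np.zeros((m, 2, p))
    # weight coordinates (softmax, last component as reference):
    # d w_k / d z_j = w_k (delta_kj - w_j)  =>  d alpha/d z_j = w_j (c_j t^u_j - alpha)
    J[:, 0, parametrization.sl_z] = w[:-1] * (ctu[:, :-1] - alpha[:, None])
    J[:, 1, parametrization.sl_z] = w[:-1] * (atv[:, :-1] - beta[:, None])
    # log a_k: only beta; d beta / d log a_k = w_k a_k t^v_k
    J[:, 1, parametrization.sl_log_a] = w * atv
    # log c_k: only alpha
    J[:, 0, parametrization.sl_log_c] = w * ctu
    # u: only alpha; d alpha / d u_k = w_k c_k t^u_k log t
    if parametrization.spec.shared_u:
        J[:, 0, parametrization.sl_u] = ((w * ctu).sum(axis=1) * logt[:, 0])[:, None]
    else:
        J[:, 0, parametrization.sl_u] = w * ctu * logt
    # v: only beta
    J[:, 1, parametrization.sl_v] = w * atv * logt
    if np.ndim(t) == 0:
        return J[0]
    return J


def alpha_beta_posterior(laplace: LaplacePosterior, t: float) -> AlphaBetaPosterior:
    """Delta-method bivariate normal for (alpha_t, beta_t) at fixed t."""
    alpha, beta = alpha_beta_point(laplace.params, float(t))
    J = alpha_beta_gradient(laplace.mode, float(t), laplace.parametrization)
    cov = J @ laplace.cov @ J.T
    return AlphaBetaPosterior(t=float(t), mean=np.array([alpha, beta]), cov=cov)


def alpha_beta_posterior_batch(laplace: LaplacePosterior, ts: np.ndarray):
    """Vectorized delta method over an array of times.

    Returns ``(means, covs)`` with shapes (m, 2) and (m, 2, 2); used by the
    dose-posterior simulator where each Monte-Carlo draw has its own t*.
    """
    ts = np.asarray(ts, dtype=float)
    alpha, beta = alpha_beta_point(laplace.params, ts)
    means = np.column_stack([alpha, beta])
    J = alpha_beta_gradient(laplace.mode, ts, laplace.parametrization)  # (m, 2, p)
    covs = np.einsum("mip,pq,mjq->mij", J, laplace.cov, J)
    covs = 0.5 * (covs + np.swapaxes(covs, 1, 2))
    return means, covs
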