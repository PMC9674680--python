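"""Mapping between constrained mixture parameters and an unconstrained vector.

Optimization, the Hessian and the Gaussian (Laplace) posterior all live in an
unconstrained space:

* weights via the additive log-ratio (softmax with the last component as
  reference), K-1 free coordinates;
* ``a_k`` and ``c_k`` via log;
* exponents ``u`` (one coordinate when shared) and ``v_k`` untransformed.

The coordinate layout is ``[z_1..z_{K-1}, log_a_1..log_a_K,
log_c_1..log_c_K, u (or u_1..u_K), v_1..v_K]``.
"""

from __future__ import annotations

import numpy as np

from .model_core import MixtureParams, MixtureSpec

__all__ = ["Parametrization"]


class Parametrization:
    """Bijection between :class:`MixtureParams` and R^p for a given spec."""

    def __init__(self, spec: MixtureSpec):
        self.spec = spec
        K = spec.K
        self._n_z = K - 1
        self._n_u = 1 if spec.shared_u else K
        self.p = spec.n_free_params
        names = [f"z{k + 1}" for k in range(self._n_z)]
        names += [f"log_a{k + 1}" for k in range(K)]
        names += [f"log_c{k + 1}" for k in range(K)]
        names += ["u"] if spec.shared_u else [f"u{k + 1}" for k in range(K)]
        names += [f"v{k + 1}" for k in range(K)]
        self.names = names

    # -- slices into the free vector ------------------------------------
    @property
    def sl_z(self) -> slice:
        return slice(0, self._n_z)

    @property
    def sl_log_a(self) -> slice:
        return slice(self._n_z, self._n_z + self.spec.K)

    @property
    def sl_log_c(self) -> slice:
        K = self.spec.K
        return slice(self._n_z + K, self._n_z + 2 * K)

    @property
    def sl_u(self) -> slice:
        K = self.spec.K
        return slice(self._n_z + 2 * K, self._n_z + 2 * K + self._n_u)

    @property
    def sl_v(self) -> slice:
        K = self.spec.K
        start = self._n_z + 2 * K + self._n_u
        return slice(start, start + K)

    # -- maps ------------------------------------------------------------
    def to_free(self, params: MixtureParams) -> np.ndarray:
        K = self.spec.K
        if params.K != K:
            raise ValueError(f"params have K={params.K}, spec expects {K}")
        if self.spec.shared_u and not np.allclose(params.u, params.u[0]):
            raise ValueError("shared-u spec requires identical u across components")
        z = np.log(params.weights[:-1] / params.weights[-1])
        u = params.u[:1] if self.spec.shared_u else params.u
        return np.concatenate([z, np.log(params.a), np.log(params.c), u, params.v])

    def to_params(self, free: np.ndarray) -> MixtureParams:
        free = np.asarray(free, dtype=float)
        if free.shape != (self.p,):
            raise ValueError(f"free vector must have length {self.p}, got {free.shape}")
        K = self.spec.K
        z_full = np.append(free[self.sl_z], 0.0)
        z_full -= z_full.max()  # softmax stabilisation
        w = np.exp(z_full)
        w /= w.sum()
        u = free[self.sl_u]
        if self.spec.shared_u:
            u = np.full(K, u[0])
        return MixtureParams(
            weights=w,
            a=np.exp(free[self.sl_log_a]),
            c=np.exp(free[self.sl_log_c]),
            u=u,
            v=free[self.sl_v].copy(),
        )

    def weights_jacobian(self, weights: np.ndarray) -> np.ndarray:
        """d w_k / d z_j, shape (K, K-1): softmax Jacobian with fixed reference."""
        K = self.spec.K
        J = np.zeros((K, K - 1))
        for j in range(K - 1):
            J[:, j] = -weights * weights[j]
            J[j, j] += weights[j]
        return J

    def describe(self) -> dict:
        """Serializable descriptor of the coordinate layout."""
        return {
            "K": self.spec.K,
            "shared_u": self.spec.shared_u,
            "coordinates": list(self.names),
            "weights": "additive-log-ratio (last component reference)",
            "a_c": "log",
            "u_v": "identity",
        }
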