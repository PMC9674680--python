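"""Poisson mixture model for gamma-H2AX foci counts over dose and time.

The number of radiation-induced foci per cell is modelled as a finite mixture
of Poisson distributions.  Each mixture component ``k`` has a mean surface

    lambda_k(d, t) = c_k * t**u_k + a_k * t**v_k * d

where ``d`` is the absorbed dose in gray and ``t`` the post-irradiation time
in hours.  The first term describes the spontaneous (background) focus level
and its time evolution; the second term is the dose-induced yield, linear in
dose at any fixed time, with its own repair-kinetics exponent.  Mixture
components capture sub-populations of blood cells with different
radiosensitivity, and make the marginal count distribution overdispersed
relative to a single Poisson, as observed in real foci data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "MixtureSpec",
    "MixtureParams",
    "CalibrationDataset",
    "lambda_surface",
    "mixture_pmf",
    "log_likelihood",
    "mean_surface",
    "aic",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Structural description of a Poisson mixture model.

    Parameters
    ----------
    K : int
        Number of mixture components (>= 1).
    shared_u : bool
        If True, all components share a single background-decay exponent u.
    """

    K: int
    shared_u: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")

    @property
    def n_free_params(self) -> int:
        """Number of free parameters: (K-1) weights + a,c,v per component + u."""
        return (self.K - 1) + 3 * self.K + (1 if self.shared_u else self.K)


@dataclass
class MixtureParams:
    """Weights and surface coefficients of a Poisson mixture.

    All arrays have length K.  ``u`` is stored per component even for
    shared-u models (with identical entries), which keeps every surface
    evaluation uniform.

    Invariants: weights are positive and sum to one; ``a`` and ``c`` are
    strictly positive so the Poisson mean is positive for every d >= 0,
    t > 0.  Exponents ``u`` and ``v`` are unconstrained in sign (foci decay
    over time corresponds to negative values).
    """

    weights: np.ndarray
    a: np.ndarray
    c: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("weights", "a", "c", "u", "v"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        K = self.K
        for name in ("a", "c", "u", "v"):
            if getattr(self, name).shape != (K,):
                raise ValueError(f"{name} must have length K={K}")
        if np.any(self.weights <= 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        if np.any(self.a <= 0) or np.any(self.c <= 0):
            raise ValueError("a and c must be strictly positive")

    @property
    def K(self) -> int:
        return len(self.weights)

    def canonicalized(self) -> "MixtureParams":
        """Return a copy with components sorted ascending by the dose slope a_k.

        Mixture likelihoods are invariant under component relabelling; the
        ascending-``a`` order fixes one representative so that fitted models,
        MCMC draws and reports are comparable.
        """
        order = np.argsort(self.a, kind="stable")
        return MixtureParams(
            weights=self.weights[order],
            a=self.a[order],
            c=self.c[order],
            u=self.u[order],
            v=self.v[order],
        )


class CalibrationDataset:
    """Per-cell foci counts with known dose (Gy) and post-irradiation time (h).

    Internally the records are also aggregated over unique
    ``(dose, time, count)`` triples, which makes likelihood evaluation cost
    proportional to the number of distinct triples rather than the number of
    cells — calibration designs have few conditions and small count ranges.
    """

    def __init__(self, y: Sequence[int], d: Sequence[float], t: Sequence[float]):
        y = np.asarray(y)
        d = np.asarray(d, dtype=float)
        t = np.asarray(t, dtype=float)
        if not (len(y) == len(d) == len(t)):
            raise ValueError("y, d, t must have equal length")
        if len(y) == 0:
            raise ValueError("dataset must be non-empty")
        if not np.all(np.equal(np.mod(y, 1), 0)) or np.any(y < 0):
            raise ValueError("foci counts must be non-negative integers")
        if np.any(t <= 0):
            raise ValueError("times must be strictly positive")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        self.y = y.astype(np.int64)
        self.d = d
        self.t = t
        # aggregate unique (d, t, y) rows with multiplicities
        stacked = np.column_stack([d, t, self.y])
        uniq, counts = np.unique(stacked, axis=0, return_counts=True)
        self._uy = uniq[:, 2].astype(np.int64)
        self._ud = uniq[:, 0]
        self._ut = uniq[:, 1]
        self._uw = counts.astype(float)

    @property
    def N(self) -> int:
        return len(self.y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CalibrationDataset":
        required = ["foci_count", "dose_gy", "time_h"]
        missing = [col for col in required if col not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        return cls(df["foci_count"].to_numpy(), df["dose_gy"].to_numpy(), df["time_h"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"foci_count": self.y, "dose_gy": self.d, "time_h": self.t})

    def conditions(self) -> pd.DataFrame:
        """Unique (dose, time) conditions with cell counts."""
        df = self.to_dataframe()
        return (
            df.groupby(["dose_gy", "time_h"], as_index=False)
            .agg(n_cells=("foci_count", "size"), mean_foci=("foci_count", "mean"))
        )


def _component_means(params: MixtureParams, d, t) -> np.ndarray:
    """lambda_k(d, t) for all components; broadcasts d, t against the K axis."""
    d = np.asarray(d, dtype=float)[..., None]
    t = np.asarray(t, dtype=float)[..., None]
    return params.c * t ** params.u + params.a * t ** params.v * d


def lambda_surface(params: MixtureParams, k: int, d: float, t: float) -> float:
    """Mean surface of component ``k`` (0-based): c_k t^u_k + a_k t^v_k d."""
    if not 0 <= k < params.K:
        raise IndexError(f"component index {k} out of range for K={params.K}")
    if np.any(np.asarray(t) <= 0):
        raise ValueError("t must be strictly positive")
    if np.any(np.asarray(d) < 0):
        raise ValueError("d must be non-negative")
    return params.c[k] * t ** params.u[k] + params.a[k] * t ** params.v[k] * d


def mixture_pmf(params: MixtureParams, y, d: float, t: float):
    """P(Y = y) under the mixture at condition (d, t); vectorized over y."""
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.all(np.equal(np.mod(y_arr, 1), 0)):
        raise ValueError("y must be a non-negative integer")
    lam = _component_means(params, d, t)  # (..., K)
    logp = (
        -lam
        + y_arr[..., None] * np.log(lam)
        - gammaln(y_arr[..., None] + 1.0)
    )
    out = np.exp(logsumexp(logp, axis=-1, b=params.weights))
    return out if out.shape else float(out)


def log_likelihood(params: MixtureParams, data: CalibrationDataset) -> float:
    """Mixture log-likelihood over all cells, with log-sum-exp stabilisation.

    Returns ``-inf`` (rather than raising) when a component mean is
    non-positive or non-finite, so optimizers can treat invalid parameter
    points as excluded.
    """
    lam = _component_means(params, data._ud, data._ut)  # (n_unique, K)
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        return -np.inf
    y = data._uy[:, None]
    logp = -lam + y * np.log(lam) - gammaln(y + 1.0)
    per_row = logsumexp(logp, axis=1, b=params.weights)
    return float(np.dot(data._uw, per_row))


def mean_surface(params: MixtureParams, d, t):
    """Expected foci count mu(d|t) = sum_k w_k lambda_k(d,t) = alpha_t + beta_t d."""
    if np.any(np.asarray(t) <= 0):
        raise ValueError("t must be strictly positive")
    lam = _component_means(params, d, t)
    out = lam @ params.weights
    return out if np.ndim(out) else float(out)


def aic(params: MixtureParams, spec: MixtureSpec, data: CalibrationDataset) -> float:
    """Akaike information criterion 2p - 2*loglik; lower is better."""
    return 2.0 * spec.n_free_params - 2.0 * log_likelihood(params, data)
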