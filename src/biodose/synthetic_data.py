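"""Synthetic calibration and patient data from the Poisson mixture model.

Emulates the laboratory calibration design: irradiate cells at a grid of
doses (0-3 Gy) and score gamma-H2AX foci at several post-irradiation times
(0.5-24 h), 500 cells per (dose, time) condition.  Counts are drawn from
the generative mixture: each cell picks a component with probability w_k
and then a Poisson count with mean lambda_k(d, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_estimation import PatientSummary
from .model_core import CalibrationDataset, MixtureParams

__all__ = [
    "DesignGrid",
    "paper_like_params",
    "generate_calibration_data",
    "generate_patient_sample",
]

DEFAULT_DOSES = (0.0, 0.5, 1.0, 2.0, 3.0)
DEFAULT_TIMES = (0.5, 1.0, 2.0, 4.0, 24.0)


@dataclass(frozen=True)
class DesignGrid:
    """Fully crossed (dose, time) calibration design."""

    doses: tuple = DEFAULT_DOSES
    times: tuple = DEFAULT_TIMES
    cells_per_condition: int = 500

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if any(t <= 0 for t in self.times):
            raise ValueError("times must be strictly positive")
        if self.cells_per_condition < 1:
            raise ValueError("cells_per_condition must be >= 1")

    @property
    def n_conditions(self) -> int:
        return len(self.doses) * len(self.times)


def paper_like_params() -> MixtureParams:
    """A two-component fixture with realistic foci kinetics.

    Chosen to give roughly 0.5-1 spontaneous foci per cell and up to ~25
    foci at 3 Gy / 0.5 h, decaying over 24 h — magnitudes typical of
    gamma-H2AX calibration experiments.  These are synthetic fixture values,
    not estimates from any real dataset.
    """
    return MixtureParams(
        weights=np.array([0.6, 0.4]),
        a=np.array([3.0, 6.0]),
        c=np.array([0.4, 0.8]),
        u=np.array([-0.3, -0.3]),
        v=np.array([-0.5, -0.9]),
    )


def _draw_counts(
    params: MixtureParams, d: float, t: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    comp = rng.choice(params.K, size=n, p=params.weights)
    lam = params.c[comp] * t ** params.u[comp] + params.a[comp] * t ** params.v[comp] * d
    return rng.poisson(lam)


def generate_calibration_data(
    params: MixtureParams, grid: DesignGrid | None = None, seed: int | None = None
) -> CalibrationDataset:
    """Simulate per-cell foci counts over the full design; deterministic given seed."""
    grid = grid or DesignGrid()
    rng = np.random.default_rng(seed)
    y, d_col, t_col = [], [], []
    for d in grid.doses:
        for t in grid.times:
            counts = _draw_counts(params, float(d), float(t), grid.cells_per_condition, rng)
            y.append(counts)
            d_col.append(np.full(grid.cells_per_condition, d, dtype=float))
            t_col.append(np.full(grid.cells_per_condition, t, dtype=float))
    return CalibrationDataset(np.concatenate(y), np.concatenate(d_col), np.concatenate(t_col))


def generate_patient_sample(
    params: MixtureParams,
    true_dose: float,
    true_time: float,
    n_cells: int = 500,
    seed: int | None = None,
) -> tuple[PatientSummary, np.ndarray]:
    """Simulate a patient's foci counts at a true (dose, time).

    Returns both the aggregate summary (all the estimating laboratory sees)
    and the raw per-cell counts, so the aggregate-only interface can be
    tested as a boundary.
    """
    if true_dose < 0:
        raise ValueError("true_dose must be non-negative")
    if true_time <= 0:
        raise ValueError("true_time must be strictly positive")
    rng = np.random.default_rng(seed)
    counts = _draw_counts(params, float(true_dose), float(true_time), n_cells, rng)
    summary = PatientSummary(
        x_bar=float(np.mean(counts)), s=float(np.std(counts, ddof=1)), n=n_cells
    )
    return summary, counts
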