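"""File formats: calibration CSV and the calibration-output exchange file.

The calibration CSV has one row per scored cell with columns
``foci_count,dose_gy,time_h``.  The calibration output file is the complete
handoff between the calibrating and the estimating laboratory: model
structure, parametrization descriptor, posterior mode, covariance matrix,
log posterior and AIC, as JSON (or YAML, by file extension).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import LaplacePosterior
from .model_core import CalibrationDataset, MixtureSpec
from .parametrization import Parametrization

__all__ = [
    "read_calibration_csv",
    "write_calibration_csv",
    "write_calibration_file",
    "read_calibration_file",
]

FORMAT_VERSION = 1


def read_calibration_csv(path) -> CalibrationDataset:
    """Read per-cell foci counts; errors name the offending row."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    required = ["foci_count", "dose_gy", "time_h"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric or missing {col} at data row {bad[0] + 1}")
    bad = df.index[(df["foci_count"] < 0) | (df["foci_count"] % 1 != 0)]
    if len(bad):
        raise ValueError(f"{path}: foci_count must be a non-negative integer at data row {bad[0] + 1}")
    bad = df.index[df["time_h"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: time_h must be positive at data row {bad[0] + 1}")
    bad = df.index[df["dose_gy"] < 0]
    if len(bad):
        raise ValueError(f"{path}: dose_gy must be non-negative at data row {bad[0] + 1}")
    return CalibrationDataset.from_dataframe(df)


def write_calibration_csv(data: CalibrationDataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


def write_calibration_file(laplace: LaplacePosterior, path, extra: dict | None = None) -> None:
    """Serialize the calibration output (mode + covariance + metadata)."""
    path = Path(path)
    payload = {
        "format_version": FORMAT_VERSION,
        "model": {"K": laplace.spec.K, "shared_u": laplace.spec.shared_u},
        "parametrization": laplace.parametrization.describe(),
        "mode": np.asarray(laplace.mode).tolist(),
        "covariance": np.asarray(laplace.cov).tolist(),
        "log_posterior": float(laplace.log_posterior_at_mode),
        "aic": None if laplace.aic is None else float(laplace.aic),
    }
    if extra:
        payload.update(extra)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_calibration_file(path) -> LaplacePosterior:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported format_version {payload.get('format_version')!r}"
        )
    spec = MixtureSpec(K=int(payload["model"]["K"]), shared_u=bool(payload["model"]["shared_u"]))
    parametrization = Parametrization(spec)
    mode = np.asarray(payload["mode"], dtype=float)
    cov = np.asarray(payload["covariance"], dtype=float)
    if mode.shape != (parametrization.p,) or cov.shape != (parametrization.p, parametrization.p):
        raise ValueError(
            f"{path}: mode/covariance shapes {mode.shape}/{cov.shape} do not match "
            f"p={parametrization.p} for K={spec.K}, shared_u={spec.shared_u}"
        )
    return LaplacePosterior(
        mode=mode,
        cov=cov,
        spec=spec,
        parametrization=parametrization,
        log_posterior_at_mode=float(payload["log_posterior"]),
        params=parametrization.to_params(mode),
        aic=payload.get("aic"),
    )
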