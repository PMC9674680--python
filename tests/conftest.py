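"""Shared fixtures: a synthetic two-component calibration study.

The session-scoped fixtures simulate the full calibration design (doses
0-3 Gy, times 0.5-24 h, 500 cells per condition), fit the K=2 shared-u
mixture and build its Laplace posterior once; most downstream tests reuse
them.
"""

import numpy as np
import pytest

from biodose import (
    DesignGrid,
    MixtureSpec,
    generate_calibration_data,
    laplace_approx,
    map_fit,
    paper_like_params,
)


@pytest.fixture(scope="session")
def true_params():
    return paper_like_params()


@pytest.fixture(scope="session")
def design():
    return DesignGrid()


@pytest.fixture(scope="session")
def cal_data(true_params, design):
    return generate_calibration_data(true_params, design, seed=2024)


@pytest.fixture(scope="session")
def k2_spec():
    return MixtureSpec(K=2, shared_u=True)


@pytest.fixture(scope="session")
def k2_fit(cal_data, k2_spec):
    return map_fit(cal_data, k2_spec, n_starts=5, seed=1)


@pytest.fixture(scope="session")
def k2_laplace(k2_fit, cal_data):
    return laplace_approx(k2_fit, cal_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
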