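"""Shared fixtures and the brute-force occupancy oracle.

The oracle recomputes predicted activity by explicit Python-loop
summation over the enumerated occupancy states, independently of the
vectorized implementation, so the two can be compared to tight
tolerance.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

import girkfit as gf


@pytest.fixture(params=["GIRK4", "GIRK1_4", "GIRK1N217D_4"])
def variant_name(request) -> str:
    return request.param


@pytest.fixture
def variant(variant_name):
    return gf.get_variant(variant_name)


@pytest.fixture
def ref_params(variant_name):
    return gf.REFERENCE_PARAMETERS[variant_name]


def oracle_theta(i: int, params, variant) -> float:
    if variant.theta_mode == "interpolated":
        return params.theta[0] + (params.theta[4] - params.theta[0]) * i / 4
    return params.theta[i]


def oracle_activity(x_g, na, params, variant, j_open: int = 4) -> float:
    """Predicted activity by explicit summation over all states."""
    z = 0.0
    num = 0.0
    for i in range(variant.i_baseline, 5):
        for j in range(5):
            k = i - variant.i_baseline
            w = (
                comb(variant.n_variable_na_sites, k)
                * (na / params.k_dn) ** k
                * comb(4, j)
                * (x_g / params.k_db) ** j
                * params.b ** (-j * (j - 1) / 2)
                * params.eta ** (-(i * j))
            )
            z += w
            if j == j_open:
                num += oracle_theta(i, params, variant) * w
    return num / z


def random_params(rng: np.random.Generator, variant) -> "gf.GatingParameters":
    """Log-uniform parameter draw covering the physically sensible range."""
    theta = {
        i: rng.uniform(0.0, 2.0) for i in variant.free_theta_indices
    }
    return gf.GatingParameters(
        k_db=10 ** rng.uniform(-4, -1),
        k_dn=10 ** rng.uniform(0, 3),
        b=10 ** rng.uniform(-1, 0.5),
        eta=10 ** rng.uniform(-1, 0.5),
        theta=theta,
    )


def random_conditions(rng: np.random.Generator) -> tuple[float, float]:
    x_g = 0.0 if rng.random() < 0.1 else 10 ** rng.uniform(-4, np.log10(0.015))
    na = 0.0 if rng.random() < 0.1 else 10 ** rng.uniform(-1, 2)
    return x_g, na
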