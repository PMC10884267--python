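"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq

from comorbid.joint import frechet_bounds, odds_ratio_from_joint

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def bisect_joint_prevalence(p_i: float, p_j: float, theta: float) -> float:
    """Independent oracle: invert the monotone map p_ij -> theta by bisection.

    Root-finds log OR(p_ij) = log theta over the open Frechet interval,
    never touching the closed-form quadratic under test.
    """
    lo, hi = frechet_bounds(p_i, p_j)
    eps = 1e-14

    def f(p: float) -> float:
        return np.log(odds_ratio_from_joint(p_i, p_j, p)) - np.log(theta)

    return brentq(f, lo + eps, hi - eps, xtol=1e-15, rtol=4 * np.finfo(float).eps)


@pytest.fixture
def joint_oracle():
    return bisect_joint_prevalence
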