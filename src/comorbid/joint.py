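"""Joint pairwise prevalence from marginal prevalences and an odds ratio.

For two conditions with national marginal prevalences Pi and Pj and odds
ratio theta, the joint prevalence Pij satisfies

    theta = Pij (1 - Pi - Pj + Pij) / [(Pi - Pij)(Pj - Pij)],

a quadratic in Pij whose unique root inside the Frechet bounds
[max(0, Pi + Pj - 1), min(Pi, Pj)] is

    Pij = [A - sqrt(A^2 - 4 theta (theta - 1) Pi Pj)] / (2 (theta - 1)),
    A = 1 + (theta - 1)(Pi + Pj),

with the independence limit Pij = Pi Pj as theta -> 1.  Conditional
comorbidity prevalences are then Pij/Pi, and the expected number of
comorbidities for an index condition i is Mi = sum_j Pij/Pi over the other
modelled conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .synthesis import PairAssociation, predict_or

Z95 = 1.959964  # two-sided 95% normal quantile, as conventionally printed

_THETA_ONE_TOL = 1e-8
_DISC_TOL = 1e-12


@dataclass
class PrevalenceEstimate:
    """National marginal prevalence of one condition, with 95% CI.

    ``se`` is derived from the (possibly asymmetric) CI as the full width
    divided by 2 * 1.959964 unless supplied explicitly.
    """

    condition: str
    prev: float
    ci_low: float
    ci_high: float
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.prev < 1):
            raise ValueError(f"{self.condition}: prevalence {self.prev} outside (0, 1)")
        if not (self.ci_low <= self.prev <= self.ci_high):
            raise ValueError(
                f"{self.condition}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket the estimate {self.prev}"
            )
        if self.se is None:
            self.se = (self.ci_high - self.ci_low) / (2.0 * Z95)
        if self.se < 0:
            raise ValueError(f"{self.condition}: negative SE")


@dataclass
class PairPrevalence:
    """Estimated joint prevalence for one condition pair."""

    cond_a: str
    cond_b: str
    p_joint: float
    p_b_given_a: float
    p_a_given_b: float
    theta_used: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def conditional_on(self, index: str) -> float:
        """Prevalence of the partner condition among people with ``index``."""
        if index == self.cond_a:
            return self.p_b_given_a
        if index == self.cond_b:
            return self.p_a_given_b
        raise KeyError(f"{index!r} is not part of pair ({self.cond_a}, {self.cond_b})")

    def partner_of(self, index: str) -> str:
        if index == self.cond_a:
            return self.cond_b
        if index == self.cond_b:
            return self.cond_a
        raise KeyError(f"{index!r} is not part of pair ({self.cond_a}, {self.cond_b})")


@dataclass
class ComorbidityProfile:
    """Comorbidity burden for one index condition."""

    index_condition: str
    conditionals: dict[str, float]
    m_expected: float
    var_m: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def frechet_bounds(p_i, p_j) -> tuple[np.ndarray, np.ndarray]:
    """Feasible interval for a joint probability with the given marginals."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    return np.maximum(0.0, p_i + p_j - 1.0), np.minimum(p_i, p_j)


def odds_ratio_from_joint(p_i, p_j, p_ij):
    """Odds ratio implied by marginals (p_i, p_j) and joint prevalence p_ij.

    theta = [p_ij (1 - p_i - p_j + p_ij)] / [(p_i - p_ij)(p_j - p_ij)].
    Accepts scalars or broadcastable arrays; p_ij must lie strictly inside
    the Frechet bounds.
    """
    p_i, p_j, p_ij = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (p_i, p_j, p_ij))
    )
    _check_marginals(p_i, p_j)
    lo, hi = frechet_bounds(p_i, p_j)
    if np.any(p_ij <= lo) or np.any(p_ij >= hi):
        raise ValueError("degenerate joint: p_ij at or outside the Frechet bounds")
    theta = (p_ij * (1.0 - p_i - p_j + p_ij)) / ((p_i - p_ij) * (p_j - p_ij))
    return theta if theta.ndim else float(theta)


def _check_marginals(p_i: np.ndarray, p_j: np.ndarray) -> None:
    if np.any((p_i <= 0) | (p_i >= 1) | (p_j <= 0) | (p_j >= 1)):
        raise ValueError("marginal prevalences must lie in (0, 1)")


def solve_joint_prevalence(p_i, p_j, theta):
    """Joint prevalence p_ij from marginals and odds ratio (closed form).

    Takes the minus root of the quadratic (the only root inside the Frechet
    bounds); branches to the exact independence limit p_i * p_j when theta
    is within 1e-8 of 1.  A discriminant negative by more than 1e-12 is an
    error; smaller negativity is treated as floating-point noise and
    clipped to zero.  Accepts scalars or broadcastable arrays.
    """
    p_i, p_j, theta = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (p_i, p_j, theta))
    )
    _check_marginals(p_i, p_j)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")

    near_one = np.abs(theta - 1.0) < _THETA_ONE_TOL
    tm1 = np.where(near_one, 1.0, theta - 1.0)  # placeholder avoids 0-division
    a = 1.0 + (theta - 1.0) * (p_i + p_j)
    disc = a * a - 4.0 * theta * (theta - 1.0) * p_i * p_j
    if np.any(disc < -_DISC_TOL):
        raise ValueError("negative discriminant: no real joint prevalence")
    disc = np.maximum(disc, 0.0)
    with np.errstate(invalid="ignore"):
        root = (a - np.sqrt(disc)) / (2.0 * tm1)
    p_ij = np.where(near_one, p_i * p_j, root)

    lo, hi = frechet_bounds(p_i, p_j)
    # guard against float drift just outside the feasible interval
    p_ij = np.clip(p_ij, lo, hi)
    return p_ij if p_ij.ndim else float(p_ij)


def pair_prevalence(
    prev_i: PrevalenceEstimate,
    prev_j: PrevalenceEstimate,
    assoc: PairAssociation,
) -> PairPrevalence:
    """Point estimate of the joint prevalence for one pair.

    The OR is predicted at the national marginals (standardising a
    meta-regression to the national prevalence level), then inverted through
    the quadratic; CI fields stay empty until the bootstrap fills them.
    """
    theta = predict_or(assoc, prev_i.prev, prev_j.prev)
    p_ij = solve_joint_prevalence(prev_i.prev, prev_j.prev, theta)
    return PairPrevalence(
        cond_a=prev_i.condition,
        cond_b=prev_j.condition,
        p_joint=p_ij,
        p_b_given_a=p_ij / prev_i.prev,
        p_a_given_b=p_ij / prev_j.prev,
        theta_used=theta,
    )


def comorbidity_profile(
    index: str,
    pairs: Sequence[PairPrevalence],
    expected_partners: Optional[Sequence[str]] = None,
) -> ComorbidityProfile:
    """Expected comorbidity burden for one index condition.

    ``m_expected`` is the sum over partner conditions of the conditional
    prevalences Pij/Pi.  Each partner must appear exactly once; if
    ``expected_partners`` is given, the pairs must cover it exactly.
    """
    if not pairs:
        raise ValueError(f"no partner pairs supplied for index {index!r}")
    conditionals: dict[str, float] = {}
    for pp in pairs:
        partner = pp.partner_of(index)
        if partner in conditionals:
            raise ValueError(f"duplicate partner condition {partner!r} for {index!r}")
        conditionals[partner] = pp.conditional_on(index)
    if expected_partners is not None:
        missing = set(expected_partners) - set(conditionals)
        extra = set(conditionals) - set(expected_partners)
        if missing or extra:
            raise ValueError(
                f"partner mismatch for {index!r}: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
    return ComorbidityProfile(
        index_condition=index,
        conditionals=conditionals,
        m_expected=float(sum(conditionals.values())),
    )


def fit_comorbidity_regression(
    profiles: Sequence[ComorbidityProfile],
    prevalences: Sequence[PrevalenceEstimate],
) -> tuple[float, float, float]:
    """Log-linear regression of the comorbidity count on index prevalence.

    Fits ln(Mi) = a + b * Pi by ordinary least squares across index
    conditions and reports (slope, factor per 10-percentage-point increase
    in prevalence = exp(0.10 * slope), Pearson r between ln Mi and Pi).
    """
    prev_by_cond: Mapping[str, PrevalenceEstimate] = {
        p.condition: p for p in prevalences
    }
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for the regression")
    mi, pi = [], []
    for prof in profiles:
        if prof.m_expected <= 0:
            raise ValueError(
                f"m_expected must be positive for the log scale "
                f"({prof.index_condition}: {prof.m_expected})"
            )
        mi.append(prof.m_expected)
        pi.append(prev_by_cond[prof.index_condition].prev)
    log_m = np.log(mi)
    res = stats.linregress(pi, log_m)
    slope = float(res.slope)
    r = float(res.rvalue) if np.std(log_m) > 0 else 0.0
    return slope, float(np.exp(0.10 * slope)), r
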