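"""Parametric bootstrap for joint-prevalence and comorbidity uncertainty.

Each iteration resamples the inputs from their assumed sampling
distributions — marginal prevalences from independent normals (truncated to
a small open interval inside (0, 1)), the association either as a normal on
the pooled log OR or as a multivariate normal on the meta-regression
coefficients (m, c) honouring their covariance — and re-solves the quadratic
for the joint prevalence.  CIs are percentile intervals of the replicates;
the variance of the expected comorbidity count Mi is approximated as the
sum of the per-pair conditional variances, treating pairs as independent.

All draws for a pair come from a single seeded generator in a fixed order
(Pi block, Pj block, association block), so results are bit-reproducible
given (seed, n_iter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .joint import Z95, PrevalenceEstimate, solve_joint_prevalence, frechet_bounds
from .synthesis import PairAssociation


@dataclass
class BootstrapConfig:
    """Settings for the parametric bootstrap."""

    n_iter: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    prevalence_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100 for CI output")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")
        if not (0 < self.prevalence_floor < 0.5):
            raise ValueError("prevalence_floor must be a small positive real")


@dataclass
class PairBootstrap:
    """Replicate vectors and percentile CIs for one condition pair."""

    cond_a: str
    cond_b: str
    p_i: np.ndarray
    p_j: np.ndarray
    theta: np.ndarray
    p_ij: np.ndarray
    ci_low: float
    ci_high: float
    theta_ci_low: float
    theta_ci_high: float
    n_redrawn: int = 0

    def conditional_replicates(self, index: str) -> np.ndarray:
        """Replicates of the conditional prevalence P(partner | index)."""
        if index == self.cond_a:
            return self.p_ij / self.p_i
        if index == self.cond_b:
            return self.p_ij / self.p_j
        raise KeyError(f"{index!r} is not part of pair ({self.cond_a}, {self.cond_b})")


@dataclass
class ComorbidityBootstrap:
    """Uncertainty summary for an expected comorbidity count Mi."""

    index_condition: str
    m_expected: float
    var_m: float
    ci_low: float
    ci_high: float
    percentile_ci_low: float
    percentile_ci_high: float


def _draw_theta(
    assoc: PairAssociation, p_i: np.ndarray, p_j: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(p_i)
    if assoc.mode == "metareg":
        mc = rng.multivariate_normal(
            [assoc.slope_m, assoc.intercept_c], assoc.cov_mc, size=n, method="svd"
        )
        return np.exp(mc[:, 0] * p_i * p_j + mc[:, 1])
    return np.exp(rng.normal(assoc.pooled_log_or, assoc.pooled_se, size=n))


def bootstrap_pair(
    prev_i: PrevalenceEstimate,
    prev_j: PrevalenceEstimate,
    assoc: PairAssociation,
    cfg: BootstrapConfig,
    rng: Optional[np.random.Generator] = None,
) -> PairBootstrap:
    """Parametric bootstrap of the joint prevalence for one pair.

    Out-of-range prevalence draws are truncated (not redrawn) to
    (floor, 1 - floor), preserving the iteration count and draw order;
    redraws are reserved for the rare iterations where the quadratic has no
    valid root, and more than 1% of such failures is an error.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_iter
    lo_p, hi_p = cfg.prevalence_floor, 1.0 - cfg.prevalence_floor

    p_i = np.clip(rng.normal(prev_i.prev, prev_i.se, size=n), lo_p, hi_p)
    p_j = np.clip(rng.normal(prev_j.prev, prev_j.se, size=n), lo_p, hi_p)
    theta = np.maximum(_draw_theta(assoc, p_i, p_j, rng), 1e-300)

    p_ij = np.empty(n)
    pending = np.arange(n)
    n_redrawn = 0
    for attempt in range(20):
        a = 1.0 + (theta[pending] - 1.0) * (p_i[pending] + p_j[pending])
        disc = a * a - 4.0 * theta[pending] * (theta[pending] - 1.0) * p_i[pending] * p_j[pending]
        bad = disc < -1e-12
        good = ~bad
        idx = pending[good]
        near1 = np.abs(theta[idx] - 1.0) < 1e-8
        tm1 = np.where(near1, 1.0, theta[idx] - 1.0)
        root = (a[good] - np.sqrt(np.maximum(disc[good], 0.0))) / (2.0 * tm1)
        vals = np.where(near1, p_i[idx] * p_j[idx], root)
        lo_f, hi_f = frechet_bounds(p_i[idx], p_j[idx])
        p_ij[idx] = np.clip(vals, lo_f, hi_f)
        pending = pending[bad]
        if pending.size == 0:
            break
        # redraw the failed iterations in place
        n_redrawn += pending.size
        p_i[pending] = np.clip(
            rng.normal(prev_i.prev, prev_i.se, size=pending.size), lo_p, hi_p
        )
        p_j[pending] = np.clip(
            rng.normal(prev_j.prev, prev_j.se, size=pending.size), lo_p, hi_p
        )
        theta[pending] = np.maximum(
            _draw_theta(assoc, p_i[pending], p_j[pending], rng), 1e-300
        )
    else:
        raise RuntimeError(
            f"bootstrap failed for pair ({prev_i.condition}, {prev_j.condition}): "
            f"{pending.size} iterations unresolved after 20 redraw rounds"
        )
    if n_redrawn > 0.01 * n:
        raise RuntimeError(
            f"bootstrap for pair ({prev_i.condition}, {prev_j.condition}) redrew "
            f"{n_redrawn}/{n} iterations (> 1%); inputs look inconsistent"
        )

    alpha = 1.0 - cfg.ci_level
    qs = [alpha / 2.0, 1.0 - alpha / 2.0]
    ci = np.quantile(p_ij, qs)
    theta_ci = np.quantile(theta, qs)
    return PairBootstrap(
        cond_a=prev_i.condition,
        cond_b=prev_j.condition,
        p_i=p_i,
        p_j=p_j,
        theta=theta,
        p_ij=p_ij,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        theta_ci_low=float(theta_ci[0]),
        theta_ci_high=float(theta_ci[1]),
        n_redrawn=n_redrawn,
    )


def bootstrap_comorbidity(
    index: str,
    pair_boots: Sequence[PairBootstrap],
    m_expected: float,
    ci_level: float = 0.95,
) -> ComorbidityBootstrap:
    """Propagate per-pair bootstrap replicates into the Mi uncertainty.

    var(Mi) = sum over partners of var(Pij/Pi replicates), assuming
    independence between pairs; the normal-approximation CI is
    Mi +/- z * sqrt(var), and a percentile CI of the summed conditional
    replicates is reported alongside.
    """
    if not pair_boots:
        raise ValueError(f"no pair replicates supplied for index {index!r}")
    lengths = {len(pb.p_ij) for pb in pair_boots}
    if len(lengths) != 1:
        raise ValueError(f"mismatched replicate lengths across pairs: {sorted(lengths)}")
    cond_reps = np.stack([pb.conditional_replicates(index) for pb in pair_boots])
    var_m = float(np.sum(np.var(cond_reps, axis=1, ddof=1)))
    half = Z95 * np.sqrt(var_m)
    total = cond_reps.sum(axis=0)
    alpha = 1.0 - ci_level
    pct = np.quantile(total, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ComorbidityBootstrap(
        index_condition=index,
        m_expected=m_expected,
        var_m=var_m,
        ci_low=float(m_expected - half),
        ci_high=float(m_expected + half),
        percentile_ci_low=float(pct[0]),
        percentile_ci_high=float(pct[1]),
    )
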