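"""Pooling pairwise disease associations across heterogeneous studies.

Two synthesis routes are provided per condition pair:

* random-effects pooling of log odds ratios (DerSimonian–Laird tau^2), used
  when fewer than three study estimates exist;
* random-effects meta-regression of the log OR on the product of the two
  study-level prevalences (REML tau^2 with a method-of-moments fallback),
  used when three or more estimates exist.  The prevalence product is the
  expected prevalence of the combination under independence; ORs fall with
  it when study sampling frames under-represent healthy individuals, so the
  regression standardises associations to a target prevalence level.

A third mode carries a fixed, externally pooled OR for pairs with no local
evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .contingency import StudyRecord

MODES = ("pooled", "metareg", "fixed")


@dataclass
class PairAssociation:
    """Synthesised association between two conditions.

    ``mode`` selects which fields are meaningful: pooled/fixed carry
    ``pooled_log_or`` and ``pooled_se``; metareg carries the slope ``m`` on
    the prevalence product, intercept ``c``, and their 2x2 covariance
    ``cov_mc`` (ordered (m, c)).
    """

    cond_a: str
    cond_b: str
    mode: str
    k_studies: int
    pooled_log_or: Optional[float] = None
    pooled_se: Optional[float] = None
    slope_m: Optional[float] = None
    intercept_c: Optional[float] = None
    cov_mc: Optional[np.ndarray] = None
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "metareg":
            if self.k_studies < 3:
                raise ValueError("metareg mode requires k_studies >= 3")
            cov = np.asarray(self.cov_mc, dtype=float)
            if cov.shape != (2, 2):
                raise ValueError("cov_mc must be 2x2")
            if not np.allclose(cov, cov.T):
                raise ValueError("cov_mc must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError("cov_mc must be positive semi-definite")
            self.cov_mc = cov
        else:
            if self.pooled_se is None or not (self.pooled_se >= 0):
                raise ValueError("pooled mode requires nonnegative pooled_se")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.cond_a, self.cond_b)))


def _effects(records: Sequence[StudyRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValueError("no study records supplied")
    y, se = zip(*(r.effect() for r in records))
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(se)):
        raise ValueError("non-finite study effect encountered")
    if np.any(se <= 0):
        raise ValueError("all study standard errors must be positive")
    return y, se


def dersimonian_laird_tau2(y: np.ndarray, se: np.ndarray) -> float:
    """Moment estimator of the between-study variance, floored at zero."""
    if len(y) < 2:
        return 0.0
    w = 1.0 / se**2
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (len(y) - 1)) / denom)


def pool_random_effects(records: Sequence[StudyRecord]) -> PairAssociation:
    """DerSimonian–Laird random-effects pooled log OR for one pair.

    Weights are 1/(se_i^2 + tau^2); the pooled SE is sqrt(1/sum of weights).
    """
    y, se = _effects(records)
    tau2 = dersimonian_laird_tau2(y, se)
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(math.sqrt(1.0 / np.sum(w)))
    return PairAssociation(
        cond_a=records[0].cond_a,
        cond_b=records[0].cond_b,
        mode="pooled",
        k_studies=len(records),
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        tau2=tau2,
    )


def _reml_nll(tau2: float, y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    xtwx = (X.T * w) @ X
    beta = np.linalg.solve(xtwx, (X.T * w) @ y)
    resid = y - X @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    return 0.5 * (-np.sum(np.log(w)) + logdet + np.sum(w * resid**2))


def _metareg_mm_tau2(y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments tau^2 for weighted regression (generalised Q)."""
    w = 1.0 / v
    xtwx_inv = np.linalg.inv((X.T * w) @ X)
    beta = xtwx_inv @ ((X.T * w) @ y)
    resid = y - X @ beta
    q_e = float(np.sum(w * resid**2))
    # trace of P = W - W X (X'WX)^-1 X'W
    tr_p = float(np.sum(w) - np.trace(xtwx_inv @ ((X.T * (w**2)) @ X)))
    k, p = X.shape
    if tr_p <= 0:
        return 0.0
    return max(0.0, (q_e - (k - p)) / tr_p)


def fit_meta_regression(
    records: Sequence[StudyRecord], knapp_hartung: bool = False
) -> PairAssociation:
    """Random-effects meta-regression of log OR on the prevalence product.

    tau^2 is estimated by restricted maximum likelihood (1-D profile over
    the restricted log-likelihood), falling back to the method-of-moments
    estimator if the profile optimisation fails.  The coefficient covariance
    is the inverse weighted-information matrix (X'WX)^-1 at the final tau^2,
    optionally rescaled by the Knapp–Hartung variance factor.
    """
    if len(records) < 3:
        raise ValueError(
            "meta-regression requires >= 3 study records; use pool_random_effects"
        )
    y, se = _effects(records)
    x = np.array([r.moderator for r in records], dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("every record needs study prevalences for the moderator")
    if np.ptp(x) == 0:
        raise ValueError("degenerate moderator: prevalence product constant across studies")
    v = se**2
    X = np.column_stack([np.ones_like(x), x])  # columns: intercept c, slope m

    ub = max(10.0 * float(np.var(y)), 1.0)
    tau2 = None
    try:
        res = minimize_scalar(
            _reml_nll, bounds=(0.0, ub), args=(y, X, v), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.success and np.isfinite(res.fun):
            tau2 = float(res.x)
            if _reml_nll(0.0, y, X, v) <= res.fun:
                tau2 = 0.0
    except np.linalg.LinAlgError:
        tau2 = None
    if tau2 is None:
        tau2 = _metareg_mm_tau2(y, X, v)

    w = 1.0 / (v + tau2)
    wls = sm.WLS(y, X, weights=w).fit()
    c_hat, m_hat = wls.params
    cov_cm = np.linalg.inv((X.T * w) @ X)
    if knapp_hartung:
        resid = y - X @ np.array([c_hat, m_hat])
        s2 = float(np.sum(w * resid**2) / (len(y) - 2))
        cov_cm = cov_cm * max(s2, 1.0)
    # reorder covariance from (c, m) to (m, c)
    perm = np.array([[0, 1], [1, 0]], dtype=float)
    cov_mc = perm @ cov_cm @ perm.T
    cov_mc = (cov_mc + cov_mc.T) / 2.0
    return PairAssociation(
        cond_a=records[0].cond_a,
        cond_b=records[0].cond_b,
        mode="metareg",
        k_studies=len(records),
        slope_m=float(m_hat),
        intercept_c=float(c_hat),
        cov_mc=cov_mc,
        tau2=float(tau2),
    )


def select_synthesis(
    records: Sequence[StudyRecord],
    fixed_or: Optional[tuple[float, float]] = None,
    cond_a: Optional[str] = None,
    cond_b: Optional[str] = None,
    knapp_hartung: bool = False,
) -> PairAssociation:
    """Choose the synthesis route for one pair.

    Meta-regression when three or more study estimates exist, simple
    random-effects pooling otherwise; a fixed external OR (given as
    ``(odds_ratio, se_log_or)``) is used only when no local records exist.
    """
    records = list(records)
    if not records:
        if fixed_or is None:
            raise ValueError("no evidence for pair")
        theta, se = fixed_or
        if theta <= 0 or se < 0:
            raise ValueError("fixed OR must be positive with nonnegative SE")
        return PairAssociation(
            cond_a=cond_a or "A",
            cond_b=cond_b or "B",
            mode="fixed",
            k_studies=1,
            pooled_log_or=math.log(theta),
            pooled_se=float(se),
            tau2=0.0,
        )
    if len(records) >= 3:
        return fit_meta_regression(records, knapp_hartung=knapp_hartung)
    return pool_random_effects(records)


def predict_or(assoc: PairAssociation, prev_a: float, prev_b: float) -> float:
    """Expected OR at the given marginal prevalences.

    Meta-regression mode evaluates theta = exp(m * Pa * Pb + c); pooled and
    fixed modes return exp(pooled log OR), independent of the prevalences.
    """
    if not (0 < prev_a < 1 and 0 < prev_b < 1):
        raise ValueError("prevalences must lie in (0, 1)")
    if assoc.mode == "metareg":
        return float(np.exp(assoc.slope_m * prev_a * prev_b + assoc.intercept_c))
    return float(np.exp(assoc.pooled_log_or))
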