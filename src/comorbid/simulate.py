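"""Synthetic study series and packaged national input tables.

The generator draws, for each simulated study, a pair of study-level
prevalences, a log OR from the surface log theta = c + m * Pi * Pj plus
between-study noise, converts these to 2x2 cell probabilities through the
joint-prevalence quadratic, optionally distorts the sampling frame by
down-weighting the no-condition cell (facility samples retain fewer healthy
individuals), and draws cell counts from a multinomial.  Down-weighting the
no-condition cell by a retention factor phi multiplies the cross-product
odds ratio by exactly phi, which is the mechanism that makes observed ORs
fall as the expected prevalence of the combination rises.

Also packaged here are the national South African input tables used in the
worked examples: marginal prevalence estimates (ages 15+) with 95% CIs for
the ten modelled conditions, and published pooled odds ratios for a few
strongly associated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, StudyRecord
from .joint import solve_joint_prevalence

Interval = tuple[float, float]

# National prevalence estimates, ages 15 and older: percent (95% CI).
# Sources: national household surveys (WHS 2003, DHS 2016, SANHANES 2012,
# SASH 2002-4) and calibrated national epidemic models for HIV and TB.
_NATIONAL_PREVALENCE_15PLUS = [
    # condition, prev %, ci_low %, ci_high %
    ("Arthritis", 11.3, 8.9, 13.7),
    ("Asthma", 3.5, 3.1, 4.0),
    ("COPD", 1.8, 1.5, 2.2),
    ("Depression", 4.9, 3.9, 5.9),
    ("Diabetes", 10.2, 8.9, 11.7),
    ("HIV", 18.2, 17.5, 18.6),
    ("Hypertension", 33.9, 31.8, 36.1),
    ("IHD", 5.6, 4.5, 6.9),
    ("Stroke", 2.6, 2.0, 3.5),
    ("Tuberculosis", 0.99, 0.95, 1.04),
]

# Published pooled odds ratios (95% CI) for the most strongly associated
# pairs, standardised to the national prevalence levels above.
_REFERENCE_ODDS_RATIOS = [
    # cond_a, cond_b, OR, ci_low, ci_high
    ("COPD", "Asthma", 14.6, 10.3, 19.9),
    ("COPD", "IHD", 9.2, 8.3, 10.2),
    ("IHD", "Stroke", 7.2, 5.9, 8.4),
    ("HIV", "Arthritis", 0.57, 0.47, 0.68),
    ("HIV", "Diabetes", 0.59, 0.35, 0.95),
]


def make_national_fixture(units: str = "proportion") -> pd.DataFrame:
    """National marginal prevalence table for the ten modelled conditions.

    Columns: condition, prev, ci_low, ci_high — as proportions by default,
    or on the percent scale with ``units="percent"``.
    """
    df = pd.DataFrame(
        _NATIONAL_PREVALENCE_15PLUS, columns=["condition", "prev", "ci_low", "ci_high"]
    )
    if units == "proportion":
        df[["prev", "ci_low", "ci_high"]] /= 100.0
    elif units != "percent":
        raise ValueError("units must be 'proportion' or 'percent'")
    return df


def reference_odds_ratios() -> pd.DataFrame:
    """Published pooled ORs for strongly associated condition pairs."""
    return pd.DataFrame(
        _REFERENCE_ODDS_RATIOS,
        columns=["cond_a", "cond_b", "odds_ratio", "ci_low", "ci_high"],
    )


@dataclass
class SimulationScenario:
    """Generative settings for a simulated study series.

    The log-OR surface is log theta = intercept_c + slope_m * Pi * Pj with
    between-study SD ``tau``.  ``study_size`` and ``healthy_retention`` may
    be scalars or (low, high) ranges sampled per study; a retention below 1
    emulates facility-based sampling frames that under-represent people
    with no conditions.
    """

    slope_m: float
    intercept_c: float
    tau: float = 0.0
    k_studies: int = 10
    study_size: Union[int, Interval] = 1000
    prev_range_a: Interval = (0.05, 0.3)
    prev_range_b: Interval = (0.05, 0.3)
    healthy_retention: Union[float, Interval] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.k_studies < 0:
            raise ValueError("k_studies must be nonnegative")
        for rng_ in (self.prev_range_a, self.prev_range_b):
            if not (0 < rng_[0] <= rng_[1] < 1):
                raise ValueError(f"prevalence range {rng_} outside (0, 1)")
        sizes = self.study_size if isinstance(self.study_size, tuple) else (self.study_size,)
        if min(sizes) < 20:
            raise ValueError("study_size must be at least 20")
        ret = (
            self.healthy_retention
            if isinstance(self.healthy_retention, tuple)
            else (self.healthy_retention,)
        )
        if not all(0 < r <= 1 for r in ret):
            raise ValueError("healthy_retention must lie in (0, 1]")


def cell_probabilities(p_i: float, p_j: float, p_ij: float) -> np.ndarray:
    """2x2 cell probabilities (both, i only, j only, neither) from marginals and joint."""
    cells = np.array(
        [p_ij, p_i - p_ij, p_j - p_ij, 1.0 - p_i - p_j + p_ij], dtype=float
    )
    if np.any(cells < 0):
        raise ValueError(
            f"negative cell probability for (p_i={p_i}, p_j={p_j}, p_ij={p_ij})"
        )
    return cells


def apply_healthy_exclusion(cells: np.ndarray, retention: float) -> np.ndarray:
    """Down-weight the no-condition cell by ``retention`` and renormalise.

    Scaling a single off-diagonal-free cell multiplies the cross-product
    odds ratio by exactly the retention factor.
    """
    if retention <= 0:
        raise ValueError("retention must be positive")
    cells = np.asarray(cells, dtype=float)
    if abs(cells.sum() - 1.0) > 1e-9:
        raise ValueError("cells must sum to 1")
    out = cells.copy()
    out[3] *= retention
    return out / out.sum()


def _draw(rng: np.random.Generator, value: Union[float, Interval]) -> float:
    if isinstance(value, tuple):
        return float(rng.uniform(value[0], value[1]))
    return float(value)


def simulate_study_series(scenario: SimulationScenario) -> list[StudyRecord]:
    """Simulate a series of studies from the log-OR surface.

    Per study: draw (Pi, Pj) uniformly from the scenario ranges, draw
    log theta about the surface, solve the quadratic for the joint
    prevalence, optionally apply the healthy-exclusion distortion, and draw
    cell counts from a multinomial of the study size.  Deterministic given
    the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    records: list[StudyRecord] = []
    n_redrawn = 0
    for k in range(scenario.k_studies):
        for _ in range(100):
            p_i = rng.uniform(*scenario.prev_range_a)
            p_j = rng.uniform(*scenario.prev_range_b)
            log_theta = (
                scenario.intercept_c
                + scenario.slope_m * p_i * p_j
                + (rng.normal(0.0, scenario.tau) if scenario.tau > 0 else 0.0)
            )
            try:
                p_ij = solve_joint_prevalence(p_i, p_j, float(np.exp(log_theta)))
                cells = cell_probabilities(p_i, p_j, p_ij)
            except ValueError:
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError(
                f"study {k}: no feasible draw after 100 attempts "
                f"({n_redrawn} redraws so far)"
            )
        retention = _draw(rng, scenario.healthy_retention)
        if retention < 1.0:
            cells = apply_healthy_exclusion(cells, retention)
        size = _draw(rng, scenario.study_size)
        counts = rng.multinomial(int(round(size)), cells)
        # multinomial can empty a margin in tiny studies; such a table is
        # still a valid record, the OR step applies its correction
        records.append(
            StudyRecord(
                study_id=f"sim-{scenario.seed}-{k:03d}",
                cond_a="A",
                cond_b="B",
                table=ContingencyTable(*[int(c) for c in counts]),
            )
        )
    return records
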