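"""Per-study 2x2 contingency tables: odds ratios and study-level prevalences.

Each study contributes, for one pair of conditions, either the four cell
counts of a 2x2 table or a precomputed log odds ratio with its standard
error.  Tables are reduced to (log OR, SE) with the Woolf variance formula,
adding a Haldane–Anscombe continuity correction of 0.5 to all four cells
when any cell is zero.  The table margins also yield the study-level
prevalences whose product serves as the meta-regression moderator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


class DegenerateTableError(ValueError):
    """Raised when a 2x2 table cannot support an odds ratio."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for a pair of binary conditions.

    ``n11`` has both conditions, ``n10`` condition A only, ``n01`` condition
    B only, ``n00`` neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        cells = (self.n11, self.n10, self.n01, self.n00)
        for c in cells:
            if int(c) != c or c < 0:
                raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if sum(cells) < 1:
            raise DegenerateTableError("empty table")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def transposed(self) -> "ContingencyTable":
        """Swap the roles of the two conditions."""
        return ContingencyTable(self.n11, self.n01, self.n10, self.n00)


def compute_odds_ratio(
    table: ContingencyTable, correction: float = 0.5
) -> tuple[float, float]:
    """Unadjusted log odds ratio and its Woolf standard error.

    When any cell is zero, ``correction`` is added to *all four* cells
    (Haldane–Anscombe); tables with no zero cell are used as-is.

    Returns
    -------
    (log_or, se_log_or)
        Natural-log odds ratio and sqrt of the summed reciprocal cells.
    """
    if correction < 0:
        raise ValueError("correction must be nonnegative")
    cells = [float(table.n11), float(table.n10), float(table.n01), float(table.n00)]
    if min(cells) == 0.0:
        cells = [c + correction for c in cells]
    if min(cells) <= 0.0:
        # diagnose which margin is empty: a full zero row/column cannot be
        # rescued by any cell-wise correction rule the caller disabled
        a, b, c, d = table.n11, table.n10, table.n01, table.n00
        margins = {
            "row A=1": a + b,
            "row A=0": c + d,
            "col B=1": a + c,
            "col B=0": b + d,
        }
        empty = [k for k, v in margins.items() if v == 0]
        raise DegenerateTableError(
            "odds ratio undefined: zero cells remain after correction"
            + (f" (empty margins: {', '.join(empty)})" if empty else "")
        )
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return log_or, se


def study_prevalences(table: ContingencyTable) -> tuple[float, float]:
    """Marginal prevalences of conditions A and B in the study sample."""
    n = table.total
    return (table.n11 + table.n10) / n, (table.n11 + table.n01) / n


@dataclass
class StudyRecord:
    """One study's evidence for one condition pair.

    Exactly one evidence source must be present: either ``table`` or the
    pair ``(log_or, se_log_or)``.  When a table is given the study-level
    prevalences are derived from its margins (overriding any supplied
    values) so that the meta-regression moderator is internally consistent.
    """

    study_id: str
    cond_a: str
    cond_b: str
    table: Optional[ContingencyTable] = None
    log_or: Optional[float] = None
    se_log_or: Optional[float] = None
    prev_a: Optional[float] = None
    prev_b: Optional[float] = None
    correction: float = field(default=0.5, repr=False)

    def __post_init__(self) -> None:
        if self.cond_a == self.cond_b:
            raise ValueError(f"cond_a == cond_b ({self.cond_a!r})")
        has_table = self.table is not None
        has_effect = self.log_or is not None or self.se_log_or is not None
        if has_table == has_effect:
            raise ValueError(
                f"study {self.study_id!r}: exactly one of table or "
                "(log_or, se_log_or) must be supplied"
            )
        if has_effect:
            if self.log_or is None or self.se_log_or is None:
                raise ValueError(
                    f"study {self.study_id!r}: log_or and se_log_or must both be given"
                )
            if not (self.se_log_or > 0):
                raise ValueError(f"study {self.study_id!r}: se_log_or must be positive")
        else:
            self.prev_a, self.prev_b = study_prevalences(self.table)
        for name, p in (("prev_a", self.prev_a), ("prev_b", self.prev_b)):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"study {self.study_id!r}: {name}={p} outside [0, 1]")

    def effect(self) -> tuple[float, float]:
        """(log OR, SE), computing from the table if that is the source."""
        if self.table is not None:
            return compute_odds_ratio(self.table, self.correction)
        return float(self.log_or), float(self.se_log_or)

    @property
    def moderator(self) -> Optional[float]:
        """Product of study prevalences, the 'expected prevalence' under independence."""
        if self.prev_a is None or self.prev_b is None:
            return None
        return self.prev_a * self.prev_b
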