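"""Descriptive statistics over clinical cohort tables.

Summaries follow the conventions of clinical tables: arithmetic mean age to one
decimal, sample (n-1 denominator) standard deviation to one decimal, mean days
post injury to two decimals, and a per-grade AIS census. Rounding is decimal
half-up, the convention of hand-reported clinical summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import InvalidParameterError
from .io_formats import CohortTable


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupSummary:
    """Printed-precision summary of one cohort group.

    ``sd_age`` is NaN when the group has a single member (sample SD undefined).
    """

    n: int
    mean_age: float
    sd_age: float
    mean_dpi: float
    grade_counts: dict[str, int]


def summarize_group(table: CohortTable) -> GroupSummary:
    """Mean/SD age, mean days post injury and AIS grade counts for one group."""
    if len(table) == 0:
        raise InvalidParameterError("cannot summarize an empty cohort table")
    ages = table.df["age"].to_numpy(dtype=float)
    dpi = table.df["days_post_injury"].to_numpy(dtype=float)
    n = len(ages)
    mean_age = _round_half_up(float(ages.mean()), 1)
    if n >= 2:
        sd_age = _round_half_up(float(ages.std(ddof=1)), 1)
    else:
        sd_age = math.nan
    mean_dpi = _round_half_up(float(dpi.mean()), 2)
    grade_counts = table.df["ais_grade"].value_counts().to_dict()
    return GroupSummary(n=n, mean_age=mean_age, sd_age=sd_age,
                        mean_dpi=mean_dpi, grade_counts=grade_counts)
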