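"""Johnson–Bickel systematic-response screening and point-based AUC.

Two rule-based criteria flag non-systematic indifference-point series:

* JB1 (local): no indifference point may exceed its predecessor by more
  than a fraction ``c1`` (default 20%) of the undiscounted amount A —
  strict inequality, so a rise of exactly ``c1*A`` is not a violation.
* JB2 (global): the last indifference point must be below the first by at
  least a fraction ``c2`` (default 10%) of A — weak inequality.

Point-based AUC is the trapezoidal area under the series after
normalizing delays to [0, 1] and values to [0, 1]; lower AUC means
steeper discounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core import Cohort, DiscountingSeries

__all__ = [
    "CriteriaConfig",
    "ScreenResult",
    "ScreeningError",
    "jb_screen",
    "auc",
    "screen_cohort",
]


class ScreeningError(ValueError):
    """Series cannot be screened as-is (e.g., missing values)."""


@dataclass(frozen=True)
class CriteriaConfig:
    """Bounds for the two criteria, as fractions of the undiscounted amount."""

    c1: float = 0.20
    c2: float = 0.10
    allowed_jb1_violations: int = 0

    def __post_init__(self):
        if not (0 < self.c1 < 1):
            raise ValueError(f"c1 must be in (0, 1), got {self.c1}")
        if not (0 <= self.c2 < 1):
            raise ValueError(f"c2 must be in [0, 1), got {self.c2}")
        if self.allowed_jb1_violations < 0:
            raise ValueError("allowed_jb1_violations must be >= 0")


@dataclass
class ScreenResult:
    jb1_pass: bool
    jb1_violation_count: int
    jb2_pass: bool
    both_pass: bool
    auc: float | None = None


def _require_complete(series: DiscountingSeries) -> np.ndarray:
    v = np.asarray(series.values, dtype=float)
    if v.size < 2:
        raise ValueError("screening requires at least two delays")
    if np.isnan(v).any():
        raise ScreeningError(
            f"series {series.participant_id!r} has missing values; impute or "
            "drop before screening (see screen_cohort(missing=...))"
        )
    return v


def jb_screen(series: DiscountingSeries, config: CriteriaConfig = CriteriaConfig()) -> ScreenResult:
    """Apply the two criteria to one complete series (AUC left unfilled)."""
    v = _require_complete(series)
    A = series.task.magnitude
    # literal form "greater than the preceding point by c1*A" so exact
    # boundary values behave identically however the bound is computed
    violations = int(np.sum(v[1:] > v[:-1] + config.c1 * A))
    jb1 = violations <= config.allowed_jb1_violations
    jb2 = bool(v[0] - v[-1] >= config.c2 * A)
    return ScreenResult(
        jb1_pass=jb1, jb1_violation_count=violations,
        jb2_pass=jb2, both_pass=jb1 and jb2,
    )


def auc(series: DiscountingSeries, *, include_origin: bool = False) -> float:
    """Point-based area under the curve, in [0, 1].

    Delays are normalized over the observed span (d_1 -> 0, d_m -> 1) and
    values by the undiscounted amount.  ``include_origin`` prepends an
    imputed point (x=0, y=1) before the first measured delay; by default
    only measured points are interpolated.
    """
    v = _require_complete(series)
    y = v / series.task.magnitude
    x = series.task.normalized_delays()
    if include_origin:
        d = np.asarray(series.task.delays, dtype=float)
        x = np.concatenate([[0.0], d / d[-1]])
        y = np.concatenate([[1.0], y])
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def screen_cohort(
    cohort: Cohort,
    config: CriteriaConfig = CriteriaConfig(),
    *,
    missing: Literal["error", "drop", "interpolate"] = "error",
    include_origin: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every series; return (per-participant table, summary table).

    The per-participant table has columns participant_id, jb1_pass,
    jb1_violations, jb2_pass, both_pass, auc.  The summary mirrors the
    usual cohort report: counts and percentages (2 decimals) of series
    passing JB1, JB2, and both, over the screened N.

    ``missing`` selects the policy for incomplete series: raise, drop the
    participant, or linearly interpolate interior gaps over delay (series
    missing their first or last point are always dropped).  Dropped series
    are counted in the summary's ``n_excluded``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = []
    n_excluded = 0
    for s in cohort.series:
        if not s.is_complete:
            if missing == "error":
                _require_complete(s)  # raises ScreeningError
            elif missing == "drop":
                n_excluded += 1
                continue
            else:
                v = s.values.copy()
                if np.isnan(v[0]) or np.isnan(v[-1]):
                    n_excluded += 1
                    continue
                d = np.asarray(s.task.delays)
                ok = ~np.isnan(v)
                v = np.interp(d, d[ok], v[ok])
                s = DiscountingSeries(s.participant_id, s.task, v)
        res = jb_screen(s, config)
        res.auc = auc(s, include_origin=include_origin)
        rows.append({
            "participant_id": s.participant_id,
            "jb1_pass": res.jb1_pass,
            "jb1_violations": res.jb1_violation_count,
            "jb2_pass": res.jb2_pass,
            "both_pass": res.both_pass,
            "auc": res.auc,
        })
    table = pd.DataFrame(
        rows, columns=["participant_id", "jb1_pass", "jb1_violations",
                       "jb2_pass", "both_pass", "auc"],
    )
    n = len(table)
    summary = pd.DataFrame({
        "criterion": ["Systematic Local (JB1)", "Systematic Global (JB2)",
                      "Both Systematic"],
        "count": [int(table["jb1_pass"].sum()), int(table["jb2_pass"].sum()),
                  int(table["both_pass"].sum())] if n else [0, 0, 0],
    })
    summary["percentage"] = (
        (100.0 * summary["count"] / n).round(2) if n else np.nan
    )
    summary.attrs["n_screened"] = n
    summary.attrs["n_excluded"] = n_excluded
    return table, summary
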