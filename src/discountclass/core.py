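"""Domain types for delay-discounting data and tabular I/O.

An adjusting-amount delay-discounting task yields, for each participant,
one *indifference point* per delay: the immediate amount judged equal in
value to the fixed delayed amount (the larger-later reward, LLR).  The
containers here hold one task's indifference-point series for a cohort of
participants and support round-trippable CSV storage in long or wide
layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HCP_DELAYS_MONTHS",
    "TaskSpec",
    "DiscountingSeries",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "CohortFormatError",
    "CohortSchemaError",
    "CohortParseError",
    "CohortValidationError",
]

#: Delays of the Human-Connectome-Project-style money choice tasks,
#: in months: 1 mo, 6 mo, 1 y, 3 y, 5 y, 10 y.
HCP_DELAYS_MONTHS: tuple[float, ...] = (1.0, 6.0, 12.0, 36.0, 60.0, 120.0)


class CohortFormatError(ValueError):
    """Required columns missing from an input file."""


class CohortSchemaError(ValueError):
    """Delays in the file do not match the task specification."""


class CohortParseError(ValueError):
    """A cell could not be parsed as a number."""


class CohortValidationError(ValueError):
    """Values violate task invariants (e.g., outside [0, A])."""

    def __init__(self, message: str, participant_ids: Sequence[str] = ()):
        super().__init__(message)
        self.participant_ids = list(participant_ids)


@dataclass(frozen=True)
class TaskSpec:
    """One delay-discounting task: a fixed delayed amount offered at several delays.

    Parameters
    ----------
    magnitude
        Undiscounted amount A of the larger-later reward, in currency
        units (e.g., 200 or 40000).  Must be positive.
    delays
        Strictly increasing delays in months; at least two.
    label
        Free-text task name.
    """

    magnitude: float
    delays: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "delays", tuple(float(d) for d in self.delays))
        if not self.magnitude > 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")
        if len(self.delays) < 2:
            raise ValueError("at least two delays are required")
        if any(d <= 0 for d in self.delays):
            raise ValueError("delays must all be > 0")
        if any(b <= a for a, b in zip(self.delays, self.delays[1:])):
            raise ValueError("delays must be strictly increasing")

    @property
    def n_delays(self) -> int:
        return len(self.delays)

    def normalized_delays(self) -> np.ndarray:
        """Delays mapped affinely onto [0, 1] (first delay -> 0, last -> 1)."""
        d = np.asarray(self.delays, dtype=float)
        return (d - d[0]) / (d[-1] - d[0])


def hcp_task(magnitude: float, label: str = "") -> TaskSpec:
    """Convenience constructor for a task with the six HCP delays."""
    return TaskSpec(magnitude=magnitude, delays=HCP_DELAYS_MONTHS,
                    label=label or f"${magnitude:g} task")


@dataclass
class DiscountingSeries:
    """One participant's indifference points over the task delays.

    ``values[j]`` is the indifference point at ``task.delays[j]`` in
    currency units; missing entries are NaN.  Non-missing values must lie
    in [0, A].
    """

    participant_id: str
    task: TaskSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.task.n_delays,):
            raise ValueError(
                f"series {self.participant_id!r}: expected {self.task.n_delays} "
                f"values, got shape {self.values.shape}"
            )
        v = self.values
        bad = (~np.isnan(v)) & ((v < 0) | (v > self.task.magnitude))
        if bad.any():
            raise CohortValidationError(
                f"series {self.participant_id!r}: values outside "
                f"[0, {self.task.magnitude}] at delays "
                f"{[self.task.delays[j] for j in np.flatnonzero(bad)]}",
                participant_ids=[self.participant_id],
            )

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscountingSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.task == other.task
            and np.allclose(self.values, other.values, atol=1e-6, equal_nan=True)
        )


@dataclass
class Cohort:
    """A list of series sharing one TaskSpec, with optional ground-truth classes.

    ``true_class`` (synthetic cohorts only) maps participant_id to the
    planted generating class, 1-based.
    """

    task: TaskSpec
    series: list[DiscountingSeries] = field(default_factory=list)
    true_class: dict[str, int] | None = None

    def __post_init__(self):
        ids = [s.participant_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(
                f"duplicate participant_ids: {dupes}", participant_ids=dupes
            )
        for s in self.series:
            if s.task != self.task:
                raise CohortValidationError(
                    f"series {s.participant_id!r} has a different TaskSpec"
                )

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.series]

    def complete_subset(self) -> "Cohort":
        """Cohort restricted to series without missing values."""
        keep = [s for s in self.series if s.is_complete]
        tc = None
        if self.true_class is not None:
            ids = {s.participant_id for s in keep}
            tc = {k: v for k, v in self.true_class.items() if k in ids}
        return Cohort(task=self.task, series=keep, true_class=tc)

    def values_matrix(self) -> np.ndarray:
        """N x m matrix of indifference points (NaN where missing)."""
        return np.vstack([s.values for s in self.series]) if self.series else \
            np.empty((0, self.task.n_delays))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.task == other.task
            and len(self) == len(other)
            and all(a == b for a, b in zip(self.series, other.series))
        )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long layout columns:  participant_id, delay_months, indifference_point
#                        [, true_class]
# Wide layout columns:  participant_id, ip_<delay> per delay [, true_class]
# ---------------------------------------------------------------------------

_LONG_COLS = ["participant_id", "delay_months", "indifference_point"]


def _wide_cols(task: TaskSpec) -> list[str]:
    return [f"ip_{d:g}" for d in task.delays]


def read_cohort(path: str | Path, layout: str, task: TaskSpec) -> Cohort:
    """Read a cohort CSV in ``long`` or ``wide`` layout.

    Rows with values outside [0, A] raise :class:`CohortValidationError`
    naming the offending participant_ids; delays in the file must match
    ``task.delays`` exactly.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    df = pd.read_csv(path, dtype={"participant_id": str})
    if layout == "long":
        missing = [c for c in _LONG_COLS if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing required columns: {missing}")
        vals = pd.to_numeric(df["indifference_point"], errors="coerce")
        raw = df["indifference_point"]
        bad_parse = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad_parse.any():
            row = int(np.flatnonzero(bad_parse.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric indifference_point at file row {row + 2} "
                f"(participant {df['participant_id'].iloc[row]!r})"
            )
        df = df.assign(indifference_point=vals)
        file_delays = sorted(set(pd.to_numeric(df["delay_months"])))
        if tuple(float(d) for d in file_delays) != task.delays:
            raise CohortSchemaError(
                f"delays in file {file_delays} do not match task delays "
                f"{list(task.delays)}"
            )
        wide = df.pivot_table(
            index="participant_id", columns="delay_months",
            values="indifference_point", aggfunc="first", sort=False,
        ).reindex(columns=list(task.delays))
        order = df["participant_id"].drop_duplicates().tolist()
        wide = wide.reindex(order)
        tc = None
        if "true_class" in df.columns:
            tc = (
                df.drop_duplicates("participant_id")
                .set_index("participant_id")["true_class"]
                .dropna().astype(int).to_dict()
            )
        return _build_cohort(task, wide.index.tolist(), wide.to_numpy(), tc)

    # wide layout
    if "participant_id" not in df.columns:
        raise CohortFormatError("missing required column: ['participant_id']")
    cols = _wide_cols(task)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        extra_ip = [c for c in df.columns if c.startswith("ip_") and c not in cols]
        if extra_ip or missing:
            raise CohortSchemaError(
                f"delay columns {sorted(missing)} expected but absent"
                + (f"; unexpected delay columns {extra_ip}" if extra_ip else "")
            )
    vals = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna() & df[cols].notna() & (df[cols].astype(str) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise CohortParseError(
            f"non-numeric value in column {cols[j]} at file row {i + 2} "
            f"(participant {df['participant_id'].iloc[i]!r})"
        )
    tc = None
    if "true_class" in df.columns:
        tc = (
            df.set_index("participant_id")["true_class"].dropna().astype(int)
            .to_dict()
        )
    return _build_cohort(task, df["participant_id"].tolist(), vals.to_numpy(), tc)


def _build_cohort(task, ids, matrix, true_class):
    A = task.magnitude
    offenders = [
        pid for pid, row in zip(ids, matrix)
        if np.any((~np.isnan(row)) & ((row < 0) | (row > A)))
    ]
    if offenders:
        raise CohortValidationError(
            f"indifference points outside [0, {A}] for participants: "
            f"{offenders}", participant_ids=offenders,
        )
    series = [
        DiscountingSeries(participant_id=str(pid), task=task, values=row)
        for pid, row in zip(ids, matrix)
    ]
    return Cohort(task=task, series=series, true_class=true_class)


def write_cohort(cohort: Cohort, path: str | Path, layout: str) -> None:
    """Write a cohort CSV (long omits missing rows; wide leaves cells empty)."""
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    tc = cohort.true_class or {}
    if layout == "long":
        rows = []
        for s in cohort.series:
            for d, v in zip(s.task.delays, s.values):
                if np.isnan(v):
                    continue
                row = {
                    "participant_id": s.participant_id,
                    "delay_months": d,
                    "indifference_point": round(float(v), 6),
                }
                if cohort.true_class is not None:
                    row["true_class"] = tc.get(s.participant_id)
                rows.append(row)
        cols = _LONG_COLS + (["true_class"] if cohort.true_class is not None else [])
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        cols = _wide_cols(cohort.task)
        data = {"participant_id": cohort.participant_ids}
        mat = cohort.values_matrix()
        for j, c in enumerate(cols):
            data[c] = np.round(mat[:, j], 6) if len(cohort) else []
        if cohort.true_class is not None:
            data["true_class"] = [tc.get(p) for p in cohort.participant_ids]
        pd.DataFrame(data).to_csv(path, index=False)
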