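"""Containers for irregularly observed functional / longitudinal data.

Data are a ragged collection {(t_ij, Y_ij) : i = 1..n, j = 1..m_i} on a closed
domain T = [a, b]: one smooth latent trajectory per subject, observed with
noise at subject-specific times.  Subjects may have different numbers of
observations and different time points (irregular design); the dense common
design (every subject on the same grid) is the special case where all time
vectors coincide.

Observation order within a subject is preserved as given — nothing downstream
may depend on it — and duplicate times are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "SubjectRecord",
    "FunctionalSample",
    "DemeanedSample",
    "read_long_csv",
    "write_long_csv",
]


@dataclass(frozen=True)
class Domain:
    """Closed interval [a, b] on which trajectories live."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or not np.isfinite(self.b):
            raise ValueError("domain endpoints must be finite")
        if not self.a < self.b:
            raise ValueError(f"domain requires a < b, got [{self.a}, {self.b}]")

    @property
    def width(self) -> float:
        return self.b - self.a

    def middle_half(self) -> tuple[float, float]:
        """The central-50% subinterval, used for noise-variance estimation
        away from boundary effects of the covariance smoother."""
        w = self.width
        return (self.a + 0.25 * w, self.a + 0.75 * w)

    def contains(self, t: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        tol = rtol * self.width
        t = np.asarray(t, dtype=float)
        return (t >= self.a - tol) & (t <= self.b + tol)


@dataclass
class SubjectRecord:
    """Observations for one subject: times t_ij and responses Y_ij."""

    id: Hashable
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"subject {self.id!r}: times (len {self.times.size}) and values "
                f"(len {self.values.size}) must have equal length"
            )
        if self.times.size < 1:
            raise ValueError(f"subject {self.id!r} has no observations")

    @property
    def m(self) -> int:
        return self.times.size


@dataclass
class FunctionalSample:
    """Ragged sample of subjects on a common domain."""

    subjects: list[SubjectRecord]
    domain: Domain

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for s in self.subjects:
            if not np.all(self.domain.contains(s.times)):
                bad = s.times[~self.domain.contains(s.times)]
                raise ValueError(
                    f"subject {s.id!r} has times outside the domain "
                    f"[{self.domain.a}, {self.domain.b}]: {bad[:5]}"
                )

    @property
    def n(self) -> int:
        """Number of subjects."""
        return len(self.subjects)

    @property
    def counts(self) -> np.ndarray:
        """Per-subject observation counts m_i."""
        return np.array([s.m for s in self.subjects], dtype=int)

    @property
    def n_obs(self) -> int:
        """Total observation count N = sum m_i."""
        return int(self.counts.sum()) if self.subjects else 0

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All (t_ij, Y_ij) concatenated in subject order."""
        if not self.subjects:
            return np.empty(0), np.empty(0)
        t = np.concatenate([s.times for s in self.subjects])
        y = np.concatenate([s.values for s in self.subjects])
        return t, y

    def times_list(self) -> list[np.ndarray]:
        return [s.times for s in self.subjects]

    def values_list(self) -> list[np.ndarray]:
        return [s.values for s in self.subjects]

    def with_values(self, values: Sequence[np.ndarray]) -> "FunctionalSample":
        """Copy of this sample with per-subject responses replaced."""
        if len(values) != self.n:
            raise ValueError("need one value vector per subject")
        subs = [
            SubjectRecord(s.id, s.times.copy(), np.asarray(v, dtype=float))
            for s, v in zip(self.subjects, values)
        ]
        return FunctionalSample(subs, self.domain)

    def to_frame(
        self,
        subject_col: str = "subject",
        time_col: str = "time",
        value_col: str = "value",
    ) -> pd.DataFrame:
        rows = {
            subject_col: np.repeat([s.id for s in self.subjects], self.counts)
            if self.subjects
            else np.empty(0, dtype=object),
        }
        t, y = self.pooled()
        rows[time_col] = t
        rows[value_col] = y
        return pd.DataFrame(rows)

    @classmethod
    def from_arrays(
        cls,
        times: np.ndarray,
        values: np.ndarray,
        domain: Domain | None = None,
        ids: Sequence[Hashable] | None = None,
    ) -> "FunctionalSample":
        """Build a balanced sample from (n, m) arrays of times and values."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.shape != values.shape or times.ndim != 2:
            raise ValueError("times and values must be equal-shape (n, m) arrays")
        n = times.shape[0]
        if ids is None:
            ids = list(range(n))
        if domain is None:
            domain = Domain(float(times.min()), float(times.max()))
        subs = [SubjectRecord(ids[i], times[i], values[i]) for i in range(n)]
        return cls(subs, domain)


@dataclass
class DemeanedSample(FunctionalSample):
    """A FunctionalSample whose values are residuals Y_ij - muhat(t_ij).

    Carries a reference to the mean fit that produced it so the bootstrap can
    re-add the estimated mean when regenerating data.
    """

    mean_fit: object = field(default=None, repr=False)


def read_long_csv(
    path,
    subject_col: str = "subject",
    time_col: str = "time",
    value_col: str = "value",
    domain: Domain | None = None,
) -> FunctionalSample:
    """Read long-format repeated-measures data (one row per observation).

    The domain defaults to the observed time range [min t, max t] unless given.
    Subjects and within-subject rows keep file order.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: file has no data rows")
    missing = [c for c in (subject_col, time_col, value_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    for c in (time_col, value_col):
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {c!r} contains non-numeric entries") from exc
    if df[[subject_col, time_col, value_col]].isna().any().any():
        raise ValueError(f"{path}: missing values in subject/time/value columns")

    subjects = [
        SubjectRecord(sid, g[time_col].to_numpy(float), g[value_col].to_numpy(float))
        for sid, g in df.groupby(subject_col, sort=False)
    ]
    if domain is None:
        domain = Domain(float(df[time_col].min()), float(df[time_col].max()))
    return FunctionalSample(subjects, domain)


def write_long_csv(
    sample: FunctionalSample,
    path,
    subject_col: str = "subject",
    time_col: str = "time",
    value_col: str = "value",
) -> None:
    """Write a sample as long CSV; inverse of :func:`read_long_csv` up to
    float round-trip.  An empty sample yields a header-only file."""
    sample.to_frame(subject_col, time_col, value_col).to_csv(path, index=False)
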