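"""Core survival-data containers.

A cohort is the universal input of this package: one observed time and one
event indicator per subject (1 = event, 0 = right-censored), with features or
images carried separately.  A soft assignment is an n x k row-stochastic
matrix of group-membership probabilities; hard labels are the one-hot special
case, which recovers the classical k-sample setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurvivalCohort", "SoftAssignment", "DegenerateCohortError"]


class DegenerateCohortError(ValueError):
    """Raised when a cohort (or mini-batch) contains no observed events."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Right-censored survival data: strictly positive times, 0/1 events."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.float64)
        events = np.asarray(self.events)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be 1D arrays of equal length")
        if not np.all(times > 0):
            raise ValueError("all survival times must be strictly positive")
        if not np.all(np.isin(events, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int64))

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def require_events(self) -> None:
        if self.n_events == 0:
            raise DegenerateCohortError(
                "degenerate cohort: no observed events; the logrank statistic "
                "is undefined without at least one event"
            )

    def subset(self, idx) -> "SurvivalCohort":
        return SurvivalCohort(self.times[idx], self.events[idx])


@dataclass(frozen=True)
class SoftAssignment:
    """n x k row-stochastic matrix of group-membership probabilities."""

    probs: np.ndarray
    _ROW_TOL: float = field(default=1e-9, repr=False)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] < 2:
            raise ValueError("probs must be an n x k matrix with k >= 2")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        rows = probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > self._ROW_TOL):
            worst = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(
                f"row {worst} sums to {rows[worst]:.12f}; rows must sum to 1"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def k(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_labels(cls, labels, k: int | None = None) -> "SoftAssignment":
        """One-hot (hard) assignment from integer labels."""
        labels = np.asarray(labels, dtype=np.int64)
        if k is None:
            k = int(labels.max()) + 1
        probs = np.zeros((labels.shape[0], k))
        probs[np.arange(labels.shape[0]), labels] = 1.0
        return cls(probs)

    @classmethod
    def uniform(cls, n: int, k: int) -> "SoftAssignment":
        return cls(np.full((n, k), 1.0 / k))

    def hard_labels(self) -> np.ndarray:
        return self.probs.argmax(axis=1)
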