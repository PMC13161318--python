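"""The k-sample multivariate logrank statistic and its soft relaxation.

For k groups and unique event times t_1 < ... < t_m the classical statistic
accumulates observed events O_{g,j} and expected events
E_{g,j} = d_j * R_g(t_j) / |R(t_j)| per group and event time, where R_g is
the group's at-risk count and d_j the number of events at t_j.  With
Z_g = sum_j (O_{g,j} - E_{g,j}) and V the hypergeometric variance-covariance
matrix, L = Z^T V^{-1} Z is chi-square with k-1 degrees of freedom under the
null of identical survival curves.

The relaxation replaces the hard group indicator of each subject with a
probability row p_i over the k groups: observed events and at-risk counts
become probability-weighted sums, which makes L a differentiable function of
the assignment matrix while reducing exactly to the classical statistic for
one-hot rows.  Training maximizes L (survival heterogeneity across clusters)
while a barrier on the mean assignment proportions keeps cluster sizes from
collapsing; :func:`partial_logrank_loss` returns the minimization form
``-L + lambda * penalty``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import autodiff as ad
from .cohort import DegenerateCohortError, SoftAssignment, SurvivalCohort

__all__ = [
    "RiskTable",
    "LogrankResult",
    "LossConfig",
    "ConditioningError",
    "build_risk_table",
    "covariance_matrix",
    "multivariate_logrank",
    "balance_penalty",
    "balance_alpha",
    "partial_logrank_loss",
]


class ConditioningError(np.linalg.LinAlgError):
    """Raised when the reduced covariance block cannot be inverted."""


@dataclass(frozen=True)
class RiskTable:
    """Per-event-time bookkeeping for the (soft) k-sample logrank statistic.

    One row per unique event time: ``d`` events, per-group soft at-risk mass
    ``at_risk``, total at-risk ``total_at_risk``, and per-group observed /
    expected events.  Conservation (columns of ``observed`` and ``expected``
    summing to ``d`` row-wise) is guaranteed by construction for any
    row-stochastic assignment.
    """

    event_times: np.ndarray  # (m,) strictly increasing
    d: np.ndarray  # (m,) events per time
    at_risk: np.ndarray  # (m, k) soft at-risk mass per group
    total_at_risk: np.ndarray  # (m,)
    observed: np.ndarray  # (m, k)
    expected: np.ndarray  # (m, k)

    @property
    def k(self) -> int:
        return self.at_risk.shape[1]

    @property
    def n_times(self) -> int:
        return self.event_times.shape[0]


@dataclass(frozen=True)
class LogrankResult:
    """Observed-minus-expected vector, covariance, statistic and p-value."""

    Z: np.ndarray
    V: np.ndarray
    statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class LossConfig:
    """Configuration of the total training objective.

    ``lambda_penalty`` weighs the balance barrier against the statistic;
    ``ridge_eps`` is added to the diagonal of the reduced covariance block
    during training for numerical stability (0 recovers the exact
    statistic); ``clamp_eps`` bounds mean probabilities away from the
    barrier's poles before the penalty (never before the statistic).
    """

    k: int
    lambda_penalty: float = 10.0**-0.7
    ridge_eps: float = 1e-6
    clamp_eps: float = 1e-7

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be nonnegative")
        if self.ridge_eps < 0:
            raise ValueError("ridge_eps must be nonnegative")

    @property
    def alpha_exponent(self) -> float:
        return balance_alpha(self.k)


def balance_alpha(k: int) -> float:
    """Barrier exponent ln(1/2)/ln(1/k); maps 1/k to exactly 1/2."""
    if k < 2:
        raise ValueError("k must be at least 2")
    return math.log(0.5) / math.log(1.0 / k)


def _event_structure(cohort: SurvivalCohort):
    """Constant masks shared by the numpy and autodiff paths.

    Returns unique event times ``et`` (m,), event counts ``d`` (m,), the
    at-risk indicator ``A`` (m, n) with A[j, i] = 1 iff T_i >= t_j (risk set
    closed on the left: subjects censored at t_j are still at risk at t_j),
    and the event indicator ``B`` (m, n) with B[j, i] = 1 iff subject i has
    an event exactly at t_j.
    """
    cohort.require_events()
    times, events = cohort.times, cohort.events
    et = np.unique(times[events == 1])
    A = (times[None, :] >= et[:, None]).astype(np.float64)
    B = ((times[None, :] == et[:, None]) & (events[None, :] == 1)).astype(np.float64)
    d = B.sum(axis=1)
    return et, d, A, B


def build_risk_table(cohort: SurvivalCohort, assignment: SoftAssignment) -> RiskTable:
    """Tabulate soft observed / at-risk / expected events per event time.

    Reduces to the classical k-sample bookkeeping when ``assignment`` is
    one-hot.  Tied events are pooled into a single row.
    """
    if cohort.n != assignment.n:
        raise ValueError(
            f"cohort has {cohort.n} subjects but assignment has {assignment.n} rows"
        )
    et, d, A, B = _event_structure(cohort)
    P = assignment.probs
    at_risk = A @ P
    total = A.sum(axis=1)
    observed = B @ P
    expected = (d / total)[:, None] * at_risk
    return RiskTable(
        event_times=et,
        d=d,
        at_risk=at_risk,
        total_at_risk=total,
        observed=observed,
        expected=expected,
    )


def covariance_matrix(table: RiskTable) -> np.ndarray:
    """Hypergeometric variance-covariance matrix of the O-E vector.

    V = sum_j d_j (N_j - d_j) / (N_j - 1) * [diag(r_j) - r_j r_j^T] with
    r_j = R(t_j)/N_j; event times with N_j <= 1 contribute zero (the
    hypergeometric variance is undefined there).
    """
    N = table.total_at_risk
    d = table.d
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(N > 1, d * (N - d) / np.maximum(N - 1.0, 1e-300), 0.0)
    r = table.at_risk / N[:, None]
    cr = c[:, None] * r
    V = np.diag(cr.sum(axis=0)) - cr.T @ r
    return (V + V.T) / 2.0


def multivariate_logrank(table: RiskTable, ridge_eps: float = 0.0) -> LogrankResult:
    """Chi-square k-sample logrank statistic from a (soft) risk table.

    Because rows of V sum to zero, the full system is rank k-1; the quadratic
    form is evaluated on the leading (k-1)-dimensional block, optionally
    ridge-regularized.  The p-value is the chi-square upper tail at k-1
    degrees of freedom (descriptive when the assignment is soft).
    """
    k = table.k
    Z = (table.observed - table.expected).sum(axis=0)
    V = covariance_matrix(table)
    dof = k - 1
    # Coordinates with zero variance (e.g. a group with no at-risk mass)
    # carry Z ~ 0 and would make the reduced block singular; drop them before
    # removing the final redundant coordinate.
    diag = np.diag(V)
    active = np.where(diag > 1e-12 * max(1.0, float(diag.max())))[0]
    keep = active[:-1]
    Zr = Z[keep]
    Vr = V[np.ix_(keep, keep)] + ridge_eps * np.eye(keep.size)
    if keep.size == 0 or np.allclose(Zr, 0.0, atol=1e-14):
        statistic = 0.0
    else:
        try:
            sol = np.linalg.solve(Vr, Zr)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(
                "reduced covariance block is singular; increase ridge_eps"
            ) from exc
        if not np.all(np.isfinite(sol)):
            raise ConditioningError(
                "reduced covariance block is numerically singular"
            )
        statistic = float(Zr @ sol)
    p_value = float(stats.chi2.sf(statistic, dof)) if statistic > 0 else 1.0
    return LogrankResult(Z=Z, V=V, statistic=statistic, dof=dof, p_value=p_value)


def balance_penalty(mean_probs, k: int | None = None) -> float:
    """Asymmetric barrier on mean assignment proportions.

    P(p) = (1/k) * sum_i 1/(p_i^a - (p_i^a)^2) - 4 with a = ln(1/2)/ln(1/k).
    The exponent maps 1/k to 1/2, so P is exactly 0 at the uniform simplex
    point and diverges as any proportion approaches 0 or 1.  Callers must
    clamp probabilities into (0, 1); values on the boundary raise.
    """
    p = np.asarray(mean_probs, dtype=np.float64)
    if k is None:
        k = p.shape[0]
    if p.shape != (k,):
        raise ValueError(f"expected a length-{k} proportion vector")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(
            "proportions must lie strictly inside (0, 1); clamp before calling"
        )
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    q = p ** balance_alpha(k)
    return float(np.sum(1.0 / (q - q * q)) / k - 4.0)


def _soft_statistic_graph(cohort: SurvivalCohort, probs: ad.Tensor, ridge_eps: float):
    """Differentiable soft k-sample logrank statistic as an autodiff node."""
    et, d, A, B = _event_structure(cohort)
    k = probs.shape[1]
    O = B @ probs  # (m, k) partial observed events
    R = A @ probs  # (m, k) partial at-risk mass
    N = R.sum(axis=1, keepdims=True)  # (m, 1) total at-risk
    E = R * (d[:, None] / N)
    Z = (O - E).sum(axis=0)  # (k,)
    r = R / N
    valid = (A.sum(axis=1) > 1).astype(np.float64)
    # d_j (N_j - d_j) / (N_j - 1); N here is soft but equals the count for
    # row-stochastic inputs.  Guard N_j <= 1 rows to a zero weight.
    c = valid * d * (N[:, 0] - d) / (N[:, 0] - 1.0 + (1.0 - valid))
    cr = r * c[:, None]
    V = ad.astensor(np.eye(k)) * cr.sum(axis=0) - cr.T @ r
    Zr = Z[:-1]
    Vr = V[:-1, :-1] + ad.astensor(ridge_eps * np.eye(k - 1))
    return Zr @ ad.inv(Vr) @ Zr


def partial_logrank_loss(
    cohort: SurvivalCohort,
    probs,
    config: LossConfig,
):
    """Total differentiable training objective ``-L + lambda * P(mean probs)``.

    ``probs`` may be a plain array or an autodiff :class:`~survclust.autodiff.
    Tensor` (e.g. the softmax output of a network), in which case the returned
    scalar Tensor backpropagates end to end into the assignment
    probabilities.  The barrier argument is the column mean of ``probs`` over
    the batch, clamped into ``(clamp_eps, 1 - clamp_eps)``; the statistic
    itself is never clamped.

    Raises :class:`~survclust.cohort.DegenerateCohortError` when the batch
    has no events — a data condition distinguishable from numeric failure.
    """
    t = ad.astensor(probs)
    if t.shape[1] != config.k:
        raise ValueError(
            f"assignment has {t.shape[1]} columns but config.k = {config.k}"
        )
    if t.shape[0] != cohort.n:
        raise ValueError("assignment row count does not match cohort size")
    stat = _soft_statistic_graph(cohort, t, config.ridge_eps)
    mean_p = t.mean(axis=0)
    clamped = ad.clip(mean_p, config.clamp_eps, 1.0 - config.clamp_eps)
    q = clamped ** config.alpha_exponent
    barrier = (1.0 / (q - q * q)).sum() * (1.0 / config.k) - 4.0
    return -stat + config.lambda_penalty * barrier
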