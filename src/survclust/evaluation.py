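"""Scoring clusterings: truth matching, ranking metrics, concordance,
Kaplan-Meier summaries, and bootstrap comparison machinery.

Unsupervised cluster labels are permutation-ambiguous, so recovery metrics
first match clusters to ground-truth classes by the globally optimal
permutation of the confusion matrix; per-class one-vs-rest AUROC / AUPRC are
then computed with the matched probability column as the score.

Prognostic value is summarized by Harrell's concordance index of a cluster
risk ordering derived from training-partition Kaplan-Meier medians, with
percentile bootstrap confidence intervals (subject-level resampling, 9999
replicates by default) and paired-difference one-sided p-values for model
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import average_precision_score, confusion_matrix, roc_auc_score

from .cohort import SurvivalCohort
from .logrank import build_risk_table, multivariate_logrank
from .cohort import SoftAssignment

__all__ = [
    "match_clusters",
    "apply_permutation",
    "per_class_auroc_auprc",
    "derive_risk_order",
    "cluster_c_index",
    "km_curve",
    "KMCurve",
    "bootstrap_cindex",
    "paired_bootstrap_pvalue",
    "BootstrapComparison",
    "EvaluationReport",
    "evaluate_clustering",
]


# ------------------------------------------------------------------ matching
def match_clusters(pred_labels, true_labels, k: int) -> np.ndarray:
    """Permutation ``perm`` (cluster -> truth class) maximizing agreement.

    Solved exactly: exhaustively for k <= 5, by the assignment-problem
    solver for larger k (both globally optimal).
    """
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("label arrays must have equal length")
    C = confusion_matrix(true, pred, labels=np.arange(k))  # rows truth, cols pred
    if k <= 5:
        best, best_score = None, -1
        for perm in permutations(range(k)):
            score = sum(C[perm[c], c] for c in range(k))
            if score > best_score:
                best, best_score = perm, score
        return np.asarray(best, dtype=int)
    truth_idx, cluster_idx = linear_sum_assignment(-C)
    perm = np.empty(k, dtype=int)
    perm[cluster_idx] = truth_idx
    return perm


def apply_permutation(probs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Reorder probability columns so column t scores truth class t."""
    probs = np.asarray(probs)
    out = np.empty_like(probs)
    for c, t in enumerate(perm):
        out[:, t] = probs[:, c]
    return out


def per_class_auroc_auprc(soft_probs, true_labels, permutation) -> dict:
    """One-vs-rest AUROC and AUPRC per truth class after matching.

    A class absent from the truth labels yields NaN for that class (reported,
    never silently dropped).
    """
    probs = apply_permutation(np.asarray(soft_probs, dtype=float), permutation)
    true = np.asarray(true_labels, dtype=int)
    k = probs.shape[1]
    auroc, auprc = np.full(k, np.nan), np.full(k, np.nan)
    for c in range(k):
        y = (true == c).astype(int)
        if y.min() == y.max():  # class absent (or universal)
            continue
        auroc[c] = roc_auc_score(y, probs[:, c])
        auprc[c] = average_precision_score(y, probs[:, c])
    return {"auroc": auroc, "auprc": auprc}


# ------------------------------------------------------------ risk & c-index
def derive_risk_order(
    train_labels, train_cohort: SurvivalCohort, k: int, strict: bool = True
) -> np.ndarray:
    """Cluster ids ordered best-survival-first on the TRAIN partition.

    Ordering key: decreasing Kaplan-Meier median survival, ties broken by
    mean observed time, then cluster id.  With ``strict`` (default) an empty
    cluster raises; otherwise empty clusters are ranked last by id, which is
    the behaviour cross-validation needs on early, still-collapsing models.
    """
    labels = np.asarray(train_labels, dtype=int)
    keys = []
    for c in range(k):
        m = labels == c
        if not m.any():
            if strict:
                raise ValueError(f"cluster {c} is empty on the training partition")
            keys.append((np.inf, np.inf, c))
            continue
        curve = km_curve(train_cohort.subset(m))
        med = curve.median if np.isfinite(curve.median) else np.inf
        keys.append((-med if np.isfinite(med) else -np.inf,
                     -float(train_cohort.times[m].mean()), c))
    order = sorted(range(k), key=lambda c: keys[c])
    return np.asarray(order, dtype=int)


def cluster_c_index(cluster_labels, cohort: SurvivalCohort, risk_order) -> float:
    """Harrell's concordance of the cluster risk ranking.

    Risk score of a subject = rank of its cluster in ``risk_order`` (0 = best
    survival).  Usable pairs: the subject with the earlier time had an event
    and strictly outlived by the comparator, or times are tied with exactly
    one event (the censored subject outlived the event).  Score ties count
    one half.
    """
    labels = np.asarray(cluster_labels, dtype=int)
    rank = np.empty(len(risk_order), dtype=float)
    rank[np.asarray(risk_order, dtype=int)] = np.arange(len(risk_order))
    risk = rank[labels]
    return _harrell(cohort.times, cohort.events, risk)


def _harrell(times, events, risk) -> float:
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    r = np.asarray(risk, float)
    ev = np.where(e == 1)[0]
    if ev.size == 0:
        raise ValueError("no usable pairs: cohort has no events")
    ti, ri = t[ev][:, None], r[ev][:, None]
    # pair (i event, j any): usable if t_i < t_j, or t_i == t_j and j censored
    later = (t[None, :] > ti) | ((t[None, :] == ti) & (e[None, :] == 0))
    # avoid double counting event-event pairs counted from both sides: the
    # strict t_i < t_j criterion already does; tied event pairs are unusable.
    conc = later & (r[None, :] < ri)
    tied = later & (r[None, :] == ri)
    usable = later.sum()
    if usable == 0:
        raise ValueError("no usable pairs under the concordance convention")
    return float((conc.sum() + 0.5 * tied.sum()) / usable)


# ------------------------------------------------------------------------ KM
@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate: right-continuous steps at ``times``."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # inf when S never reaches 0.5

    def at(self, horizons) -> np.ndarray:
        horizons = np.atleast_1d(np.asarray(horizons, float))
        idx = np.searchsorted(self.times, horizons, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out


def km_curve(cohort: SurvivalCohort) -> KMCurve:
    """Kaplan-Meier estimator of the cohort's survival function."""
    if cohort.n == 0:
        raise ValueError("cannot estimate a survival curve from an empty subset")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.times, cohort.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # drop the t=0 anchor row for a pure event-time step function
    keep = times > 0
    median = float(kmf.median_survival_time_)
    return KMCurve(times=times[keep], survival=surv[keep], median=median)


# ------------------------------------------------------------------ bootstrap
@dataclass(frozen=True)
class BootstrapComparison:
    """Percentile-bootstrap summary for one or two models."""

    n_boot: int
    median_a: float
    ci_a: tuple[float, float]
    median_b: float | None = None
    ci_b: tuple[float, float] | None = None
    delta_median: float | None = None
    delta_ci: tuple[float, float] | None = None
    p_one_sided: float | None = None


def _boot_cindex(times, events, risk, idx) -> float:
    return _harrell(times[idx], events[idx], risk[idx])


def bootstrap_cindex(
    risk_scores, cohort: SurvivalCohort, n_boot: int = 9999, seed: int = 0
) -> BootstrapComparison:
    """Subject-level bootstrap median and 95% percentile CI of the c-index."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    risk = np.asarray(risk_scores, dtype=float)
    vals = np.empty(n_boot)
    n = cohort.n
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            try:
                vals[b] = _boot_cindex(cohort.times, cohort.events, risk, idx)
                break
            except ValueError:
                continue  # replicate without usable pairs: redraw
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapComparison(
        n_boot=n_boot, median_a=float(np.median(vals)), ci_a=(float(lo), float(hi))
    )


def paired_bootstrap_pvalue(
    risk_a,
    risk_b,
    cohort: SurvivalCohort,
    n_boot: int = 9999,
    seed: int = 0,
) -> BootstrapComparison:
    """Paired bootstrap comparison of two risk scorings of the same cohort.

    Identical resampling indices are applied to both models per replicate;
    the one-sided p-value is the percentile position of zero in the
    paired-difference distribution, min(p(d <= 0), p(d >= 0)), with ties
    split between both sides and a floor of 1/n_boot.
    """
    a, b = np.asarray(risk_a, float), np.asarray(risk_b, float)
    if a.shape != b.shape or a.shape[0] != cohort.n:
        raise ValueError("risk scores must cover the same subjects")
    rng = np.random.default_rng(seed)
    n = cohort.n
    ca, cb = np.empty(n_boot), np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            try:
                ca[i] = _boot_cindex(cohort.times, cohort.events, a, idx)
                cb[i] = _boot_cindex(cohort.times, cohort.events, b, idx)
                break
            except ValueError:
                continue
    delta = ca - cb
    tie_half = 0.5 * np.mean(delta == 0.0)
    p = min(np.mean(delta < 0) + tie_half, np.mean(delta > 0) + tie_half)
    p = max(float(p), 1.0 / n_boot)
    lo_a, hi_a = np.percentile(ca, [2.5, 97.5])
    lo_b, hi_b = np.percentile(cb, [2.5, 97.5])
    lo_d, hi_d = np.percentile(delta, [2.5, 97.5])
    return BootstrapComparison(
        n_boot=n_boot,
        median_a=float(np.median(ca)),
        ci_a=(float(lo_a), float(hi_a)),
        median_b=float(np.median(cb)),
        ci_b=(float(lo_b), float(hi_b)),
        delta_median=float(np.median(delta)),
        delta_ci=(float(lo_d), float(hi_d)),
        p_one_sided=p,
    )


# --------------------------------------------------------------- full report
@dataclass(frozen=True)
class EvaluationReport:
    """Everything the pipeline reports about one clustering of one cohort."""

    k: int
    permutation: np.ndarray | None
    auroc_per_class: np.ndarray | None
    auprc_per_class: np.ndarray | None
    risk_order: np.ndarray
    c_index: float
    c_index_ci: tuple[float, float]
    logrank_statistic: float
    logrank_p: float
    km_summaries: list[dict]

    def to_dict(self) -> dict:
        def _arr(x):
            return None if x is None else np.asarray(x).tolist()

        return {
            "k": self.k,
            "permutation": _arr(self.permutation),
            "auroc_per_class": _arr(self.auroc_per_class),
            "auprc_per_class": _arr(self.auprc_per_class),
            "risk_order": _arr(self.risk_order),
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "km_summaries": self.km_summaries,
        }


def evaluate_clustering(
    soft_probs: np.ndarray,
    cohort: SurvivalCohort,
    true_labels=None,
    risk_order=None,
    horizons=(1.0, 2.0),
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Score a (held-out) soft clustering of a cohort.

    With ``true_labels`` supplied, clusters are matched to truth and
    per-class AUROC / AUPRC reported.  The logrank p-value across the
    model-derived clusters is descriptive (the clusters were chosen to
    separate survival).  ``risk_order`` defaults to an order derived on the
    scored data itself — pass a train-derived order for honest held-out
    concordance.
    """
    probs = np.asarray(soft_probs, dtype=float)
    k = probs.shape[1]
    hard = probs.argmax(axis=1)
    perm = auroc = auprc = None
    if true_labels is not None:
        perm = match_clusters(hard, true_labels, k)
        scores = per_class_auroc_auprc(probs, true_labels, perm)
        auroc, auprc = scores["auroc"], scores["auprc"]
    if risk_order is None:
        risk_order = derive_risk_order(hard, cohort, k, strict=False)
    cidx = cluster_c_index(hard, cohort, risk_order)
    boot = bootstrap_cindex(
        _risk_from_order(hard, risk_order), cohort, n_boot=n_boot, seed=seed
    )
    table = build_risk_table(cohort, SoftAssignment.from_labels(hard, k))
    lr = multivariate_logrank(table)
    km_summaries = []
    for c in range(k):
        m = hard == c
        if not m.any():
            km_summaries.append({"cluster": c, "n": 0})
            continue
        curve = km_curve(cohort.subset(m))
        km_summaries.append(
            {
                "cluster": c,
                "n": int(m.sum()),
                "median_survival": curve.median,
                "horizons": list(map(float, horizons)),
                "survival_at_horizons": curve.at(horizons).tolist(),
            }
        )
    return EvaluationReport(
        k=k,
        permutation=perm,
        auroc_per_class=auroc,
        auprc_per_class=auprc,
        risk_order=np.asarray(risk_order, dtype=int),
        c_index=cidx,
        c_index_ci=boot.ci_a,
        logrank_statistic=lr.statistic,
        logrank_p=lr.p_value,
        km_summaries=km_summaries,
    )


def _risk_from_order(labels, risk_order) -> np.ndarray:
    rank = np.empty(len(risk_order), dtype=float)
    rank[np.asarray(risk_order, dtype=int)] = np.arange(len(risk_order))
    return rank[np.asarray(labels, dtype=int)]
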