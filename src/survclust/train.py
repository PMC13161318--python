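"""Mini-batch training of clustering networks against the partial logrank
objective, and 5-fold cross-validation with leakage-free preprocessing.

Each mini-batch forms its own risk set: the soft k-sample logrank statistic
is computed over the batch's times and events, the balance barrier over the
batch's mean assignment probabilities, and the summed objective
``-L + lambda * P`` is backpropagated through the network.  A sampled batch
containing zero events leaves the statistic undefined; such a batch is
resampled once and then skipped with a logged warning.

Cross-validation is stratified by event status (so every fold contains
events), fits the tabular preprocessor on each training partition only, and
concatenates held-out soft assignments back into original subject order.
Because unsupervised cluster labels are arbitrary per fold, folds are
relabeled into a shared, truth-free convention before concatenation: the
fold with the highest training statistic anchors the label space (its
columns ordered best-survival-first by its train risk order), and every
other fold is mapped to the anchor by maximum agreement of the fold models'
full-cohort hard labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import DegenerateCohortError, SurvivalCohort
from .logrank import LossConfig, partial_logrank_loss
from .nn import CNN, MLP, AdamW
from .preprocess import fit_preprocessor

__all__ = ["TrainConfig", "TrainingLog", "train_cluster_model", "cross_validate"]

MLP_DEFAULTS = dict(
    learning_rate=10.0**-3.9,
    epochs=20,
    batch_size=128,
    weight_decay=10.0**-2.2,
    lambda_penalty=10.0**-0.7,
)
CNN_DEFAULTS = dict(
    learning_rate=10.0**-3.0,
    epochs=100,
    batch_size=32,
    weight_decay=10.0**-1.0,
    lambda_penalty=10.0**-1.0,
)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (AdamW with decoupled weight decay)."""

    learning_rate: float = MLP_DEFAULTS["learning_rate"]
    epochs: int = 20
    batch_size: int = 128
    weight_decay: float = MLP_DEFAULTS["weight_decay"]
    lambda_penalty: float = MLP_DEFAULTS["lambda_penalty"]
    ridge_eps: float = 1e-6
    n_folds: int = 5
    n_starts: int = 2  # independent inits per fold; best training statistic wins
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate > 1e-2:
            import warnings

            warnings.warn(
                "learning rates above 1e-2 can overpower the balance penalty "
                "and destabilize training; consider a slower rate",
                stacklevel=2,
            )

    @classmethod
    def for_mlp(cls, **kw) -> "TrainConfig":
        return cls(**{**MLP_DEFAULTS, **kw})

    @classmethod
    def for_cnn(cls, **kw) -> "TrainConfig":
        return cls(**{**CNN_DEFAULTS, "epochs": 100, "batch_size": 32, **kw})


@dataclass
class TrainingLog:
    """Per-epoch means of the objective and its two components."""

    epochs: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def append_epoch(self, **kw) -> None:
        self.epochs.append(kw)

    @property
    def final_loss(self) -> float:
        return self.epochs[-1]["loss"] if self.epochs else float("nan")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def train_cluster_model(
    cohort: SurvivalCohort,
    X: np.ndarray,
    model,
    config: TrainConfig,
    log: TrainingLog | None = None,
):
    """Fit a clustering network on preprocessed inputs; returns (model, log).

    Deterministic given ``config.seed`` and the model's init seed.  Raises on
    a NaN objective with diagnostics rather than training through it.
    """
    cohort.require_events()
    n = cohort.n
    if config.batch_size > n:
        raise ValueError("batch_size exceeds the number of training subjects")
    loss_cfg = LossConfig(
        k=model.k,
        lambda_penalty=config.lambda_penalty,
        ridge_eps=config.ridge_eps,
    )
    opt = AdamW(
        model.params, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    rng = np.random.default_rng(config.seed)
    log = log if log is not None else TrainingLog()
    for epoch in range(config.epochs):
        losses, stats, pens, balances = [], [], [], []
        for batch in _batches(n, config.batch_size, rng):
            if cohort.events[batch].sum() == 0:
                batch = rng.permutation(n)[: config.batch_size]  # resample once
                if cohort.events[batch].sum() == 0:
                    log.warnings.append(
                        f"epoch {epoch}: skipped a mini-batch with no events"
                    )
                    continue
            sub = cohort.subset(batch)
            probs = model(X[batch])
            loss = partial_logrank_loss(sub, probs, loss_cfg)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; last batch balance "
                    f"{probs.data.mean(axis=0).round(4).tolist()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            pen = (value + _stat_from_loss(loss)) / max(loss_cfg.lambda_penalty, 1e-300)
            losses.append(value)
            stats.append(_stat_from_loss(loss))
            pens.append(pen if loss_cfg.lambda_penalty > 0 else 0.0)
            balances.append(probs.data.mean(axis=0))
        balance = (
            np.mean(balances, axis=0)
            if balances
            else np.full(model.k, np.nan)
        )
        log.append_epoch(
            epoch=epoch,
            loss=float(np.mean(losses)) if losses else float("nan"),
            statistic=float(np.mean(stats)) if stats else float("nan"),
            penalty=float(np.mean(pens)) if pens else float("nan"),
            balance=balance.tolist(),
        )
    return model, log


def _stat_from_loss(loss) -> float:
    # the statistic subgraph is the first parent chain: loss = (-stat) + lam*pen
    # cheaper and exact: recover from stored forward values
    neg_stat = loss._parents[0].data if loss._parents else None
    return float(-neg_stat) if neg_stat is not None else float("nan")


@dataclass
class FoldResult:
    """Artifacts of one cross-validation fold."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: object
    preprocessor: object | None
    log: TrainingLog
    risk_order: np.ndarray  # cluster ids sorted best-survival-first


@dataclass
class CVResult:
    """Concatenated held-out assignments plus per-fold artifacts."""

    assignments: np.ndarray  # (n, k), original subject order, risk-aligned
    folds: list[FoldResult]

    def hard_labels(self) -> np.ndarray:
        return self.assignments.argmax(axis=1)


def _make_model(kind: str, k: int, seed: int, input_dim=None, input_size=None,
                hidden=None, blocks=None):
    if kind == "mlp":
        kw = {} if hidden is None else {"hidden": tuple(hidden)}
        return MLP(input_dim=input_dim, k=k, seed=seed, **kw)
    if kind == "cnn":
        kw = {} if blocks is None else {"blocks": blocks}
        return CNN(input_size=input_size, k=k, seed=seed, **kw)
    raise ValueError(f"unknown model kind {kind!r}")


def cross_validate(
    cohort: SurvivalCohort,
    X: np.ndarray,
    config: TrainConfig,
    k: int = 3,
    kind: str = "mlp",
    hidden=None,
    blocks=None,
    align_folds: bool = True,
) -> CVResult:
    """Stratified k-fold CV of a clustering network.

    Tabular inputs (``kind='mlp'``) get a per-fold train-fitted preprocessor;
    image inputs (``kind='cnn'``) are expected already contrast-enhanced
    (a per-image operation with no train/test coupling).  Per-fold seeds are
    derived as ``config.seed + fold``.
    """
    from .evaluation import derive_risk_order, match_clusters  # avoid cycle

    n = cohort.n
    if n < config.n_folds * k:
        raise ValueError("cohort too small for the requested folds and clusters")
    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    assignments = np.zeros((n, k))
    folds: list[FoldResult] = []
    raw: list[tuple] = []  # (test probs, full-cohort labels, risk order, score)
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(n), cohort.events)):
        if cohort.events[tr].sum() == 0 or cohort.events[te].sum() == 0:
            raise DegenerateCohortError(
                f"fold {fold} has no events even under event-stratified folding"
            )
        fold_seed = config.seed + fold
        if kind == "mlp":
            pre = fit_preprocessor(X[tr])
            Xtr, Xte = pre.transform(X[tr]), pre.transform(X[te])
            model_kw = dict(input_dim=X.shape[1], hidden=hidden)
        else:
            pre = None
            Xtr, Xte = X[tr], X[te]
            model_kw = dict(input_size=X.shape[-2:], blocks=blocks)
        # The objective is non-convex; a start occasionally locks into a
        # degenerate partition recognizable by its far lower training
        # statistic.  Run a few independent inits and keep the best by the
        # objective itself (no labels involved).
        best = None
        for start in range(max(1, config.n_starts)):
            start_seed = fold_seed + 7919 * start
            start_cfg = TrainConfig(**{**config.__dict__, "seed": start_seed})
            model = _make_model(kind, k, start_seed, **model_kw)
            model, log = train_cluster_model(
                cohort.subset(tr), Xtr, model, start_cfg
            )
            tail = [e["statistic"] for e in log.epochs[-5:]]
            score = float(np.mean(tail)) if tail else -np.inf
            if best is None or score > best[0]:
                best = (score, model, log)
        score, model, log = best
        train_probs = model.predict_proba(Xtr)
        order = derive_risk_order(
            train_probs.argmax(axis=1), cohort.subset(tr), k=k, strict=False
        )
        probs_te = model.predict_proba(Xte)
        # fold model's hard labels over the whole cohort, for alignment
        Xall = pre.transform(X) if pre is not None else X
        full_labels = model.predict_proba(Xall).argmax(axis=1)
        raw.append((probs_te, full_labels, order, score))
        folds.append(
            FoldResult(
                fold=fold,
                train_idx=tr,
                test_idx=te,
                model=model,
                preprocessor=pre,
                log=log,
                risk_order=order,
            )
        )
    if align_folds:
        # Unsupervised labels are arbitrary per fold.  Anchor on the fold
        # with the highest training statistic, relabel its columns by its
        # train risk order (column 0 = best survival), then map every other
        # fold to the anchor by maximum agreement of the models' full-cohort
        # hard labels — a truth-free alignment that stays correct even when
        # a fold's own survival ranking is distorted by a partial merge.
        anchor = int(np.argmax([score for (_, _, _, score) in raw]))
        _, anchor_labels, anchor_order, _ = raw[anchor]
        anchor_rank = np.empty(k, dtype=int)
        anchor_rank[np.asarray(anchor_order)] = np.arange(k)
        anchor_aligned = anchor_rank[anchor_labels]
        for f, (probs_te, full_labels, order, _) in zip(folds, raw):
            perm = (
                anchor_rank
                if f.fold == folds[anchor].fold
                else match_clusters(full_labels, anchor_aligned, k)
            )
            aligned = np.empty_like(probs_te)
            for col, target in enumerate(perm):
                aligned[:, target] = probs_te[:, col]
            assignments[f.test_idx] = aligned
    else:
        for f, (probs_te, _, _, _) in zip(folds, raw):
            assignments[f.test_idx] = probs_te
    return CVResult(assignments=assignments, folds=folds)
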