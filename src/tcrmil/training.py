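"""Cohort splitting and the optimisation loop.

Training follows the protocol of the original study: Adam (initial learning
rate 1e-3, weight decay 1e-3), bag-level cross-entropy, batches of 100 bags,
at most 1000 epochs with early stopping once the validation loss has failed
to improve for 40 consecutive epochs.  Model selection is decoupled from the
stopping rule: the returned parameters come from the epoch with the best
validation AUC (or lowest validation loss, configurable) seen before the
stop.  The whole loop is deterministic given its seed.

``train_with_restarts`` re-initialises and re-trains ``n_restarts`` times
(the study used 50) and keeps the restart with the best validation selection
metric; ties go to the lowest restart seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cme_model as cm
from .embedding import EmbeddedCohort
from .evaluation import roc_auc


class DivergenceError(RuntimeError):
    """Non-finite loss encountered during optimisation."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.001
    batch_size: int = 100
    max_epochs: int = 1000
    patience: int = 40
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_restarts: int = 1
    seed: int = 0
    selection_metric: str = "val_auc"  # or "val_loss"

    def __post_init__(self) -> None:
        if sum(self.split_ratios) <= 0:
            raise ValueError("split ratios must sum to a positive value")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.selection_metric not in ("val_auc", "val_loss"):
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def __len__(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# splitting


def _largest_remainder_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    total = float(sum(ratios))
    exact = [n * r / total for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_indices(
    labels: np.ndarray,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index arrays, reproducible by seed.

    Stratified splitting applies the ratio within each class label, so class
    proportions are preserved within rounding.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    if stratified:
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    else:
        groups = [np.arange(len(labels))]
    for idx in groups:
        perm = rng.permutation(idx)
        sizes = _largest_remainder_sizes(len(perm), ratios)
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].extend(perm[:a])
        parts[1].extend(perm[a:b])
        parts[2].extend(perm[b:])
    return tuple(np.sort(np.array(p, dtype=np.int64)) for p in parts)


def split_cohort(bags: Sequence, ratios=(0.6, 0.2, 0.2), seed: int = 0, stratified: bool = True):
    """Split a sequence of labelled bags into (train, val, test) lists."""
    labels = np.array([b.label for b in bags])
    tr, va, te = split_indices(labels, ratios, seed, stratified)
    pick = lambda idx: [bags[i] for i in idx]
    return pick(tr), pick(va), pick(te)


# ---------------------------------------------------------------------------
# Adam


class Adam:
    """Standard Adam with decoupled-from-nothing L2 weight decay added to the
    gradient (the convention of the reference deep-learning stack)."""

    def __init__(self, params: cm.CMEParams, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(a, dtype=float) for name, a in params.leaves()}
        self.v = {name: np.zeros_like(a, dtype=float) for name, a in params.leaves()}

    def step(self, params: cm.CMEParams, grads: cm.CMEParams) -> None:
        self.t += 1
        g_leaves = dict(grads.leaves())
        for name, p in params.leaves():
            g = g_leaves[name] + self.wd * p
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# loss/metric evaluation helpers


def _eval_binary(cohort: EmbeddedCohort, config, params):
    """Validation value of the full training objective (bag cross-entropy
    plus the weighted per-sequence term) and the validation AUC.  Early
    stopping watches the same quantity the optimiser minimises; monitoring
    the bag term alone stops training long before the motif filters settle."""
    scores, _, cache = cm.forward_binary_batch(
        cohort.X, cohort.lengths, cohort.mask, config, params, train=False
    )
    loss = float(np.mean(cm._bce(scores, cohort.labels)))
    if config.aux_sequence_loss_weight > 0.0:
        yr = np.clip(cache["yhat_raw"], cm.EPS, 1.0 - cm.EPS)
        aux = cm._bce(yr, cohort.labels[:, None])
        loss += config.aux_sequence_loss_weight * float(
            np.sum(np.where(cohort.mask, aux, 0.0)) / cohort.mask.sum()
        )
    auc = roc_auc(cohort.labels, scores) if len(np.unique(cohort.labels)) > 1 else float("nan")
    return loss, auc, scores


def _eval_multiclass(cohort: EmbeddedCohort, config, params):
    decisions, scores, _ = cm.forward_multiclass_batch(
        cohort.X, cohort.lengths, cohort.mask, config, params, train=False
    )
    loss = cm.multiclass_loss(scores, cohort.labels)
    acc = float(np.mean(decisions == cohort.labels))
    return loss, acc, scores


def train(
    config: cm.CMEConfig,
    train_cohort: EmbeddedCohort,
    val_cohort: EmbeddedCohort,
    tcfg: TrainConfig,
    params: cm.CMEParams | None = None,
) -> tuple[cm.CMEParams, TrainingHistory]:
    """Optimise CME parameters on ``train_cohort``; monitor ``val_cohort``.

    Early stopping watches the validation loss; the returned parameters are
    the snapshot from the epoch with the best selection metric (validation
    AUC by default — for the multi-class task, validation accuracy stands in,
    since AUC is a binary notion).
    """
    if len(train_cohort) == 0 or len(val_cohort) == 0:
        raise ValueError("train and validation cohorts must be non-empty")
    if params is None:
        params = cm.init_params(config, seed=tcfg.seed)
    else:
        params = params.copy()
    binary = config.task == "binary"
    evaluate = _eval_binary if binary else _eval_multiclass
    opt = Adam(params, lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)
    hist = TrainingHistory()
    best_val_loss = np.inf
    best_key = (-np.inf, -np.inf)  # (selection metric, -val loss): AUC ties
    best_params = params.copy()  # break toward the better-calibrated epoch
    since_improve = 0
    n = len(train_cohort)
    y_all = train_cohort.labels

    for epoch in range(tcfg.max_epochs):
        ep_rng = np.random.default_rng((tcfg.seed, epoch))
        order = ep_rng.permutation(n)
        ep_losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            Xb = train_cohort.X[idx]
            Lb = train_cohort.lengths[idx]
            Mb = train_cohort.mask[idx]
            yb = y_all[idx]
            if binary:
                bag, _, cache = cm.forward_binary_batch(
                    Xb, Lb, Mb, config, params, train=True, dropout_rng=ep_rng
                )
                loss = float(np.mean(cm._bce(bag, yb)))
                if config.aux_sequence_loss_weight > 0.0:
                    yr = np.clip(cache["yhat_raw"], cm.EPS, 1 - cm.EPS)
                    aux = cm._bce(yr, yb[:, None])
                    loss += config.aux_sequence_loss_weight * float(
                        np.sum(np.where(Mb, aux, 0.0)) / Mb.sum()
                    )
                grads = cm.backward_binary_batch(cache, yb, config, params)
            else:
                _, scores, cache = cm.forward_multiclass_batch(
                    Xb, Lb, Mb, config, params, train=True, dropout_rng=ep_rng
                )
                loss = cm.multiclass_loss(scores, yb)
                grads = cm.backward_multiclass_batch(cache, yb, config, params)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            ep_losses.append((loss, len(idx)))
            opt.step(params, grads)

        train_loss = float(sum(l * w for l, w in ep_losses) / sum(w for _, w in ep_losses))
        val_loss, val_metric, _ = evaluate(val_cohort, config, params)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        hist.train_loss.append(train_loss)
        hist.val_loss.append(val_loss)
        hist.val_auc.append(val_metric)

        metric = -val_loss if tcfg.selection_metric == "val_loss" else val_metric
        if np.isnan(metric):
            metric = -np.inf
        key = (metric, -val_loss)
        if key > best_key:
            best_key = key
            best_params = params.copy()
            hist.best_epoch = epoch
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > tcfg.patience:
                hist.stop_reason = f"early_stop(patience={tcfg.patience})"
                break
    else:
        hist.stop_reason = "max_epochs"
    return best_params, hist


def train_with_restarts(
    config: cm.CMEConfig,
    train_cohort: EmbeddedCohort,
    val_cohort: EmbeddedCohort,
    tcfg: TrainConfig,
    restart_seeds: Sequence[int] | None = None,
) -> tuple[cm.CMEParams, TrainingHistory, int]:
    """Best-of-n restarts by the validation selection metric.

    Each restart trains from a fresh seeded initialisation; the restart with
    the highest selection metric wins, ties going to the lowest seed.
    Returns (params, history, winning_seed).
    """
    if restart_seeds is None:
        restart_seeds = [tcfg.seed + r for r in range(tcfg.n_restarts)]
    if not restart_seeds:
        raise ValueError("need at least one restart seed")
    best = None
    for seed in sorted(restart_seeds):
        sub_cfg = TrainConfig(**{**tcfg.__dict__, "seed": int(seed)})
        params, hist = train(config, train_cohort, val_cohort, sub_cfg)
        if hist.best_epoch < 0:
            metric = -np.inf
        elif tcfg.selection_metric == "val_loss":
            metric = -hist.val_loss[hist.best_epoch]
        else:
            metric = hist.val_auc[hist.best_epoch]
        if best is None or metric > best[0]:
            best = (metric, params, hist, int(seed))
    _, params, hist, seed = best
    return params, hist, seed
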