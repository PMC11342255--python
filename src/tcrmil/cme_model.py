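"""The convolutional MIL-ensemble (CME) predictor.

Per embedded CDR3 instance (an ``Lmax x D`` matrix with a known true length
``L``), valid convolutions with kernel sizes 2/3/4 (3/2/1 filters each by
default) slide over the un-padded span at stride 1, so a size-``s`` kernel
yields ``L - s + 1`` positions.  A monotone activation (sigmoid for the
binary model, ReLU for the multi-class variant) followed by 1-max pooling
compresses each filter to a scalar; concatenation gives a 6-dimensional
feature vector per sequence.  A single linear layer plus sigmoid converts
that into a per-sequence cancer probability

    y_hat_i = sigma(w_L . p_i + b_L).

A bag's ``k`` ordered per-sequence probabilities are aggregated by ``m``
parallel linear heads (default 5); the head outputs are averaged and a final
sigmoid gives the bag-level cancer score

    Y_hat = sigma( (1/m) sum_j (w'_j . y_hat + b'_j) ).

Losses are epsilon-clamped binary cross-entropy (bag level; an optional
auxiliary per-sequence term is available) or softmax cross-entropy for the
multi-class head.  Masked (padded) bag slots contribute a per-sequence score
of exactly zero to the aggregation input and receive no gradients.

Because the activations are monotone, max-then-activate equals
activate-then-max; pooling is therefore done on pre-activations, which also
keeps the backward pass a single scatter to the argmax position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddedBag

EPS = 1e-7  # probability clamp for the cross-entropy losses


@dataclass(frozen=True)
class CMEConfig:
    kernel_sizes: tuple[int, ...] = (2, 3, 4)
    filters_per_size: tuple[int, ...] = (3, 2, 1)
    dropout_rate: float = 0.40
    n_heads: int = 5  # ensemble width m
    k: int = 100  # bag size
    Lmax: int = 24
    embed_dim: int = 32
    task: str = "binary"  # or "multiclass"
    n_classes: int = 2
    decision_threshold: float = 0.5
    aggregator: str = "ensemble"  # "ensemble" (learned heads) or "mean" baseline
    # weight of the per-sequence cross-entropy term (each instance inherits
    # its bag's label) added to the bag-level loss; bag-level supervision
    # alone gives the motif-detecting filters too diluted a gradient to
    # bootstrap, so the joint objective is the default
    aux_sequence_loss_weight: float = 1.0
    heads_consume_logits: bool = False  # heads see pre-sigmoid scores instead

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != len(self.filters_per_size):
            raise ValueError("kernel_sizes and filters_per_size must align")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_heads < 1:
            raise ValueError("need at least one ensemble head")
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "multiclass" and self.n_classes < 2:
            raise ValueError("multiclass needs n_classes >= 2")
        if self.aggregator not in ("ensemble", "mean"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")

    @property
    def n_filters(self) -> int:
        return int(sum(self.filters_per_size))


@dataclass
class CMEParams:
    """Learned weights; shapes follow :class:`CMEConfig`.

    ``conv_W[i]`` has shape (filters_per_size[i], kernel_sizes[i], D).
    Binary: ``w_seq`` (F,), ``b_seq`` scalar, ``head_W`` (m, k), ``head_b``
    (m,).  Multiclass: ``w_seq`` (F, C), ``b_seq`` (C,), ``head_W``
    (m, k, C), ``head_b`` (m, C).
    """

    conv_W: list[np.ndarray]
    conv_b: list[np.ndarray]
    w_seq: np.ndarray
    b_seq: np.ndarray
    head_W: np.ndarray
    head_b: np.ndarray

    def copy(self) -> "CMEParams":
        return CMEParams(
            conv_W=[w.copy() for w in self.conv_W],
            conv_b=[b.copy() for b in self.conv_b],
            w_seq=self.w_seq.copy(),
            b_seq=np.array(self.b_seq, dtype=float).copy(),
            head_W=self.head_W.copy(),
            head_b=self.head_b.copy(),
        )

    def leaves(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, (w, b) in enumerate(zip(self.conv_W, self.conv_b)):
            out.append((f"conv_W{i}", w))
            out.append((f"conv_b{i}", b))
        out += [("w_seq", self.w_seq), ("b_seq", self.b_seq), ("head_W", self.head_W), ("head_b", self.head_b)]
        return out


def init_params(config: CMEConfig, seed: int = 0) -> CMEParams:
    """Gaussian initialisation scaled by fan-in, seeded."""
    rng = np.random.default_rng(seed)
    D = config.embed_dim
    conv_W = [
        rng.normal(0.0, 1.0 / np.sqrt(s * D), (f, s, D))
        for s, f in zip(config.kernel_sizes, config.filters_per_size)
    ]
    conv_b = [np.zeros(f) for f in config.filters_per_size]
    F = config.n_filters
    # Aggregation heads start near the uniform average (1/k) with small
    # seeded perturbations: a zero-mean random-sign init would feed the
    # per-sequence path incoherent gradients (motif-bearing instances sit at
    # arbitrary abundance ranks), stalling the conv filters.
    if config.task == "binary":
        w_seq = rng.normal(0.0, 1.0 / np.sqrt(F), F)
        b_seq = np.zeros(())
        head_W = 1.0 / config.k + rng.normal(0.0, 0.1 / config.k, (config.n_heads, config.k))
        head_b = np.zeros(config.n_heads)
    else:
        C = config.n_classes
        w_seq = rng.normal(0.0, 1.0 / np.sqrt(F), (F, C))
        b_seq = np.zeros(C)
        head_W = 1.0 / config.k + rng.normal(0.0, 0.1 / config.k, (config.n_heads, config.k, C))
        head_b = np.zeros((config.n_heads, C))
    return CMEParams(conv_W=conv_W, conv_b=conv_b, w_seq=w_seq, b_seq=b_seq, head_W=head_W, head_b=head_b)


# ---------------------------------------------------------------------------
# atomic operations


def sigmoid(x):
    """Logistic function 1 / (1 + e^-x); saturates gracefully."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def relu(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def one_max_pool(feature_map: np.ndarray) -> float:
    """Maximum activation of one convolutional channel."""
    feature_map = np.asarray(feature_map, dtype=float)
    if feature_map.size == 0:
        raise ValueError("cannot max-pool an empty feature map")
    return float(feature_map.max())


def conv_feature_maps(
    E: np.ndarray,
    config: CMEConfig,
    params: CMEParams,
    true_len: int | None = None,
) -> list[np.ndarray]:
    """Activated feature maps of one instance, one vector per filter.

    ``E`` is the (possibly zero-padded) embedding matrix; the convolution
    slides only over the first ``true_len`` rows (default: all rows), so a
    size-``s`` kernel yields ``true_len - s + 1`` positions.
    """
    E = np.asarray(E, dtype=float)
    L = E.shape[0] if true_len is None else int(true_len)
    act = sigmoid if config.task == "binary" else relu
    maps: list[np.ndarray] = []
    for s, W, b in zip(config.kernel_sizes, params.conv_W, params.conv_b):
        if s > L:
            raise ValueError(f"kernel size {s} exceeds sequence length {L}")
        P = L - s + 1
        for f in range(W.shape[0]):
            pre = np.array([float((E[p : p + s] * W[f]).sum()) + b[f] for p in range(P)])
            maps.append(act(pre))
    return maps


def sequence_score(
    pooled: np.ndarray,
    params: CMEParams,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Per-sequence cancer probability sigma(w_L . p + b_L).

    Dropout (training only; pass ``rng``) uses inverted scaling so the
    expected pre-activation is unchanged.
    """
    p = np.asarray(pooled, dtype=float)
    if rng is not None and dropout_rate > 0.0:
        keep = rng.random(p.shape) >= dropout_rate
        p = p * keep / (1.0 - dropout_rate)
    return float(sigmoid(p @ params.w_seq + params.b_seq))


def _bce(p: float | np.ndarray, y) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def sequence_loss(y_hat: float, y: int) -> float:
    """Binary cross-entropy of one per-sequence prediction."""
    return float(_bce(y_hat, y))


def bag_loss(Y_hat: float, Y: int) -> float:
    """Binary cross-entropy of one bag-level prediction."""
    return float(_bce(Y_hat, Y))


def bag_score(
    y_hats: np.ndarray,
    mask: np.ndarray,
    params: CMEParams,
    aggregator: str = "ensemble",
) -> float:
    """Bag-level cancer score from the k ordered per-sequence scores.

    ``ensemble``: each of the m heads maps the k-vector (masked entries
    zeroed) to a scalar; the head outputs are averaged and passed through a
    sigmoid.  ``mean``: the unweighted mean of the real instances' scores,
    reported as-is (already a probability).
    """
    y = np.where(np.asarray(mask, dtype=bool), np.asarray(y_hats, dtype=float), 0.0)
    if not np.asarray(mask, dtype=bool).any():
        raise ValueError("bag has no real instances")
    if aggregator == "mean":
        return float(y.sum() / np.asarray(mask, dtype=bool).sum())
    z = params.head_W @ y + params.head_b  # (m,)
    return float(sigmoid(z.mean()))


# ---------------------------------------------------------------------------
# vectorised forward/backward over a batch of bags


def _conv_pool_batch(X, lengths, config, params):
    """Max-pooled pre-activations for a batch.

    Returns ``pre_max`` (n, k, F) and the per-filter argmax caches needed by
    the backward pass.  Slots with no valid position (masked instances) get
    pre_max 0 and are excluded downstream.
    """
    n, k, Lmax, D = X.shape
    pre_maxes = []
    argmaxes = []
    wins = []  # window matrices, cached for the backward pass
    for s, W, b in zip(config.kernel_sizes, params.conv_W, params.conv_b):
        P = Lmax - s + 1
        Fs = W.shape[0]
        # windows (n*k*P, D*s) -> one GEMM per kernel size
        win = np.lib.stride_tricks.sliding_window_view(X, s, axis=2)  # (n,k,P,D,s)
        win = win.transpose(0, 1, 2, 4, 3).reshape(n * k * P, s * D)
        pre = (win @ W.reshape(Fs, s * D).T.astype(X.dtype)).reshape(n, k, P, Fs)
        pre = pre + b
        valid = np.arange(P)[None, None, :] <= (lengths[..., None] - s)  # (n,k,P)
        pre = np.where(valid[..., None], pre, -np.inf)
        am = np.argmax(pre, axis=2)  # (n,k,Fs)
        mx = np.take_along_axis(pre, am[:, :, None, :], axis=2)[:, :, 0, :]
        mx = np.where(np.isfinite(mx), mx, 0.0)
        pre_maxes.append(mx)
        argmaxes.append(am)
        wins.append(win)
    return np.concatenate(pre_maxes, axis=-1), argmaxes, wins


def _conv_backward(dmx, argmaxes, wins, shape, config):
    """Gradients of conv weights given d(loss)/d(pre_max)."""
    n, k, Lmax, D = shape
    gW, gb = [], []
    off = 0
    for s, f in zip(config.kernel_sizes, config.filters_per_size):
        d = dmx[..., off : off + f]  # (n,k,f)
        am = argmaxes[len(gW)]  # (n,k,f)
        win = wins[len(gW)]  # (n*k*P, s*D)
        P = Lmax - s + 1
        dpre = np.zeros((n, k, P, f), dtype=win.dtype)
        np.put_along_axis(dpre, am[:, :, None, :], d[:, :, None, :].astype(win.dtype), axis=2)
        W_g = (dpre.reshape(n * k * P, f).T @ win).reshape(f, s, D)
        gW.append(W_g.astype(float))
        gb.append(dpre.sum(axis=(0, 1, 2)).astype(float))
        off += f
    return gW, gb


def forward_binary_batch(
    X: np.ndarray,
    lengths: np.ndarray,
    inst_mask: np.ndarray,
    config: CMEConfig,
    params: CMEParams,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
):
    """Batched binary forward pass.

    Returns ``(bag_scores (n,), seq_scores (n, k), cache)``; the cache feeds
    :func:`backward_binary_batch` during training.
    """
    mx, argmaxes, wins = _conv_pool_batch(X, lengths, config, params)  # (n,k,F)
    pooled = sigmoid(mx)
    if train and config.dropout_rate > 0.0:
        if dropout_rng is None:
            raise ValueError("training with dropout requires a generator")
        keep = dropout_rng.random(pooled.shape) >= config.dropout_rate
        f = pooled * keep / (1.0 - config.dropout_rate)
    else:
        keep = None
        f = pooled
    u = f @ params.w_seq + params.b_seq  # (n,k)
    yhat_raw = sigmoid(u)
    seq_in = u if config.heads_consume_logits else yhat_raw
    seq_in = np.where(inst_mask, seq_in, 0.0)
    yhat = np.where(inst_mask, yhat_raw, 0.0)
    if config.aggregator == "mean":
        denom = inst_mask.sum(axis=1)
        bag = seq_in.sum(axis=1) / denom
        z = None
    else:
        z = seq_in @ params.head_W.T + params.head_b  # (n,m)
        bag = sigmoid(z.mean(axis=1))
    cache = {
        "mx": mx, "argmaxes": argmaxes, "wins": wins, "pooled": pooled, "keep": keep,
        "f": f, "u": u, "yhat_raw": yhat_raw, "seq_in": seq_in, "z": z, "bag": bag,
        "shape": X.shape, "inst_mask": inst_mask,
    }
    return bag, yhat, cache


def backward_binary_batch(cache, Y, config: CMEConfig, params: CMEParams):
    """Mean bag cross-entropy gradient over the batch (plus the optional
    auxiliary per-sequence term, each real instance inheriting its bag's
    label)."""
    inst_mask = cache["inst_mask"]
    n, k = cache["u"].shape
    Y = np.asarray(Y, dtype=float)
    bag = np.clip(cache["bag"], EPS, 1.0 - EPS)

    if config.aggregator == "mean":
        # d/d seq_in of mean aggregation through BCE
        denom = inst_mask.sum(axis=1)
        dbag = (bag - Y) / (bag * (1.0 - bag)) / n  # dL/dbag
        dseq_in = (dbag / denom)[:, None] * np.ones((n, k))
        g_head_W = np.zeros_like(params.head_W)
        g_head_b = np.zeros_like(params.head_b)
    else:
        dzbar = (bag - Y) / n  # BCE through the final sigmoid
        dz = np.repeat(dzbar[:, None], params.head_W.shape[0], axis=1) / params.head_W.shape[0]
        g_head_W = dz.T @ cache["seq_in"]  # (m,k)
        g_head_b = dz.sum(axis=0)
        dseq_in = dz @ params.head_W  # (n,k)

    dseq_in = np.where(inst_mask, dseq_in, 0.0)
    yr = cache["yhat_raw"]
    if config.heads_consume_logits:
        du = dseq_in
    else:
        du = dseq_in * yr * (1.0 - yr)

    lam = config.aux_sequence_loss_weight
    if lam > 0.0:
        n_real = inst_mask.sum()
        yc = np.clip(yr, EPS, 1.0 - EPS)
        du_aux = (yc - Y[:, None]) / n_real  # BCE-through-sigmoid per instance
        du = du + lam * np.where(inst_mask, du_aux, 0.0)

    g_w_seq = np.einsum("nk,nkf->f", du, cache["f"])
    g_b_seq = np.array(du.sum())
    df = du[..., None] * params.w_seq  # (n,k,F)
    if cache["keep"] is not None:
        df = df * cache["keep"] / (1.0 - config.dropout_rate)
    pooled = cache["pooled"]
    dmx = df * pooled * (1.0 - pooled)
    dmx = np.where(inst_mask[..., None], dmx, 0.0)
    g_conv_W, g_conv_b = _conv_backward(dmx, cache["argmaxes"], cache["wins"], cache["shape"], config)
    return CMEParams(
        conv_W=g_conv_W, conv_b=g_conv_b, w_seq=g_w_seq, b_seq=g_b_seq,
        head_W=g_head_W, head_b=g_head_b,
    )


def forward_multiclass_batch(
    X: np.ndarray,
    lengths: np.ndarray,
    inst_mask: np.ndarray,
    config: CMEConfig,
    params: CMEParams,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
):
    """Multi-class forward: ReLU activations, un-normalised class scores.

    Returns ``(decisions (n,), class_scores (n, C), cache)``; the decision is
    the argmax class (ties -> lowest index).
    """
    mx, argmaxes, wins = _conv_pool_batch(X, lengths, config, params)
    pooled = relu(mx)
    if train and config.dropout_rate > 0.0:
        if dropout_rng is None:
            raise ValueError("training with dropout requires a generator")
        keep = dropout_rng.random(pooled.shape) >= config.dropout_rate
        f = pooled * keep / (1.0 - config.dropout_rate)
    else:
        keep = None
        f = pooled
    u = f @ params.w_seq + params.b_seq  # (n,k,C)
    yhat = relu(u)
    yhat = np.where(inst_mask[..., None], yhat, 0.0)
    z = np.einsum("nkc,mkc->nmc", yhat, params.head_W) + params.head_b  # (n,m,C)
    scores = z.mean(axis=1)  # (n,C)
    decisions = scores.argmax(axis=1)
    cache = {
        "mx": mx, "argmaxes": argmaxes, "wins": wins, "pooled": pooled, "keep": keep,
        "f": f, "u": u, "yhat": yhat, "scores": scores, "shape": X.shape,
        "inst_mask": inst_mask,
    }
    return decisions, scores, cache


def backward_multiclass_batch(cache, y, config: CMEConfig, params: CMEParams):
    """Softmax cross-entropy gradient for the multi-class head."""
    inst_mask = cache["inst_mask"]
    scores = cache["scores"]
    n, C = scores.shape
    m = params.head_W.shape[0]
    S = scores - scores.max(axis=1, keepdims=True)
    P = np.exp(S)
    P /= P.sum(axis=1, keepdims=True)
    dscores = P.copy()
    dscores[np.arange(n), y] -= 1.0
    dscores /= n  # (n,C)
    dz = np.repeat(dscores[:, None, :], m, axis=1) / m  # (n,m,C)
    g_head_W = np.einsum("nmc,nkc->mkc", dz, cache["yhat"])
    g_head_b = dz.sum(axis=0)
    dyhat = np.einsum("nmc,mkc->nkc", dz, params.head_W)
    dyhat = np.where(inst_mask[..., None], dyhat, 0.0)
    du = dyhat * (cache["u"] > 0)
    g_w_seq = np.einsum("nkc,nkf->fc", du, cache["f"])
    g_b_seq = du.sum(axis=(0, 1))
    df = np.einsum("nkc,fc->nkf", du, params.w_seq)
    if cache["keep"] is not None:
        df = df * cache["keep"] / (1.0 - config.dropout_rate)
    dmx = df * (cache["mx"] > 0)
    dmx = np.where(inst_mask[..., None], dmx, 0.0)
    g_conv_W, g_conv_b = _conv_backward(dmx, cache["argmaxes"], cache["wins"], cache["shape"], config)
    return CMEParams(
        conv_W=g_conv_W, conv_b=g_conv_b, w_seq=g_w_seq, b_seq=g_b_seq,
        head_W=g_head_W, head_b=g_head_b,
    )


def multiclass_loss(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean softmax cross-entropy of un-normalised class scores."""
    S = scores - scores.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(S).sum(axis=1))
    return float(np.mean(logZ - S[np.arange(len(y)), y]))


# ---------------------------------------------------------------------------
# single-bag convenience wrappers (the composition the atomic ops define)


def forward_binary(bag: EmbeddedBag, config: CMEConfig, params: CMEParams):
    """One bag -> (bag cancer score, per-sequence scores). Eval mode."""
    X = bag.tensor[None]
    scores, yhat, _ = forward_binary_batch(
        X, bag.lengths[None], bag.mask[None], config, params, train=False
    )
    return float(scores[0]), yhat[0]


def forward_multiclass(bag: EmbeddedBag, config: CMEConfig, params: CMEParams):
    """One bag -> (class decision, per-class scores). Eval mode."""
    d, scores, _ = forward_multiclass_batch(
        bag.tensor[None], bag.lengths[None], bag.mask[None], config, params, train=False
    )
    if scores.shape[1] != config.n_classes:
        raise ValueError("params do not match n_classes")
    return int(d[0]), scores[0]


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path: str | Path,
    config: CMEConfig,
    params: CMEParams,
    fingerprint: dict | None = None,
    seed: int | None = None,
) -> None:
    """Versioned checkpoint: config + weights + embedding-backend fingerprint."""
    path = Path(path)
    arrays = {name: arr for name, arr in params.leaves()}
    meta = {
        "format_version": 1,
        "config": {**{k: (list(v) if isinstance(v, tuple) else v) for k, v in config.__dict__.items()}},
        "embedding_fingerprint": fingerprint or {},
        "seed": seed,
        "n_conv": len(params.conv_W),
    }
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[CMEConfig, CMEParams, dict]:
    z = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(z["__meta__"]))
    cfg_d = meta["config"]
    cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
    cfg_d["filters_per_size"] = tuple(cfg_d["filters_per_size"])
    config = CMEConfig(**cfg_d)
    n_conv = meta["n_conv"]
    params = CMEParams(
        conv_W=[z[f"conv_W{i}"] for i in range(n_conv)],
        conv_b=[z[f"conv_b{i}"] for i in range(n_conv)],
        w_seq=z["w_seq"],
        b_seq=z["b_seq"],
        head_W=z["head_W"],
        head_b=z["head_b"],
    )
    return config, params, meta
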