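"""Per-residue embedding of CDR3 sequences.

Three interchangeable backends produce an L x D matrix for a length-L CDR3:

``pretrained_plm``
    Adapter around an external protein language model checkpoint with the
    standard BERT-base contract: 12 self-attention layers, 12 heads, hidden
    width 768, per-head key dimension 64.  The checkpoint is optional at
    runtime; without it the adapter still declares its configuration but
    refuses to embed, pointing at ``mini_encoder``.

``mini_encoder``
    A small, seeded, randomly initialised multi-head self-attention stack
    built from the scaled dot-product attention primitive below.  It is
    deterministic given its seed and cheap enough for CPU test runs while
    exercising the same attention arithmetic as the full model.

``physicochemical``
    Row lookup in a user-supplied 20 x P amino-acid property table.

All backends are length-preserving: the output has exactly one row per
residue.  Bags of embedded sequences are zero-padded to ``Lmax`` (default 24,
the maximum admissible CDR3 length) and stacked into k x Lmax x D tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .repertoire_io import AMINO_ACIDS, RepertoireBag

# vocabulary: 0 = pad, 1 = begin, 2 = end, 3.. = residues
PAD_ID, BOS_ID, EOS_ID = 0, 1, 2
_RESIDUE_OFFSET = 3
_AA_TO_ID = {aa: i + _RESIDUE_OFFSET for i, aa in enumerate(AMINO_ACIDS)}
VOCAB_SIZE = _RESIDUE_OFFSET + len(AMINO_ACIDS)

DEFAULT_LMAX = 24


class EmbeddingError(ValueError):
    pass


class MissingWeightsError(RuntimeError):
    """Pretrained checkpoint not available in this environment."""


@dataclass(frozen=True)
class TokenSequence:
    """Integer token ids for one CDR3 (begin/end specials included)."""

    tokens: tuple[int, ...]
    source_len: int

    def residue_ids(self) -> np.ndarray:
        return np.array([t for t in self.tokens if t >= _RESIDUE_OFFSET], dtype=np.int64)


def tokenize(cdr3_aa: str) -> TokenSequence:
    """Encode an amino-acid string as begin + residue tokens + end.

    Deterministic and invertible up to the special tokens; any character
    outside the 20-letter alphabet is a validation error.
    """
    if not cdr3_aa:
        raise EmbeddingError("cannot tokenize an empty sequence")
    ids = []
    for ch in cdr3_aa:
        if ch not in _AA_TO_ID:
            raise EmbeddingError(f"unknown amino acid {ch!r} in {cdr3_aa!r}")
        ids.append(_AA_TO_ID[ch])
    return TokenSequence(tokens=(BOS_ID, *ids, EOS_ID), source_len=len(cdr3_aa))


def detokenize(ts: TokenSequence) -> str:
    return "".join(AMINO_ACIDS[t - _RESIDUE_OFFSET] for t in ts.tokens if t >= _RESIDUE_OFFSET)


# ---------------------------------------------------------------------------
# scaled dot-product attention


def attention_scores(Q: np.ndarray, K: np.ndarray, d_k: int) -> np.ndarray:
    """Pairwise attention scores Q K^T / sqrt(d_k)."""
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    if Q.ndim != 2 or K.ndim != 2 or Q.shape[1] != K.shape[1]:
        raise ValueError(f"shape mismatch: Q {Q.shape} vs K {K.shape}")
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    return Q @ K.T / np.sqrt(d_k)


def _softmax_rows(S: np.ndarray) -> np.ndarray:
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=-1, keepdims=True)


def attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    d_k: int | None = None,
    key_mask: np.ndarray | None = None,
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V — each row of weights sums to one.

    ``key_mask`` (boolean per key) excludes padded positions from the
    normalisation.
    """
    V = np.asarray(V, dtype=float)
    if d_k is None:
        d_k = np.asarray(K).shape[1]
    S = attention_scores(Q, K, d_k)
    if V.shape[0] != S.shape[1]:
        raise ValueError("V rows must match number of keys")
    if key_mask is not None:
        S = np.where(key_mask[None, :], S, -np.inf)
    return _softmax_rows(S) @ V


# ---------------------------------------------------------------------------
# backends


def _sinusoidal_positions(L: int, D: int) -> np.ndarray:
    pos = np.arange(L)[:, None]
    i = np.arange(D)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / D)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


@dataclass(frozen=True)
class AttentionConfig:
    """Architecture contract of an attention encoder."""

    n_layers: int = 12
    n_heads: int = 12
    hidden: int = 768

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads != 0:
            raise ValueError("hidden width must be divisible by the head count")

    @property
    def d_k(self) -> int:
        return self.hidden // self.n_heads


class MiniEncoder:
    """Seeded random-weight multi-head self-attention encoder.

    Not a trained language model: its purpose is a deterministic, contextual,
    injective-in-practice representation of residues that the convolutional
    scorer downstream can learn from, while running the literal scaled
    dot-product attention computation.  Residual connections and layer
    normalisation keep token identity recoverable; sinusoidal positional
    encodings (on by default) make the representation order-sensitive.
    """

    name = "mini_encoder"

    def __init__(
        self,
        embed_dim: int = 32,
        n_layers: int = 2,
        n_heads: int = 4,
        seed: int = 0,
        use_positional: bool = True,
    ):
        self.config = AttentionConfig(n_layers=n_layers, n_heads=n_heads, hidden=embed_dim)
        self.embed_dim = embed_dim
        self.seed = seed
        self.use_positional = use_positional
        d_k = self.config.d_k
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(embed_dim)
        self.tok_emb = rng.normal(0.0, 1.0, (len(AMINO_ACIDS), embed_dim))
        self.layers = []
        for _ in range(n_layers):
            self.layers.append(
                {
                    "Wq": rng.normal(0.0, s, (n_heads, embed_dim, d_k)),
                    "Wk": rng.normal(0.0, s, (n_heads, embed_dim, d_k)),
                    "Wv": rng.normal(0.0, s, (n_heads, embed_dim, d_k)),
                    "Wo": rng.normal(0.0, s, (embed_dim, embed_dim)),
                    "W1": rng.normal(0.0, s, (embed_dim, 2 * embed_dim)),
                    "b1": np.zeros(2 * embed_dim),
                    "W2": rng.normal(0.0, s, (2 * embed_dim, embed_dim)),
                    "b2": np.zeros(embed_dim),
                }
            )

    @staticmethod
    def _layer_norm(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=-1, keepdims=True)
        sd = X.std(axis=-1, keepdims=True)
        return (X - mu) / (sd + 1e-8)

    def fingerprint(self) -> dict:
        return {
            "backend": self.name,
            "embed_dim": self.embed_dim,
            "n_layers": self.config.n_layers,
            "n_heads": self.config.n_heads,
            "seed": self.seed,
            "positional": self.use_positional,
        }

    def embed(self, ts: TokenSequence) -> np.ndarray:
        """One sequence -> L x D matrix (special tokens carry no rows)."""
        ids = ts.residue_ids() - _RESIDUE_OFFSET
        X = self.tok_emb[ids]
        if self.use_positional:
            X = X + _sinusoidal_positions(len(ids), self.embed_dim)
        d_k = self.config.d_k
        for lp in self.layers:
            heads = [
                attention(X @ lp["Wq"][h], X @ lp["Wk"][h], X @ lp["Wv"][h], d_k)
                for h in range(self.config.n_heads)
            ]
            A = np.concatenate(heads, axis=1) @ lp["Wo"]
            X = self._layer_norm(X + A)
            H = np.tanh(X @ lp["W1"] + lp["b1"]) @ lp["W2"] + lp["b2"]
            X = self._layer_norm(X + H)
        return X

    def embed_many(self, sequences: Sequence[TokenSequence]) -> list[np.ndarray]:
        """Batched embedding of many sequences (same arithmetic as
        :meth:`embed`, vectorised across the batch with key masking)."""
        if not sequences:
            return []
        lens = np.array([ts.source_len for ts in sequences])
        L = int(lens.max())
        B, D = len(sequences), self.embed_dim
        ids = np.zeros((B, L), dtype=np.int64)
        mask = np.zeros((B, L), dtype=bool)
        for i, ts in enumerate(sequences):
            r = ts.residue_ids() - _RESIDUE_OFFSET
            ids[i, : len(r)] = r
            mask[i, : len(r)] = True
        X = self.tok_emb[ids]
        if self.use_positional:
            X = X + _sinusoidal_positions(L, D)[None]
        X = np.where(mask[..., None], X, 0.0)
        d_k = self.config.d_k
        for lp in self.layers:
            # (H, B, L, d_k) projections
            Q = np.einsum("bld,hde->hble", X, lp["Wq"])
            K = np.einsum("bld,hde->hble", X, lp["Wk"])
            V = np.einsum("bld,hde->hble", X, lp["Wv"])
            S = np.einsum("hble,hbme->hblm", Q, K) / np.sqrt(d_k)
            S = np.where(mask[None, :, None, :], S, -np.inf)
            W = _softmax_rows(S)
            Hd = np.einsum("hblm,hbme->hble", W, V)
            A = np.concatenate([Hd[h] for h in range(Hd.shape[0])], axis=-1) @ lp["Wo"]
            X = self._layer_norm(X + A)
            H2 = np.tanh(X @ lp["W1"] + lp["b1"]) @ lp["W2"] + lp["b2"]
            X = self._layer_norm(X + H2)
            X = np.where(mask[..., None], X, 0.0)
        return [X[i, : lens[i]].copy() for i in range(B)]


class PretrainedPLMAdapter:
    """Adapter for an external pretrained protein language model.

    Declares the BERT-base architecture contract (12 layers, 12 heads,
    hidden 768, d_k 64) without requiring the checkpoint; embedding without
    the weights raises :class:`MissingWeightsError` advising the
    ``mini_encoder`` backend.  When a compatible model object is supplied it
    must map a token-id array to final hidden states; begin/end rows are
    stripped so the result is exactly L x 768.
    """

    name = "pretrained_plm"

    def __init__(self, model=None):
        self.config = AttentionConfig(n_layers=12, n_heads=12, hidden=768)
        self.embed_dim = self.config.hidden
        self._model = model

    def fingerprint(self) -> dict:
        return {"backend": self.name, "embed_dim": self.embed_dim, "loaded": self._model is not None}

    def embed(self, ts: TokenSequence) -> np.ndarray:
        if self._model is None:
            raise MissingWeightsError(
                "no pretrained protein language model checkpoint is available; "
                "use the mini_encoder backend for offline runs"
            )
        H = np.asarray(self._model(np.array(ts.tokens)), dtype=float)
        if H.shape != (ts.source_len + 2, self.embed_dim):
            raise EmbeddingError(
                f"model returned shape {H.shape}, expected {(ts.source_len + 2, self.embed_dim)}"
            )
        return H[1:-1]  # strip begin/end rows

    def embed_many(self, sequences: Sequence[TokenSequence]) -> list[np.ndarray]:
        return [self.embed(ts) for ts in sequences]


class PhysicochemicalBackend:
    """Per-residue lookup in a 20 x P amino-acid property table.

    The table is supplied by the user (rows ordered as ``AMINO_ACIDS``); no
    silent default exists.  :func:`example_property_table` ships a documented
    synthetic placeholder for tests and demos.
    """

    name = "physicochemical"

    def __init__(self, table: np.ndarray):
        table = np.asarray(table, dtype=float)
        if table.ndim != 2 or table.shape[0] != len(AMINO_ACIDS):
            raise EmbeddingError("property table must have one row per amino acid (20 rows)")
        self.table = table
        self.embed_dim = table.shape[1]

    def fingerprint(self) -> dict:
        return {"backend": self.name, "embed_dim": self.embed_dim}

    def embed(self, ts: TokenSequence) -> np.ndarray:
        return self.table[ts.residue_ids() - _RESIDUE_OFFSET]

    def embed_many(self, sequences: Sequence[TokenSequence]) -> list[np.ndarray]:
        return [self.embed(ts) for ts in sequences]


def example_property_table(n_properties: int = 15, seed: int = 7) -> np.ndarray:
    """Synthetic standardized 20 x P placeholder property table.

    Stands in for a published physicochemical descriptor matrix in offline
    tests; each column is zero-mean/unit-variance across the 20 residues.
    """
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(len(AMINO_ACIDS), n_properties))
    T = (T - T.mean(axis=0)) / T.std(axis=0)
    return T


_BACKENDS = {"mini_encoder": MiniEncoder, "pretrained_plm": PretrainedPLMAdapter}


def make_backend(name: str, **kwargs):
    """Factory for embedding backends by name."""
    if name == "mini_encoder":
        return MiniEncoder(**kwargs)
    if name == "pretrained_plm":
        return PretrainedPLMAdapter(**kwargs)
    if name == "physicochemical":
        return PhysicochemicalBackend(**kwargs)
    raise EmbeddingError(f"unknown embedding backend {name!r}")


def embed_sequence(ts: TokenSequence, backend) -> np.ndarray:
    """L x D embedding of one tokenised sequence via ``backend``."""
    E = backend.embed(ts)
    if E.shape[0] != ts.source_len:
        raise EmbeddingError("backend did not preserve sequence length")
    return E


# ---------------------------------------------------------------------------
# stacking into bag tensors


@dataclass
class EmbeddedBag:
    """k x Lmax x D tensor of per-residue embeddings for one bag."""

    tensor: np.ndarray
    lengths: np.ndarray  # (k,) true residue counts, 0 for padded slots
    mask: np.ndarray  # (k,) True for real instances
    Lmax: int

    def unstack(self) -> list[np.ndarray]:
        """Recover the original per-sequence matrices of the real slots."""
        return [self.tensor[i, : self.lengths[i]].copy() for i in range(len(self.mask)) if self.mask[i]]


def pad_and_stack(
    embeddings: Sequence[np.ndarray], k: int, Lmax: int = DEFAULT_LMAX
) -> EmbeddedBag:
    """Zero-pad each L x D matrix to Lmax rows and stack into a k-slot tensor.

    Rows beyond an instance's true length are exactly zero; missing slots
    (fewer than ``k`` inputs) are fully zero with mask False.
    """
    if len(embeddings) > k:
        raise ValueError(f"got {len(embeddings)} instances for a bag of size {k}")
    D = embeddings[0].shape[1] if embeddings else 1
    tensor = np.zeros((k, Lmax, D))
    lengths = np.zeros(k, dtype=np.int64)
    mask = np.zeros(k, dtype=bool)
    for i, E in enumerate(embeddings):
        L = E.shape[0]
        if L > Lmax:
            raise ValueError(f"sequence length {L} exceeds Lmax={Lmax}")
        tensor[i, :L] = E
        lengths[i] = L
        mask[i] = True
    return EmbeddedBag(tensor=tensor, lengths=lengths, mask=mask, Lmax=Lmax)


@dataclass
class EmbeddedCohort:
    """Stacked embeddings for n bags: n x k x Lmax x D plus bookkeeping."""

    X: np.ndarray
    lengths: np.ndarray  # (n, k)
    mask: np.ndarray  # (n, k)
    labels: np.ndarray  # (n,)
    sample_ids: list[str]
    fingerprint: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "EmbeddedCohort":
        idx = np.asarray(idx)
        return EmbeddedCohort(
            X=self.X[idx],
            lengths=self.lengths[idx],
            mask=self.mask[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            fingerprint=self.fingerprint,
        )

    def save(self, path: str | Path) -> None:
        import json

        np.savez_compressed(
            path,
            X=self.X,
            lengths=self.lengths,
            mask=self.mask,
            labels=self.labels,
            sample_ids=np.array(self.sample_ids),
            fingerprint=np.array(json.dumps(self.fingerprint)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddedCohort":
        import json

        z = np.load(path, allow_pickle=False)
        return cls(
            X=z["X"],
            lengths=z["lengths"],
            mask=z["mask"],
            labels=z["labels"],
            sample_ids=[str(s) for s in z["sample_ids"]],
            fingerprint=json.loads(str(z["fingerprint"])),
        )


def embed_bags(
    bags: Sequence[RepertoireBag],
    backend,
    Lmax: int = DEFAULT_LMAX,
) -> EmbeddedCohort:
    """Embed every real instance of every bag and stack into one cohort tensor.

    All sequences are embedded in one batched pass through the backend, then
    redistributed to their bags.
    """
    all_ts: list[TokenSequence] = []
    owners: list[tuple[int, int]] = []
    for b_i, bag in enumerate(bags):
        for s_i, (clone, real) in enumerate(zip(bag.instances, bag.mask)):
            if real and clone is not None:
                all_ts.append(tokenize(clone.cdr3_aa))
                owners.append((b_i, s_i))
    mats = backend.embed_many(all_ts)
    k = bags[0].k if bags else 0
    D = backend.embed_dim
    n = len(bags)
    # float32: halves the memory traffic of the convolutional scorer
    X = np.zeros((n, k, Lmax, D), dtype=np.float32)
    lengths = np.zeros((n, k), dtype=np.int64)
    mask = np.zeros((n, k), dtype=bool)
    for (b_i, s_i), E in zip(owners, mats):
        L = E.shape[0]
        if L > Lmax:
            raise ValueError(f"sequence length {L} exceeds Lmax={Lmax}")
        X[b_i, s_i, :L] = E
        lengths[b_i, s_i] = L
        mask[b_i, s_i] = True
    return EmbeddedCohort(
        X=X,
        lengths=lengths,
        mask=mask,
        labels=np.array([b.label for b in bags], dtype=np.int64),
        sample_ids=[b.sample_id for b in bags],
        fingerprint=backend.fingerprint(),
    )
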