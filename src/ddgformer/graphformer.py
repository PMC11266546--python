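"""Distance-biased graph transformer over atom tokens.

Atoms are tokens; there is no positional encoding, so the architecture is
permutation-equivariant and, because geometry enters only through pairwise
distances, invariant under rigid motions of the structure by construction.

Each token starts as Concat(element embedding, physical features) projected
to the hidden width H.  Pairwise distances D are expanded into K Gaussian
radial basis channels plus a C-way one-hot distance category; a linear map
of these pair features yields an additive per-head attention bias applied to
the pre-softmax logits of every attention layer.  An attention block is two
biased attention layers followed by one MLP, each with pre-layer-norm
residual wiring.

For masked-amino-acid pretraining, the final-layer states of all tokens
within 8 Å of the masked residue's Cα are mean-pooled and passed through a
Linear-ReLU-Linear classifier (hidden 128, output 20) whose softmax gives
the 20 amino-acid likelihoods.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import (EMA, Embedding, LayerNorm, Linear, Module, Tensor,
                        concat, softmax)
from ._tables import AA_INDEX, AA_ORDER, ELEMENT_VOCAB, PAD_INDEX
from .microenv import Microenvironment

__all__ = [
    "BackboneConfig", "AALikelihoods", "GraphTransformerBackbone",
    "rbf_encode", "categorize_distance", "default_bandwidths",
    "cross_entropy", "pretrain_loss",
]


def default_bandwidths(k: int = 16, lo: float = 0.5, hi: float = 20.0
                       ) -> tuple[float, ...]:
    """Log-spaced Gaussian RBF bandwidths (Angstrom)."""
    return tuple(np.geomspace(lo, hi, k))


@dataclass
class BackboneConfig:
    embed_dim: int = 20                 # element-embedding width E
    phys_dim: int = 2                   # physical features P (charge, SASA)
    token_dim: int = 128                # hidden width H
    n_blocks: int = 4
    n_heads: int = 8
    rbf_k: int = 16
    rbf_bandwidths: tuple = field(default_factory=default_bandwidths)
    n_distance_classes: int = 4
    class_boundaries: tuple = (2.2, 4.0, 8.0)   # covalent/first-shell/mid/long
    classifier_hidden: int = 128
    mlp_hidden: int | None = None       # defaults to 5*token_dim
    dropout: float = 0.1
    max_tokens: int = 512

    def __post_init__(self):
        if self.token_dim % self.n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        if len(self.rbf_bandwidths) != self.rbf_k:
            raise ValueError("need rbf_k bandwidths")
        if any(b <= 0 for b in self.rbf_bandwidths):
            raise ValueError("bandwidths must be positive")
        if list(self.class_boundaries) != sorted(self.class_boundaries):
            raise ValueError("class boundaries must be ascending")
        if len(self.class_boundaries) != self.n_distance_classes - 1:
            raise ValueError("need n_distance_classes - 1 boundaries")
        if self.mlp_hidden is None:
            self.mlp_hidden = 5 * self.token_dim

    @classmethod
    def desk(cls, **over) -> "BackboneConfig":
        """Small CPU-scale configuration for tests and toy runs."""
        kw = dict(token_dim=32, n_blocks=1, n_heads=4, classifier_hidden=32,
                  mlp_hidden=64, dropout=0.0)
        kw.update(over)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rbf_bandwidths"] = list(self.rbf_bandwidths)
        d["class_boundaries"] = list(self.class_boundaries)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["rbf_bandwidths"] = tuple(d["rbf_bandwidths"])
        d["class_boundaries"] = tuple(d["class_boundaries"])
        return cls(**d)


@dataclass
class AALikelihoods:
    probs: np.ndarray   # (20,), canonical AA order

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (20,):
            raise ValueError("need 20 amino-acid likelihoods")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("likelihoods must be a probability vector")

    def top(self) -> str:
        return AA_ORDER[int(np.argmax(self.probs))]


def rbf_encode(D: np.ndarray, bandwidths) -> np.ndarray:
    """(N,N,K) Gaussian kernels exp(-D^2 / (2 sigma_k^2))."""
    bw = np.asarray(bandwidths, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("bandwidths must be positive")
    D = np.asarray(D, dtype=float)
    return np.exp(-(D[..., None] ** 2) / (2.0 * bw ** 2))


def categorize_distance(D: np.ndarray, boundaries) -> np.ndarray:
    """(N,N,C) one-hot distance category.

    Bins are [0, b1], (b1, b2], (b2, b3], (b3, inf): a distance exactly at a
    boundary falls in the lower bin (closed-right convention).
    """
    b = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly ascending")
    idx = np.searchsorted(b, np.asarray(D, dtype=float), side="left")
    out = np.zeros(D.shape + (len(b) + 1,))
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


class _Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class BiasedSelfAttention(Module):
    """Multi-head self-attention with an additive distance-derived bias."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        H = cfg.token_dim
        self.n_heads = cfg.n_heads
        self.d_head = H // cfg.n_heads
        self.qkv = Linear(H, 3 * H, rng)
        self.out = Linear(H, H, rng)
        self.bias_proj = Linear(cfg.rbf_k + cfg.n_distance_classes,
                                cfg.n_heads, rng)

    def attention_bias(self, pair_feats: np.ndarray) -> Tensor:
        """(N,N,K+C) pair features -> (Head,N,N) additive logits."""
        b = self.bias_proj(Tensor(pair_feats))        # (N, N, Head)
        return b.transpose(2, 0, 1)

    def __call__(self, x: Tensor, pair_feats: np.ndarray,
                 key_mask: np.ndarray | None = None) -> Tensor:
        N = x.shape[0]
        H = self.n_heads * self.d_head
        qkv = self.qkv(x)
        q = qkv[:, 0:H].reshape(N, self.n_heads, self.d_head).transpose(1, 0, 2)
        k = qkv[:, H:2 * H].reshape(N, self.n_heads, self.d_head).transpose(1, 0, 2)
        v = qkv[:, 2 * H:3 * H].reshape(N, self.n_heads, self.d_head).transpose(1, 0, 2)
        logits = q @ k.transpose(0, 2, 1) * (1.0 / math.sqrt(self.d_head))
        logits = logits + self.attention_bias(pair_feats)
        if key_mask is not None:
            # padded keys get -inf-like logits so softmax ignores them
            add = np.where(np.asarray(key_mask, bool), 0.0, -1e30)
            logits = logits + Tensor(add[None, None, :])
        attn = softmax(logits, axis=-1)
        ctx = (attn @ v).transpose(1, 0, 2).reshape(N, H)
        return self.out(ctx)


class AttentionBlock(Module):
    """Two biased attention layers and one MLP, pre-LN residual wiring."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        H = cfg.token_dim
        self.ln1 = LayerNorm(H)
        self.attn1 = BiasedSelfAttention(cfg, rng)
        self.ln2 = LayerNorm(H)
        self.attn2 = BiasedSelfAttention(cfg, rng)
        self.ln3 = LayerNorm(H)
        self.fc1 = Linear(H, cfg.mlp_hidden, rng)
        self.fc2 = Linear(cfg.mlp_hidden, H, rng)
        self.drop = _Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor, pair_feats: np.ndarray,
                 key_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.drop(self.attn1(self.ln1(x), pair_feats, key_mask))
        x = x + self.drop(self.attn2(self.ln2(x), pair_feats, key_mask))
        x = x + self.drop(self.fc2(self.fc1(self.ln3(x)).relu()))
        return x


class GraphTransformerBackbone(Module):
    """Self-supervised backbone + masked-amino-acid classifier."""

    def __init__(self, config: BackboneConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or BackboneConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.element_embed = Embedding(PAD_INDEX + 1, cfg.embed_dim, rng)
        self.in_proj = Linear(cfg.embed_dim + cfg.phys_dim, cfg.token_dim, rng)
        self.blocks = [AttentionBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.final_ln = LayerNorm(cfg.token_dim)
        self.cls_fc1 = Linear(cfg.token_dim, cfg.classifier_hidden, rng)
        self.cls_fc2 = Linear(cfg.classifier_hidden, 20, rng)

    # -- featurization ----------------------------------------------------
    def pair_features(self, D: np.ndarray) -> np.ndarray:
        cfg = self.config
        return np.concatenate(
            [rbf_encode(D, cfg.rbf_bandwidths),
             categorize_distance(D, cfg.class_boundaries)], axis=-1)

    # -- forward ----------------------------------------------------------
    def forward_tokens(self, env: Microenvironment) -> Tensor:
        """Final-layer token states, (N, H)."""
        if env.n_tokens == 0:
            raise ValueError("empty microenvironment")
        if env.n_tokens > self.config.max_tokens:
            raise ValueError(f"{env.n_tokens} tokens exceeds cap "
                             f"{self.config.max_tokens}")
        e = self.element_embed(env.elements)
        h = self.in_proj(concat([e, Tensor(env.phys)], axis=1))
        pf = self.pair_features(env.distances)
        for block in self.blocks:
            h = block(h, pf)
        return self.final_ln(h)

    def masked_aa_logits(self, env: Microenvironment) -> Tensor:
        """20-way logits from the 8 Å mean-pooled token states."""
        if not env.pool_mask.any():
            raise ValueError("no atoms inside the pooling shell; cannot pool")
        h = self.forward_tokens(env)
        idx = np.flatnonzero(env.pool_mask)
        pooled = h[idx].mean(axis=0)                 # (H,)
        return self.cls_fc2(self.cls_fc1(pooled.reshape(1, -1)).relu()).reshape(20)

    def predict_masked_aa(self, env: Microenvironment) -> AALikelihoods:
        logits = self.masked_aa_logits(env)
        return AALikelihoods(softmax(logits).data)

    def n_parameters(self) -> int:
        return super().n_parameters()

    # -- checkpointing ----------------------------------------------------
    SCHEMA_VERSION = 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        meta = {"schema_version": self.SCHEMA_VERSION,
                "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GraphTransformerBackbone":
        path = Path(path)
        npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
        meta = json.loads(Path(npz).with_suffix(".json").read_text())
        model = cls(BackboneConfig.from_dict(meta["config"]))
        with np.load(npz) as data:
            model.load_state_dict(dict(data))
        return model


def cross_entropy(logits: Tensor, label_aa: str) -> Tensor:
    """-log softmax(logits)[label], numerically safe, differentiable."""
    if label_aa not in AA_INDEX:
        raise KeyError(f"unknown amino acid {label_aa!r}")
    p = softmax(logits)
    return -(p[AA_INDEX[label_aa]].log())


def pretrain_loss(probs: AALikelihoods | np.ndarray, label_aa: str) -> float:
    """Cross-entropy -log p(label) of an already-normalized prediction."""
    if label_aa not in AA_INDEX:
        raise KeyError(f"unknown amino acid {label_aa!r}")
    p = probs.probs if isinstance(probs, AALikelihoods) else np.asarray(probs)
    return float(-np.log(p[AA_INDEX[label_aa]]))
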