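"""Losses, optimizer recipes, and pretrain/fine-tune loops.

The reference recipe: Huber loss (δ = 1 kcal/mol), AdamW with a 5e-5
learning rate on regression-head parameters and 2e-5 on backbone
parameters, effective batch 960 as micro-batch 240 with 4 accumulation
steps, weight decay 0.1, a weight EMA with η = 0.99 used at evaluation,
and 750 iterations.  The small-dataset recipe freezes the backbone and
uses lr 5e-7 (resuming from a large-scale run) or 5e-5 (from scratch)
with batch 1024 for 500 iterations.  A constant learning rate is used
throughout.

Desk-scale presets shrink batch sizes and iteration counts so the loops
run in seconds to minutes on one CPU; everything else is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import EMA, AdamW, Tensor
from .ddg_head import StabilityModel
from .graphformer import GraphTransformerBackbone, cross_entropy
from .microenv import Microenvironment
from .thermo_augment import DdgRecord

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "huber_loss", "huber_loss_tensor", "ema_update",
           "pretrain_run", "finetune_run", "TrainingHistory"]


@dataclass
class TrainConfig:
    huber_delta: float = 1.0
    head_lr: float = 5e-5
    backbone_lr: float = 2e-5
    micro_batch: int = 240
    accumulation: int = 4          # effective batch = micro_batch * accumulation
    weight_decay: float = 0.1
    ema_eta: float = 0.99
    iterations: int = 750
    freeze_backbone: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.head_lr <= 0 or self.backbone_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.micro_batch < 1 or self.accumulation < 1:
            raise ValueError("batch settings must be positive")

    @property
    def batch_size(self) -> int:
        return self.micro_batch * self.accumulation

    @classmethod
    def reference(cls, **over) -> "TrainConfig":
        """Full-scale end-to-end recipe."""
        return cls(**over)

    @classmethod
    def small_set(cls, from_scratch: bool = False, **over) -> "TrainConfig":
        """Small-dataset recipe: frozen backbone, batch 1024, 500 iterations."""
        kw = dict(head_lr=5e-5 if from_scratch else 5e-7,
                  micro_batch=1024, accumulation=1, iterations=500,
                  freeze_backbone=True)
        kw.update(over)
        return cls(**kw)

    @classmethod
    def desk(cls, **over) -> "TrainConfig":
        """CPU-scale preset for tests and toy benchmarks."""
        kw = dict(head_lr=3e-3, backbone_lr=1e-3, micro_batch=16,
                  accumulation=1, weight_decay=0.01, iterations=200)
        kw.update(over)
        return cls(**kw)


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"step": range(len(self.loss)), "loss": self.loss})


def huber_loss(residual, delta: float = 1.0):
    """Huber loss: 0.5 r^2 for |r| <= δ, else δ(|r| - 0.5 δ)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(residual, dtype=float)
    quad = np.abs(r) <= delta
    out = np.where(quad, 0.5 * r ** 2, delta * (np.abs(r) - 0.5 * delta))
    return float(out) if out.ndim == 0 else out


def huber_loss_tensor(residual: Tensor, delta: float = 1.0) -> Tensor:
    """Differentiable Huber loss on a scalar residual tensor."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    quad = float(abs(float(residual.data)) <= delta)
    return (quad * 0.5) * residual * residual \
        + (1.0 - quad) * delta * (residual.abs() - 0.5 * delta)


def ema_update(shadow: np.ndarray, live: np.ndarray, eta: float = 0.99
               ) -> np.ndarray:
    """shadow <- eta * shadow + (1 - eta) * live (shapes must match)."""
    shadow = np.asarray(shadow, dtype=float)
    live = np.asarray(live, dtype=float)
    if shadow.shape != live.shape:
        raise ValueError(f"shape mismatch: {shadow.shape} vs {live.shape}")
    return eta * shadow + (1.0 - eta) * live


def _param_ids(params) -> set[int]:
    return {id(p) for p in params}


def pretrain_run(model: GraphTransformerBackbone,
                 environments: list[Microenvironment],
                 config: TrainConfig) -> tuple[GraphTransformerBackbone,
                                               TrainingHistory]:
    """Masked-amino-acid pretraining with cross-entropy loss.

    Environments without a label are skipped with a warning; training is
    deterministic under ``config.seed``.  The returned model carries the
    EMA shadow weights in ``model._ema`` for evaluation-time swapping.
    """
    usable = [e for e in environments if e.label_aa is not None]
    history = TrainingHistory(
        skipped=[str(e.meta) for e in environments if e.label_aa is None])
    for s in history.skipped:
        logger.warning("skipping unlabeled environment %s", s)
    if not usable:
        raise ValueError("no labeled environments to pretrain on")
    rng = np.random.default_rng(config.seed)
    opt = AdamW([{"params": model.parameters(), "lr": config.head_lr,
                  "weight_decay": config.weight_decay}])
    ema = EMA(model, eta=config.ema_eta)
    model.train()
    for _step in range(config.iterations):
        opt.zero_grad()
        total = 0.0
        for _acc in range(config.accumulation):
            idx = rng.integers(0, len(usable), size=min(config.micro_batch,
                                                        len(usable)))
            losses = [cross_entropy(model.masked_aa_logits(usable[i]),
                                    usable[i].label_aa) for i in idx]
            batch_loss = sum(losses[1:], losses[0]) * (1.0 / len(losses))
            (batch_loss * (1.0 / config.accumulation)).backward()
            total += float(batch_loss.data) / config.accumulation
        opt.step()
        ema.update(model)
        history.loss.append(total)
    model.eval()
    model._ema = ema
    return model, history


def finetune_run(model: StabilityModel, records: list[DdgRecord],
                 env_for: dict[tuple, Microenvironment],
                 config: TrainConfig) -> tuple[StabilityModel, TrainingHistory]:
    """Fine-tune the ΔΔG model with Huber loss and per-group learning rates.

    ``env_for`` maps (protein_id, chain, position) to the masked wild-type
    microenvironment; augmented (TP/TR) records reuse the same environment
    with non-wild-type "from" embeddings.  Records without an environment
    are skipped with a warning.  When ``config.freeze_backbone`` is set the
    backbone parameters are excluded from the optimizer and bit-identical
    after the run.
    """
    usable, history = [], TrainingHistory()
    for r in records:
        env = env_for.get(r.site)
        if env is None:
            history.skipped.append(str(r.site))
            logger.warning("no microenvironment for %s; record skipped", r.site)
        else:
            usable.append((r, env))
    if not usable:
        raise ValueError("every record was skipped; nothing to train on")

    backbone_params = model.backbone.parameters()
    backbone_ids = _param_ids(backbone_params)
    head_params = [p for p in model.parameters() if id(p) not in backbone_ids]
    groups = [{"params": head_params, "lr": config.head_lr,
               "weight_decay": config.weight_decay}]
    if not config.freeze_backbone:
        groups.append({"params": backbone_params, "lr": config.backbone_lr,
                       "weight_decay": config.weight_decay})
    opt = AdamW(groups)
    ema = EMA(model, eta=config.ema_eta)
    rng = np.random.default_rng(config.seed)
    model.train()
    for _step in range(config.iterations):
        opt.zero_grad()
        total = 0.0
        for _acc in range(config.accumulation):
            idx = rng.integers(0, len(usable), size=min(config.micro_batch,
                                                        len(usable)))
            # records sharing a microenvironment share one backbone forward
            # and one contextualization per amino acid (losses are summed
            # before backward, so subgraph reuse is exact)
            tok_cache: dict[int, tuple] = {}
            u_cache: dict[tuple, Tensor] = {}
            losses = []
            for i in idx:
                rec, env = usable[i]
                key = id(env)
                if key not in tok_cache:
                    tok = model.backbone.forward_tokens(env)
                    pf = model._extend_pair_features(
                        model.backbone.pair_features(env.distances))
                    tok_cache[key] = (tok, pf)
                tok, pf = tok_cache[key]
                for aa in (rec.from_aa, rec.to_aa):
                    if (key, aa) not in u_cache:
                        u_cache[(key, aa)] = model._contextualize(
                            tok, model.aa_embedding(aa), pf)
                diff = u_cache[(key, rec.to_aa)] - u_cache[(key, rec.from_aa)]
                pred = model.decoder(diff).reshape(())
                losses.append(huber_loss_tensor(pred - rec.ddg,
                                                config.huber_delta))
            batch_loss = sum(losses[1:], losses[0]) * (1.0 / len(losses))
            (batch_loss * (1.0 / config.accumulation)).backward()
            total += float(batch_loss.data) / config.accumulation
        if config.freeze_backbone:
            for p in backbone_params:
                p.grad = None
        opt.step()
        ema.update(model)
        history.loss.append(total)
    model.eval()
    model._ema = ema
    return model, history
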