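"""Siamese ΔΔG regression head over one masked microenvironment.

A point mutation is represented by two structural amino-acid embeddings —
the weight vectors of the "from" and "to" output neurons of the backbone's
masked-residue classifier.  Each embedding is appended as a CLS token to the
microenvironment's token states and contextualized by the regression head's
own attention blocks; the two branches share weights (Siamese) and never
co-attend.  The contextualized CLS states are subtracted and linearly
decoded:

    ddg = w · (u_to - u_from)        [kcal/mol, positive = destabilizing]

With the decoder bias fixed at zero this enforces the state-function
property of Gibbs free energy exactly: self-mutations decode to 0 and
predictions are antisymmetric under swapping "from" and "to", so
thermodynamic cycles close by construction.

Because the mutation enters only through the CLS embeddings, a single
masked microenvironment serves all 380 mutation types at a position; a deep
mutational scan needs one environment build plus 20 branch
contextualizations per residue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import LayerNorm, Linear, Module, Tensor, concat
from ._tables import AA_INDEX, AA_ORDER, THREE_TO_ONE
from .graphformer import AttentionBlock, BackboneConfig, GraphTransformerBackbone
from .microenv import DEFAULT_RADIUS, Microenvironment, build_masked_microenv
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

__all__ = ["StructuralAAEmbeddings", "MutationQuery", "DdgPrediction",
           "StabilityModel", "extract_aa_embeddings"]


@dataclass
class StructuralAAEmbeddings:
    """20×H matrix; row a is the classifier weight vector of amino acid a."""
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 20:
            raise ValueError("embeddings must be 20 x H")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embeddings must be finite")

    def row(self, aa: str) -> np.ndarray:
        return self.matrix[AA_INDEX[aa]]


@dataclass
class MutationQuery:
    structure_id: str
    chain: str
    residue_number: int
    from_aa: str
    to_aa: str


@dataclass
class DdgPrediction:
    ddg: float               # kcal/mol, positive = destabilizing
    query: MutationQuery


def extract_aa_embeddings(backbone: GraphTransformerBackbone
                          ) -> StructuralAAEmbeddings:
    """Read the structural AA embeddings off the classifier's final layer."""
    w = backbone.cls_fc2.weight.data        # (hidden, 20)
    if w.shape[1] != 20:
        raise ValueError(f"classifier final layer must have 20 outputs, "
                         f"got {w.shape}")
    return StructuralAAEmbeddings(w.T.copy())


class StabilityModel(Module):
    """Pretrained (or fresh) backbone plus Siamese regression head."""

    def __init__(self, backbone: GraphTransformerBackbone | None = None,
                 n_head_blocks: int = 2, use_decoder_bias: bool = False,
                 freeze_embeddings: bool = False, seed: int = 0):
        super().__init__()
        self.backbone = backbone or GraphTransformerBackbone(seed=seed)
        cfg = self.backbone.config
        if cfg.classifier_hidden != cfg.token_dim:
            raise ValueError(
                "structural AA embeddings live in the classifier's hidden "
                f"space ({cfg.classifier_hidden}) which must match the token "
                f"width ({cfg.token_dim}) to act as CLS tokens")
        rng = np.random.default_rng(seed + 1)
        self.head_blocks = [AttentionBlock(cfg, rng)
                            for _ in range(n_head_blocks)]
        self.head_ln = LayerNorm(cfg.token_dim)
        self.decoder = Linear(cfg.token_dim, 1, rng, bias=use_decoder_bias)
        self.n_head_blocks = n_head_blocks
        self.use_decoder_bias = use_decoder_bias
        self.freeze_embeddings = freeze_embeddings

    # -- embeddings -------------------------------------------------------
    def aa_embedding(self, aa: str) -> Tensor:
        """(1, H) structural embedding of one amino acid, live by default.

        Live means the tensor is a differentiable view of the classifier
        weights, so fine-tuning updates the embeddings unless frozen.
        """
        if aa not in AA_INDEX:
            raise KeyError(f"unknown amino acid code {aa!r}")
        col = self.backbone.cls_fc2.weight[:, AA_INDEX[aa]]
        e = col.reshape(1, -1)
        return e.detach() if self.freeze_embeddings else e

    def embeddings(self) -> StructuralAAEmbeddings:
        return extract_aa_embeddings(self.backbone)

    # -- forward ----------------------------------------------------------
    @staticmethod
    def _extend_pair_features(pf: np.ndarray) -> np.ndarray:
        """Add a CLS row/column of all-zero pair features."""
        n, _, f = pf.shape
        ext = np.zeros((n + 1, n + 1, f))
        ext[:n, :n] = pf
        return ext

    def contextualize(self, token_states: Tensor, aa_embedding: Tensor,
                      pair_features: np.ndarray | None = None) -> Tensor:
        """Run one Siamese branch; returns the final CLS state (1, H).

        ``pair_features`` are the (N, N, K+C) distance features among the
        atom tokens; the CLS token always gets an all-zero feature row and
        column (it has no coordinates).  Omitting them uses zeros
        throughout, which is only meaningful for unit checks.
        """
        n = token_states.shape[0]
        if pair_features is None:
            f = (self.backbone.config.rbf_k
                 + self.backbone.config.n_distance_classes)
            pf_ext = np.zeros((n + 1, n + 1, f))
        else:
            pf_ext = self._extend_pair_features(pair_features)
        return self._contextualize(token_states, aa_embedding, pf_ext)

    def _contextualize(self, token_states: Tensor, aa_embedding: Tensor,
                       pf_ext: np.ndarray) -> Tensor:
        if aa_embedding.shape[-1] != token_states.shape[-1]:
            raise ValueError("embedding width does not match token states")
        h = concat([token_states, aa_embedding], axis=0)
        for block in self.head_blocks:
            h = block(h, pf_ext)
        h = self.head_ln(h)
        return h[token_states.shape[0]].reshape(1, -1)

    def branch_states(self, env: Microenvironment, aas: list[str]
                      ) -> dict[str, Tensor]:
        """Contextualized CLS state per amino acid (tokens computed once)."""
        tokens = self.backbone.forward_tokens(env)
        pf_ext = self._extend_pair_features(
            self.backbone.pair_features(env.distances))
        return {aa: self._contextualize(tokens, self.aa_embedding(aa), pf_ext)
                for aa in aas}

    def ddg_tensor(self, env: Microenvironment, from_aa: str, to_aa: str
                   ) -> Tensor:
        """Differentiable ΔΔG prediction (scalar tensor)."""
        states = self.branch_states(env, [from_aa, to_aa]
                                    if from_aa != to_aa else [from_aa])
        u_from = states[from_aa]
        u_to = states[to_aa] if to_aa in states else u_from
        return self.decoder(u_to - u_from).reshape(())

    def predict_ddg(self, env: Microenvironment, from_aa: str, to_aa: str
                    ) -> DdgPrediction:
        was_training = self.training
        self.eval()
        try:
            ddg = float(self.ddg_tensor(env, from_aa, to_aa).data)
        finally:
            if was_training:
                self.train()
        q = MutationQuery(env.meta.get("structure_id", ""),
                          env.meta.get("chain", ""),
                          env.meta.get("residue_number", -1),
                          from_aa, to_aa)
        return DdgPrediction(ddg=ddg, query=q)

    # -- deep mutational scan --------------------------------------------
    def dms_scan(self, structure: ProteinStructure,
                 chains: list[str] | None = None,
                 radius: float = DEFAULT_RADIUS) -> pd.DataFrame:
        """Predict all 19 substitutions at every selected residue.

        One masked microenvironment and 20 branch contextualizations per
        residue; the cached branch states are recombined into the 19
        (wild-type -> other) predictions.
        """
        was_training = self.training
        self.eval()
        rows = []
        try:
            for chain_id, resnum, resname in structure.residues():
                if chains is not None and chain_id not in chains:
                    continue
                wt = THREE_TO_ONE.get(resname)
                if wt is None:
                    continue
                try:
                    env = build_masked_microenv(structure, chain_id, resnum,
                                                radius=radius)
                except (ValueError, KeyError) as exc:
                    logger.warning("skipping %s/%s: %s", chain_id, resnum, exc)
                    continue
                states = self.branch_states(env, list(AA_ORDER))
                u = {aa: s.data for aa, s in states.items()}
                w = self.decoder.weight.data[:, 0]
                for to_aa in AA_ORDER:
                    if to_aa == wt:
                        continue
                    ddg = float((u[to_aa] - u[wt]).ravel() @ w)
                    if self.decoder.bias is not None:
                        ddg += float(self.decoder.bias.data[0])
                    rows.append((structure.structure_id, chain_id, resnum,
                                 wt, to_aa, ddg))
        finally:
            if was_training:
                self.train()
        df = pd.DataFrame(rows, columns=["structure_id", "chain", "position",
                                         "from_aa", "to_aa",
                                         "ddg_pred_kcal_mol"])
        return df.sort_values(["chain", "position", "to_aa"],
                              kind="stable").reset_index(drop=True)

    # -- checkpointing ----------------------------------------------------
    SCHEMA_VERSION = 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        meta = {"schema_version": self.SCHEMA_VERSION,
                "config": self.backbone.config.to_dict(),
                "n_head_blocks": self.n_head_blocks,
                "use_decoder_bias": self.use_decoder_bias,
                "freeze_embeddings": self.freeze_embeddings}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StabilityModel":
        path = Path(path)
        npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
        meta = json.loads(Path(npz).with_suffix(".json").read_text())
        backbone = GraphTransformerBackbone(
            BackboneConfig.from_dict(meta["config"]))
        model = cls(backbone, n_head_blocks=meta["n_head_blocks"],
                    use_decoder_bias=meta["use_decoder_bias"],
                    freeze_embeddings=meta["freeze_embeddings"])
        with np.load(npz) as data:
            model.load_state_dict(dict(data))
        return model
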