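"""Masked-residue microenvironments.

A microenvironment is the set of atom tokens within a radius of a target
residue's Cα, with every atom of the target residue removed ("masked").
The Cα coordinate is remembered as the center even though the atom itself
is gone.  Atoms within 8 Å of the center form the pooling shell whose final
token states are averaged for the masked-amino-acid classifier.

Boundary convention: atoms at exactly the environment radius or pooling
cutoff are included (closed ball), keeping counts deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from ._tables import THREE_TO_ONE, element_code
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 16.0      # environment radius (Angstrom)
POOL_CUTOFF = 8.0          # first-contact-shell pooling radius (Angstrom)
DEFAULT_MAX_TOKENS = 512   # attention-cost cap; farthest atoms dropped


@dataclass
class Microenvironment:
    center: np.ndarray                 # Cα of the masked residue (3,)
    elements: np.ndarray               # (N,) int codes into ELEMENT_VOCAB
    phys: np.ndarray                   # (N, 2): partial charge, SASA
    coords: np.ndarray                 # (N, 3) Angstrom
    distances: np.ndarray              # (N, N) Angstrom
    pool_mask: np.ndarray              # (N,) bool, distance to center <= 8 A
    label_aa: str | None = None        # one-letter code of the masked residue
    meta: dict = field(default_factory=dict)

    @property
    def n_tokens(self) -> int:
        return len(self.elements)

    def save(self, path: str | Path) -> None:
        """Write the tensor bundle (.npz) plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez(path, center=self.center, elements=self.elements,
                 phys=self.phys, coords=self.coords,
                 distances=self.distances, pool_mask=self.pool_mask)
        meta = dict(self.meta)
        meta["label_aa"] = self.label_aa
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Microenvironment":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        label = meta.pop("label_aa", None)
        return cls(center=data["center"], elements=data["elements"],
                   phys=data["phys"], coords=data["coords"],
                   distances=data["distances"], pool_mask=data["pool_mask"],
                   label_aa=label, meta=meta)


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    D = cdist(coords, coords)
    np.fill_diagonal(D, 0.0)
    return D


def pooling_mask(coords: np.ndarray, center: np.ndarray,
                 cutoff: float = POOL_CUTOFF) -> np.ndarray:
    """True where distance(atom, center) <= cutoff (closed ball)."""
    if cutoff <= 0:
        raise ValueError("pooling cutoff must be positive")
    d = np.linalg.norm(np.asarray(coords, float) - np.asarray(center, float),
                       axis=1)
    return d <= cutoff


def build_masked_microenv(structure: ProteinStructure, chain: str,
                          residue_number: int,
                          radius: float = DEFAULT_RADIUS,
                          pool_cutoff: float = POOL_CUTOFF,
                          max_tokens: int = DEFAULT_MAX_TOKENS,
                          ) -> Microenvironment:
    """Mask a residue and collect the surrounding atom tokens.

    All atoms of the target residue are removed; the remaining atoms within
    ``radius`` of the target's Cα are retained (closed ball), truncated to
    ``max_tokens`` by ascending distance if necessary.
    """
    target = structure.residue_atoms(chain, residue_number)  # KeyError if absent
    ca = next((a for a in target if a.atom_name == "CA"), None)
    if ca is None:
        raise ValueError(f"residue {chain}/{residue_number} of "
                         f"{structure.structure_id!r} has no C-alpha atom")
    center = np.asarray(ca.coords, dtype=float)
    label = THREE_TO_ONE.get(target[0].residue_name)

    target_ids = set(map(id, target))
    others = [a for a in structure.atoms if id(a) not in target_ids]
    if others:
        coords = np.array([a.coords for a in others], dtype=float)
        dist = np.linalg.norm(coords - center, axis=1)
        keep = np.flatnonzero(dist <= radius)
    else:
        keep = np.array([], dtype=int)
    if keep.size == 0:
        raise ValueError(
            f"no atoms within {radius} A of {chain}/{residue_number}: "
            "isolated residue or degenerate radius")
    if keep.size > max_tokens:
        order = keep[np.argsort(dist[keep], kind="stable")][:max_tokens]
        keep = np.sort(order)
        logger.info("environment truncated to %d tokens (radius %.1f A)",
                    max_tokens, radius)

    kept = [others[i] for i in keep]
    coords = np.array([a.coords for a in kept], dtype=float)
    env = Microenvironment(
        center=center,
        elements=np.array([element_code(a.element) for a in kept], dtype=int),
        phys=np.array([[a.partial_charge, a.sasa] for a in kept], dtype=float),
        coords=coords,
        distances=pairwise_distances(coords),
        pool_mask=pooling_mask(coords, center, pool_cutoff),
        label_aa=label,
        meta={"structure_id": structure.structure_id, "chain": chain,
              "residue_number": residue_number, "radius": radius},
    )
    return env
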