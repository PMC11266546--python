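"""Protein structure parsing and per-atom physical features.

Atoms are parsed from PDB or mmCIF files (via gemmi) into a flat,
order-preserving :class:`ProteinStructure`.  Two feature-assignment passes
attach the per-atom physical properties used by the graph transformer:
partial charges from a bundled AMBER-style lookup and solvent-accessible
surface area (SASA) from a deterministic Shrake–Rupley implementation with
golden-spiral sphere points.

SASA is always computed on the full, unmasked structure: the features
describe the native chemical environment before any residue is masked.
Hydrogens are kept if present in the file and never added.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (THREE_TO_ONE, default_charge_table, element_code,
                      vdw_radius)

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed into atoms."""


@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    element: str               # one of C,N,O,S,P,H or "other"
    residue_name: str          # 3-letter code (or het name)
    chain_id: str
    residue_number: int        # author numbering
    insertion_code: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    partial_charge: float = 0.0
    sasa: float = 0.0
    hetero: bool = False


@dataclass
class ProteinStructure:
    atoms: list[AtomRecord]
    structure_id: str = ""
    resolution: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            index.setdefault((a.chain_id, a.residue_number), []).append(i)
        self.index = index

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[AtomRecord]:
        idx = self.index.get((chain_id, residue_number))
        if idx is None:
            raise KeyError(f"no residue {chain_id}/{residue_number} in "
                           f"structure {self.structure_id!r}")
        return [self.atoms[i] for i in idx]

    def residue_name(self, chain_id: str, residue_number: int) -> str:
        return self.residue_atoms(chain_id, residue_number)[0].residue_name

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered (chain_id, residue_number, residue_name) triples."""
        seen: list[tuple[str, int, str]] = []
        done: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if key not in done:
                done.add(key)
                seen.append((a.chain_id, a.residue_number, a.residue_name))
        return seen


def parse_structure(path: str | Path, model_index: int = 0,
                    keep_hetero: bool = True,
                    keep_waters: bool = False) -> ProteinStructure:
    """Parse a PDB/mmCIF file into a :class:`ProteinStructure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first in file order).  Waters are excluded unless
    ``keep_waters``; other hetero atoms are retained unless ``keep_hetero``
    is False.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if model_index >= len(st):
        raise StructureParseError(
            f"model index {model_index} out of range: {path} has "
            f"{len(st)} model(s)")
    model = st[model_index]

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES and not keep_waters:
                continue
            het = res.het_flag == "H"
            if het and res.name not in _WATER_NAMES and not keep_hetero:
                continue
            # resolve altlocs: keep the highest-occupancy conformer per atom
            # name; ties keep the first occurrence in file order
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                serial += 1
                el = atom.element.name if atom.element else "C"
                atoms.append(AtomRecord(
                    serial=serial,
                    atom_name=name,
                    element=el,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    hetero=het,
                ))
    if not atoms:
        raise StructureParseError(
            f"model {model_index} of {path} contains no atoms")
    res_ = st.resolution if st.resolution and st.resolution > 0 else None
    return ProteinStructure(atoms=atoms, structure_id=st.name or path.stem,
                            resolution=res_)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write ATOM/HETATM records (PDB v3.3 fixed columns)."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            rec = "HETATM" if a.hetero else "ATOM  "
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            el = a.element if len(a.element) <= 2 else a.element[:2]
            fh.write(
                f"{rec}{a.serial:5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id[:1]}{a.residue_number:4d}{a.insertion_code or ' ':1s}"
                f"   {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {el.upper():>2s}\n")
        fh.write("END\n")


def chain_sequences(structure: ProteinStructure) -> dict[str, str]:
    """One-letter amino-acid sequence per chain (standard residues only)."""
    seqs: dict[str, str] = {}
    for chain_id, _num, name in structure.residues():
        one = THREE_TO_ONE.get(name)
        if one is not None:
            seqs[chain_id] = seqs.get(chain_id, "") + one
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line
    return seqs


def assign_partial_charges(
        structure: ProteinStructure,
        charge_table: dict[tuple[str, str], float] | None = None,
) -> ProteinStructure:
    """Set every atom's partial charge from a (residue, atom-name) lookup.

    Atoms absent from the table get charge 0.0; the number of such atoms is
    logged and recorded in ``structure.metadata['n_uncharged']``.
    """
    table = default_charge_table() if charge_table is None else charge_table
    missing = 0
    for a in structure.atoms:
        q = table.get((a.residue_name, a.atom_name))
        if q is None:
            a.partial_charge = 0.0
            missing += 1
        else:
            a.partial_charge = q
    structure.metadata["n_uncharged"] = missing
    if missing:
        logger.warning("%d/%d atoms had no charge-table entry (set to 0.0)",
                       missing, len(structure.atoms))
    return structure


def _golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(structure: ProteinStructure, probe_radius: float = 1.4,
                 n_sphere_points: int = 960) -> ProteinStructure:
    """Per-atom SASA (Shrake–Rupley, deterministic golden-spiral points).

    Each atom is expanded by the probe radius; the accessible fraction of
    its expanded sphere is the fraction of test points not inside any
    neighbouring expanded sphere.
    """
    if len(structure) == 0:
        raise ValueError("cannot compute SASA of an empty structure")
    coords = structure.coords
    radii = np.array([vdw_radius(a.element) + probe_radius
                      for a in structure.atoms])
    sphere = _golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    for i, atom in enumerate(structure.atoms):
        r = radii[i]
        pts = coords[i] + r * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], r + max_r)
                 if j != i]
        if neigh:
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom.sasa = 4.0 * math.pi * r * r * frac
    return structure


def residue_sasa(structure: ProteinStructure, chain_id: str,
                 residue_number: int) -> float:
    return sum(a.sasa for a in structure.residue_atoms(chain_id, residue_number))
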