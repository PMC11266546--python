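"""Deterministic synthetic fixtures: toy structures, ΔΔG tables, planted tasks.

Everything here exists so the rest of the package is testable offline and
in seconds: small α-helical structures with plausible geometry, ΔΔG tables
with the statistical shape that thermodynamic permutations assume (one wild
type per position, several distinct characterized mutants, a destabilizing
skew), and a planted antisymmetric regression task with a known generative
model for parameter-recovery benchmarks.

All generators are bit-reproducible under their seed.  The structures are
parametric helices (rise 1.5 Å, 100° twist, Cα radius 2.3 Å — consecutive
Cα–Cα ≈ 3.8 Å) with one side-chain pseudo-atom per residue beyond glycine;
the pseudo-atom's element encodes the residue's chemical class so that
environments carry elemental signal without a rotamer engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import AA_INDEX, AA_ORDER, ONE_TO_THREE
from .microenv import Microenvironment, pairwise_distances, pooling_mask
from .structure_io import AtomRecord, ProteinStructure
from .thermo_augment import DdgRecord

__all__ = ["SyntheticSpec", "make_helix_structure", "make_ddg_table",
           "make_planted_task", "make_pretrain_toy", "AA_PROPERTIES"]

# fixed per-AA properties for planted tasks: normalized hydropathy
# (Kyte-Doolittle), normalized side-chain volume, formal charge
_KD = {"A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
       "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
       "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
       "W": -0.9, "Y": -1.3}
_VOL = {"A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
        "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
        "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
        "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6}
_CHG = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

AA_PROPERTIES = np.array(
    [[_KD[a] / 4.5, (_VOL[a] - 60.1) / 167.7, _CHG.get(a, 0.0)]
     for a in AA_ORDER])

# pseudo side-chain element per chemical class
_SIDE_ELEMENT = {**{a: "C" for a in "AILVFWP"},
                 **{a: "O" for a in "STNQYDE"},
                 **{a: "N" for a in "KRH"},
                 **{a: "S" for a in "CM"}}


@dataclass
class SyntheticSpec:
    n_residues: int = 30
    sequence: str | None = None      # derived from the potential if None
    seed: int = 0
    noise_sd: float = 0.3            # kcal/mol, ~average experimental error
    potential: np.ndarray | None = None   # planted per-AA potential g (20,)
    plan: dict[int, int] = field(default_factory=dict)  # position -> n mutants

    def resolved_potential(self) -> np.ndarray:
        if self.potential is not None:
            return np.asarray(self.potential, dtype=float)
        rng = np.random.default_rng(self.seed + 1000)
        # positive-mean potential: mutations away from low-g wild types are
        # mostly destabilizing, emulating curated experimental tables
        return rng.normal(1.2, 1.0, size=20)

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence
        g = self.resolved_potential()
        rng = np.random.default_rng(self.seed + 2000)
        low = [AA_ORDER[i] for i in np.argsort(g)[:8] if AA_ORDER[i] != "G"]
        return "".join(rng.choice(low, size=self.n_residues))


def make_helix_structure(spec: SyntheticSpec | str, seed: int | None = None,
                         structure_id: str = "synth", chain_id: str = "A",
                         jitter: float = 0.0) -> ProteinStructure:
    """Parametric α-helix with backbone N, CA, C, O and one pseudo side chain.

    ``spec`` may be a :class:`SyntheticSpec` or a plain sequence string.
    Coordinates are deterministic; optional Gaussian jitter (Å) is drawn
    from the seed.
    """
    if isinstance(spec, SyntheticSpec):
        sequence = spec.resolved_sequence()
        seed = spec.seed if seed is None else seed
    else:
        sequence = spec
        seed = 0 if seed is None else seed
    for aa in sequence:
        if aa not in AA_INDEX:
            raise ValueError(f"invalid amino acid {aa!r} in sequence")
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least 2 residues")
    rise, twist, radius = 1.5, np.deg2rad(100.0), 2.3
    i = np.arange(n)
    ca = np.column_stack([radius * np.cos(twist * i),
                          radius * np.sin(twist * i), rise * i])

    def unit(v):
        return v / np.linalg.norm(v)

    def radial(p):
        r = np.array([p[0], p[1], 0.0])
        return unit(r) if np.linalg.norm(r) > 1e-9 else np.array([1.0, 0, 0])

    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 0
    for k, aa in enumerate(sequence):
        res3 = ONE_TO_THREE[aa]
        prev_dir = unit(ca[k - 1] - ca[k]) if k > 0 else unit(ca[0] - ca[1])
        next_dir = (unit(ca[k + 1] - ca[k]) if k < n - 1
                    else unit(ca[-1] - ca[-2]))
        pos = {
            "N": ca[k] + 1.46 * prev_dir,
            "CA": ca[k],
            "C": ca[k] + 1.52 * next_dir,
            "O": ca[k] + 1.52 * next_dir + 1.23 * radial(ca[k]),
        }
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        if aa != "G":
            pos["CB"] = ca[k] + 1.53 * radial(ca[k])
            elements["CB"] = _SIDE_ELEMENT[aa]
        for name in ("N", "CA", "C", "O", *(["CB"] if aa != "G" else [])):
            serial += 1
            xyz = pos[name]
            if jitter > 0:
                xyz = xyz + rng.normal(0.0, jitter, size=3)
            atoms.append(AtomRecord(
                serial=serial, atom_name=name, element=elements[name],
                residue_name=res3, chain_id=chain_id, residue_number=k + 1,
                coords=np.asarray(xyz, dtype=float)))
    return ProteinStructure(atoms=atoms, structure_id=structure_id)


def declared_atom_count(sequence: str) -> int:
    """The atom count make_helix_structure will produce for a sequence."""
    return 4 * len(sequence) + sum(1 for aa in sequence if aa != "G")


def make_ddg_table(spec: SyntheticSpec, structure: ProteinStructure,
                   chain_id: str = "A") -> list[DdgRecord]:
    """Original-provenance ΔΔG records from a planted per-AA potential.

    ddg(wt -> a) = g(a) - g(wt) + Normal(0, noise_sd); per-position
    measurement counts follow ``spec.plan`` (position -> number of distinct
    mutant amino acids).  Output satisfies the augmentation preconditions:
    one wild type per position, distinct mutants.
    """
    g = spec.resolved_potential()
    rng = np.random.default_rng(spec.seed + 3000)
    records: list[DdgRecord] = []
    for position, n_mut in sorted(spec.plan.items()):
        wt3 = structure.residue_name(chain_id, position)
        wt = next(a for a, three in ONE_TO_THREE.items() if three == wt3)
        candidates = [a for a in AA_ORDER if a != wt]
        mutants = rng.choice(candidates, size=n_mut, replace=False)
        for m in mutants:
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            records.append(DdgRecord(
                protein_id=structure.structure_id, chain=chain_id,
                position=position, from_aa=wt, to_aa=str(m),
                ddg=float(g[AA_INDEX[m]] - g[AA_INDEX[wt]] + noise),
                provenance="original", source="synthetic"))
    return records


def _local_density(structure: ProteinStructure, chain_id: str,
                   position: int, cutoff: float = 8.0) -> float:
    ca = next(a for a in structure.residue_atoms(chain_id, position)
              if a.atom_name == "CA")
    coords = structure.coords
    d = np.linalg.norm(coords - ca.coords, axis=1)
    return float((d <= cutoff).sum())


def make_planted_task(spec: SyntheticSpec, n_structures: int = 3,
                      pairs_per_position: int = 10, test_fraction: float = 0.3,
                      gamma: float = 0.4,
                      ) -> tuple[dict[str, ProteinStructure],
                                 list[DdgRecord], list[DdgRecord]]:
    """Planted antisymmetric ΔΔG task with disjoint train/test positions.

    ΔΔG(from -> to) = w* · (φ(to) - φ(from))
                      + γ · density(position) · (φ_vol(to) - φ_vol(from))
                      + Normal(0, noise_sd)

    with φ the fixed AA property embedding and density the centered,
    scaled atom count within 8 Å of the position's Cα.  The target is
    exactly antisymmetric in (from, to) at zero noise, and a linear probe
    on φ(to) - φ(from) alone explains most, not all, of the variance — the
    density term is the structural headroom.
    """
    w_star = np.array([1.8, 1.0, 0.7])
    rng = np.random.default_rng(spec.seed + 4000)
    structures: dict[str, ProteinStructure] = {}
    sites: list[tuple[str, int, float]] = []
    for s in range(n_structures):
        sid = f"planted{s}"
        seq = "".join(rng.choice(list(AA_ORDER.replace("G", "")),
                                 size=spec.n_residues))
        st = make_helix_structure(seq, seed=spec.seed + s, structure_id=sid)
        structures[sid] = st
        for pos in range(1, spec.n_residues + 1):
            sites.append((sid, pos, _local_density(st, "A", pos)))
    dens = np.array([d for (_, _, d) in sites])
    dens = (dens - dens.mean()) / (dens.std() + 1e-12)

    order = rng.permutation(len(sites))
    n_test = int(round(test_fraction * len(sites)))
    test_idx = set(order[:n_test].tolist())

    train, test = [], []
    for si, (sid, pos, _) in enumerate(sites):
        for _ in range(pairs_per_position):
            fa, ta = rng.choice(list(AA_ORDER), size=2, replace=False)
            dphi = AA_PROPERTIES[AA_INDEX[ta]] - AA_PROPERTIES[AA_INDEX[fa]]
            ddg = float(w_star @ dphi + gamma * dens[si] * dphi[1])
            if spec.noise_sd > 0:
                ddg += rng.normal(0.0, spec.noise_sd)
            rec = DdgRecord(protein_id=sid, chain="A", position=pos,
                            from_aa=str(fa), to_aa=str(ta), ddg=ddg,
                            provenance="original", source="planted")
            (test if si in test_idx else train).append(rec)
    return structures, train, test


def make_pretrain_toy(n_envs: int = 120, seed: int = 0, n_classes: int = 3
                      ) -> list[Microenvironment]:
    """Toy masked-AA environments whose label is decodable from a feature.

    Class k (label ``A``/``G``/``L``/... in canonical order) plants
    ``2 + 7k`` nitrogen atoms among 24 carbon atoms scattered in the 8 Å
    pooling shell: the mean-pooled element composition determines the
    label exactly.
    """
    labels = [AA_ORDER[i] for i in
              np.linspace(0, 19, n_classes).astype(int)]
    rng = np.random.default_rng(seed)
    envs = []
    for i in range(n_envs):
        k = i % n_classes
        n_total = 24
        n_nitrogen = 2 + 7 * k
        elements = np.array([1] * n_nitrogen + [0] * (n_total - n_nitrogen))
        # uniform in a 3-7 A shell around the center
        u = rng.normal(size=(n_total, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.uniform(3.0, 7.0, size=n_total)
        coords = u * r[:, None]
        phys = np.column_stack([rng.normal(0, 0.2, n_total),
                                rng.uniform(0, 40, n_total)])
        envs.append(Microenvironment(
            center=np.zeros(3), elements=elements, phys=phys, coords=coords,
            distances=pairwise_distances(coords),
            pool_mask=pooling_mask(coords, np.zeros(3)),
            label_aa=labels[k],
            meta={"structure_id": f"toy{i}", "chain": "A",
                  "residue_number": i + 1}))
    return envs
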