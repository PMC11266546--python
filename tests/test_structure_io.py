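"""Parsing, charge assignment, and Shrake-Rupley SASA."""

import math

import numpy as np
import pytest

from ddgformer._tables import default_charge_table, per_residue_charge_sums
from ddgformer.structure_io import (StructureParseError, assign_partial_charges,
                                    chain_sequences, compute_sasa,
                                    parse_structure, write_pdb,
                                    _golden_spiral_points)
from ddgformer.structure_io import AtomRecord, ProteinStructure
from ddgformer.synthetic import (SyntheticSpec, declared_atom_count,
                                 make_helix_structure)
from tests.conftest import rigid_motion


def _atom(x, y, z, element="C", name="CA", res="ALA", resnum=1, serial=1):
    return AtomRecord(serial=serial, atom_name=name, element=element,
                      residue_name=res, chain_id="A", residue_number=resnum,
                      coords=np.array([x, y, z], dtype=float))


# -- parsing --------------------------------------------------------------

def test_parse_synthetic_helix_atom_count(tmp_path):
    spec = SyntheticSpec(seed=3, n_residues=5)
    st = make_helix_structure(spec, structure_id="h5")
    seq = spec.resolved_sequence()
    assert len(st) == declared_atom_count(seq)
    path = tmp_path / "h5.pdb"
    write_pdb(st, path)
    parsed = parse_structure(path)
    assert len(parsed) == len(st)


def test_altloc_keeps_highest_occupancy(tmp_path):
    pdb = tmp_path / "alt.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00"
        "           N\n"
        "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60  0.00"
        "           C\n"
        "ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.40  0.00"
        "           C\n"
        "END\n")
    st = parse_structure(pdb)
    cas = [a for a in st.atoms if a.atom_name == "CA"]
    assert len(cas) == 1
    assert cas[0].coords[0] == pytest.approx(1.0)
    assert cas[0].occupancy == pytest.approx(0.6)


def test_empty_file_is_a_parse_error(tmp_path):
    empty = tmp_path / "empty.pdb"
    empty.write_text("")
    with pytest.raises(StructureParseError):
        parse_structure(empty)


def test_missing_model_index_error(tmp_path, helix):
    path = tmp_path / "h.pdb"
    write_pdb(helix, path)
    with pytest.raises(StructureParseError, match="model index 3"):
        parse_structure(path, model_index=3)


def test_roundtrip_preserves_coordinates_to_pdb_precision(tmp_path, helix):
    path = tmp_path / "rt.pdb"
    write_pdb(helix, path)
    back = parse_structure(path)
    assert len(back) == len(helix)
    assert np.abs(back.coords - helix.coords).max() <= 1e-3 + 1e-9


def test_chain_sequences(helix):
    seqs = chain_sequences(helix)
    assert set(seqs) == {"A"}
    assert len(seqs["A"]) == 20


# -- partial charges ------------------------------------------------------

def test_charge_lookup_identity():
    st = ProteinStructure([_atom(0, 0, 0, "N", "N", "GLY")])
    assign_partial_charges(st)
    table = default_charge_table()
    assert st.atoms[0].partial_charge == table[("GLY", "N")]
    assert st.metadata["n_uncharged"] == 0


def test_unknown_atom_gets_zero_with_warning_count():
    st = ProteinStructure([_atom(0, 0, 0, "C", "C99", "LIG")])
    assign_partial_charges(st)
    assert st.atoms[0].partial_charge == 0.0
    assert st.metadata["n_uncharged"] == 1


def test_total_charge_matches_per_residue_sums():
    """Brute-force summation over the bundled table equals the assigned sum
    for a structure containing every tabulated atom of three residues."""
    table = default_charge_table()
    sums = per_residue_charge_sums()
    atoms, serial = [], 0
    for i, res in enumerate(("ALA", "ARG", "TRP")):
        for (r, name), _q in table.items():
            if r == res:
                serial += 1
                atoms.append(_atom(serial * 2.0, 0, 0, "C", name, res,
                                   resnum=i + 1, serial=serial))
    st = ProteinStructure(atoms)
    assign_partial_charges(st)
    total = sum(a.partial_charge for a in st.atoms)
    expected = sums["ALA"] + sums["ARG"] + sums["TRP"]
    assert total == pytest.approx(expected, abs=1e-12)


# -- SASA -----------------------------------------------------------------

def test_isolated_carbon_sphere_area():
    st = ProteinStructure([_atom(0, 0, 0, "C")])
    compute_sasa(st)
    expected = 4 * math.pi * (1.7 + 1.4) ** 2     # ~120.76 A^2
    assert st.atoms[0].sasa == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(120.76, abs=0.01)


def test_distant_atoms_fully_exposed():
    st = ProteinStructure([_atom(0, 0, 0, "C"),
                           _atom(100, 0, 0, "O", serial=2, resnum=2)])
    compute_sasa(st)
    assert st.atoms[0].sasa == pytest.approx(4 * math.pi * 3.1 ** 2)
    assert st.atoms[1].sasa == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2)


def test_fully_enclosed_atom_has_zero_sasa():
    """An atom caged by a dense shell gets zero area, matching a
    brute-force point-rejection oracle at high point count."""
    shell_dirs = _golden_spiral_points(80)
    atoms = [_atom(0, 0, 0, "C")]
    for i, d in enumerate(shell_dirs):
        p = 1.8 * d
        atoms.append(_atom(p[0], p[1], p[2], "C", serial=i + 2, resnum=i + 2))
    st = ProteinStructure(atoms)
    compute_sasa(st)
    assert st.atoms[0].sasa == 0.0

    # independent oracle: dense point rejection with simple loops
    pts = np.array([3.1 * d for d in _golden_spiral_points(4000)])
    centers = np.array([a.coords for a in atoms[1:]])
    exposed = 0
    for pt in pts:
        if all(np.linalg.norm(pt - c) >= 3.1 for c in centers):
            exposed += 1
    assert exposed == 0


def test_sasa_translation_invariant(helix):
    import copy
    moved = copy.deepcopy(helix)
    for a in moved.atoms:
        a.coords = a.coords + np.array([37.0, -12.0, 5.0])
    compute_sasa(moved)
    orig = np.array([a.sasa for a in helix.atoms])
    new = np.array([a.sasa for a in moved.atoms])
    assert np.abs(orig - new).max() < 1e-6


def test_sasa_rotation_invariant_within_one_percent(helix):
    import copy
    Q, _t = rigid_motion(np.random.default_rng(5))
    moved = copy.deepcopy(helix)
    for a in moved.atoms:
        a.coords = Q @ a.coords
    compute_sasa(moved)
    orig = sum(a.sasa for a in helix.atoms)
    new = sum(a.sasa for a in moved.atoms)
    assert abs(orig - new) / orig < 0.01


def test_total_sasa_non_increasing_as_atoms_added():
    rng = np.random.default_rng(9)
    atoms = [_atom(*rng.uniform(-4, 4, 3), serial=i + 1, resnum=i + 1)
             for i in range(12)]
    prev_totals = []
    for n in (4, 8, 12):
        st = ProteinStructure([_atom(*a.coords, serial=a.serial,
                                     resnum=a.residue_number)
                               for a in atoms[:n]])
        compute_sasa(st)
        # total over the first 4 atoms only: occlusion can only grow
        prev_totals.append(sum(x.sasa for x in st.atoms[:4]))
    assert prev_totals[0] >= prev_totals[1] >= prev_totals[2]


def test_empty_structure_sasa_errors():
    with pytest.raises(ValueError):
        compute_sasa(ProteinStructure([]))


def test_sasa_agrees_with_independent_implementation(helix):
    """Cross-check against biotite's Shrake-Rupley on the same radii."""
    biotite = pytest.importorskip("biotite.structure")
    import biotite.structure as struc
    from ddgformer._tables import vdw_radius

    arr = struc.AtomArray(len(helix))
    arr.coord = helix.coords.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = [a.residue_number for a in helix.atoms]
    arr.res_name[:] = [a.residue_name for a in helix.atoms]
    arr.atom_name[:] = [a.atom_name for a in helix.atoms]
    arr.element[:] = [a.element for a in helix.atoms]
    radii = np.array([vdw_radius(a.element) for a in helix.atoms],
                     dtype=np.float32)
    ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                     vdw_radii=radii)
    ours = np.array([a.sasa for a in helix.atoms])
    assert np.abs(ours - ref).sum() / ref.sum() < 0.05
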