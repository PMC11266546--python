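"""Bundled physical reference tables.

Charge values are an AMBER-style per-(residue, atom-name) lookup for heavy
atoms plus amide hydrogens; the table is a stand-in for a force-field
assignment and is swappable through configuration (``charge_table=`` on
:func:`ddgformer.structure_io.assign_partial_charges`).  Van der Waals radii
follow common united-set values; theoretical maximum SASA per amino acid is
the Tien et al. (2013) theoretical set, used to normalize RSA.
"""

from __future__ import annotations

# canonical 20-amino-acid ordering used everywhere (alphabetical one-letter)
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# hydrophobicity classes as used in the RSA bias analysis; G, C, P belong to
# neither class
POLAR_AAS = frozenset("STNQDERKHY")
HYDROPHOBIC_AAS = frozenset("LMIVFWA")

# atom-element vocabulary for the graph transformer
ELEMENT_VOCAB = ("C", "N", "O", "S", "P", "H", "other")
ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENT_VOCAB)}
PAD_INDEX = len(ELEMENT_VOCAB)  # 7


def element_code(element: str) -> int:
    return ELEMENT_INDEX.get(element.upper() if len(element) == 1
                             else element.capitalize(), ELEMENT_INDEX["other"])


# van der Waals radii (Angstrom)
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
    "other": 1.80,
}


def vdw_radius(element: str) -> float:
    return VDW_RADII[ELEMENT_VOCAB[element_code(element)]]


# theoretical maximum SASA (A^2) per residue, Tien et al. 2013
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# shared backbone charges (amide H included; applies to every residue unless
# overridden below)
_BACKBONE = {
    "N": -0.4157, "H": 0.2719, "CA": -0.0252, "HA": 0.0698,
    "C": 0.5973, "O": -0.5679, "OXT": -0.8055,
}

# side-chain heavy-atom charges, AMBER-style
_SIDECHAIN = {
    "ALA": {"CB": -0.1825},
    "ARG": {"CB": -0.0007, "CG": 0.0390, "CD": 0.0486, "NE": -0.5295,
            "CZ": 0.8076, "NH1": -0.8627, "NH2": -0.8627},
    "ASN": {"CB": -0.2041, "CG": 0.7130, "OD1": -0.5931, "ND2": -0.9191},
    "ASP": {"CB": -0.0303, "CG": 0.7994, "OD1": -0.8014, "OD2": -0.8014},
    "CYS": {"CB": -0.1231, "SG": -0.3119},
    "GLN": {"CB": -0.0036, "CG": -0.0645, "CD": 0.6951, "OE1": -0.6086,
            "NE2": -0.9407},
    "GLU": {"CB": 0.0560, "CG": 0.0136, "CD": 0.8054, "OE1": -0.8188,
            "OE2": -0.8188},
    "GLY": {},
    "HIS": {"CB": -0.1012, "CG": 0.1868, "ND1": -0.5432, "CD2": -0.2207,
            "CE1": 0.1635, "NE2": -0.2795},
    "ILE": {"CB": 0.1303, "CG1": -0.0430, "CG2": -0.3204, "CD1": -0.0660},
    "LEU": {"CB": -0.1102, "CG": 0.3531, "CD1": -0.4121, "CD2": -0.4121},
    "LYS": {"CB": -0.0094, "CG": 0.0187, "CD": -0.0479, "CE": -0.0143,
            "NZ": -0.3854},
    "MET": {"CB": 0.0342, "CG": 0.0018, "SD": -0.2737, "CE": -0.0536},
    "PHE": {"CB": -0.0343, "CG": 0.0118, "CD1": -0.1256, "CD2": -0.1256,
            "CE1": -0.1704, "CE2": -0.1704, "CZ": -0.1072},
    "PRO": {"CB": -0.0070, "CG": 0.0189, "CD": 0.0192, "N": -0.2548},
    "SER": {"CB": 0.2117, "OG": -0.6546},
    "THR": {"CB": 0.3654, "OG1": -0.6761, "CG2": -0.2438},
    "TRP": {"CB": -0.0050, "CG": -0.1415, "CD1": -0.1638, "CD2": 0.1243,
            "NE1": -0.3418, "CE2": 0.1380, "CE3": -0.2387, "CZ2": -0.2601,
            "CZ3": -0.1972, "CH2": -0.1134},
    "TYR": {"CB": -0.0152, "CG": -0.0011, "CD1": -0.1906, "CD2": -0.1906,
            "CE1": -0.2341, "CE2": -0.2341, "CZ": 0.3226, "OH": -0.5579},
    "VAL": {"CB": 0.2985, "CG1": -0.3192, "CG2": -0.3192},
}


def default_charge_table() -> dict[tuple[str, str], float]:
    """(residue_name, atom_name) -> partial charge, for the 20 standard AAs."""
    table: dict[tuple[str, str], float] = {}
    for res, side in _SIDECHAIN.items():
        for atom, q in _BACKBONE.items():
            table[(res, atom)] = q
        table.update({(res, atom): q for atom, q in side.items()})
    return table


def per_residue_charge_sums() -> dict[str, float]:
    """Sum of bundled charges per residue (used by summation checks)."""
    table = default_charge_table()
    sums: dict[str, float] = {}
    for (res, _), q in table.items():
        sums[res] = sums.get(res, 0.0) + q
    return sums
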