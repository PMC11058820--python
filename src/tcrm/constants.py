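"""Shared chemical tables: amino-acid codes, chi definitions, H-bond roles.

All tables cover the 20 standard amino acids and heavy atoms only; the
package never models hydrogens (crystal inputs at ~2.2-2.4 A lack them).
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = tuple(sorted(AA3_TO_1))

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# chi dihedral definitions (heavy atoms). Order matters: chi1..chiN.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    # ALA/GLY: no chi. PRO: ring treated as rigid (placed from template).
}

# chis whose terminal group is planar/sp2-like; sampled on a coarser grid
SP2_TERMINAL_CHI = {
    ("ASN", 2), ("ASP", 2), ("GLN", 3), ("GLU", 3),
    ("HIS", 2), ("PHE", 2), ("TRP", 2), ("TYR", 2),
}

# heavy-atom hydrogen-bond capability (donor = carries an H in reality)
HBOND_DONORS: dict[str, tuple[str, ...]] = {
    "*": ("N",),  # backbone amide (not for PRO)
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),  # backbone carbonyl / C-terminal carboxylate
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

# antecedent heavy atom bonded to each donor (for the D-antecedent angle test)
DONOR_ANTECEDENT: dict[str, str] = {
    "N": "CA", "NE": "CD", "NH1": "CZ", "NH2": "CZ", "ND2": "CG",
    "NE2": "CD", "ND1": "CG", "NZ": "CE", "OG": "CB", "OG1": "CB",
    "NE1": "CD1", "OH": "CZ", "SG": "CB",
}
# HIS NE2 antecedent differs from GLN NE2; resolved per residue type
DONOR_ANTECEDENT_BY_RES = {("HIS", "NE2"): "CD2", ("GLN", "NE2"): "CD"}

# charged groups for salt-bridge detection
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
CTERM_CARBOXYLATE = ("O", "OXT")
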