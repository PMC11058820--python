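"""Internal-coordinate backbone construction (NeRF) for ideal chains.

Used by the synthetic-structure generators (ideal helices and extended
peptides at prescribed phi/psi) and by the CDR loop refiner when rebuilding
loop backbones from perturbed torsions.
"""

from __future__ import annotations

import numpy as np

from .geometry import rotation_about_axis

# ideal backbone geometry (lengths A, angles deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float
               ) -> np.ndarray:
    """Position a new atom D given chain a-b-c: |c-D| = bond,
    angle(b,c,D) = angle, dihedral(a,b,c,D) = torsion (NeRF)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms for NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omegas=None) -> list[dict]:
    """Backbone N/CA/C/O coordinates for n residues from torsions.

    ``phis[0]`` is unused (no preceding carbonyl); the last psi orients the
    final carbonyl oxygen.  Returns one dict per residue.
    """
    n = len(phis)
    if len(psis) != n:
        raise ValueError("phi/psi lists differ in length")
    omegas = [180.0] * n if omegas is None else list(omegas)

    residues: list[dict] = []
    # seed frame for residue 0
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = residues[-1]
        Ni = place_atom(prev["N"], prev["CA"], prev["C"],
                        BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CAi = place_atom(prev["CA"], prev["C"], Ni,
                         BOND_N_CA, ANGLE_C_N_CA, omegas[i])
        Ci = place_atom(prev["C"], Ni, CAi,
                        BOND_CA_C, ANGLE_N_CA_C, phis[i])
        residues.append({"N": Ni, "CA": CAi, "C": Ci})
    # carbonyl oxygens: O_i placed anti to the next amide nitrogen
    # (torsion N-CA-C-O = psi + 180)
    from .geometry import dihedral
    for i, res in enumerate(residues):
        if i + 1 < n:
            psi = dihedral(res["N"], res["CA"], res["C"],
                           residues[i + 1]["N"])
        else:
            psi = psis[i]
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return residues


def backbone_torsions(residues: list[dict]) -> tuple[list, list, list]:
    """(phi, psi, omega) lists from backbone coordinate dicts; terminal
    undefined angles are filled with the ideal trans values."""
    from .geometry import dihedral
    n = len(residues)
    phis, psis, omegas = [], [], []
    for i, r in enumerate(residues):
        if i == 0:
            phis.append(-57.0)
            omegas.append(180.0)
        else:
            p = residues[i - 1]
            phis.append(dihedral(p["C"], r["N"], r["CA"], r["C"]))
            omegas.append(dihedral(p["CA"], p["C"], r["N"], r["CA"]))
        if i + 1 < n:
            nxt = residues[i + 1]
            psis.append(dihedral(r["N"], r["CA"], r["C"], nxt["N"]))
        else:
            psis.append(135.0)
    return phis, psis, omegas


def helix_axis_frame(residues: list[dict]) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit axis direction) of a built segment from its CAs."""
    cas = np.array([r["CA"] for r in residues])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    return centroid, axis


def orient_segment(residues: list[dict], direction=(1.0, 0.0, 0.0),
                   origin=(0.0, 0.0, 0.0)) -> list[dict]:
    """Rigidly move a built segment so its CA axis lies along ``direction``
    with the CA centroid at ``origin``."""
    centroid, axis = helix_axis_frame(residues)
    target = np.asarray(direction, float)
    target = target / np.linalg.norm(target)
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = np.dot(axis, target)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else rotation_about_axis(
            _any_perpendicular(axis), 180.0)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / (s * s))
    origin = np.asarray(origin, float)
    out = []
    for r in residues:
        out.append({k: R @ (p - centroid) + origin for k, p in r.items()})
    return out


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, w)) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)
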