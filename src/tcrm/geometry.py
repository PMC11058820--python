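"""Rigid-body superposition and TCR-pMHC docking geometry.

The docking (crossing) angle follows the disulfide-vector convention: the
vector connecting the V-alpha and V-beta intrachain disulfides and the
peptide N->C axis are both projected into the MHC groove plane and the angle
between the projections is reported in [0, 180), viewed along the peptide.
The incident angle is the tilt of the disulfide-connecting vector out of
the groove plane, in [0, 90].  Conventions differ across the literature, so
the reference frame (helix windows defining the groove plane, SG midpoints
vs CA for the disulfide anchors) is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import (ComplexPartition, StructureModel,
                       variable_domain_disulfide)

__all__ = [
    "SuperpositionResult", "GroovePlane", "DockingGeometry",
    "kabsch_superpose", "rmsd", "groove_plane", "docking_geometry",
    "dihedral", "rotation_about_axis",
]

# default MHC-heavy-chain author-numbering windows for the alpha1/alpha2
# groove helices of a class I fold
DEFAULT_HELIX_WINDOWS = ((50, 85), (138, 175))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, A
    rmsd: float               # A
    n_atoms: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class GroovePlane:
    point: np.ndarray        # point on the plane (helix-CA centroid)
    normal: np.ndarray       # unit normal, oriented toward the TCR
    residual: float          # RMS point-plane distance of the fit, A

    def project(self, v: np.ndarray) -> np.ndarray:
        """Project a direction vector into the plane."""
        return v - np.dot(v, self.normal) * self.normal


@dataclass
class DockingGeometry:
    crossing_angle: float    # degrees in [0, 180)
    incident_angle: float    # degrees in [0, 90]
    tcr_axis: np.ndarray     # unit, V-alpha disulfide -> V-beta disulfide
    peptide_axis: np.ndarray  # unit, N-term CA -> C-term CA
    groove_plane_normal: np.ndarray
    plane: GroovePlane = field(repr=False, default=None)


def _as_points(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point set, got shape {p.shape}")
    return p


def kabsch_superpose(ref, mov) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mov`` onto ``ref`` (Kabsch).

    Returns the proper rotation R and translation t minimizing
    ``|ref - (mov R^T + t)|``; reflections are corrected via the SVD
    determinant sign.
    """
    P, Q = _as_points(ref), _as_points(mov)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in size: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    moved = Q @ R.T + t
    val = float(np.sqrt(np.mean(np.sum((P - moved) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=val, n_atoms=n)


def rmsd(a, b, superpose: bool = False) -> float:
    """Root-mean-square deviation between matched point sets (A).

    ``superpose=True`` returns the Kabsch-minimized value, otherwise the raw
    coordinate deviation.
    """
    P, Q = _as_points(a), _as_points(b)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in size: {P.shape} vs {Q.shape}")
    if superpose:
        return kabsch_superpose(P, Q).rmsd
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def _window_ca(model: StructureModel, chain_id: str,
               windows) -> np.ndarray:
    pts = []
    for res in model.chain(chain_id).residues:
        if any(lo <= res.seq_id <= hi for lo, hi in windows):
            ca = res.atom("CA")
            if ca is not None:
                pts.append(ca.coords)
    return np.array(pts, dtype=float)


def groove_plane(model: StructureModel, partition: ComplexPartition,
                 helix_windows=DEFAULT_HELIX_WINDOWS) -> GroovePlane:
    """Least-squares plane through the CA atoms of the two groove helices.

    The normal is oriented toward the TCR side (positive dot product with
    the groove-centroid -> TCR-centroid vector).
    """
    pts = np.concatenate([
        _window_ca(model, cid, helix_windows) for cid in partition.mhc_heavy
    ]) if partition.mhc_heavy else np.empty((0, 3))
    if len(pts) < 3:
        raise ValueError(
            f"fewer than 3 CA atoms in helix windows {helix_windows} "
            f"of chains {partition.mhc_heavy}")
    centroid = pts.mean(axis=0)
    # smallest principal direction of the centered points
    _, s, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    residual = s[2] / np.sqrt(len(pts))
    tcr_atoms = np.concatenate([
        np.concatenate([r.coords() for r in model.chain(cid).residues])
        for cid in partition.tcr_chains()
    ])
    if np.dot(tcr_atoms.mean(axis=0) - centroid, normal) < 0:
        normal = -normal
    return GroovePlane(point=centroid, normal=normal, residual=float(residual))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _disulfide_anchor(model: StructureModel, chain_ids,
                      use_sg: bool = True) -> np.ndarray:
    (cid,) = chain_ids if len(chain_ids) == 1 else (chain_ids[0],)
    r1, r2, _ = variable_domain_disulfide(model.chain(cid))
    name = "SG" if use_sg else "CA"
    return 0.5 * (r1.atom(name).coords + r2.atom(name).coords)


def docking_geometry(model: StructureModel, partition: ComplexPartition,
                     helix_windows=DEFAULT_HELIX_WINDOWS,
                     disulfide_anchor: str = "SG") -> DockingGeometry:
    """Crossing and incident angles of the TCR over the pMHC platform."""
    pep_chain = model.chain(partition.peptide[0])
    cas = [r.atom("CA") for r in pep_chain.residues if r.atom("CA")]
    if len(cas) < 5:
        raise ValueError(f"peptide has only {len(cas)} CA atoms; need >= 5")
    peptide_axis = _unit(cas[-1].coords - cas[0].coords)

    use_sg = disulfide_anchor.upper() == "SG"
    a = _disulfide_anchor(model, partition.tcr_alpha, use_sg)
    b = _disulfide_anchor(model, partition.tcr_beta, use_sg)
    tcr_axis = _unit(b - a)

    plane = groove_plane(model, partition, helix_windows)
    p_t = plane.project(tcr_axis)
    p_p = plane.project(peptide_axis)
    if np.linalg.norm(p_t) < 1e-9 or np.linalg.norm(p_p) < 1e-9:
        raise ValueError("axis perpendicular to the groove plane; "
                         "crossing angle undefined")
    cosang = np.clip(np.dot(_unit(p_t), _unit(p_p)), -1.0, 1.0)
    crossing = float(np.degrees(np.arccos(cosang)))
    if crossing >= 180.0:
        crossing = 0.0

    tilt = np.degrees(np.arccos(np.clip(np.dot(tcr_axis, plane.normal),
                                        -1.0, 1.0)))
    incident = float(abs(90.0 - tilt))
    return DockingGeometry(
        crossing_angle=crossing, incident_angle=incident,
        tcr_axis=tcr_axis, peptide_axis=peptide_axis,
        groove_plane_normal=plane.normal, plane=plane)


# ---------------------------------------------------------------------------
# small vector helpers shared by the builders

def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_deg`` (right-handed)."""
    u = _unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)
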