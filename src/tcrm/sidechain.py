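"""Side-chain placement from idealized residue templates.

Templates are biotite's bundled chemical-component definitions (heavy atoms
only).  A side chain is placed by superposing the template backbone
(N, CA, C) onto the target backbone and then driving the chi dihedrals to
requested values by rotating the downstream atoms about each chi axis.
Rotamers come from a deterministic staggered chi grid rather than a
statistical library; the grid is adequate for ranking fixed-backbone point
mutations and keeps scans exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np

from .constants import CHI_ATOMS, SP2_TERMINAL_CHI, STANDARD_AA
from .geometry import dihedral, kabsch_superpose, rotation_about_axis
from .structio import Atom, ResidueRec

__all__ = ["RotamerLibrary", "residue_template", "side_chain_atom_names",
           "place_side_chain", "mutate_residue"]

_BACKBONE = ("N", "CA", "C", "O", "OXT")


@lru_cache(maxsize=None)
def residue_template(aa3: str):
    """Heavy-atom idealized template: (names, coords, bonds dict)."""
    import biotite.structure.info as info
    if aa3 not in STANDARD_AA:
        raise ValueError(f"not a standard residue: {aa3}")
    arr = info.residue(aa3)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx_map = {}
    names, coords = [], []
    for i in np.flatnonzero(keep):
        idx_map[i] = len(names)
        names.append(str(arr.atom_name[i]))
        coords.append(arr.coord[i])
    bonds: dict[str, set[str]] = {n: set() for n in names}
    for a, b, _ in arr.bonds.as_array():
        if a in idx_map and b in idx_map:
            na, nb = names[idx_map[a]], names[idx_map[b]]
            bonds[na].add(nb)
            bonds[nb].add(na)
    return tuple(names), np.array(coords, dtype=float), bonds


def side_chain_atom_names(aa3: str) -> tuple[str, ...]:
    names, _, _ = residue_template(aa3)
    return tuple(n for n in names if n not in _BACKBONE)


@lru_cache(maxsize=None)
def _chi_downstream(aa3: str, chi_index: int) -> tuple[str, ...]:
    """Atoms moved by chi_index (1-based): the connected component behind
    the rotated bond, restricted to side-chain atoms."""
    names, _, bonds = residue_template(aa3)
    _, b, c, _ = CHI_ATOMS[aa3][chi_index - 1]
    seen = {b}
    stack = [c]
    comp = set()
    while stack:
        cur = stack.pop()
        if cur in comp:
            continue
        comp.add(cur)
        for nb in bonds[cur]:
            if nb != b and nb not in comp:
                stack.append(nb)
    return tuple(n for n in names if n in comp and n not in _BACKBONE)


@dataclass(frozen=True)
class RotamerLibrary:
    """Deterministic staggered chi grid.

    sp3 chis sample (-60, 60, 180); terminal sp2-like chis sample
    (-90, 0, 90).  ``ex_level`` = 1 adds +/-30 deg half-steps around every
    sp3 value (the 'extra rotamer' switch of design protocols).
    """
    ex_level: int = 0
    sp3_values: tuple = (-60.0, 60.0, 180.0)
    sp2_values: tuple = (-90.0, 0.0, 90.0)

    def chi_values(self, aa3: str, chi_index: int) -> tuple[float, ...]:
        if (aa3, chi_index) in SP2_TERMINAL_CHI:
            return self.sp2_values
        vals = list(self.sp3_values)
        if self.ex_level >= 1:
            for v in self.sp3_values:
                vals.extend((v - 30.0, v + 30.0))
        return tuple(_wrap(v) for v in vals)

    def rotamers(self, aa3: str) -> list[tuple[float, ...]]:
        """Ordered chi tuples; [()] for residues with no rotatable chi."""
        chis = CHI_ATOMS.get(aa3, [])
        if not chis or aa3 == "PRO":  # proline ring kept as the template
            return [()]
        grids = [self.chi_values(aa3, k + 1) for k in range(len(chis))]
        return [tuple(c) for c in product(*grids)]


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def place_side_chain(backbone: dict, aa3: str,
                     chi: tuple[float, ...] = ()) -> dict[str, np.ndarray]:
    """Side-chain heavy-atom coordinates for a residue of type ``aa3``.

    ``backbone`` maps at least N/CA/C to coordinates.  The template is
    superposed on the backbone triad and the chi angles are then set; an
    empty ``chi`` keeps the template's own conformation (used for PRO and
    for chi-less residues).
    """
    sc_names = side_chain_atom_names(aa3)
    if not sc_names:
        return {}
    names, coords, _ = residue_template(aa3)
    pos = {n: coords[i].copy() for i, n in enumerate(names)}
    tri = np.array([pos["N"], pos["CA"], pos["C"]])
    tgt = np.array([backbone["N"], backbone["CA"], backbone["C"]])
    sup = kabsch_superpose(tgt, tri)
    placed = {n: sup.rotation @ pos[n] + sup.translation for n in names}
    # anchor exactly on the real backbone for the chi reference frame
    for n in ("N", "CA", "C"):
        placed[n] = np.asarray(backbone[n], float)

    chis = CHI_ATOMS.get(aa3, [])
    for k, value in enumerate(chi):
        if k >= len(chis):
            break
        a, b, c, d = chis[k]
        current = dihedral(placed[a], placed[b], placed[c], placed[d])
        delta = value - current
        axis = placed[c] - placed[b]
        R = rotation_about_axis(axis, delta)
        origin = placed[b]
        for n in _chi_downstream(aa3, k + 1):
            placed[n] = R @ (placed[n] - origin) + origin
    return {n: placed[n] for n in sc_names}


def mutate_residue(res: ResidueRec, new_aa3: str,
                   chi: tuple[float, ...] = ()) -> ResidueRec:
    """A copy of ``res`` with its side chain replaced by ``new_aa3`` built
    at the given chi angles; backbone atoms are preserved bit-identically."""
    backbone = {}
    for n in ("N", "CA", "C"):
        a = res.atom(n)
        if a is None:
            raise ValueError(f"residue {res.key} lacks backbone atom {n}")
        backbone[n] = a.coords
    new_atoms = [a for a in res.atoms if a.name in _BACKBONE]
    sc = place_side_chain(backbone, new_aa3, chi)
    serial = max((a.serial for a in new_atoms), default=0)
    ridx = new_atoms[0].residue_index if new_atoms else 0
    names, _, _ = residue_template(new_aa3)
    for n in names:  # canonical template order
        if n in sc:
            serial += 1
            new_atoms.append(Atom(
                serial=serial, name=n, element=n[0],
                residue_index=ridx, alt_loc="", coords=sc[n]))
    return ResidueRec(chain_id=res.chain_id, seq_id=res.seq_id,
                      insertion_code=res.insertion_code,
                      aa_type=new_aa3, atoms=new_atoms)
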