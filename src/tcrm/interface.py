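"""Solvent accessibility, buried surface, and interface contact mapping.

SASA uses the Shrake-Rupley rolling-probe algorithm with a deterministic
golden-spiral point lattice (no randomness), so results are exactly
reproducible for a given ``n_points``.  Buried surface area follows the
additive convention BSA = SASA(A) + SASA(B) - SASA(AB).  Hydrogen bonds and
salt bridges are detected on heavy atoms only, from per-residue
donor/acceptor capability tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import (CTERM_CARBOXYLATE, DONOR_ANTECEDENT,
                        DONOR_ANTECEDENT_BY_RES, HBOND_ACCEPTORS,
                        HBOND_DONORS, NEGATIVE_ATOMS, POSITIVE_ATOMS)
from .structio import ComplexPartition, StructureModel, extract_chains

__all__ = [
    "SasaResult", "InterfaceArea", "ContactCriteria", "Contact", "ContactSet",
    "shrake_rupley", "buried_surface_area", "find_contacts",
    "select_design_positions", "DesignPosition",
]


@dataclass
class SasaResult:
    per_atom: dict          # (residue key, atom name) -> A^2
    per_residue: dict       # residue key -> A^2
    total: float            # A^2
    probe_radius: float
    n_sphere_points: int


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere lattice with n points."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(model: StructureModel, probe_radius: float = 1.4,
                  n_points: int = 960) -> SasaResult:
    """Per-atom solvent-accessible surface area (A^2).

    Each atom's area is (exposed lattice points / n_points) * 4 pi (r+p)^2
    where lattice points occluded by any neighbor's expanded sphere are
    removed.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable lattice")
    atoms = []
    keys = []
    for res in model.iter_residues():
        for a in res.atoms:
            atoms.append(a)
            keys.append((res.key, a.name))
    if not atoms:
        raise ValueError("model has no atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.radius for a in atoms]) + probe_radius
    lattice = _sphere_lattice(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    neighbor_lists = tree.query_ball_point(coords, r=max_reach)

    per_atom = {}
    total = 0.0
    for i, (key, a) in enumerate(zip(keys, atoms)):
        pts = coords[i] + radii[i] * lattice
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            rj = radii[j]
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > rj * rj
            if not exposed.any():
                break
        area = exposed.sum() / n_points * 4.0 * np.pi * radii[i] ** 2
        per_atom[key] = float(area)
        total += area

    per_residue: dict = {}
    for (rkey, _), area in per_atom.items():
        per_residue[rkey] = per_residue.get(rkey, 0.0) + area
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      total=float(total), probe_radius=probe_radius,
                      n_sphere_points=n_points)


@dataclass
class InterfaceArea:
    bsa_total: float            # A^2, TCR vs pMHC
    bsa_by_side: dict           # {"tcr": A^2, "pmhc": A^2}
    peptide_burial: float       # A^2, peptide free vs in the MHC groove


def _side_sasa_in_complex(complex_sasa: SasaResult,
                          model: StructureModel, chain_ids) -> float:
    wanted = set(chain_ids)
    return sum(area for (rkey, _), area in complex_sasa.per_atom.items()
               if rkey[0] in wanted)


def buried_surface_area(model: StructureModel, partition: ComplexPartition,
                        probe_radius: float = 1.4,
                        n_points: int = 960) -> InterfaceArea:
    """Interface BSA between the TCR and pMHC sides plus peptide burial."""
    tcr_ids, pmhc_ids = partition.tcr_chains(), partition.pmhc_chains()
    tcr = extract_chains(model, tcr_ids)
    pmhc = extract_chains(model, pmhc_ids)
    whole = extract_chains(model, tcr_ids + pmhc_ids)
    groove = extract_chains(model, partition.mhc_heavy + partition.b2m
                            + partition.peptide)
    peptide = extract_chains(model, partition.peptide)

    kw = dict(probe_radius=probe_radius, n_points=n_points)
    s_tcr = shrake_rupley(tcr, **kw)
    s_pmhc = shrake_rupley(pmhc, **kw)
    s_all = shrake_rupley(whole, **kw)
    s_groove = shrake_rupley(groove, **kw)
    s_pep = shrake_rupley(peptide, **kw)

    bsa_total = s_tcr.total + s_pmhc.total - s_all.total
    by_side = {
        "tcr": s_tcr.total - _side_sasa_in_complex(s_all, model, tcr_ids),
        "pmhc": s_pmhc.total - _side_sasa_in_complex(s_all, model, pmhc_ids),
    }
    pep_in_groove = sum(
        area for (rkey, _), area in s_groove.per_atom.items()
        if rkey[0] in set(partition.peptide))
    return InterfaceArea(
        bsa_total=float(bsa_total), bsa_by_side=by_side,
        peptide_burial=float(s_pep.total - pep_in_groove))


# ---------------------------------------------------------------------------
# contacts

@dataclass
class ContactCriteria:
    vdw_cutoff: float = 4.0          # A, any heavy-atom pair
    hbond_da_cutoff: float = 3.5     # A, donor-acceptor heavy atoms
    hbond_angle_min: float = 120.0   # deg, antecedent-donor-acceptor
    saltbridge_cutoff: float = 4.0   # A, charged-group heavy atoms

    def __post_init__(self):
        for name in ("vdw_cutoff", "hbond_da_cutoff", "saltbridge_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Contact:
    residue_a: tuple          # (chain, seq_id, icode)
    residue_b: tuple
    kind: str                 # vdw | hbond | saltbridge
    atom_a: str
    atom_b: str
    distance: float           # A


@dataclass
class ContactSet:
    contacts: list[Contact] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Contact]:
        return [c for c in self.contacts if c.kind == kind]


def _residue_hbond_atoms(res, table) -> list[str]:
    names = []
    for n in table.get("*", ()):
        if res.aa_type == "PRO" and n == "N" and table is HBOND_DONORS:
            continue  # proline backbone N has no amide hydrogen
        if res.atom(n):
            names.append(n)
    for n in table.get(res.aa_type, ()):
        if res.atom(n):
            names.append(n)
    return names


def _donor_antecedent(res, donor: str):
    name = DONOR_ANTECEDENT_BY_RES.get((res.aa_type, donor),
                                       DONOR_ANTECEDENT.get(donor))
    return res.atom(name) if name else None


def _charged_atoms(res, is_cterm: bool, sign: int) -> list[str]:
    table = POSITIVE_ATOMS if sign > 0 else NEGATIVE_ATOMS
    names = [n for n in table.get(res.aa_type, ()) if res.atom(n)]
    if sign < 0 and is_cterm and res.atom("OXT"):
        names.extend(n for n in CTERM_CARBOXYLATE if res.atom(n))
    return names


def contacts_between(model: StructureModel, chains_a, chains_b,
                     criteria: ContactCriteria | None = None) -> ContactSet:
    """All vdw/hbond/saltbridge contacts across two chain selections."""
    crit = criteria or ContactCriteria()
    res_a = [r for cid in chains_a for r in model.chain(cid).residues]
    res_b = [r for cid in chains_b for r in model.chain(cid).residues]
    cterm_a = {r.key for cid in chains_a
               for r in model.chain(cid).residues[-1:]}
    cterm_b = {r.key for cid in chains_b
               for r in model.chain(cid).residues[-1:]}

    coords_b = np.concatenate([r.coords() for r in res_b])
    owner_b = np.concatenate([
        np.full(len(r.atoms), i) for i, r in enumerate(res_b)])
    tree_b = cKDTree(coords_b)
    name_b = [a.name for r in res_b for a in r.atoms]

    max_cut = max(crit.vdw_cutoff, crit.hbond_da_cutoff,
                  crit.saltbridge_cutoff)
    contacts: list[Contact] = []
    for ra in res_a:
        ca = ra.coords()
        hits = tree_b.query_ball_point(ca, r=max_cut)
        touched = sorted({int(owner_b[j]) for row in hits for j in row})
        for ib in touched:
            rb = res_b[ib]
            contacts.extend(_residue_pair_contacts(
                ra, rb, crit, ra.key in cterm_a, rb.key in cterm_b))
    contacts.sort(key=lambda c: (c.kind, c.residue_a, c.residue_b,
                                 c.atom_a, c.atom_b))
    return ContactSet(contacts=contacts)


def _residue_pair_contacts(ra, rb, crit: ContactCriteria,
                           ra_cterm: bool, rb_cterm: bool) -> list[Contact]:
    out = []
    pa, pb = ra.coords(), rb.coords()
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)

    # vdw: one record per residue pair, closest heavy-atom pair
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] <= crit.vdw_cutoff:
        out.append(Contact(ra.key, rb.key, "vdw",
                           ra.atoms[i].name, rb.atoms[j].name,
                           float(d[i, j])))

    # hydrogen bonds: donor(A)->acceptor(B) and donor(B)->acceptor(A)
    for don_res, acc_res, flip in ((ra, rb, False), (rb, ra, True)):
        for dn in _residue_hbond_atoms(don_res, HBOND_DONORS):
            don = don_res.atom(dn)
            ante = _donor_antecedent(don_res, dn)
            for an in _residue_hbond_atoms(acc_res, HBOND_ACCEPTORS):
                acc = acc_res.atom(an)
                dist = float(np.linalg.norm(don.coords - acc.coords))
                if dist > crit.hbond_da_cutoff or dist < 2.0:
                    continue
                if ante is not None:
                    v1 = ante.coords - don.coords
                    v2 = acc.coords - don.coords
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang < crit.hbond_angle_min:
                        continue
                if flip:
                    out.append(Contact(ra.key, rb.key, "hbond", an, dn, dist))
                else:
                    out.append(Contact(ra.key, rb.key, "hbond", dn, an, dist))

    # salt bridges: one record per residue pair, closest qualifying pair
    best = None
    for sa, sb, ca_ct, cb_ct in ((1, -1, ra_cterm, rb_cterm),
                                 (-1, 1, ra_cterm, rb_cterm)):
        for na in _charged_atoms(ra, ca_ct, sa):
            for nb in _charged_atoms(rb, cb_ct, sb):
                dist = float(np.linalg.norm(
                    ra.atom(na).coords - rb.atom(nb).coords))
                if dist <= crit.saltbridge_cutoff and (
                        best is None or dist < best[2]):
                    best = (na, nb, dist)
    if best:
        out.append(Contact(ra.key, rb.key, "saltbridge",
                           best[0], best[1], best[2]))
    return out


def find_contacts(model: StructureModel, partition: ComplexPartition,
                  criteria: ContactCriteria | None = None) -> ContactSet:
    """Contacts across the TCR/pMHC boundary and the peptide/MHC boundary."""
    tcr_pmhc = contacts_between(model, partition.tcr_chains(),
                                partition.pmhc_chains(), criteria)
    pep_mhc = contacts_between(model, partition.peptide,
                               partition.mhc_heavy + partition.b2m, criteria)
    merged = tcr_pmhc.contacts + pep_mhc.contacts
    merged.sort(key=lambda c: (c.kind, c.residue_a, c.residue_b,
                               c.atom_a, c.atom_b))
    return ContactSet(contacts=merged)


# ---------------------------------------------------------------------------
# design-position selection

@dataclass(frozen=True)
class DesignPosition:
    chain_id: str
    seq_id: int
    insertion_code: str
    aa_type: str
    role: str      # tcr_alpha | tcr_beta

    @property
    def key(self):
        return (self.chain_id, self.seq_id, self.insertion_code)


def select_design_positions(model: StructureModel,
                            partition: ComplexPartition,
                            cutoff: float = 8.0,
                            restrict_to=None,
                            reference: str = "peptide"
                            ) -> list[DesignPosition]:
    """TCR residues with any heavy atom within ``cutoff`` of the reference.

    ``reference`` is ``"peptide"`` (default: the peptide chain alone) or
    ``"pmhc"`` (the whole peptide-MHC surface).  ``restrict_to`` optionally
    intersects with a set of (chain_id, seq_id) or (chain_id, seq_id, icode)
    keys, e.g. CDR ranges.  Output is ordered by (chain, seq_id, icode).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ref_ids = (partition.peptide if reference == "peptide"
               else partition.pmhc_chains())
    ref_coords = np.concatenate([
        np.concatenate([r.coords() for r in model.chain(cid).residues])
        for cid in ref_ids])
    tree = cKDTree(ref_coords)

    allowed = None
    if restrict_to is not None:
        allowed = {(k[0], k[1], k[2] if len(k) > 2 else "")
                   for k in restrict_to}

    out = []
    for role in ("tcr_alpha", "tcr_beta"):
        for cid in getattr(partition, role):
            for res in model.chain(cid).residues:
                if allowed is not None and res.key not in allowed:
                    continue
                d, _ = tree.query(res.coords(), k=1)
                if d.min() <= cutoff:
                    out.append(DesignPosition(
                        chain_id=cid, seq_id=res.seq_id,
                        insertion_code=res.insertion_code,
                        aa_type=res.aa_type, role=role))
    out.sort(key=lambda p: (p.chain_id, p.seq_id, p.insertion_code))
    return out
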