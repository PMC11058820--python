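"""Fixed-backbone point-mutation scanning and CDR loop refinement.

The scan protocol mirrors structure-based affinity maturation: TCR residues
near the peptide are substituted to every natural amino acid except
cysteine (the wild-type identity included, so each position contributes 19
candidates), only the mutant side chain is repacked on the fixed wild-type
backbone, and candidates are ranked by the change in the interface binding
score B = E(complex) - E(TCR) - E(pMHC).  Loop refinement combines random
phi/psi perturbations, cyclic-coordinate-descent (CCD) closure onto the
fixed anchors, and Metropolis acceptance on the pose energy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .constants import AA3_TO_1, STANDARD_AA
from .energetics import (BindingScore, EnergyBreakdown, EnergyModel,
                         FlatPose, atom_parameters, binding_score,
                         pair_terms_kernel, score_pose)
from .geometry import dihedral, kabsch_superpose
from .interface import DesignPosition
from .sidechain import (RotamerLibrary, mutate_residue, place_side_chain,
                        residue_template, side_chain_atom_names)
from .structio import ComplexPartition, StructureModel

__all__ = [
    "MutationCandidate", "DesignConfig", "PlacementResult", "ScanRow",
    "ScanResult", "enumerate_substitutions", "place_mutation",
    "scan_mutations", "combine_mutations", "refine_cdr_loops", "ccd_close",
]

_GREEK = {"tcr_alpha": "α", "tcr_beta": "β"}


@dataclass(frozen=True)
class MutationCandidate:
    position: DesignPosition
    wt_aa: str                 # three-letter
    mut_aa: str                # three-letter, never CYS
    label: str = ""

    def __post_init__(self):
        if self.mut_aa == "CYS":
            raise ValueError("cysteine substitutions are excluded")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        greek = _GREEK.get(self.position.role, self.position.chain_id)
        return (f"{greek}{AA3_TO_1[self.wt_aa]}{self.position.seq_id}"
                f"{AA3_TO_1[self.mut_aa]}")

    @property
    def is_self(self) -> bool:
        return self.wt_aa == self.mut_aa


@dataclass
class DesignConfig:
    cutoff_8A: float = 8.0               # design-position selection, A
    exclude: tuple = ("CYS",)
    repack_shell: float = 0.0            # 0 = mutant side chain only
    loop_n_cycles: int = 100
    loop_kT: float = 1.0
    loop_torsion_step: float = 10.0      # deg
    seed: int = 0

    def fingerprint(self, em: EnergyModel, rotlib: RotamerLibrary) -> str:
        blob = json.dumps({
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(self).items()},
            "em": {"weights": em.weights, "eps0": em.eps0,
                   "cutoff": em.cutoff, "version": em.version},
            "rotlib": {"ex_level": rotlib.ex_level,
                       "sp3": rotlib.sp3_values, "sp2": rotlib.sp2_values},
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def enumerate_substitutions(positions, exclude=("CYS",)
                            ) -> list[MutationCandidate]:
    """All substitutions at the given positions: one candidate per amino
    acid not in ``exclude`` (the wild-type identity is included, so the
    default yields exactly 19 candidates per position)."""
    if not positions:
        raise ValueError("no positions given")
    excluded = set(exclude) | {"CYS"}
    out = []
    for pos in positions:
        if pos.aa_type not in STANDARD_AA:
            raise ValueError(
                f"position {pos.chain_id}:{pos.seq_id} is not a standard "
                f"residue ({pos.aa_type})")
        for aa in STANDARD_AA:
            if aa in excluded:
                continue
            out.append(MutationCandidate(position=pos, wt_aa=pos.aa_type,
                                         mut_aa=aa))
    return out


@dataclass
class PlacementResult:
    model: StructureModel
    rotamer_index: int
    chi: tuple
    pose_energy: EnergyBreakdown


def _strip_side_chain(model: StructureModel, key) -> StructureModel:
    out = model.copy()
    chain = out.chain(key[0])
    for idx, res in enumerate(chain.residues):
        if res.key == key:
            chain.residues[idx] = mutate_residue(res, "GLY")
            chain.residues[idx].aa_type = res.aa_type
            return out
    raise KeyError(f"no residue {key}")


def _residue_uid(model: StructureModel, key) -> int:
    for uid, res in enumerate(model.iter_residues()):
        if res.key == key:
            return uid
    raise KeyError(f"no residue {key}")


def _weighted_total(em: EnergyModel, terms: dict) -> float:
    return sum(em.weights[k] * terms[k] for k in EnergyBreakdown.TERMS)


def place_mutation(model: StructureModel, candidate: MutationCandidate,
                   rotlib: RotamerLibrary | None = None,
                   em: EnergyModel | None = None) -> PlacementResult:
    """Build the mutant side chain at the rotamer minimizing the total pose
    energy; the backbone and every other residue are bit-identical to the
    input (ties broken toward the lowest rotamer index)."""
    em = em or EnergyModel()
    rotlib = rotlib or RotamerLibrary()
    key = candidate.position.key
    res = model.residue(*key)
    for n in ("N", "CA", "C", "O"):
        if res.atom(n) is None:
            raise ValueError(f"residue {key} lacks backbone atom {n}")
    backbone = {n: res.atom(n).coords for n in ("N", "CA", "C")}

    env = _strip_side_chain(model, key)
    env_pose = FlatPose(env, em)
    env_energy = score_pose(env, em)
    uid = _residue_uid(env, key)

    sc_names = side_chain_atom_names(candidate.mut_aa)
    rotamers = rotlib.rotamers(candidate.mut_aa)
    if sc_names:
        ext = atom_parameters(candidate.mut_aa, sc_names, em)
        best = None
        for idx, chi in enumerate(rotamers):
            sc = place_side_chain(backbone, candidate.mut_aa, chi)
            coords = np.array([sc[n] for n in sc_names])
            terms = env_pose.external_terms(coords, ext, (uid,))
            total = _weighted_total(em, terms)
            if best is None or total < best[0]:
                best = (total, idx, chi, terms)
        _, best_idx, best_chi, best_terms = best
    else:
        best_idx, best_chi = 0, ()
        best_terms = dict.fromkeys(EnergyBreakdown.TERMS, 0.0)

    mutated = model.copy()
    chain = mutated.chain(key[0])
    for idx, r in enumerate(chain.residues):
        if r.key == key:
            chain.residues[idx] = mutate_residue(r, candidate.mut_aa,
                                                 best_chi)
            break
    pose_energy = EnergyBreakdown.from_terms(em.weights, **{
        k: getattr(env_energy, k) + best_terms[k]
        for k in EnergyBreakdown.TERMS})
    return PlacementResult(model=mutated, rotamer_index=best_idx,
                           chi=best_chi, pose_energy=pose_energy)


# ---------------------------------------------------------------------------
# scanning

@dataclass
class ScanRow:
    candidate: MutationCandidate
    rotamer_index: int
    binding: EnergyBreakdown | None
    delta_binding: float
    error: str | None = None


@dataclass
class ScanResult:
    rows: list[ScanRow]
    ranking: list[ScanRow]
    wild_type_binding: BindingScore
    fingerprint: str
    seed: int

    def to_records(self) -> list[dict]:
        out = []
        for rank, row in enumerate(self.ranking, start=1):
            rec = {"rank": rank, "label": row.candidate.label,
                   "delta_binding": row.delta_binding,
                   "rotamer_index": row.rotamer_index,
                   "error": row.error or ""}
            if row.binding is not None:
                rec.update({f"binding_{k}": v
                            for k, v in row.binding.as_dict().items()})
            out.append(rec)
        return out

    def to_tsv(self) -> str:
        recs = self.to_records()
        cols = list(recs[0].keys()) if recs else []
        lines = ["\t".join(cols)]
        for rec in recs:
            lines.append("\t".join(
                f"{rec[c]:.6f}" if isinstance(rec[c], float) else str(rec[c])
                for c in cols))
        return "\n".join(lines) + "\n"


def _rank(rows: list[ScanRow]) -> list[ScanRow]:
    ok = [r for r in rows if r.error is None]
    bad = [r for r in rows if r.error is not None]
    ok.sort(key=lambda r: (r.delta_binding, r.candidate.position.key,
                           r.candidate.mut_aa))
    return ok + bad


def scan_mutations(model: StructureModel, partition: ComplexPartition,
                   candidates, rotlib: RotamerLibrary | None = None,
                   em: EnergyModel | None = None,
                   config: DesignConfig | None = None) -> ScanResult:
    """Place and score every candidate; rank ascending by the change in
    binding score (improvements first).  Failed candidates are kept with an
    error flag and sort to the end."""
    em = em or EnergyModel()
    rotlib = rotlib or RotamerLibrary()
    config = config or DesignConfig()
    wt = binding_score(model, partition, em)
    rows: list[ScanRow] = []
    for cand in candidates:
        try:
            placed = place_mutation(model, cand, rotlib, em)
            bs = binding_score(placed.model, partition, em)
            rows.append(ScanRow(
                candidate=cand, rotamer_index=placed.rotamer_index,
                binding=bs.binding,
                delta_binding=bs.binding.total - wt.binding.total))
        except Exception as exc:  # recorded, not dropped silently
            rows.append(ScanRow(candidate=cand, rotamer_index=-1,
                                binding=None, delta_binding=float("nan"),
                                error=str(exc)))
    return ScanResult(rows=rows, ranking=_rank(rows), wild_type_binding=wt,
                      fingerprint=config.fingerprint(em, rotlib),
                      seed=config.seed)


# ---------------------------------------------------------------------------
# combinations

_JOINT_SEARCH_LIMIT = 4096


def _pair_cross_terms(sc1, names1, aa1, sc2, names2, aa2, em) -> dict:
    c1 = np.array([sc1[n] for n in names1])
    c2 = np.array([sc2[n] for n in names2])
    p1 = atom_parameters(aa1, names1, em)
    p2 = atom_parameters(aa2, names2, em)
    ii, jj = np.meshgrid(np.arange(len(names1)), np.arange(len(names2)),
                         indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    r = np.linalg.norm(c1[ii] - c2[jj], axis=1)
    return pair_terms_kernel(r, {k: v[ii] for k, v in p1.items()},
                             {k: v[jj] for k, v in p2.items()}, em)


def combine_mutations(model: StructureModel, partition: ComplexPartition,
                      singles, rotlib: RotamerLibrary | None = None,
                      em: EnergyModel | None = None,
                      config: DesignConfig | None = None) -> ScanResult:
    """Score all pairwise combinations of the given single mutations.

    Positions must be pairwise distinct.  When the two mutant side chains
    are within interaction range of each other the rotamer pair is searched
    exhaustively; otherwise each side chain is packed independently (the
    fixed backbone makes the order immaterial).
    """
    em = em or EnergyModel()
    rotlib = rotlib or RotamerLibrary()
    config = config or DesignConfig()
    singles = list(singles)
    keys = [c.position.key for c in singles]
    if len(set(keys)) != len(keys):
        raise ValueError("overlapping positions among the single mutations")
    wt = binding_score(model, partition, em)
    rows: list[ScanRow] = []
    for c1, c2 in combinations(singles, 2):
        try:
            merged, rot_idx = _place_pair(model, c1, c2, rotlib, em)
            bs = binding_score(merged, partition, em)
            cand = MutationCandidate(
                position=c1.position, wt_aa=c1.wt_aa, mut_aa=c1.mut_aa,
                label=f"{c1.label}-{c2.label}")
            rows.append(ScanRow(
                candidate=cand, rotamer_index=rot_idx, binding=bs.binding,
                delta_binding=bs.binding.total - wt.binding.total))
        except Exception as exc:
            cand = MutationCandidate(
                position=c1.position, wt_aa=c1.wt_aa, mut_aa=c1.mut_aa,
                label=f"{c1.label}-{c2.label}")
            rows.append(ScanRow(candidate=cand, rotamer_index=-1,
                                binding=None, delta_binding=float("nan"),
                                error=str(exc)))
    return ScanResult(rows=rows, ranking=_rank(rows), wild_type_binding=wt,
                      fingerprint=config.fingerprint(em, rotlib),
                      seed=config.seed)


def _place_pair(model, c1, c2, rotlib, em):
    first = place_mutation(model, c1, rotlib, em)
    both = place_mutation(first.model, c2, rotlib, em)
    r1 = both.model.residue(*c1.position.key)
    r2 = both.model.residue(*c2.position.key)
    n1 = [a for a in r1.atoms if a.name not in ("N", "CA", "C", "O", "OXT")]
    n2 = [a for a in r2.atoms if a.name not in ("N", "CA", "C", "O", "OXT")]
    if n1 and n2:
        d = min(float(np.linalg.norm(a.coords - b.coords))
                for a in n1 for b in n2)
        if d < em.cutoff:
            return _joint_search(model, c1, c2, rotlib, em)
    return both.model, both.rotamer_index


def _joint_search(model, c1, c2, rotlib, em):
    """Exhaustive rotamer-pair search with both side chains stripped."""
    k1, k2 = c1.position.key, c2.position.key
    env = _strip_side_chain(_strip_side_chain(model, k1), k2)
    pose = FlatPose(env, em)
    uid1, uid2 = _residue_uid(env, k1), _residue_uid(env, k2)
    bb1 = {n: model.residue(*k1).atom(n).coords for n in ("N", "CA", "C")}
    bb2 = {n: model.residue(*k2).atom(n).coords for n in ("N", "CA", "C")}
    names1 = side_chain_atom_names(c1.mut_aa)
    names2 = side_chain_atom_names(c2.mut_aa)
    p1 = atom_parameters(c1.mut_aa, names1, em)
    p2 = atom_parameters(c2.mut_aa, names2, em)
    rots1 = rotlib.rotamers(c1.mut_aa)
    rots2 = rotlib.rotamers(c2.mut_aa)
    if len(rots1) * len(rots2) > _JOINT_SEARCH_LIMIT:
        rots1 = rots1[::2]  # coarsen deterministically
        rots2 = rots2[::2]

    placed1 = [place_side_chain(bb1, c1.mut_aa, chi) for chi in rots1]
    placed2 = [place_side_chain(bb2, c2.mut_aa, chi) for chi in rots2]
    env1 = [
        _weighted_total(em, pose.external_terms(
            np.array([sc[n] for n in names1]), p1, (uid1, uid2)))
        if names1 else 0.0 for sc in placed1]
    env2 = [
        _weighted_total(em, pose.external_terms(
            np.array([sc[n] for n in names2]), p2, (uid1, uid2)))
        if names2 else 0.0 for sc in placed2]
    best = None
    for i1, sc1 in enumerate(placed1):
        for i2, sc2 in enumerate(placed2):
            cross = 0.0
            if names1 and names2:
                cross = _weighted_total(em, _pair_cross_terms(
                    sc1, names1, c1.mut_aa, sc2, names2, c2.mut_aa, em))
            total = env1[i1] + env2[i2] + cross
            if best is None or total < best[0]:
                best = (total, i1, i2)
    _, i1, i2 = best
    merged = model.copy()
    for key, aa, chi in ((k1, c1.mut_aa, rots1[i1]),
                         (k2, c2.mut_aa, rots2[i2])):
        chain = merged.chain(key[0])
        for idx, r in enumerate(chain.residues):
            if r.key == key:
                chain.residues[idx] = mutate_residue(r, aa, chi)
                break
    return merged, i1 * len(rots2) + i2


# ---------------------------------------------------------------------------
# CCD loop refinement

@dataclass
class RefinementResult:
    model: StructureModel
    trajectory: list[dict] = field(default_factory=list)
    failed_closures: int = 0
    best_energy: float = float("nan")
    seed: int = 0


def ccd_close(loop_bb: list[dict], anchor_prev: dict, target_next: dict,
              omegas=None, phi_next: float = -57.0,
              max_iter: int = 500, tol: float = 0.1
              ) -> tuple[list[dict], float]:
    """Cyclic coordinate descent: drive the rebuilt loop so the implied
    next-anchor backbone triad lands on ``target_next`` (N/CA/C).

    ``loop_bb`` holds per-residue N/CA/C dicts built off ``anchor_prev``.
    Returns (adjusted loop backbones, closure RMSD over the anchor triad).
    """
    from .build import (ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C, BOND_CA_C,
                        BOND_C_N, BOND_N_CA, place_atom)
    from .geometry import rotation_about_axis
    n = len(loop_bb)
    omegas = [180.0] * (n + 1) if omegas is None else list(omegas)
    targets = np.array([target_next[k] for k in ("N", "CA", "C")])

    # explicit moving copy of the next-anchor triad, built once off the
    # last loop residue; afterwards it rotates with every downstream DOF
    last = loop_bb[-1]
    Nn = place_atom(last["N"], last["CA"], last["C"],
                    BOND_C_N, ANGLE_CA_C_N, 135.0)
    CAn = place_atom(last["CA"], last["C"], Nn,
                     BOND_N_CA, ANGLE_C_N_CA, omegas[-1])
    Cn = place_atom(last["C"], Nn, CAn, BOND_CA_C, ANGLE_N_CA_C, phi_next)
    mov = np.array([Nn, CAn, Cn])

    def closure():
        return float(np.sqrt(np.mean(np.sum((mov - targets) ** 2, axis=1))))

    # free torsions: phi_i and psi_i of each loop residue; the psi of the
    # last residue moves only the anchor copy
    for _ in range(max_iter):
        for i in range(n):
            for kind in ("phi", "psi"):
                if kind == "phi":
                    b, c = loop_bb[i]["N"], loop_bb[i]["CA"]
                    pts = [(i, "C")]
                else:
                    b, c = loop_bb[i]["CA"], loop_bb[i]["C"]
                    pts = []
                pts += [(j, name) for j in range(i + 1, n)
                        for name in ("N", "CA", "C")]
                axis = c - b
                nrm = np.linalg.norm(axis)
                if nrm < 1e-9:
                    continue
                axis = axis / nrm
                # CCD-optimal rotation from the three anchor points
                a_sum = b_sum = 0.0
                for m, f in zip(mov, targets):
                    o = b + np.dot(m - b, axis) * axis
                    rvec = m - o
                    if np.linalg.norm(rvec) < 1e-9:
                        continue
                    fvec = f - o
                    a_sum += np.dot(fvec, rvec)
                    b_sum += np.dot(fvec, np.cross(axis, rvec))
                theta = np.degrees(np.arctan2(b_sum, a_sum))
                if abs(theta) < 1e-12:
                    continue
                R = rotation_about_axis(axis, theta)
                for j, name in pts:
                    loop_bb[j][name] = R @ (loop_bb[j][name] - b) + b
                mov = (mov - b) @ R.T + b
        if closure() < tol:
            break
    return loop_bb, closure()


def _loop_indices(model, chain_id, start, end):
    chain = model.chain(chain_id)
    idxs = [i for i, r in enumerate(chain.residues)
            if start <= r.seq_id <= end]
    if len(idxs) < 3:
        raise ValueError(f"loop {chain_id}:{start}-{end} has < 3 residues")
    if idxs[0] == 0 or idxs[-1] == len(chain.residues) - 1:
        raise ValueError(
            f"loop {chain_id}:{start}-{end} lacks fixed anchor residues")
    return chain, idxs


def _rebuild_loop(model, chain_id, start, end, new_bb):
    """Install new loop backbones; side chains ride rigidly on the local
    (N, CA, C) frame; carbonyl O is re-derived from the new geometry."""
    from .build import ANGLE_CA_C_O, BOND_C_O, place_atom
    out = model.copy()
    chain, idxs = _loop_indices(out, chain_id, start, end)
    for k, i in enumerate(idxs):
        res = chain.residues[i]
        old = np.array([res.atom(n).coords for n in ("N", "CA", "C")])
        new = np.array([new_bb[k][n] for n in ("N", "CA", "C")])
        sup = kabsch_superpose(new, old)
        nxt = (chain.residues[i + 1].atom("N").coords
               if k == len(idxs) - 1 else new_bb[k + 1]["N"])
        tor = dihedral(new_bb[k]["N"], new_bb[k]["CA"], new_bb[k]["C"],
                       nxt) + 180.0
        for a in res.atoms:
            if a.name in ("N", "CA", "C"):
                a.coords = np.asarray(new_bb[k][a.name], float)
            elif a.name == "O":
                a.coords = place_atom(new_bb[k]["N"], new_bb[k]["CA"],
                                      new_bb[k]["C"], BOND_C_O,
                                      ANGLE_CA_C_O, tor)
            else:
                a.coords = sup.rotation @ a.coords + sup.translation
    return out


def refine_cdr_loops(model: StructureModel, loops,
                     config: DesignConfig | None = None,
                     em: EnergyModel | None = None,
                     closure_tol: float = 0.1) -> RefinementResult:
    """Monte-Carlo loop refinement with CCD closure.

    ``loops`` is a list of (chain_id, start_seq, end_seq); the residues
    immediately flanking each range are fixed anchors.  Each cycle perturbs
    the phi/psi of one random loop residue, closes the break by CCD, and
    applies Metropolis acceptance at ``loop_kT`` on the total pose energy.
    The best-energy conformation seen is returned; unclosable proposals are
    counted and rejected.
    """
    from .build import (ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C, BOND_CA_C,
                        BOND_C_N, BOND_N_CA, place_atom)
    config = config or DesignConfig()
    em = em or EnergyModel()
    for chain_id, start, end in loops:
        _loop_indices(model, chain_id, start, end)
    if config.loop_n_cycles == 0:
        out = model.copy()
        return RefinementResult(model=out, best_energy=float("nan"),
                                seed=config.seed)
    rng = np.random.default_rng(config.seed)
    work = model.copy()
    e_cur = score_pose(work, em).total
    best_model, e_best = work.copy(), e_cur
    trajectory = []
    failed = 0
    for cycle in range(config.loop_n_cycles):
        chain_id, start, end = loops[cycle % len(loops)]
        chain, idxs = _loop_indices(work, chain_id, start, end)
        res_bb = [{n: chain.residues[i].atom(n).coords.copy()
                   for n in ("N", "CA", "C")} for i in idxs]
        prev = chain.residues[idxs[0] - 1]
        nxt = chain.residues[idxs[-1] + 1]
        anchor_prev = {n: prev.atom(n).coords for n in ("N", "CA", "C")}
        target_next = {n: nxt.atom(n).coords for n in ("N", "CA", "C")}

        # measured torsions of the current loop
        phis, psis, omegas = [], [], [180.0]
        seq_bb = [anchor_prev] + res_bb + [target_next]
        for k in range(1, len(seq_bb) - 1):
            phis.append(dihedral(seq_bb[k - 1]["C"], seq_bb[k]["N"],
                                 seq_bb[k]["CA"], seq_bb[k]["C"]))
            psis.append(dihedral(seq_bb[k]["N"], seq_bb[k]["CA"],
                                 seq_bb[k]["C"], seq_bb[k + 1]["N"]))
            omegas.append(dihedral(seq_bb[k - 1]["CA"], seq_bb[k - 1]["C"],
                                   seq_bb[k]["N"], seq_bb[k]["CA"]))
        pick = int(rng.integers(len(idxs)))
        phis[pick] += float(rng.uniform(-config.loop_torsion_step,
                                        config.loop_torsion_step))
        psis[pick] += float(rng.uniform(-config.loop_torsion_step,
                                        config.loop_torsion_step))
        psi_prev = dihedral(anchor_prev["N"], anchor_prev["CA"],
                            anchor_prev["C"], res_bb[0]["N"])

        # rebuild forward from the fixed N anchor with the new torsions
        new_bb = []
        a, b, c = anchor_prev["N"], anchor_prev["CA"], anchor_prev["C"]
        for k in range(len(idxs)):
            Nk = place_atom(a, b, c, BOND_C_N, ANGLE_CA_C_N,
                            psi_prev if k == 0 else psis[k - 1])
            CAk = place_atom(b, c, Nk, BOND_N_CA, ANGLE_C_N_CA, omegas[k])
            Ck = place_atom(c, Nk, CAk, BOND_CA_C, ANGLE_N_CA_C, phis[k])
            new_bb.append({"N": Nk, "CA": CAk, "C": Ck})
            a, b, c = Nk, CAk, Ck
        phi_next = dihedral(res_bb[-1]["C"], target_next["N"],
                            target_next["CA"], target_next["C"])
        new_bb, closure = ccd_close(new_bb, anchor_prev, target_next,
                                    omegas=omegas + [180.0],
                                    phi_next=phi_next, tol=closure_tol)
        if closure >= closure_tol:
            failed += 1
            trajectory.append({"cycle": cycle, "accepted": False,
                               "closure_rmsd": closure, "energy": e_cur,
                               "best_energy": e_best})
            continue
        proposal = _rebuild_loop(work, chain_id, start, end, new_bb)
        e_new = score_pose(proposal, em).total
        accept = (e_new <= e_cur
                  or rng.random() < np.exp(-(e_new - e_cur) / config.loop_kT))
        if accept:
            work, e_cur = proposal, e_new
            if e_cur < e_best:
                best_model, e_best = work.copy(), e_cur
        trajectory.append({"cycle": cycle, "accepted": bool(accept),
                           "closure_rmsd": closure, "energy": e_cur,
                           "best_energy": e_best})
    return RefinementResult(model=best_model, trajectory=trajectory,
                            failed_closures=failed, best_energy=e_best,
                            seed=config.seed)
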