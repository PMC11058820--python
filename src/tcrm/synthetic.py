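"""Seeded generators for every fixture the pipeline needs.

The toy complex is a geometric idealization of the TCR-pMHC architecture,
not a homology model: an MHC-platform stand-in made of two ideal
antiparallel alpha-helices (phi/psi = -57/-47) flanking a groove, an
extended 9-mer peptide lying between them, a small helical
beta-2-microglobulin stand-in packed under the platform, and two TCR
variable-domain stand-ins (helix hairpins), each carrying a real CYS-CYS
disulfide, positioned so the disulfide-connecting vector makes exactly the
requested crossing and incident angles.  Ground truth (angles, roles,
design positions, planted interactions) is always returned alongside and,
when written to disk, stored as a sidecar JSON so downstream checks never
re-derive it from the fixture.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assays import ElisaPlate, Sensorgram, simulate_sensorgram, \
    write_plate, write_sensorgrams
from .build import (HELIX_PHI_PSI, STRAND_PHI_PSI, build_backbone,
                    orient_segment)
from .constants import AA1_TO_3
from .design import MutationCandidate, place_mutation
from .energetics import EnergyModel, atom_parameters, binding_score, \
    pair_terms_kernel
from .geometry import rotation_about_axis
from .interface import DesignPosition
from .sidechain import RotamerLibrary, mutate_residue, place_side_chain, \
    residue_template, side_chain_atom_names
from .structio import (Atom, Chain, ComplexPartition, ResidueRec,
                       StructureModel, partition_complex, write_structure)

__all__ = ["SyntheticComplexSpec", "PlantedCase", "build_toy_complex",
           "plant_clash_case", "generate_spr_dataset",
           "generate_elisa_plate", "TOY_CHAIN_MAP"]

# fixed chain letters of the generated fixture (roles are still verified
# through partition_complex in tests rather than assumed)
TOY_CHAIN_MAP = {"A": "mhc_heavy", "B": "b2m", "C": "peptide",
                 "D": "tcr_alpha", "E": "tcr_beta"}

_PEPTIDE_PATTERN = "VVGAVGVGK"  # KRAS 8-16 G12V nonapeptide

# layout constants (A): chosen once to give a clash-free groove with the
# TCR stand-ins hovering a realistic contact distance above the peptide
_HELIX_Y = 8.2
_PEPTIDE_Z = 2.0
_B2M_Z = -12.5
_DISULFIDE_SEP = 24.0       # V-alpha SG-mid to V-beta SG-mid
_CB_CB_TARGET = 5.65        # gives SG-SG ~2.03 with SG on the CB-CB line
_SG_FROM_CB = 1.812


@dataclass
class SyntheticComplexSpec:
    crossing_angle_target: float = 62.0   # deg
    incident_angle_target: float = 8.0    # deg
    peptide_length: int = 9
    interface_gap: float = 3.0            # vertical TCR clearance, A
    jitter: float = 0.03                  # per-coordinate Gaussian sd, A
    seed: int = 1

    def __post_init__(self):
        if not 0.0 < self.crossing_angle_target < 180.0:
            raise ValueError("crossing angle target must be in (0, 180)")
        if not 0.0 <= self.incident_angle_target < 60.0:
            raise ValueError("incident angle target must be in [0, 60)")
        if not 5 <= self.peptide_length <= 11:
            raise ValueError("peptide length must be 5-11")


def _seq_ids(start: int, n: int) -> list[int]:
    return list(range(start, start + n))


def _chain_from_bb(chain_id: str, aas: list[str], seq_ids: list[int],
                   bbs: list[dict]) -> Chain:
    chain = Chain(chain_id)
    for aa, sid, bb in zip(aas, seq_ids, bbs):
        res = ResidueRec(chain_id=chain_id, seq_id=sid, insertion_code="",
                         aa_type=aa)
        atoms = [("N", "N", bb["N"]), ("CA", "C", bb["CA"]),
                 ("C", "C", bb["C"]), ("O", "O", bb["O"])]
        sc = place_side_chain(bb, aa, ())
        names, _, _ = residue_template(aa)
        for n in names:
            if n in sc:
                atoms.append((n, n[0], sc[n]))
        for k, (name, el, xyz) in enumerate(atoms):
            res.atoms.append(Atom(serial=0, name=name, element=el,
                                  residue_index=0, alt_loc="",
                                  coords=np.asarray(xyz, float)))
        chain.residues.append(res)
    return chain


def _random_sequence(rng, n: int, pool=("ALA", "ALA", "SER", "THR", "VAL")
                     ) -> list[str]:
    return [pool[int(rng.integers(len(pool)))] for _ in range(n)]


def _helix(n: int) -> list[dict]:
    phi, psi = HELIX_PHI_PSI
    return build_backbone([phi] * n, [psi] * n)


def _tcr_domain_template(rng) -> tuple[list, list, list]:
    """Two antiparallel helices with a central engineered disulfide.

    Returns (aas, seq_ids, backbones-with-sidechain-overrides) in local
    coordinates with the SG midpoint at the origin; element [2] is a list
    of (aa, seq_id, bb dict, sg_override or None).
    """
    n = 13
    cys_idx = 6
    bbA = orient_segment(_helix(n), (1, 0, 0), (0.0, -6.0, 0.0))
    bbB = orient_segment(_helix(n), (-1, 0, 0), (0.0, +6.0, 0.0))

    def _cb(bb):
        sc = place_side_chain(bb, "CYS", ())
        return sc["CB"]

    # rotate each helix about its own axis so the central CYS CB points
    # toward the partner helix
    def _spin(bb_list, want_y: float, y0: float):
        cb = _cb(bb_list[cys_idx])
        ca = bb_list[cys_idx]["CA"]
        w = cb - ca
        w_perp = np.array([0.0, w[1], w[2]])
        cur = np.degrees(np.arctan2(w_perp[2], w_perp[1]))
        tgt = 0.0 if want_y > 0 else 180.0
        R = rotation_about_axis((1.0, 0.0, 0.0), tgt - cur)
        out = []
        for bb in bb_list:
            out.append({k: R @ (p - np.array([0.0, y0, 0.0]))
                        + np.array([0.0, y0, 0.0]) for k, p in bb.items()})
        return out

    bbA = _spin(bbA, +1.0, -6.0)
    bbB = _spin(bbB, -1.0, +6.0)
    cb1, cb2 = _cb(bbA[cys_idx]), _cb(bbB[cys_idx])
    u = cb2 - cb1
    d0 = np.linalg.norm(u)
    u = u / d0
    shift = (d0 - _CB_CB_TARGET) * u
    bbB = [{k: p - shift for k, p in bb.items()} for bb in bbB]
    cb2 = cb2 - shift
    sg1 = cb1 + _SG_FROM_CB * u
    sg2 = cb2 - _SG_FROM_CB * u
    mid = 0.5 * (sg1 + sg2)

    entries = []
    aasA = _random_sequence(rng, n)
    aasB = _random_sequence(rng, n)
    aasA[cys_idx] = "CYS"
    aasB[cys_idx] = "CYS"
    for seg, aas, base in ((bbA, aasA, 1), (bbB, aasB, 20)):
        for k, bb in enumerate(seg):
            sg = None
            if aas[k] == "CYS":
                sg = (sg1 if seg is bbA else sg2) - mid
            entries.append((aas[k], base + k,
                            {kk: p - mid for kk, p in bb.items()}, sg))
    return entries


def _place_entries(entries, R: np.ndarray, t: np.ndarray,
                   chain_id: str) -> Chain:
    chain = Chain(chain_id)
    for aa, sid, bb, sg in entries:
        bb_glob = {k: R @ p + t for k, p in bb.items()}
        res = ResidueRec(chain_id=chain_id, seq_id=sid, insertion_code="",
                         aa_type=aa)
        atoms = [("N", "N", bb_glob["N"]), ("CA", "C", bb_glob["CA"]),
                 ("C", "C", bb_glob["C"]), ("O", "O", bb_glob["O"])]
        sc = place_side_chain(bb_glob, aa, ())
        if sg is not None:
            sc["SG"] = R @ sg + t
        names, _, _ = residue_template(aa)
        for n in names:
            if n in sc:
                atoms.append((n, n[0], sc[n]))
        for name, el, xyz in atoms:
            res.atoms.append(Atom(serial=0, name=name, element=el,
                                  residue_index=0, alt_loc="",
                                  coords=np.asarray(xyz, float)))
        chain.residues.append(res)
    return chain


def _renumber(model: StructureModel) -> None:
    serial = 0
    ridx = 0
    for res in model.iter_residues():
        for a in res.atoms:
            serial += 1
            a.serial = serial
            a.residue_index = ridx
        ridx += 1


def _peptide_sequence(length: int) -> list[str]:
    pat = _PEPTIDE_PATTERN
    one = (pat[:length] if length <= len(pat)
           else pat + "A" * (length - len(pat)))
    return [AA1_TO_3[c] for c in one]


def _relax_side_chains(model: StructureModel, chain_ids,
                           em: EnergyModel, rotlib: RotamerLibrary,
                           max_passes: int = 6) -> StructureModel:
    """Iterate self-substitutions until every TCR side chain sits at its
    minimum-energy rotamer given the others (fixed point => exact
    self-substitution neutrality in later scans)."""
    work = model
    prev = None
    for _ in range(max_passes):
        choices = []
        for cid in chain_ids:
            for res in work.chain(cid).residues:
                if res.aa_type in ("GLY", "CYS"):
                    continue  # CYS: keep the engineered disulfide geometry
                pos = DesignPosition(chain_id=cid, seq_id=res.seq_id,
                                     insertion_code=res.insertion_code,
                                     aa_type=res.aa_type,
                                     role="tcr_alpha")
                cand = MutationCandidate(position=pos, wt_aa=res.aa_type,
                                         mut_aa=res.aa_type)
                placed = place_mutation(work, cand, rotlib, em)
                work = placed.model
                choices.append(placed.rotamer_index)
        if choices == prev:
            break
        prev = choices
    return work


def _design_positions_truth(model: StructureModel, cutoff: float = 8.0
                            ) -> list[tuple[str, int]]:
    """Ground-truth interface positions, measured directly with plain
    distance arithmetic (independent of the interface module)."""
    pep = np.concatenate([r.coords()
                          for r in model.chain("C").residues])
    out = []
    for cid in ("D", "E"):
        for res in model.chain(cid).residues:
            d = np.linalg.norm(res.coords()[:, None, :] - pep[None, :, :],
                               axis=2)
            if d.min() <= cutoff:
                out.append((cid, res.seq_id))
    return out


def build_toy_complex(spec: SyntheticComplexSpec | None = None,
                      relax: bool = True,
                      plant_saltbridge: bool = False,
                      em: EnergyModel | None = None
                      ) -> tuple[StructureModel, dict]:
    """Five-chain toy TCR-pMHC complex plus its ground-truth record."""
    spec = spec or SyntheticComplexSpec()
    em = em or EnergyModel()
    rng = np.random.default_rng(spec.seed)
    rotlib = RotamerLibrary()

    # MHC platform: groove helices along +/- x (author numbering matching
    # the default class-I helix windows)
    n1, n2 = 36, 38
    h1 = orient_segment(_helix(n1), (1, 0, 0), (0.0, -_HELIX_Y, 0.0))
    h2 = orient_segment(_helix(n2), (-1, 0, 0), (0.0, +_HELIX_Y, 0.0))
    mhc = _chain_from_bb("A", _random_sequence(rng, n1) ,
                         _seq_ids(50, n1), h1)
    mhc2 = _chain_from_bb("A", _random_sequence(rng, n2),
                          _seq_ids(138, n2), h2)
    mhc.residues.extend(mhc2.residues)

    # b2m stand-in under the alpha1 helix
    nb = 16
    b2m_bb = orient_segment(_helix(nb), (1, 0, 0),
                            (0.0, -_HELIX_Y, _B2M_Z))
    b2m = _chain_from_bb("B", _random_sequence(rng, nb),
                         _seq_ids(1, nb), b2m_bb)

    # peptide: extended strand in the groove
    phi, psi = STRAND_PHI_PSI
    pep_bb = build_backbone([phi] * spec.peptide_length,
                            [psi] * spec.peptide_length)
    pep_bb = orient_segment(pep_bb, (1, 0, 0), (0.0, 0.0, _PEPTIDE_Z))
    pep_aas = _peptide_sequence(spec.peptide_length)
    pep = _chain_from_bb("C", pep_aas, _seq_ids(1, spec.peptide_length),
                         pep_bb)

    # TCR axis relative to the actual peptide N->C direction (projected)
    ca1 = pep.residues[0].atom("CA").coords
    ca9 = pep.residues[-1].atom("CA").coords
    v = ca9 - ca1
    p_proj = np.array([v[0], v[1], 0.0])
    p_proj /= np.linalg.norm(p_proj)
    theta = np.radians(spec.crossing_angle_target)
    inc = np.radians(spec.incident_angle_target)
    Rz = rotation_about_axis((0, 0, 1), spec.crossing_angle_target)
    d_inplane = Rz @ p_proj
    t_axis = np.cos(inc) * d_inplane + np.sin(inc) * np.array([0, 0, 1.0])

    z_mid = _PEPTIDE_Z + 3.0 + spec.interface_gap + 4.0
    center = np.array([0.0, 0.0, z_mid])
    A = center - 0.5 * _DISULFIDE_SEP * t_axis
    B = center + 0.5 * _DISULFIDE_SEP * t_axis

    w = np.cross(np.array([0, 0, 1.0]), d_inplane)
    w /= np.linalg.norm(w)
    Rdom = np.column_stack([w, np.cross(np.array([0, 0, 1.0]), w),
                            np.array([0, 0, 1.0])])
    if np.linalg.det(Rdom) < 0:
        Rdom[:, 1] = -Rdom[:, 1]

    dom_a = _tcr_domain_template(rng)
    dom_b = _tcr_domain_template(rng)
    tcr_a = _place_entries(dom_a, Rdom, A, "D")
    tcr_b = _place_entries(dom_b, Rdom, B, "E")

    model = StructureModel(
        chains=[Chain("A", mhc.residues), b2m, pep, tcr_a, tcr_b],
        metadata={"title": "synthetic TCR-pMHC toy complex",
                  "deposition_id": f"TOY{spec.seed}", "model_number": 1})

    # seeded jitter: different seeds -> different coordinates
    if spec.jitter > 0:
        for a in model.iter_atoms():
            a.coords = a.coords + rng.normal(0.0, spec.jitter, 3)
    _renumber(model)
    model.validate()

    if relax:
        # every chain: template-conformation side chains settle into their
        # minimum-energy rotamers (exact fixed point => later wild-type
        # self-substitutions are neutral by construction)
        model = _relax_side_chains(model, ("A", "B", "C", "D", "E"),
                                   em, rotlib)

    truth = {
        "seed": spec.seed,
        "crossing_angle": spec.crossing_angle_target,
        "incident_angle": spec.incident_angle_target,
        "peptide_length": spec.peptide_length,
        "peptide_sequence": "".join(
            r.one_letter for r in model.chain("C").residues),
        "chain_roles": dict(TOY_CHAIN_MAP),
        "atom_counts": {c.chain_id: sum(len(r.atoms) for r in c.residues)
                        for c in model.chains},
        "design_positions_8A": _design_positions_truth(model),
        "planted_saltbridge": None,
    }

    if plant_saltbridge:
        truth["planted_saltbridge"] = _plant_saltbridge(model)
        _renumber(model)
    return model, truth


def _plant_saltbridge(model: StructureModel) -> dict:
    """Rebuild the TCR residue closest to the peptide as ASP and extend a
    synthetic peptide lysine toward it, ending NZ ~3.2 A from OD1 (a
    favorable cross-interface electrostatic pair, no clash)."""
    cand = None
    pep_res = list(model.chain("C").residues)
    for cid in ("D", "E"):
        for res in model.chain(cid).residues:
            cb = res.atom("CB")
            if cb is None or res.aa_type == "CYS":
                continue
            for pr in pep_res:
                d = float(np.linalg.norm(cb.coords
                                         - pr.atom("CA").coords))
                if cand is None or d < cand[0]:
                    cand = (d, res, pr)
    _, tcr_res, pep_partner = cand
    chain = model.chain(tcr_res.chain_id)
    idx = chain.residues.index(tcr_res)
    # ASP pointing generally down: pick the rotamer whose OD1 is closest
    # to the partner CA
    best = None
    for chi in RotamerLibrary().rotamers("ASP"):
        sc = place_side_chain(
            {n: tcr_res.atom(n).coords for n in ("N", "CA", "C")},
            "ASP", chi)
        d = float(np.linalg.norm(sc["OD1"] - pep_partner.atom("CA").coords))
        if best is None or d < best[0]:
            best = (d, chi)
    chain.residues[idx] = mutate_residue(tcr_res, "ASP", best[1])
    od1 = chain.residues[idx].atom("OD1").coords

    _graft_extended_lys(model, pep_partner, od1, end_dist=3.2)
    return {"tcr_residue": (tcr_res.chain_id, tcr_res.seq_id),
            "peptide_residue": (pep_partner.chain_id, pep_partner.seq_id),
            "target_distance": 3.2}


def _graft_extended_lys(model: StructureModel, pep_res: ResidueRec,
                        target: np.ndarray, end_dist: float) -> None:
    """Replace a peptide residue with a synthetic lysine whose side chain
    runs straight from its CA toward ``target``, placing NZ at
    ``end_dist`` from it.  Bond geometry is idealized along the ray (a
    deliberate synthetic construction, not a rotamer)."""
    ca = pep_res.atom("CA").coords
    u = target - ca
    u = u / np.linalg.norm(u)
    nz = target - end_dist * u
    positions = {"NZ": nz}
    for k, name in enumerate(("CE", "CD", "CG", "CB"), start=1):
        positions[name] = nz - 1.53 * k * u
    chain = model.chain(pep_res.chain_id)
    idx = chain.residues.index(pep_res)
    new = mutate_residue(pep_res, "LYS", ())
    for a in new.atoms:
        if a.name in positions:
            a.coords = positions[a.name]
    chain.residues[idx] = new


# ---------------------------------------------------------------------------
# planted-clash benchmark

@dataclass
class PlantedCase:
    complex: StructureModel
    partition: ComplexPartition
    clash_position: DesignPosition
    wt_aa: str = "ARG"
    expected_best: str = "GLY"
    seed: int = 0
    ground_truth: dict = field(default_factory=dict)


def plant_clash_case(seed: int = 0, n_clashes: int = 1,
                     em: EnergyModel | None = None) -> PlantedCase:
    """Toy complex with a planted steric clash at a TCR interface residue.

    A synthetic peptide lysine is extended to within 0.8x the LJ contact
    distance of the residue's CB, so every substitution that keeps a CB
    retains the clash and glycine (the recorded ``expected_best``) is the
    unique clash-relieving choice; the wild type is rebuilt as arginine at
    its maximum-clash rotamer, so even the ARG->ALA truncation strictly
    reduces the repulsive term.
    """
    em = em or EnergyModel()
    rotlib = RotamerLibrary()
    spec = SyntheticComplexSpec(seed=seed)
    model, truth = build_toy_complex(spec, relax=True, em=em)
    partition = partition_complex(model, TOY_CHAIN_MAP)[0]

    clash_records = []
    used_partners: set[int] = set()
    roles = [("D", "tcr_alpha"), ("E", "tcr_beta")][:n_clashes]
    for cid, role in roles:
        pep_res_list = [r for r in model.chain("C").residues
                        if r.seq_id not in used_partners]
        cand = None
        for res in model.chain(cid).residues:
            cb = res.atom("CB")
            if cb is None or res.aa_type == "CYS":
                continue
            for pr in pep_res_list:
                d = float(np.linalg.norm(cb.coords - pr.atom("CA").coords))
                if cand is None or d < cand[0]:
                    cand = (d, res, pr)
        _, tcr_res, partner = cand
        used_partners.add(partner.seq_id)

        # graft the clashing lysine: NZ at 0.7x contact distance from CB
        contact = em.lj_params["C"][0] + em.lj_params["N"][0]
        cb = tcr_res.atom("CB").coords
        _graft_extended_lys(model, partner, cb, end_dist=0.7 * contact)

        # wild-type ARG at its maximum cross-interface-repulsion rotamer
        pep_coords = np.concatenate(
            [r.coords() for r in model.chain("C").residues])
        pep_params_names = [(r.aa_type, a.name)
                            for r in model.chain("C").residues
                            for a in r.atoms]
        names = side_chain_atom_names("ARG")
        p_arg = atom_parameters("ARG", names, em)
        bb = {n: tcr_res.atom(n).coords for n in ("N", "CA", "C")}
        worst = None
        for k, chi in enumerate(rotlib.rotamers("ARG")):
            sc = place_side_chain(bb, "ARG", chi)
            coords = np.array([sc[n] for n in names])
            ii, jj = np.meshgrid(np.arange(len(names)),
                                 np.arange(len(pep_coords)), indexing="ij")
            r = np.linalg.norm(coords[ii.ravel()]
                               - pep_coords[jj.ravel()], axis=1)
            pp = atom_parameters(
                "LYS", [n for _, n in pep_params_names], em,
                elements=[n[0] for _, n in pep_params_names])
            terms = pair_terms_kernel(
                r, {kk: v[ii.ravel()] for kk, v in p_arg.items()},
                {kk: v[jj.ravel()] for kk, v in pp.items()}, em)
            if worst is None or terms["lj_rep"] > worst[0]:
                worst = (terms["lj_rep"], chi)
        chain = model.chain(cid)
        idx = chain.residues.index(tcr_res)
        chain.residues[idx] = mutate_residue(tcr_res, "ARG", worst[1])
        clash_records.append({
            "role": role, "chain_id": cid, "seq_id": tcr_res.seq_id,
            "partner_seq_id": partner.seq_id,
            "planted_rep": float(worst[0])})

    _renumber(model)
    model.validate()

    first = clash_records[0]
    pos = DesignPosition(chain_id=first["chain_id"],
                         seq_id=first["seq_id"], insertion_code="",
                         aa_type="ARG", role=first["role"])
    case = PlantedCase(
        complex=model, partition=partition, clash_position=pos,
        wt_aa="ARG", expected_best="GLY", seed=seed,
        ground_truth={"clashes": clash_records, "toy": truth})

    # construction verified by scoring: GLY at the planted position must
    # relieve at least 1 kcal/mol of interface repulsion
    wt_b = binding_score(model, partition, em)
    cand = MutationCandidate(position=pos, wt_aa="ARG", mut_aa="GLY")
    gly = place_mutation(model, cand, rotlib, em)
    gly_b = binding_score(gly.model, partition, em)
    relief = wt_b.binding.lj_rep - gly_b.binding.lj_rep
    if relief < 1.0:
        raise RuntimeError(
            f"planted clash too weak (rep relief {relief:.3f} kcal/mol)")
    case.ground_truth["rep_relief"] = float(relief)
    return case


# ---------------------------------------------------------------------------
# assay datasets

def generate_spr_dataset(truth: dict, conc_series, noise_sd: float,
                         seed: int, out_dir=None,
                         t_assoc: float = 60.0, t_dissoc: float = 120.0,
                         dt: float = 0.5
                         ) -> tuple[list[Sensorgram], dict]:
    """Simulate a 1:1 sensorgram series and (optionally) write the CSV
    plus a sidecar JSON carrying the generating truth."""
    sensorgrams = simulate_sensorgram(
        truth["ka"], truth["kd"], truth["rmax"], conc_series,
        t_assoc=t_assoc, t_dissoc=t_dissoc, dt=dt,
        noise_sd=noise_sd, seed=seed)
    sidecar = {"truth": dict(truth), "conc_series_M": list(conc_series),
               "noise_sd": noise_sd, "seed": seed,
               "t_assoc_s": t_assoc, "t_dissoc_s": t_dissoc, "dt_s": dt,
               "KD_M": truth["kd"] / truth["ka"]}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_sensorgrams(sensorgrams, out_dir / "sensorgrams.csv")
        (out_dir / "sensorgrams.truth.json").write_text(
            json.dumps(sidecar, indent=1))
    return sensorgrams, sidecar


def generate_elisa_plate(true_percentages: dict,
                         control_ods: tuple[float, float] = (0.15, 1.10),
                         replicate_sd: float = 0.02,
                         n_replicates: int = 4, seed: int = 0,
                         out_dir=None) -> tuple[ElisaPlate, dict]:
    """ELISA plate with sample ODs synthesized by inverting the percent-
    positive formula around the given control ODs (default n = 4
    biological replicates)."""
    neg, pos = control_ods
    if neg == pos:
        raise ValueError("control ODs must be distinct")
    rng = np.random.default_rng(seed)
    wells = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]
    it = iter(wells)
    od, roles = {}, {}
    for _ in range(n_replicates):
        w = next(it)
        od[w] = pos + (rng.normal(0.0, replicate_sd) if replicate_sd else 0)
        roles[w] = "positive"
    for _ in range(n_replicates):
        w = next(it)
        od[w] = neg + (rng.normal(0.0, replicate_sd) if replicate_sd else 0)
        roles[w] = "negative"
    for pep in sorted(true_percentages):
        p = true_percentages[pep]
        for _ in range(n_replicates):
            w = next(it)
            od[w] = (neg + (pos - neg) * p / 100.0
                     + (rng.normal(0.0, replicate_sd) if replicate_sd
                        else 0))
            roles[w] = pep
    plate = ElisaPlate(od=od, roles=roles)
    sidecar = {"true_percentages": dict(true_percentages),
               "control_ods": [neg, pos], "replicate_sd": replicate_sd,
               "n_replicates": n_replicates, "seed": seed}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_plate(plate, out_dir / "elisa_plate.csv")
        (out_dir / "elisa_plate.truth.json").write_text(
            json.dumps(sidecar, indent=1))
    return plate, sidecar


def write_toy_complex(spec: SyntheticComplexSpec, out_dir,
                      **kwargs) -> tuple[Path, Path]:
    """Write the toy complex PDB and its ground-truth sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, truth = build_toy_complex(spec, **kwargs)
    pdb = out_dir / f"toy_complex_seed{spec.seed}.pdb"
    sidecar = out_dir / f"toy_complex_seed{spec.seed}.truth.json"
    write_structure(model, pdb, "pdb")
    sidecar.write_text(json.dumps(truth, indent=1, default=str))
    return pdb, sidecar
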