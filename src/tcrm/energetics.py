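"""Decomposable pairwise pose score and the interface binding score.

The score is a transparent physics-style analogue of the scoring functions
used for fixed-backbone design: a split Lennard-Jones (attractive /
repulsive, with the repulsive branch linearly extrapolated at very short
range so clashes stay finite and smooth), screened Coulomb electrostatics
with a distance-dependent dielectric eps(r) = eps0 * r, a Gaussian-exclusion
(Lazaridis-Karplus form) implicit solvation term, and a short-range
heavy-atom hydrogen-bond well.  It is strictly pairwise over heavy atoms,
with intra-residue pairs and 1-2/1-3 pairs across the peptide bond excluded,
and every term smoothly switched to zero across a cutoff window, so the
interface binding score

    B = E(complex) - E(TCR) - E(pMHC)

computed on identical coordinates reduces exactly to the sum of
cross-partner pair energies.  Absolute values are not comparable to any
molecular-mechanics force field; the score exists to *rank* candidate
mutations, which is all the design protocol needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import HBOND_ACCEPTORS, HBOND_DONORS
from .structio import ComplexPartition, StructureModel, extract_chains

__all__ = ["EnergyModel", "EnergyBreakdown", "BindingScore", "FlatPose",
           "score_pose", "binding_score", "EnergeticsError"]

COULOMB_CONSTANT = 332.064  # kcal mol^-1 A e^-2

_PARAM_DIR = Path(__file__).parent / "params"
PARAMETER_SET_VERSION = "v1"


class EnergeticsError(ValueError):
    pass


def _read_tsv(name: str) -> list[list[str]]:
    rows = []
    for line in (_PARAM_DIR / name).read_text().splitlines():
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


def _default_lj() -> dict:
    return {r[0]: (float(r[1]), float(r[2])) for r in _read_tsv("lj.tsv")}


def _default_solvation() -> dict:
    return {r[0]: (float(r[1]), float(r[2]), float(r[3]))
            for r in _read_tsv("solvation.tsv")}


def _default_charges() -> dict:
    return {(r[0], r[1]): float(r[2]) for r in _read_tsv("charges.tsv")}


@dataclass
class EnergyModel:
    """Parameter set and functional-form constants for the pose score."""
    weights: dict = field(default_factory=lambda: {
        "lj_attr": 1.0, "lj_rep": 0.55, "coulomb": 1.0,
        "solvation": 1.0, "hbond": 1.0})
    lj_params: dict = field(default_factory=_default_lj)
    solvation_params: dict = field(default_factory=_default_solvation)
    charges: dict = field(default_factory=_default_charges)
    eps0: float = 10.0            # eps(r) = eps0 * r
    cutoff: float = 6.0           # A
    switch_on: float = 5.5        # A, start of the switching window
    rep_knee: float = 0.6         # linear extrapolation below rep_knee*rmin
    hbond_full: float = 2.8       # A, full-strength donor-acceptor distance
    hbond_zero: float = 3.5       # A, hbond well reaches zero
    hbond_strength: float = 1.0   # kcal/mol at full strength
    version: str = PARAMETER_SET_VERSION

    def __post_init__(self):
        if self.cutoff <= self.switch_on:
            raise EnergeticsError("cutoff must exceed the switch window start")
        if any(w < 0 for w in self.weights.values()):
            raise EnergeticsError("weights must be non-negative")


@dataclass
class EnergyBreakdown:
    lj_attr: float = 0.0
    lj_rep: float = 0.0
    coulomb: float = 0.0
    solvation: float = 0.0
    hbond: float = 0.0
    total: float = 0.0

    TERMS = ("lj_attr", "lj_rep", "coulomb", "solvation", "hbond")

    @classmethod
    def from_terms(cls, weights: dict, **terms) -> "EnergyBreakdown":
        total = sum(weights[k] * terms.get(k, 0.0) for k in cls.TERMS)
        return cls(total=total, **terms)

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            **{k: getattr(self, k) - getattr(other, k) for k in self.TERMS},
            total=self.total - other.total)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (*self.TERMS, "total")}


@dataclass
class BindingScore:
    complex: EnergyBreakdown
    tcr_alone: EnergyBreakdown
    pmhc_alone: EnergyBreakdown
    binding: EnergyBreakdown


# ---------------------------------------------------------------------------
# flattened pose representation

_NAME_CODE = {"N": 1, "CA": 2, "C": 3, "O": 4}
# 1-2 and 1-3 pairs across the backbone link, as (code_prev, code_next)
_LINK_EXCLUDED = {(3, 1), (3, 2), (2, 1), (4, 1)}


def is_donor(aa_type: str, name: str) -> bool:
    if name in HBOND_DONORS.get("*", ()) and aa_type != "PRO":
        return True
    return name in HBOND_DONORS.get(aa_type, ())


def is_acceptor(aa_type: str, name: str) -> bool:
    return (name in HBOND_ACCEPTORS.get("*", ())
            or name in HBOND_ACCEPTORS.get(aa_type, ()))


def atom_parameters(aa_type: str, atom_names, em: EnergyModel,
                    elements=None) -> dict:
    """Per-atom parameter arrays for a residue type (layout of
    :meth:`FlatPose.params`); used to trial side chains not yet in a pose."""
    n = len(atom_names)
    out = {k: np.zeros(n) for k in ("rmin_half", "eps", "charge",
                                    "dgfree", "lam", "vol")}
    out["donor"] = np.zeros(n, dtype=bool)
    out["acceptor"] = np.zeros(n, dtype=bool)
    for k, name in enumerate(atom_names):
        el = (elements[k] if elements is not None else name[0]).upper()
        if el not in em.lj_params:
            raise EnergeticsError(f"no parameters for element {el} ({name})")
        out["rmin_half"][k], out["eps"][k] = em.lj_params[el]
        (out["dgfree"][k], out["lam"][k],
         out["vol"][k]) = em.solvation_params[el]
        q = em.charges.get((aa_type, name))
        if q is None:
            q = em.charges.get(("*", name), 0.0)
        out["charge"][k] = q
        out["donor"][k] = is_donor(aa_type, name)
        out["acceptor"][k] = is_acceptor(aa_type, name)
    return out


class FlatPose:
    """Array view of a model with per-atom energy parameters attached."""

    def __init__(self, model: StructureModel, em: EnergyModel):
        coords, rmin_half, eps, charge = [], [], [], []
        dgfree, lam, vol, donor, acceptor = [], [], [], [], []
        res_uid, chain_idx, seq, name_code = [], [], [], []
        untyped = []
        uid = 0
        for ci, chain in enumerate(model.chains):
            for res in chain.residues:
                has_oxt = res.atom("OXT") is not None
                for a in res.atoms:
                    el = a.element.upper()
                    if el not in em.lj_params:
                        untyped.append(f"{res.label()}/{a.name}({el})")
                        continue
                    rh, e = em.lj_params[el]
                    dg, lm, v = em.solvation_params[el]
                    q = em.charges.get((res.aa_type, a.name))
                    if q is None:
                        q = em.charges.get(("*", a.name), 0.0)
                    if a.name == "OXT" and not has_oxt:
                        q = 0.0
                    coords.append(a.coords)
                    rmin_half.append(rh)
                    eps.append(e)
                    charge.append(q)
                    dgfree.append(dg)
                    lam.append(lm)
                    vol.append(v)
                    donor.append(is_donor(res.aa_type, a.name))
                    acceptor.append(is_acceptor(res.aa_type, a.name))
                    res_uid.append(uid)
                    chain_idx.append(ci)
                    seq.append(res.seq_id)
                    name_code.append(_NAME_CODE.get(a.name, 0))
                uid += 1
        if untyped:
            raise EnergeticsError(
                "atoms without energy parameters: " + ", ".join(untyped))
        if not coords:
            raise EnergeticsError("no scorable atoms")
        self.coords = np.array(coords, dtype=float)
        self.rmin_half = np.array(rmin_half)
        self.eps = np.array(eps)
        self.charge = np.array(charge)
        self.dgfree = np.array(dgfree)
        self.lam = np.array(lam)
        self.vol = np.array(vol)
        self.donor = np.array(donor, dtype=bool)
        self.acceptor = np.array(acceptor, dtype=bool)
        self.res_uid = np.array(res_uid, dtype=np.int64)
        self.chain_idx = np.array(chain_idx, dtype=np.int64)
        self.seq = np.array(seq, dtype=np.int64)
        self.name_code = np.array(name_code, dtype=np.int64)
        self.em = em
        self._disulfide_excl = self._find_disulfide_exclusions(model)

    def _find_disulfide_exclusions(self, model) -> set:
        """1-2 (SG-SG) and 1-3 (SG-CB) pairs across disulfide bridges are
        bonded, not nonbonded contacts."""
        sg = []
        k = 0
        for res in model.iter_residues():
            for a in res.atoms:
                el = a.element.upper()
                if el not in self.em.lj_params:
                    continue
                if res.aa_type == "CYS" and a.name in ("SG", "CB"):
                    sg.append((a.name, k, int(self.res_uid[k])))
                k += 1
        excl = set()
        sgs = [t for t in sg if t[0] == "SG"]
        cbs = {uid: idx for (name, idx, uid) in sg if name == "CB"}
        for x in range(len(sgs)):
            for y in range(x + 1, len(sgs)):
                _, i, ui = sgs[x]
                _, j, uj = sgs[y]
                if ui == uj:
                    continue
                d = np.linalg.norm(self.coords[i] - self.coords[j])
                if d <= 2.5:
                    excl.add((min(i, j), max(i, j)))
                    for a, b in ((i, cbs.get(uj)), (j, cbs.get(ui))):
                        if b is not None:
                            excl.add((min(a, b), max(a, b)))
        return excl

    def __len__(self):
        return len(self.coords)

    @property
    def tree(self) -> cKDTree:
        if getattr(self, "_tree", None) is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    def params(self, idx) -> dict:
        return {k: getattr(self, k)[idx]
                for k in ("rmin_half", "eps", "charge", "dgfree", "lam",
                          "vol", "donor", "acceptor")}

    # pair selection -------------------------------------------------------

    def _excluded(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        same_res = self.res_uid[i] == self.res_uid[j]
        same_chain = self.chain_idx[i] == self.chain_idx[j]
        dseq = self.seq[j] - self.seq[i]
        link = np.zeros(len(i), dtype=bool)
        for a, b in _LINK_EXCLUDED:
            link |= ((dseq == 1) & (self.name_code[i] == a)
                     & (self.name_code[j] == b))
            link |= ((dseq == -1) & (self.name_code[j] == a)
                     & (self.name_code[i] == b))
        out = same_res | (same_chain & link)
        if self._disulfide_excl:
            lo = np.minimum(i, j)
            hi = np.maximum(i, j)
            n = len(self.coords)
            keys = lo * n + hi
            excl_keys = np.array(sorted(a * n + b
                                        for a, b in self._disulfide_excl))
            out |= np.isin(keys, excl_keys)
        return out

    def all_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        pairs = self.tree.query_pairs(self.em.cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        i, j = pairs[:, 0], pairs[:, 1]
        keep = ~self._excluded(i, j)
        return i[keep], j[keep]

    # pair energies --------------------------------------------------------

    def pair_terms(self, i: np.ndarray, j: np.ndarray) -> dict:
        """Per-term sums over the given in-pose index pairs."""
        r = np.linalg.norm(self.coords[i] - self.coords[j], axis=1)
        return pair_terms_kernel(r, self.params(i), self.params(j), self.em)

    def external_terms(self, ext_coords: np.ndarray, ext_params: dict,
                       exclude_res_uid=()) -> dict:
        """Interaction terms between external atoms and the pose.

        ``ext_params`` holds per-external-atom parameter arrays in the same
        layout as :meth:`params`.  Pose atoms whose residue uid is listed in
        ``exclude_res_uid`` are skipped (used to drop a residue's own
        backbone when trialling its side-chain rotamers).
        """
        ext_coords = np.asarray(ext_coords, float)
        if len(ext_coords) == 0:
            return dict.fromkeys(EnergyBreakdown.TERMS, 0.0)
        hits = self.tree.query_ball_point(ext_coords, self.em.cutoff)
        excl = set(exclude_res_uid)
        ii, jj = [], []
        for k, row in enumerate(hits):
            for j in sorted(row):
                if int(self.res_uid[j]) not in excl:
                    ii.append(k)
                    jj.append(j)
        if not ii:
            return dict.fromkeys(EnergyBreakdown.TERMS, 0.0)
        ii = np.array(ii, dtype=np.int64)
        jj = np.array(jj, dtype=np.int64)
        r = np.linalg.norm(ext_coords[ii] - self.coords[jj], axis=1)
        pa = {k: v[ii] for k, v in ext_params.items()}
        return pair_terms_kernel(r, pa, self.params(jj), self.em)


def pair_terms_kernel(r: np.ndarray, pa: dict, pb: dict,
                      em: EnergyModel) -> dict:
    """Per-term energy sums for atom pairs at distances ``r`` with
    parameter arrays ``pa``/``pb`` for the two sides."""
    r = np.maximum(np.asarray(r, float), 1e-6)
    inside = r < em.cutoff
    r = r[inside]
    pa = {k: v[inside] for k, v in pa.items()}
    pb = {k: v[inside] for k, v in pb.items()}
    if len(r) == 0:
        return dict.fromkeys(EnergyBreakdown.TERMS, 0.0)

    # switching window: 1 below switch_on, cubic smoothstep to 0 at cutoff
    t = np.clip((r - em.switch_on) / (em.cutoff - em.switch_on), 0.0, 1.0)
    sw = 1.0 - t * t * (3.0 - 2.0 * t)

    rmin = pa["rmin_half"] + pb["rmin_half"]
    eps = np.sqrt(pa["eps"] * pb["eps"])
    x = rmin / r
    lj = eps * (x ** 12 - 2.0 * x ** 6)
    attr = np.where(r >= rmin, lj, -eps)
    rep = np.where(r >= rmin, 0.0, lj + eps)
    knee = em.rep_knee * rmin
    xk = 1.0 / em.rep_knee
    f0 = eps * (xk ** 12 - 2.0 * xk ** 6) + eps
    slope = eps * 12.0 * (-xk ** 12 + xk ** 6) / knee
    rep = np.where(r < knee, f0 + slope * (r - knee), rep)

    coul = (COULOMB_CONSTANT * pa["charge"] * pb["charge"]
            / (em.eps0 * r * r))

    def lk(p, q):
        lamb = p["lam"]
        xs = (r - p["rmin_half"]) / lamb
        pref = p["dgfree"] / (2.0 * np.pi ** 1.5 * lamb * r * r)
        return -pref * np.exp(-xs * xs) * q["vol"]

    solv = lk(pa, pb) + lk(pb, pa)

    da = ((pa["donor"] & pb["acceptor"]) | (pb["donor"] & pa["acceptor"]))
    th = np.clip((r - em.hbond_full) / (em.hbond_zero - em.hbond_full),
                 0.0, 1.0)
    hb = np.where(da, -em.hbond_strength
                  * (1.0 - th * th * (3.0 - 2.0 * th)), 0.0)

    out = {
        "lj_attr": float(np.sum(attr * sw)),
        "lj_rep": float(np.sum(rep * sw)),
        "coulomb": float(np.sum(coul * sw)),
        "solvation": float(np.sum(solv * sw)),
        "hbond": float(np.sum(hb * sw)),
    }
    for k, v in out.items():
        if not np.isfinite(v):
            raise EnergeticsError(f"non-finite {k} term")
    return out


def score_pose(model: StructureModel, em: EnergyModel | None = None
               ) -> EnergyBreakdown:
    """Total decomposed pose energy of a model (kcal/mol, model units)."""
    em = em or EnergyModel()
    pose = FlatPose(model, em)
    i, j = pose.all_pairs()
    terms = pose.pair_terms(i, j)
    return EnergyBreakdown.from_terms(em.weights, **terms)


def binding_score(model: StructureModel, partition: ComplexPartition,
                  em: EnergyModel | None = None) -> BindingScore:
    """Interface score B = E(complex) - E(TCR) - E(pMHC).

    The separated partners keep their complex coordinates (no relaxation
    after separation), so with a strictly pairwise score B equals the sum of
    cross-partner pair energies.
    """
    em = em or EnergyModel()
    tcr = extract_chains(model, partition.tcr_chains())
    pmhc = extract_chains(model, partition.pmhc_chains())
    whole = extract_chains(model, partition.tcr_chains()
                           + partition.pmhc_chains())
    e_complex = score_pose(whole, em)
    e_tcr = score_pose(tcr, em)
    e_pmhc = score_pose(pmhc, em)
    return BindingScore(complex=e_complex, tcr_alone=e_tcr,
                        pmhc_alone=e_pmhc,
                        binding=e_complex - e_tcr - e_pmhc)
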