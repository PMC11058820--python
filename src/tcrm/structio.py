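"""Macromolecular coordinate I/O and TCR-pMHC chain-role assignment.

Structures are read through gemmi (PDB and mmCIF) into a lightweight
in-memory model of chains/residues/heavy atoms.  A five-way role partition
(TCR alpha, TCR beta, MHC heavy chain, beta-2-microglobulin, peptide) can be
given explicitly per chain or inferred with contact-based heuristics that do
not assume particular chain letters.

Conventions (fixed for the whole package):

* highest-occupancy alternate location kept, ties broken by file order;
* waters always dropped, other hetero residues dropped unless requested;
* author residue numbering (with insertion codes) is the public convention;
* hydrogens are not modeled - every computation uses heavy atoms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .constants import AA3_TO_1, STANDARD_AA, WATER_NAMES

__all__ = [
    "Atom", "ResidueRec", "Chain", "StructureModel", "ComplexPartition",
    "StructIOError", "PartitionError", "read_structure", "write_structure",
    "partition_complex", "extract_chains", "find_disulfides", "assign_radius",
]

ROLES = ("tcr_alpha", "tcr_beta", "mhc_heavy", "b2m", "peptide")
_ROLE_ALIASES = {
    "mhc": "mhc_heavy", "heavy": "mhc_heavy", "alpha": "tcr_alpha",
    "beta": "tcr_beta", "b2m": "b2m", "pep": "peptide",
}

# disulfide S-S heavy-atom distance threshold
DISULFIDE_CUTOFF = 2.5


class StructIOError(ValueError):
    """Raised for unreadable files, unknown elements or unwritable models."""


class PartitionError(ValueError):
    """Raised when chain roles cannot be resolved or validated."""


def _load_radius_table() -> dict[str, float]:
    table = {}
    path = Path(__file__).parent / "params" / "vdw_radii.tsv"
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


_RADIUS_TABLE = _load_radius_table()


def assign_radius(name: str, element: str) -> float:
    """Solvent-accessibility radius (A) from the bundled element/name table."""
    for key in (f"name:{name}", f"element:{element.upper()}"):
        if key in _RADIUS_TABLE:
            return _RADIUS_TABLE[key]
    return _RADIUS_TABLE["default"]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    alt_loc: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    radius: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructIOError(f"non-finite coordinates for atom {self.name}")
        if self.radius == 0.0:
            self.radius = assign_radius(self.name, self.element)
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructIOError(
                f"occupancy {self.occupancy} outside [0,1] for atom {self.name}")


@dataclass
class ResidueRec:
    chain_id: str
    seq_id: int
    insertion_code: str
    aa_type: str  # three-letter code of a standard residue, or "HETERO"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.aa_type in STANDARD_AA

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.aa_type, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def label(self) -> str:
        ins = self.insertion_code or ""
        return f"{self.chain_id}:{self.one_letter}{self.seq_id}{ins}"


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueRec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.chains:
            raise StructIOError("model has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructIOError(f"duplicate chain ids: {ids}")
        seen = set()
        for res in self.iter_residues():
            if res.key in seen:
                raise StructIOError(f"duplicate residue key {res.key}")
            seen.add(res.key)
            names = [a.name for a in res.atoms]
            if len(set(names)) != len(names):
                raise StructIOError(
                    f"duplicate atom names in residue {res.key}: {names}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def iter_residues(self):
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self):
        for res in self.iter_residues():
            yield from res.atoms

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.iter_atoms()], dtype=float)

    def residue(self, chain_id: str, seq_id: int, icode: str = "") -> ResidueRec:
        for res in self.chain(chain_id).residues:
            if res.seq_id == seq_id and res.insertion_code == icode:
                return res
        raise KeyError(f"no residue {chain_id}:{seq_id}{icode}")

    def copy(self) -> "StructureModel":
        chains = [
            Chain(c.chain_id, [
                dataclasses.replace(r, atoms=[
                    dataclasses.replace(a, coords=a.coords.copy())
                    for a in r.atoms])
                for r in c.residues])
            for c in self.chains
        ]
        return StructureModel(chains, dict(self.metadata))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigid-transformed copy (y = R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in out.iter_atoms():
            a.coords = R @ a.coords + t
        return out


def extract_chains(model: StructureModel, chain_ids) -> StructureModel:
    """Sub-model restricted to ``chain_ids`` (original chain order kept)."""
    wanted = set(chain_ids)
    missing = wanted - set(model.chain_ids())
    if missing:
        raise KeyError(f"chains not in model: {sorted(missing)}")
    chains = [c for c in model.chains if c.chain_id in wanted]
    sub = StructureModel(chains, dict(model.metadata))
    return sub.copy()


# ---------------------------------------------------------------------------
# reading

_GEMMI_FORMAT = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path, format: str = "auto", keep_hetero: bool = False,
                   model_index: int = 0) -> StructureModel:
    """Read a PDB/mmCIF file into a :class:`StructureModel`.

    Waters are always dropped; other hetero residues are dropped unless
    ``keep_hetero`` (they get ``aa_type == "HETERO"``).  Alternate locations
    are resolved to the highest-occupancy conformer (ties: first in file).
    """
    path = Path(path)
    if not path.exists():
        raise StructIOError(f"no such file: {path}")
    if format not in _GEMMI_FORMAT:
        raise StructIOError(f"unknown format {format!r}; use pdb/mmcif/auto")
    try:
        st = gemmi.read_structure(str(path), format=_GEMMI_FORMAT[format])
    except (RuntimeError, ValueError) as exc:
        raise StructIOError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructIOError(f"{path.name}: no models found")
    gmodel = st[model_index]

    model = StructureModel(metadata={
        "title": st.name, "deposition_id": st.name,
        "model_number": getattr(gmodel, "num", model_index + 1),
    })
    serial = 0
    res_index = 0
    for gchain in gmodel:
        chain = Chain(gchain.name)
        for gres in gchain:
            resname = gres.name.strip().upper()
            if resname in WATER_NAMES:
                continue
            standard = resname in STANDARD_AA
            if not standard and not keep_hetero:
                continue
            res = ResidueRec(
                chain_id=gchain.name,
                seq_id=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                aa_type=resname if standard else "HETERO",
            )
            # resolve alt-locs: keep highest occupancy, ties -> first in file
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for ga in gres:
                if ga.name not in best:
                    best[ga.name] = ga
                    order.append(ga.name)
                elif ga.occ > best[ga.name].occ:
                    best[ga.name] = ga
            for name in order:
                ga = best[name]
                el = ga.element.name if ga.element else ""
                if not el or el.upper() == "X":
                    raise StructIOError(
                        f"unknown element for atom {gchain.name}/"
                        f"{gres.seqid.num}/{ga.name}")
                serial += 1
                res.atoms.append(Atom(
                    serial=serial, name=ga.name, element=el,
                    residue_index=res_index,
                    alt_loc=(ga.altloc or "").strip(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=ga.b_iso,
                ))
            if res.atoms:
                chain.residues.append(res)
                res_index += 1
        if chain.residues:
            model.chains.append(chain)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# writing

_PDB_COORD_MIN, _PDB_COORD_MAX = -999.999, 9999.999


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(model.metadata.get("deposition_id", "model"))
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.aa_type if res.is_standard else "UNK"
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_standard else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                if a.alt_loc:
                    ga.altloc = a.alt_loc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def _write_mmcif(model: StructureModel, path: Path) -> None:
    # gemmi's writer rounds to 9 significant digits; coordinates here are
    # emitted with shortest round-trip repr so read(write(m)) is bit-exact.
    lines = [
        f"data_{model.metadata.get('deposition_id', 'model')}",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_comp_id",
        "_atom_site.auth_asym_id",
        "_atom_site.auth_atom_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 0
    for ci, chain in enumerate(model.chains):
        for li, res in enumerate(chain.residues, start=1):
            comp = res.aa_type if res.is_standard else "UNK"
            ins = res.insertion_code or "?"
            for a in res.atoms:
                serial += 1
                alt = a.alt_loc or "."
                x, y, z = (repr(float(v)) for v in a.coords)
                lines.append(
                    f"ATOM {serial} {a.element} {a.name} {alt} {comp} "
                    f"{chain.chain_id} {ci + 1} {li} {ins} {x} {y} {z} "
                    f"{a.occupancy:g} {a.b_factor:g} {res.seq_id} {comp} "
                    f"{chain.chain_id} {a.name} 1")
    path.write_text("\n".join(lines) + "\n")


def write_structure(model: StructureModel, path, format: str = "pdb") -> None:
    """Write ``model`` as PDB (fixed 3-decimal columns) or mmCIF (lossless)."""
    path = Path(path)
    model.validate()
    if format == "pdb":
        coords = model.coords()
        if coords.min() < _PDB_COORD_MIN or coords.max() > _PDB_COORD_MAX:
            raise StructIOError(
                "coordinates exceed the fixed-width PDB fields "
                f"([{_PDB_COORD_MIN}, {_PDB_COORD_MAX}] A); write mmCIF instead")
        st = _to_gemmi(model)
        st.write_pdb(str(path))
    elif format == "mmcif":
        _write_mmcif(model, path)
    else:
        raise StructIOError(f"unknown format {format!r}; use pdb or mmcif")


# ---------------------------------------------------------------------------
# disulfides and role partition

def find_disulfides(chain: Chain) -> list[tuple[ResidueRec, ResidueRec, float]]:
    """Intrachain CYS SG-SG pairs within the disulfide cutoff, sorted by
    sequence position."""
    cys = [r for r in chain.residues if r.aa_type == "CYS" and r.atom("SG")]
    out = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(
                cys[i].atom("SG").coords - cys[j].atom("SG").coords))
            if d <= DISULFIDE_CUTOFF:
                out.append((cys[i], cys[j], d))
    out.sort(key=lambda t: (t[0].seq_id, t[1].seq_id))
    return out


def variable_domain_disulfide(chain: Chain):
    """The lowest-numbered intrachain disulfide (variable-domain by
    convention: the V domain precedes the C domain in sequence)."""
    pairs = find_disulfides(chain)
    if not pairs:
        raise PartitionError(
            f"chain {chain.chain_id}: no intrachain disulfide "
            f"(CYS SG pair within {DISULFIDE_CUTOFF} A) - not a TCR chain?")
    return pairs[0]


@dataclass(frozen=True)
class ComplexPartition:
    """Chain ids per biological role for one TCR-pMHC copy."""
    tcr_alpha: tuple[str, ...]
    tcr_beta: tuple[str, ...]
    mhc_heavy: tuple[str, ...]
    b2m: tuple[str, ...]
    peptide: tuple[str, ...]
    copy_label: str = "copy1"

    def role_chains(self) -> dict[str, tuple[str, ...]]:
        return {role: getattr(self, role) for role in ROLES}

    def all_chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for role in ROLES:
            out.extend(getattr(self, role))
        return tuple(out)

    def tcr_chains(self) -> tuple[str, ...]:
        return self.tcr_alpha + self.tcr_beta

    def pmhc_chains(self) -> tuple[str, ...]:
        return self.mhc_heavy + self.b2m + self.peptide

    def validate(self, model: StructureModel) -> None:
        seen: set[str] = set()
        for role in ROLES:
            ids = getattr(self, role)
            if not ids:
                raise PartitionError(f"role {role} has no chains")
            for cid in ids:
                if cid in seen:
                    raise PartitionError(
                        f"chain {cid} assigned to more than one role")
                seen.add(cid)
                model.chain(cid)  # raises KeyError if absent
        pep_len = sum(len(model.chain(c)) for c in self.peptide)
        if not 8 <= pep_len <= 11:
            raise PartitionError(
                f"peptide role has {pep_len} residues; expected 8-11")
        for role in ("tcr_alpha", "tcr_beta"):
            for cid in getattr(self, role):
                variable_domain_disulfide(model.chain(cid))


def _min_chain_distance(a: Chain, b: Chain) -> float:
    ca = np.concatenate([r.coords() for r in a.residues])
    cb = np.concatenate([r.coords() for r in b.residues])
    from scipy.spatial import cKDTree
    d, _ = cKDTree(cb).query(ca, k=1)
    return float(d.min())


def _contact_count(a: Chain, b: Chain, cutoff: float = 4.5) -> int:
    ca = np.concatenate([r.coords() for r in a.residues])
    cb = np.concatenate([r.coords() for r in b.residues])
    from scipy.spatial import cKDTree
    return int(cKDTree(ca).count_neighbors(cKDTree(cb), cutoff))


def _auto_partition(model: StructureModel) -> list[ComplexPartition]:
    chains = {c.chain_id: c for c in model.chains}
    peptides = [c for c in model.chains
                if 8 <= len(c) <= 11 and all(r.is_standard for r in c.residues)]
    if not peptides:
        raise PartitionError(
            "peptide role unresolved: no chain of 8-11 standard residues")
    others = [c for c in model.chains if c not in peptides]
    if len(others) < 4 * len(peptides):
        raise PartitionError(
            f"found {len(peptides)} peptide(s) but only {len(others)} other "
            "chains; need 4 per copy (MHC heavy, b2m, TCR alpha, TCR beta)")

    # MHC heavy chain = most atomic contacts with the peptide
    copies: list[dict[str, str]] = []
    taken: set[str] = set()
    for pep in sorted(peptides, key=lambda c: c.chain_id):
        counts = sorted(
            ((_contact_count(pep, c), c.chain_id) for c in others
             if c.chain_id not in taken),
            key=lambda t: (-t[0], t[1]))
        if counts[0][0] == 0:
            raise PartitionError(
                f"no chain contacts peptide chain {pep.chain_id}; "
                "MHC heavy role unresolved")
        if len(counts) > 1 and counts[0][0] == counts[1][0]:
            raise PartitionError(
                "ambiguous MHC heavy assignment for peptide "
                f"{pep.chain_id}: candidates {counts[0][1]}, {counts[1][1]}")
        mhc_id = counts[0][1]
        taken.add(mhc_id)
        copies.append({"peptide": pep.chain_id, "mhc_heavy": mhc_id})

    # distribute remaining chains to the nearest copy
    remaining = [c for c in others if c.chain_id not in taken]
    members: dict[int, list[Chain]] = {i: [] for i in range(len(copies))}
    for c in sorted(remaining, key=lambda c: c.chain_id):
        dists = [
            _min_chain_distance(c, chains[copies[i]["mhc_heavy"]])
            for i in range(len(copies))
        ]
        members[int(np.argmin(dists))].append(c)

    partitions = []
    for i, copy in enumerate(copies):
        group = members[i]
        if len(group) != 3:
            raise PartitionError(
                f"copy with peptide {copy['peptide']}: expected 3 chains for "
                f"b2m/TCR roles, found {[c.chain_id for c in group]}")
        pep = chains[copy["peptide"]]
        # the two TCR chains sit on the peptide face; b2m is the chain
        # farthest from the peptide under the platform
        by_dist = sorted(group, key=lambda c: (_min_chain_distance(c, pep),
                                               c.chain_id))
        near_pep, b2m = by_dist[:2], by_dist[2]
        for c in near_pep:
            variable_domain_disulfide(c)  # both TCR chains must have one

        # alpha chain: V-domain disulfide centroid nearer the peptide N-term
        nterm = pep.residues[0].atom("CA").coords

        def _ss_centroid(c: Chain) -> np.ndarray:
            r1, r2, _ = variable_domain_disulfide(c)
            return 0.5 * (r1.atom("SG").coords + r2.atom("SG").coords)

        near_pep.sort(key=lambda c: (
            float(np.linalg.norm(_ss_centroid(c) - nterm)), c.chain_id))
        alpha, beta = near_pep
        partitions.append(ComplexPartition(
            tcr_alpha=(alpha.chain_id,), tcr_beta=(beta.chain_id,),
            mhc_heavy=(copy["mhc_heavy"],), b2m=(b2m.chain_id,),
            peptide=(copy["peptide"],), copy_label=f"copy{i + 1}"))
    partitions.sort(key=lambda p: p.peptide)
    return partitions


def partition_complex(model: StructureModel,
                      chain_map: dict[str, str] | str = "auto",
                      ) -> list[ComplexPartition]:
    """Assign chains to the five TCR-pMHC roles.

    ``chain_map`` maps chain id -> role name (aliases: mhc, alpha, beta, pep)
    or is the string ``"auto"`` for heuristic assignment; one partition is
    returned per complete copy found.
    """
    if chain_map == "auto":
        parts = _auto_partition(model)
    else:
        roles: dict[str, list[str]] = {r: [] for r in ROLES}
        for cid, role in chain_map.items():
            role = _ROLE_ALIASES.get(role, role)
            if role not in ROLES:
                raise PartitionError(
                    f"unknown role {role!r}; expected one of {ROLES}")
            roles[role].append(cid)
        for role, ids in roles.items():
            if not ids:
                raise PartitionError(f"role {role} missing from chain_map")
        parts = [ComplexPartition(
            **{r: tuple(sorted(ids)) for r, ids in roles.items()})]
    for p in parts:
        p.validate(model)
    return parts
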