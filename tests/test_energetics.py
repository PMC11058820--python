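"""Pairwise pose score: closed forms, brute-force oracle, binding score."""

import numpy as np
import pytest

from tcrm.constants import HBOND_ACCEPTORS, HBOND_DONORS
from tcrm.energetics import (COULOMB_CONSTANT, EnergeticsError,
                             EnergyBreakdown, EnergyModel, FlatPose,
                             binding_score, score_pose)
from tcrm.geometry import rotation_about_axis
from tcrm.structio import Atom, Chain, ResidueRec, StructureModel


def _atom_model(entries):
    """One single-atom HETERO residue per entry (name, element, xyz)."""
    chain = Chain("Z")
    for k, (name, el, xyz) in enumerate(entries, start=1):
        atom = Atom(serial=k, name=name, element=el, residue_index=k,
                    alt_loc="", coords=np.asarray(xyz, float))
        chain.residues.append(ResidueRec("Z", k, "", "HETERO", [atom]))
    return StructureModel([chain])


class TestClosedForms:
    def test_neutral_pair_at_rmin_gives_minus_epsilon(self, em):
        rmin = 2 * em.lj_params["C"][0]
        eps = em.lj_params["C"][1]
        model = _atom_model([("X1", "C", [0, 0, 0]),
                             ("X2", "C", [rmin, 0, 0])])
        e = score_pose(model, em)
        assert np.isclose(e.lj_attr, -eps, atol=1e-12)
        assert e.lj_rep == 0.0
        assert e.coulomb == 0.0

    def test_pair_beyond_cutoff_scores_zero(self, em):
        model = _atom_model([("X1", "C", [0, 0, 0]),
                             ("X2", "C", [em.cutoff + 0.5, 0, 0])])
        e = score_pose(model, em)
        assert all(getattr(e, k) == 0.0 for k in EnergyBreakdown.TERMS)

    def test_total_is_weighted_sum_of_terms(self, toy_model, em):
        e = score_pose(toy_model, em)
        expect = sum(em.weights[k] * getattr(e, k)
                     for k in EnergyBreakdown.TERMS)
        assert np.isclose(e.total, expect, atol=1e-9)

    def test_untyped_element_is_reported(self, em):
        model = _atom_model([("Q1", "Zn", [0, 0, 0]),
                             ("X2", "C", [3, 0, 0])])
        with pytest.raises(EnergeticsError, match="Q1"):
            score_pose(model, em)


def _naive_oracle(model, em):
    """Independent O(n^2) double-loop implementation of the documented
    functional forms (no trees, no vectorization)."""
    atoms = []
    for ci, chain in enumerate(model.chains):
        for res in chain.residues:
            has_oxt = res.atom("OXT") is not None
            for a in res.atoms:
                el = a.element.upper()
                q = em.charges.get((res.aa_type, a.name),
                                   em.charges.get(("*", a.name), 0.0))
                if a.name == "OXT" and not has_oxt:
                    q = 0.0
                donor = (a.name in HBOND_DONORS.get("*", ())
                         and res.aa_type != "PRO") or \
                    a.name in HBOND_DONORS.get(res.aa_type, ())
                acc = a.name in HBOND_ACCEPTORS.get("*", ()) or \
                    a.name in HBOND_ACCEPTORS.get(res.aa_type, ())
                atoms.append(dict(
                    xyz=a.coords, el=el, q=q, donor=donor, acc=acc,
                    res=(ci, res.seq_id, res.insertion_code), name=a.name,
                    ci=ci, seq=res.seq_id))
    link = {("C", "N"), ("C", "CA"), ("CA", "N"), ("O", "N")}
    sums = dict.fromkeys(EnergyBreakdown.TERMS, 0.0)
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ai, aj = atoms[i], atoms[j]
            if ai["res"] == aj["res"]:
                continue
            if ai["ci"] == aj["ci"]:
                if (aj["seq"] - ai["seq"] == 1
                        and (ai["name"], aj["name"]) in link):
                    continue
                if (ai["seq"] - aj["seq"] == 1
                        and (aj["name"], ai["name"]) in link):
                    continue
            r = float(np.linalg.norm(ai["xyz"] - aj["xyz"]))
            if r >= em.cutoff:
                continue
            t = max(0.0, min(1.0, (r - em.switch_on)
                             / (em.cutoff - em.switch_on)))
            sw = 1.0 - t * t * (3 - 2 * t)
            ri, ei = em.lj_params[ai["el"]]
            rj, ej = em.lj_params[aj["el"]]
            rmin, eps = ri + rj, np.sqrt(ei * ej)
            x = rmin / r
            lj = eps * (x ** 12 - 2 * x ** 6)
            if r >= rmin:
                attr, rep = lj, 0.0
            else:
                attr = -eps
                knee = em.rep_knee * rmin
                if r >= knee:
                    rep = lj + eps
                else:
                    xk = 1 / em.rep_knee
                    f0 = eps * (xk ** 12 - 2 * xk ** 6) + eps
                    slope = eps * 12 * (-xk ** 12 + xk ** 6) / knee
                    rep = f0 + slope * (r - knee)
            sums["lj_attr"] += attr * sw
            sums["lj_rep"] += rep * sw
            sums["coulomb"] += (COULOMB_CONSTANT * ai["q"] * aj["q"]
                                / (em.eps0 * r * r)) * sw

            def lk(p, q_):
                dg, lam, _ = em.solvation_params[p["el"]]
                vol = em.solvation_params[q_["el"]][2]
                rh = em.lj_params[p["el"]][0]
                xs = (r - rh) / lam
                return -(dg / (2 * np.pi ** 1.5 * lam * r * r)
                         * np.exp(-xs * xs)) * vol

            sums["solvation"] += (lk(ai, aj) + lk(aj, ai)) * sw
            if (ai["donor"] and aj["acc"]) or (aj["donor"] and ai["acc"]):
                th = max(0.0, min(1.0, (r - em.hbond_full)
                                  / (em.hbond_zero - em.hbond_full)))
                sums["hbond"] += -em.hbond_strength \
                    * (1 - th * th * (3 - 2 * th)) * sw
    return sums


def test_matches_naive_double_loop_oracle(toy_model, em):
    """Vectorized score equals a brute-force reimplementation on the
    peptide chain (no disulfides there, every term exercised)."""
    from tcrm.structio import extract_chains
    pep = extract_chains(toy_model, ["C"])
    mine = score_pose(pep, em)
    oracle = _naive_oracle(pep, em)
    for k in EnergyBreakdown.TERMS:
        assert abs(getattr(mine, k) - oracle[k]) < 1e-9, k


def test_energy_is_continuous_across_breakpoints(em):
    """Scan a two-atom separation through rmin, the extrapolation knee and
    the switching window; adjacent samples must not jump."""
    rmin = 2 * em.lj_params["C"][0]
    rs = np.concatenate([
        np.linspace(0.5, em.cutoff + 0.2, 2000),
        em.rep_knee * rmin + np.array([-1e-9, 0.0, 1e-9]),
        rmin + np.array([-1e-9, 0.0, 1e-9]),
        em.switch_on + np.array([-1e-9, 0.0, 1e-9]),
        em.cutoff + np.array([-1e-9, 0.0, 1e-9]),
    ])
    rs = np.sort(rs)
    totals = []
    for r in rs:
        model = _atom_model([("X1", "C", [0, 0, 0]),
                             ("X2", "C", [r, 0, 0])])
        totals.append(score_pose(model, em).total)
    totals = np.array(totals)
    gaps = np.abs(np.diff(totals))
    dr = np.diff(rs)
    tight = dr < 1e-8
    assert gaps[tight].max() < 1e-6


def test_rigid_motion_invariance(toy_model, em):
    e0 = score_pose(toy_model, em)
    R = rotation_about_axis((1.0, -1.0, 2.0), 29.0)
    moved = toy_model.transformed(R, np.array([4.0, 5.0, 6.0]))
    e1 = score_pose(moved, em)
    for k in EnergyBreakdown.TERMS:
        assert abs(getattr(e0, k) - getattr(e1, k)) < 1e-6, k


class TestBindingScore:
    def test_separated_partners_score_zero_binding(self, toy_model,
                                                   toy_partition, em):
        far = toy_model.copy()
        for cid in toy_partition.tcr_chains():
            for res in far.chain(cid).residues:
                for a in res.atoms:
                    a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        bs = binding_score(far, toy_partition, em)
        assert abs(bs.binding.total) < 1e-9

    def test_componentwise_subtraction_identity(self, toy_model,
                                                toy_partition, em):
        bs = binding_score(toy_model, toy_partition, em)
        for k in (*EnergyBreakdown.TERMS, "total"):
            assert np.isclose(
                getattr(bs.binding, k),
                getattr(bs.complex, k) - getattr(bs.tcr_alone, k)
                - getattr(bs.pmhc_alone, k), atol=1e-9)

    def test_binding_equals_cross_partner_pair_sum(self, toy_model,
                                                   toy_partition, em):
        bs = binding_score(toy_model, toy_partition, em)
        pose = FlatPose(toy_model, em)
        i, j = pose.all_pairs()
        tcr_idx = {toy_model.chain_ids().index(c)
                   for c in toy_partition.tcr_chains()}
        side_i = np.isin(pose.chain_idx[i], list(tcr_idx))
        side_j = np.isin(pose.chain_idx[j], list(tcr_idx))
        cross = side_i != side_j
        terms = pose.pair_terms(i[cross], j[cross])
        total = sum(em.weights[k] * terms[k] for k in EnergyBreakdown.TERMS)
        assert abs(bs.binding.total - total) < 1e-9

    def test_planted_lys_asp_pair_gives_favorable_coulomb(self, em):
        from tcrm.structio import partition_complex
        from tcrm.synthetic import (SyntheticComplexSpec, TOY_CHAIN_MAP,
                                    build_toy_complex)
        model, truth = build_toy_complex(SyntheticComplexSpec(seed=4),
                                         plant_saltbridge=True, em=em)
        assert truth["planted_saltbridge"] is not None
        part = partition_complex(model, TOY_CHAIN_MAP)[0]
        bs = binding_score(model, part, em)
        assert bs.binding.coulomb < 0
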