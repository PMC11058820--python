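"""SASA, buried surface area, contacts and design-position selection."""

import numpy as np
import pytest

from tcrm.geometry import rotation_about_axis
from tcrm.interface import (ContactCriteria, buried_surface_area,
                            contacts_between, find_contacts, shrake_rupley,
                            select_design_positions)
from tcrm.structio import Atom, Chain, ResidueRec, StructureModel


def _cluster(coords, radii, chain_id="Z"):
    """HETERO single-atom residues at given coordinates (test scaffold)."""
    chain = Chain(chain_id)
    for k, (xyz, r) in enumerate(zip(coords, radii), start=1):
        atom = Atom(serial=k, name=f"X{k}", element="C", residue_index=k,
                    alt_loc="", coords=np.asarray(xyz, float), radius=r)
        chain.residues.append(
            ResidueRec(chain_id, k, "", "HETERO", [atom]))
    return StructureModel([chain])


def _mc_sasa_oracle(coords, radii, probe, n=40000, seed=0):
    """Independent Monte-Carlo surface estimate (random sphere points)."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + expanded[i] * v
        free = np.ones(n, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) > expanded[j] ** 2
        total += free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total


class TestShrakeRupley:
    def test_single_sphere_matches_analytic_area(self):
        model = _cluster([[0.0, 0, 0]], [1.7])
        res = shrake_rupley(model, probe_radius=1.4)
        assert np.isclose(res.total, 4 * np.pi * 3.1 ** 2, atol=1e-9)

    def test_distant_atoms_keep_isolated_area(self):
        model = _cluster([[0.0, 0, 0], [50.0, 0, 0]], [1.7, 1.7])
        res = shrake_rupley(model, probe_radius=1.4)
        iso = 4 * np.pi * 3.1 ** 2
        assert all(np.isclose(a, iso, atol=1e-9)
                   for a in res.per_atom.values())

    def test_total_equals_sum_of_per_atom(self, toy_model):
        from tcrm.structio import extract_chains
        res = shrake_rupley(extract_chains(toy_model, ["C"]))
        assert np.isclose(res.total, sum(res.per_atom.values()), atol=1e-6)
        assert all(v >= 0 for v in res.per_atom.values())

    def test_matches_monte_carlo_oracle_within_2_percent(self, rng):
        coords = rng.normal(size=(10, 3)) * 2.0
        radii = rng.uniform(1.4, 1.9, size=10)
        model = _cluster(coords, radii)
        mine = shrake_rupley(model, probe_radius=1.4, n_points=960).total
        oracle = _mc_sasa_oracle(coords, radii, probe=1.4)
        assert abs(mine - oracle) / oracle < 0.02

    def test_burial_monotonicity(self, rng):
        coords = rng.normal(size=(8, 3)) * 1.5
        radii = [1.7] * 8
        before = shrake_rupley(_cluster(coords, radii)).per_atom
        grown = np.vstack([coords, [[0.5, 0.5, 0.5]]])
        after = shrake_rupley(_cluster(grown, radii + [1.7])).per_atom
        for key, area in before.items():
            assert after[key] <= area + 1e-9

    def test_lattice_convergence_under_point_doubling(self, toy_model):
        from tcrm.structio import extract_chains
        pep = extract_chains(toy_model, ["C"])
        a = shrake_rupley(pep, n_points=960).total
        b = shrake_rupley(pep, n_points=1920).total
        assert abs(a - b) / b < 0.01

    def test_too_few_points_rejected(self, toy_model):
        with pytest.raises(ValueError, match="92"):
            shrake_rupley(toy_model, n_points=50)


class TestBuriedSurface:
    def test_separated_partners_bury_nothing(self, toy_model,
                                             toy_partition):
        far = toy_model.copy()
        for cid in toy_partition.tcr_chains():
            for res in far.chain(cid).residues:
                for a in res.atoms:
                    a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        area = buried_surface_area(far, toy_partition, n_points=240)
        assert abs(area.bsa_total) < 1e-6
        assert abs(area.peptide_burial) > 1.0  # groove burial remains

    def test_interface_area_is_positive_and_split_consistently(
            self, toy_model, toy_partition):
        area = buried_surface_area(toy_model, toy_partition, n_points=240)
        assert area.bsa_total > 0
        split_sum = sum(area.bsa_by_side.values())
        assert np.isclose(split_sum, area.bsa_total, rtol=1e-6)
        assert area.peptide_burial > 100  # peptide sits in the groove

    def test_rigid_motion_invariance_within_lattice_resolution(
            self, toy_model, toy_partition):
        # the sphere lattice is fixed in space, so rotation changes the
        # sampling; agreement tightens with the point count
        a0 = buried_surface_area(toy_model, toy_partition, n_points=960)
        R = rotation_about_axis((0.3, 1.0, 0.2), 41.0)
        moved = toy_model.transformed(R, np.array([3.0, -8.0, 2.0]))
        a1 = buried_surface_area(moved, toy_partition, n_points=960)
        assert abs(a0.bsa_total - a1.bsa_total) / a0.bsa_total < 0.02
        # pure translation leaves every neighbor geometry identical
        shifted = toy_model.transformed(np.eye(3),
                                        np.array([5.0, 6.0, 7.0]))
        a2 = buried_surface_area(shifted, toy_partition, n_points=240)
        a3 = buried_surface_area(toy_model, toy_partition, n_points=240)
        assert abs(a2.bsa_total - a3.bsa_total) < 1e-9


def _residue_with(chain, seq, aa, atoms):
    res = ResidueRec(chain, seq, "", aa)
    for k, (name, el, xyz) in enumerate(atoms, start=1):
        res.atoms.append(Atom(serial=k, name=name, element=el,
                              residue_index=seq, alt_loc="",
                              coords=np.asarray(xyz, float)))
    return res


class TestContacts:
    def _two_chain_model(self, separation):
        lys = _residue_with("A", 1, "LYS", [
            ("N", "N", [0, 0, 0]), ("CA", "C", [1.46, 0, 0]),
            ("C", "C", [2.0, 1.4, 0]), ("O", "O", [1.5, 2.4, 0]),
            ("CE", "C", [2.4, -1.2, 1.0]),
            ("NZ", "N", [3.0, -1.5, 2.0]),
        ])
        od1 = np.array([3.0, -1.5, 2.0 + separation])
        asp = _residue_with("B", 1, "ASP", [
            ("N", "N", od1 + [2.0, 2.0, 1.0]),
            ("CA", "C", od1 + [1.5, 1.5, 1.8]),
            ("C", "C", od1 + [2.5, 1.0, 2.5]),
            ("O", "O", od1 + [3.5, 1.2, 2.5]),
            ("CG", "C", od1 + [0.8, 0.4, 0.8]),
            ("OD1", "O", od1),
        ])
        return StructureModel([Chain("A", [lys]), Chain("B", [asp])])

    def test_far_apart_residues_have_no_contacts(self):
        model = self._two_chain_model(separation=20.0)
        out = contacts_between(model, ["A"], ["B"])
        assert out.contacts == []

    def test_constructed_salt_bridge_detected_with_vdw(self):
        model = self._two_chain_model(separation=3.0)
        out = contacts_between(model, ["A"], ["B"])
        kinds = {c.kind for c in out.contacts}
        assert "saltbridge" in kinds and "vdw" in kinds
        sb = out.of_kind("saltbridge")[0]
        assert {sb.atom_a, sb.atom_b} == {"NZ", "OD1"}
        assert np.isclose(sb.distance, 3.0, atol=1e-9)

    def test_distances_recompute_from_coordinates(self, toy_model,
                                                  toy_partition):
        out = find_contacts(toy_model, toy_partition)
        assert out.contacts, "toy interface should produce contacts"
        for c in out.contacts:
            pa = toy_model.residue(*c.residue_a).atom(c.atom_a).coords
            pb = toy_model.residue(*c.residue_b).atom(c.atom_b).coords
            assert abs(np.linalg.norm(pa - pb) - c.distance) < 1e-6

    def test_contact_list_is_sorted_and_deduplicated(self, toy_model,
                                                     toy_partition):
        out = find_contacts(toy_model, toy_partition)
        keys = [(c.kind, c.residue_a, c.residue_b, c.atom_a, c.atom_b)
                for c in out.contacts]
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))

    def test_bad_criteria_rejected(self):
        with pytest.raises(ValueError):
            ContactCriteria(vdw_cutoff=-1.0)


class TestDesignPositions:
    def test_tiny_cutoff_selects_nothing(self, toy_model, toy_partition):
        assert select_design_positions(toy_model, toy_partition,
                                       cutoff=0.1) == []

    def test_zero_cutoff_rejected(self, toy_model, toy_partition):
        with pytest.raises(ValueError):
            select_design_positions(toy_model, toy_partition, cutoff=0.0)

    def test_matches_generator_ground_truth(self, toy_model, toy_partition,
                                            toy_truth):
        pos = select_design_positions(toy_model, toy_partition, cutoff=8.0)
        got = [(p.chain_id, p.seq_id) for p in pos]
        assert got == [tuple(t) for t in toy_truth["design_positions_8A"]]

    def test_restriction_intersects(self, toy_model, toy_partition,
                                    toy_truth):
        keep = tuple(toy_truth["design_positions_8A"][0])
        pos = select_design_positions(toy_model, toy_partition,
                                      restrict_to=[keep])
        assert [(p.chain_id, p.seq_id) for p in pos] == [keep]

    def test_pmhc_reference_is_superset_of_peptide(self, toy_model,
                                                   toy_partition):
        pep = select_design_positions(toy_model, toy_partition,
                                      reference="peptide")
        pmhc = select_design_positions(toy_model, toy_partition,
                                       reference="pmhc")
        assert {p.key for p in pep} <= {p.key for p in pmhc}

    def test_candidate_count_is_positions_times_19(self, toy_model,
                                                   toy_partition):
        from tcrm.design import enumerate_substitutions
        pos = select_design_positions(toy_model, toy_partition)
        cands = enumerate_substitutions(pos)
        assert len(cands) == len(pos) * 19
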