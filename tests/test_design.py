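"""Point-mutation scanning, combination, and CCD loop refinement."""

import numpy as np
import pytest

from tcrm.build import build_backbone
from tcrm.design import (DesignConfig, MutationCandidate, ccd_close,
                         combine_mutations, enumerate_substitutions,
                         place_mutation, refine_cdr_loops, scan_mutations)
from tcrm.energetics import score_pose
from tcrm.interface import DesignPosition, select_design_positions
from tcrm.sidechain import RotamerLibrary


def _positions(n, aa="ALA"):
    return [DesignPosition(chain_id="D", seq_id=k + 1, insertion_code="",
                           aa_type=aa, role="tcr_alpha")
            for k in range(n)]


class TestEnumeration:
    def test_52_positions_yield_988_candidates(self):
        assert len(enumerate_substitutions(_positions(52))) == 988

    def test_single_position_yields_19(self):
        cands = enumerate_substitutions(_positions(1))
        assert len(cands) == 19
        assert all(c.mut_aa != "CYS" for c in cands)
        assert any(c.is_self for c in cands)  # wild type included

    def test_extra_exclusions_shrink_the_set(self):
        cands = enumerate_substitutions(_positions(1),
                                        exclude=("CYS", "GLY", "PRO"))
        assert len(cands) == 17

    def test_cysteine_candidates_are_rejected(self):
        with pytest.raises(ValueError, match="cysteine"):
            MutationCandidate(position=_positions(1)[0], wt_aa="ALA",
                              mut_aa="CYS")

    def test_labels_use_greek_chain_letter(self):
        pos = DesignPosition("E", 51, "", "LYS", "tcr_beta")
        cand = MutationCandidate(position=pos, wt_aa="LYS", mut_aa="MET")
        assert cand.label == "βK51M"


class TestPlacement:
    def _first_position(self, toy_model, toy_partition):
        pos = select_design_positions(toy_model, toy_partition)
        return next(p for p in pos if p.aa_type not in ("GLY", "CYS"))

    def test_glycine_removes_side_chain_and_keeps_backbone(
            self, toy_model, toy_partition, rotlib, em):
        pos = self._first_position(toy_model, toy_partition)
        cand = MutationCandidate(position=pos, wt_aa=pos.aa_type,
                                 mut_aa="GLY")
        placed = place_mutation(toy_model, cand, rotlib, em)
        res = placed.model.residue(*pos.key)
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}
        old = toy_model.residue(*pos.key)
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(res.atom(name).coords,
                                  old.atom(name).coords)

    def test_all_other_residues_bit_identical(self, toy_model,
                                              toy_partition, rotlib, em):
        pos = self._first_position(toy_model, toy_partition)
        cand = MutationCandidate(position=pos, wt_aa=pos.aa_type,
                                 mut_aa="TRP")
        placed = place_mutation(toy_model, cand, rotlib, em)
        for c0, c1 in zip(toy_model.chains, placed.model.chains):
            for r0, r1 in zip(c0.residues, c1.residues):
                if r0.key == pos.key:
                    continue
                assert np.array_equal(r0.coords(), r1.coords())

    def test_self_substitution_is_optimal(self, toy_model, toy_partition,
                                          rotlib, em):
        pos = self._first_position(toy_model, toy_partition)
        cand = MutationCandidate(position=pos, wt_aa=pos.aa_type,
                                 mut_aa=pos.aa_type)
        placed = place_mutation(toy_model, cand, rotlib, em)
        wt_energy = score_pose(toy_model, em).total
        assert placed.pose_energy.total <= wt_energy + 1e-6

    def test_missing_backbone_is_an_error(self, toy_model, rotlib, em):
        broken = toy_model.copy()
        res = broken.residue("D", 3)
        res.atoms = [a for a in res.atoms if a.name != "O"]
        pos = DesignPosition("D", 3, "", res.aa_type, "tcr_alpha")
        cand = MutationCandidate(position=pos, wt_aa=res.aa_type,
                                 mut_aa="ALA")
        with pytest.raises(ValueError, match="backbone"):
            place_mutation(broken, cand, rotlib, em)

    def test_truncating_planted_arg_to_ala_reduces_repulsion(
            self, clash_case, rotlib, em):
        pos = clash_case.clash_position
        wt_rep = score_pose(clash_case.complex, em).lj_rep
        cand = MutationCandidate(position=pos, wt_aa="ARG", mut_aa="ALA")
        placed = place_mutation(clash_case.complex, cand, rotlib, em)
        assert placed.pose_energy.lj_rep < wt_rep


class TestScan:
    def test_row_count_matches_candidates(self, clash_case, rotlib, em):
        pos = clash_case.clash_position
        cands = enumerate_substitutions([pos])
        res = scan_mutations(clash_case.complex, clash_case.partition,
                             cands, rotlib, em)
        assert len(res.rows) == len(cands)
        assert len(res.ranking) == len(cands)

    def test_self_substitutions_are_neutral_on_relaxed_toy(
            self, toy_model, toy_partition, rotlib, em):
        pos = [p for p in select_design_positions(toy_model, toy_partition)
               if p.aa_type not in ("GLY", "CYS")]
        cands = [MutationCandidate(position=p, wt_aa=p.aa_type,
                                   mut_aa=p.aa_type) for p in pos]
        res = scan_mutations(toy_model, toy_partition, cands, rotlib, em)
        assert max(abs(r.delta_binding) for r in res.rows) <= 1e-6

    def test_planted_clash_reliever_ranks_first(self, clash_case, rotlib,
                                                em):
        pos = select_design_positions(clash_case.complex,
                                      clash_case.partition)
        cands = enumerate_substitutions(pos)
        res = scan_mutations(clash_case.complex, clash_case.partition,
                             cands, rotlib, em)
        top = res.ranking[0]
        assert top.candidate.position.key == clash_case.clash_position.key
        assert top.candidate.mut_aa == clash_case.expected_best
        assert top.delta_binding < 0

    def test_scan_is_deterministic(self, clash_case, rotlib, em):
        cands = enumerate_substitutions([clash_case.clash_position])
        cfg = DesignConfig(seed=42)
        a = scan_mutations(clash_case.complex, clash_case.partition,
                           cands, rotlib, em, cfg)
        b = scan_mutations(clash_case.complex, clash_case.partition,
                           cands, rotlib, em, cfg)
        assert a.to_tsv() == b.to_tsv()
        assert a.fingerprint == b.fingerprint


class TestCombine:
    def test_same_position_pair_rejected(self, toy_model, toy_partition,
                                         rotlib, em):
        pos = select_design_positions(toy_model, toy_partition)[0]
        c = MutationCandidate(position=pos, wt_aa=pos.aa_type,
                              mut_aa="LEU")
        with pytest.raises(ValueError, match="overlapping"):
            combine_mutations(toy_model, toy_partition, [c, c], rotlib, em)

    def test_far_apart_pair_is_additive(self, toy_model, toy_partition,
                                        rotlib, em):
        # pick two TCR residues whose CAs are > 20 A apart so the placed
        # side chains cannot interact with each other
        residues = [r for cid in ("D", "E")
                    for r in toy_model.chain(cid).residues
                    if r.aa_type not in ("GLY", "CYS")]
        ra, rb = next(
            (x, y) for x in residues for y in residues
            if np.linalg.norm(x.atom("CA").coords
                              - y.atom("CA").coords) > 20.0)
        roles = {"D": "tcr_alpha", "E": "tcr_beta"}
        pa = DesignPosition(ra.chain_id, ra.seq_id, "", ra.aa_type,
                            roles[ra.chain_id])
        pb = DesignPosition(rb.chain_id, rb.seq_id, "", rb.aa_type,
                            roles[rb.chain_id])
        ca = MutationCandidate(position=pa, wt_aa=pa.aa_type, mut_aa="LEU")
        cb = MutationCandidate(position=pb, wt_aa=pb.aa_type, mut_aa="PHE")
        singles = scan_mutations(toy_model, toy_partition, [ca, cb],
                                 rotlib, em)
        pair = combine_mutations(toy_model, toy_partition, [ca, cb],
                                 rotlib, em)
        d1, d2 = (r.delta_binding for r in singles.rows)
        assert np.isclose(pair.rows[0].delta_binding, d1 + d2, atol=1e-6)

    def test_two_planted_clashes_combine_synergistically(self, rotlib, em):
        from tcrm.synthetic import plant_clash_case
        case = plant_clash_case(seed=9, n_clashes=2, em=em)
        clashes = case.ground_truth["clashes"]
        singles = []
        for rec in clashes:
            pos = DesignPosition(chain_id=rec["chain_id"],
                                 seq_id=rec["seq_id"], insertion_code="",
                                 aa_type="ARG", role=rec["role"])
            singles.append(MutationCandidate(position=pos, wt_aa="ARG",
                                             mut_aa="GLY"))
        one = scan_mutations(case.complex, case.partition, singles,
                             rotlib, em)
        pair = combine_mutations(case.complex, case.partition, singles,
                                 rotlib, em)
        deltas = [r.delta_binding for r in one.rows]
        assert all(d < 0 for d in deltas)
        assert pair.rows[0].delta_binding < min(deltas)


class TestLoopRefinement:
    def test_zero_cycles_returns_identical_model(self, toy_model):
        cfg = DesignConfig(loop_n_cycles=0)
        out = refine_cdr_loops(toy_model, [("D", 4, 8)], cfg)
        assert np.array_equal(out.model.coords(), toy_model.coords())

    def test_ccd_restores_closure_after_anchor_displacement(self):
        bb = build_backbone([-57.0] * 10, [-47.0] * 10)
        loop = [dict((k, bb[i][k].copy()) for k in ("N", "CA", "C"))
                for i in range(3, 8)]
        target = {k: bb[8][k] + np.array([0.0, 0.0, 2.0])
                  for k in ("N", "CA", "C")}
        closed, closure = ccd_close(loop, bb[2], target)
        assert closure < 0.1

    def test_best_energy_is_non_increasing_and_loops_only_move(
            self, toy_model):
        cfg = DesignConfig(loop_n_cycles=15, seed=5)
        out = refine_cdr_loops(toy_model, [("D", 4, 8)], cfg)
        best = [t["best_energy"] for t in out.trajectory]
        assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(best, best[1:]))
        loop_keys = {("D", s) for s in range(4, 9)}
        for c0, c1 in zip(toy_model.chains, out.model.chains):
            for r0, r1 in zip(c0.residues, c1.residues):
                if (r0.chain_id, r0.seq_id) in loop_keys:
                    continue
                assert np.array_equal(r0.coords(), r1.coords())

    def test_refinement_is_seed_reproducible(self, toy_model):
        cfg = DesignConfig(loop_n_cycles=8, seed=11)
        a = refine_cdr_loops(toy_model, [("D", 4, 8)], cfg)
        b = refine_cdr_loops(toy_model, [("D", 4, 8)], cfg)
        assert np.array_equal(a.model.coords(), b.model.coords())

    def test_loop_without_anchor_rejected(self, toy_model):
        with pytest.raises(ValueError, match="anchor"):
            refine_cdr_loops(toy_model, [("D", 1, 5)],
                             DesignConfig(loop_n_cycles=1))
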