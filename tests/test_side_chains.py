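"""Clash rule, rotamer placement, retention policy and staged relaxation."""

import numpy as np
import pytest

import fvforge as fx
from fvforge import synthetic as syn
from fvforge.chem import CHI_ATOMS, RESIDUE_ATOMS, n_chi
from fvforge.fv_model import AtomRecord, FvStructure, NumberedResidue
from fvforge.geometry import residue_chi
from fvforge.side_chains import (SideChainError, _rebuild_residue, clash_pairs,
                                 detect_clashes, resolve_clashes)


def _free_atom_structure(coords, elements):
    """Atoms with no covalent bonds between them (one per 'residue')."""
    residues = [NumberedResidue("H", (i + 1, ""), "G",
                                [AtomRecord("CA", el, c)], "FW")
                for i, (c, el) in enumerate(zip(coords, elements))]
    return FvStructure(heavy=residues, name="cloud")


class TestClashRule:
    def test_carbon_pair_threshold_is_2_21(self, vdw_table):
        factor = 0.65
        assert factor * 2 * vdw_table["C"] == pytest.approx(2.21)
        clashing = _free_atom_structure([[0, 0, 0], [2.20, 0, 0]], ["C", "C"])
        assert len(detect_clashes(clashing, vdw_table)) == 1
        boundary = _free_atom_structure([[0, 0, 0], [2.21, 0, 0]], ["C", "C"])
        assert detect_clashes(boundary, vdw_table).clash_free

    def test_unknown_element_is_named(self, vdw_table):
        with pytest.raises(SideChainError, match="Xx"):
            detect_clashes(_free_atom_structure([[0, 0, 0]], ["Xx"]), vdw_table)

    def test_bonded_and_13_pairs_are_exempt(self, ideal_fv, vdw_table):
        # an ideal backbone is full of sub-threshold bonded distances
        report = detect_clashes(ideal_fv, vdw_table)
        assert report.clash_free

    def test_kdtree_matches_bruteforce_on_random_clouds(self, vdw_table):
        rng = np.random.default_rng(23)
        for _ in range(3):
            coords = rng.uniform(0, 12.0, size=(200, 3))
            elements = rng.choice(["C", "N", "O", "S"], 200)
            radii = np.array([vdw_table[e] for e in elements])
            fast = clash_pairs(coords, radii, 0.65)
            brute = []
            for i in range(200):
                for j in range(i + 1, 200):
                    d = np.linalg.norm(coords[i] - coords[j])
                    thr = 0.65 * (radii[i] + radii[j])
                    if d < thr:
                        brute.append((i, j))
            assert [(i, j) for i, j, _d, _t in fast] == brute

    def test_count_invariant_under_rigid_motion(self, vdw_table):
        rng = np.random.default_rng(29)
        coords = rng.uniform(0, 8.0, size=(60, 3))
        structure = _free_atom_structure(coords, ["C"] * 60)
        n0 = len(detect_clashes(structure, vdw_table))
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        moved = _free_atom_structure(coords @ rot.T + 5.0, ["C"] * 60)
        assert len(detect_clashes(moved, vdw_table)) == n0
        assert n0 > 0


class TestPartialPrediction:
    def test_identical_target_leaves_structure_unchanged(self, ideal_fv,
                                                         rotamer_library):
        out = fx.partial_side_chain_prediction(ideal_fv, None, rotamer_library)
        for ct in "HL":
            for a, b in zip(ideal_fv.domain(ct), out.domain(ct)):
                np.testing.assert_array_equal(
                    np.array([x.coord for x in a.atoms]),
                    np.array([x.coord for x in b.atoms]))

    def test_single_mutation_only_changes_that_side_chain(self, ideal_fv,
                                                          rotamer_library):
        target = {ct: {r.position: r.aa for r in ideal_fv.domain(ct)}
                  for ct in "HL"}
        pos = next(r.position for r in ideal_fv.domain("H")
                   if r.region == "FW" and r.aa == "S")
        target["H"][pos] = "F"
        out = fx.partial_side_chain_prediction(ideal_fv, target, rotamer_library)
        for r_in, r_out in zip(ideal_fv.domain("H"), out.domain("H")):
            if r_in.position == pos:
                assert r_out.aa == "F"
                assert {a.name for a in r_out.atoms} == set(RESIDUE_ATOMS["F"])
            else:
                np.testing.assert_array_equal(
                    np.array([x.coord for x in r_in.atoms]),
                    np.array([x.coord for x in r_out.atoms]))

    def test_placed_chi1_is_top_rotamer_when_unclashed(self, ideal_fv,
                                                       rotamer_library):
        target = {ct: {r.position: r.aa for r in ideal_fv.domain(ct)}
                  for ct in "HL"}
        pos = next(r.position for r in ideal_fv.domain("L") if r.aa == "A")
        target["L"][pos] = "M"
        out = fx.partial_side_chain_prediction(ideal_fv, target, rotamer_library)
        placed = out.residue_map("L")[pos]
        top_chi1 = rotamer_library("M")[0][0][0]
        assert residue_chi(placed, 1) == pytest.approx(top_chi1, abs=1e-6)

    def test_backbone_never_moves(self, family, rotamer_library):
        fv = family[0][2][0]
        target = {ct: {r.position: r.aa for r in fv.domain(ct)} for ct in fv.chains}
        # mutate a quarter of the framework
        for i, (pos, aa) in enumerate(list(target["H"].items())):
            if i % 4 == 0 and aa not in "GC":
                target["H"][pos] = "L" if aa != "L" else "V"
        out = fx.partial_side_chain_prediction(fv, target, rotamer_library)
        for ct in fv.chains:
            for a, b in zip(fv.domain(ct), out.domain(ct)):
                np.testing.assert_array_equal(a.backbone_coords(),
                                              b.backbone_coords())


class TestCompletePrediction:
    def test_gly_ala_untouched_and_atom_counts_match_chemistry(
            self, ideal_fv, rotamer_library):
        out = fx.complete_side_chain_prediction(ideal_fv, None, rotamer_library)
        for ct in "HL":
            for r_in, r_out in zip(ideal_fv.domain(ct), out.domain(ct)):
                assert [a.name for a in r_out.atoms] == \
                    list(RESIDUE_ATOMS[r_out.aa])
                if r_in.aa in "GA":
                    np.testing.assert_array_equal(
                        np.array([x.coord for x in r_in.atoms]),
                        np.array([x.coord for x in r_out.atoms]))

    def test_partial_beats_complete_on_template_equals_native(self,
                                                              rotamer_library):
        members, _ = syn.make_template_family(
            syn.FixtureSpec(n_structures=1, noise_floor=0.02, seed=41))
        native = members[0][0]
        partial = fx.partial_side_chain_prediction(native.copy(), None,
                                                   rotamer_library)
        complete = fx.complete_side_chain_prediction(native.copy(), None,
                                                     rotamer_library)
        acc_partial = fx.chi1_accuracy(partial, native)
        acc_complete = fx.chi1_accuracy(complete, native)
        assert acc_partial == pytest.approx(100.0)
        assert acc_partial >= acc_complete


class TestResolveClashes:
    def test_clash_free_input_returns_stage_none(self, ideal_fv, rotamer_library):
        out, stage = resolve_clashes(ideal_fv, rotamer_library)
        assert stage == "none"
        assert out is ideal_fv

    def test_single_resolvable_clash_resolved_locally(self, ideal_fv,
                                                      rotamer_library,
                                                      vdw_table):
        crafted = ideal_fv.copy()
        # force some long side chain into a clashing conformation
        clashing = None
        for res in (r for r in crafted.domain("H") if n_chi(r.aa) >= 2):
            for chi1 in range(-180, 180, 10):
                for chi2 in (60.0, 180.0, -60.0):
                    _rebuild_residue(res, (float(chi1), chi2, 180.0, 180.0))
                    report = detect_clashes(crafted, vdw_table)
                    if len(report):
                        clashing = res
                        break
                if clashing:
                    break
            if clashing:
                break
            _rebuild_residue(res, tuple([180.0] * 4))
        assert clashing is not None
        out, stage = resolve_clashes(crafted, rotamer_library, vdw_table)
        assert stage in ("local", "global")
        final = len(detect_clashes(out, vdw_table))
        assert final <= len(report)

    def test_final_clash_count_never_exceeds_initial(self, family,
                                                     rotamer_library, vdw_table):
        fv = family[0][-1][0]
        rebuilt = fx.complete_side_chain_prediction(fv.copy(), None,
                                                    rotamer_library)
        before = len(detect_clashes(rebuilt, vdw_table))
        out, _stage = resolve_clashes(rebuilt, rotamer_library, vdw_table)
        assert len(detect_clashes(out, vdw_table)) <= before


class TestLibraries:
    def test_rotamer_probabilities_sum_to_one(self, rotamer_library):
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            rots = rotamer_library(aa)
            if rots:
                assert sum(p for _c, p in rots) == pytest.approx(1.0, abs=1e-6)
                assert len(rots[0][0]) == len(CHI_ATOMS[aa])

    def test_vdw_radii_positive_and_carbon_17(self, vdw_table):
        assert vdw_table["C"] == 1.7
        assert all(r > 0 for r in vdw_table.radii.values())
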