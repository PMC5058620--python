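"""Fragment filtering, anchor-RMSD ranking, grafting and the fallback cascade."""

import numpy as np
import pytest

import fvforge as fx
from fvforge import synthetic as syn
from fvforge.fv_model import FvSequence
from fvforge.loop_graft import (LOOP_ORDER, AbInitioRequired, GraftError,
                                candidate_decoys, graft_loop, model_all_cdrs,
                                model_anchors, model_cdr, substitution_score)
from fvforge.template_store import FragmentStore


class TestSubstitutionScore:
    def test_poly_alanine_self_score(self):
        assert substitution_score("A" * 10, "A" * 10) == 40

    def test_asn_gly_pair(self):
        assert substitution_score("NG", "NG") == 12

    def test_matches_per_position_sum(self):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(17)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), 12))
            b = "".join(rng.choice(list(aas), 12))
            assert substitution_score(a, b) == sum(
                blosum[x, y] for x, y in zip(a, b))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(GraftError):
            substitution_score("AAA", "AA")


class TestCandidateDecoys:
    def test_self_fragment_ranks_first_with_zero_anchor_rmsd(
            self, family, fragment_stores, defs):
        fv = family[0][2][0]
        target = FvSequence.from_structure(fv)
        seq = "".join(aa for _p, aa in target.cdr_segment("H", 3, defs))
        anchors = model_anchors(fv, "H", 3, n_anchor=5)
        decoys = candidate_decoys(seq, anchors, fragment_stores["H3"],
                                  score_threshold=-10 ** 6)
        assert decoys[0].fragment.source_id == fv.name
        assert decoys[0].anchor_rmsd == pytest.approx(0.0, abs=1e-9)
        assert decoys == sorted(decoys, key=lambda d: d.anchor_rmsd)

    def test_filters_match_bruteforce_on_toy_store(self, family, fragment_stores,
                                                   defs):
        fv = family[0][0][0]
        target = FvSequence.from_structure(fv)
        seq = "".join(aa for _p, aa in target.cdr_segment("L", 1, defs))
        anchors = model_anchors(fv, "L", 1, n_anchor=5)
        toy = FragmentStore(fragment_stores["L1"].fragments[:5], "L1")
        span_tol, score_thr = 0.5, 20
        decoys = candidate_decoys(seq, anchors, toy, span_tol, score_thr)
        surviving = {d.fragment.source_id for d in decoys}
        expected = set()
        for frag in toy.fragments:
            if frag.length != len(seq):
                continue
            if abs(frag.span - anchors.span) <= span_tol and \
                    substitution_score(seq, frag.sequence) >= score_thr:
                expected.add(frag.source_id)
        assert surviving == expected

    def test_score_threshold_excludes_despite_low_anchor_rmsd(
            self, family, fragment_stores, defs):
        fv = family[0][2][0]
        target = FvSequence.from_structure(fv)
        seq = "".join(aa for _p, aa in target.cdr_segment("H", 3, defs))
        anchors = model_anchors(fv, "H", 3, n_anchor=5)
        # self-fragment has anchor RMSD 0; an impossible score floor removes it
        decoys = candidate_decoys(seq, anchors, fragment_stores["H3"],
                                  score_threshold=10 ** 6)
        assert decoys == []

    def test_empty_store_yields_empty_list(self, family, defs):
        fv = family[0][0][0]
        anchors = model_anchors(fv, "H", 1, n_anchor=5)
        assert candidate_decoys("AAAA", anchors, FragmentStore([], "H1")) == []


class TestGraft:
    def test_self_graft_reproduces_coordinates(self, family, fragment_stores, defs):
        fv = family[0][1][0]
        target = FvSequence.from_structure(fv)
        loop = target.cdr_segment("H", 3, defs)
        seq = "".join(aa for _p, aa in loop)
        anchors = model_anchors(fv, "H", 3, n_anchor=5)
        decoys = candidate_decoys(seq, anchors, fragment_stores["H3"],
                                  score_threshold=-10 ** 6)
        self_decoy = next(d for d in decoys if d.fragment.source_id == fv.name)
        grafted = graft_loop(fv, self_decoy, "H", 3, loop)
        for r_new, r_old in zip(grafted.region_residues("H", "CDR3"),
                                fv.region_residues("H", "CDR3")):
            np.testing.assert_allclose(r_new.backbone_coords(),
                                       r_old.backbone_coords(), atol=1e-6)

    def test_grafted_loop_has_target_length_and_sequence(
            self, family, fragment_stores, defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][5][0])
        out, stage, decoy = model_cdr(model, target, "H", 3, fragment_stores,
                                      defs, exclude_ids={model.name})
        loop = out.region_residues("H", "CDR3")
        expected = target.cdr_segment("H", 3, defs)
        assert [r.aa for r in loop] == [aa for _p, aa in expected]
        assert decoy.fragment.source_id != model.name

    def test_junction_ca_distances_plausible_across_family(
            self, family, fragment_stores, defs):
        members, _ = family
        model = members[0][0].copy()
        target = FvSequence.from_structure(members[7][0])
        out, _prov = model_all_cdrs(model, target, fragment_stores, defs,
                                    exclude_ids={members[7][0].name})
        for ct in "HL":
            residues = [r for r in out.domain(ct) if r.has_backbone()]
            for k in (1, 2, 3):
                idx = [i for i, r in enumerate(residues) if r.region == f"CDR{k}"]
                for i in (idx[0] - 1, idx[-1]):   # N- and C-junction steps
                    d = np.linalg.norm(residues[i].atom("CA").coord
                                       - residues[i + 1].atom("CA").coord)
                    assert 2.9 <= d <= 4.1


class TestCascade:
    def test_stage_cdr_db_when_fragment_available(self, family, fragment_stores,
                                                  defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][3][0])
        _out, stage, _decoy = model_cdr(model, target, "L", 2, fragment_stores,
                                        defs)
        assert stage == "cdr-db"

    def test_stage_fv_db_when_cdr_store_empty(self, family, fragment_stores, defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][3][0])
        staged = dict(fragment_stores)
        staged["L2"] = FragmentStore([], "L2")
        _out, stage, decoy = model_cdr(model, target, "L", 2, staged, defs)
        assert stage == "fv-db"
        assert decoy.fragment.cdr_type == "fv"

    def test_stage_seq_similar_when_filters_reject_everything(
            self, family, fragment_stores, defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][3][0])
        _out, stage, decoy = model_cdr(model, target, "L", 2, fragment_stores,
                                       defs, span_tolerance=0.0,
                                       score_threshold=10 ** 6)
        assert stage == "seq-similar"
        assert decoy.fragment.resolution <= 2.5

    def test_seq_similar_maximizes_substitution_score(self, family,
                                                      fragment_stores, defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][3][0])
        seq = "".join(aa for _p, aa in target.cdr_segment("L", 2, defs))
        _out, _stage, decoy = model_cdr(model, target, "L", 2, fragment_stores,
                                        defs, span_tolerance=0.0,
                                        score_threshold=10 ** 6)
        pool = fragment_stores["L2"].of_length(len(seq)) + \
            fragment_stores["fv"].of_length(len(seq))
        best = max(substitution_score(seq, f.sequence) for f in pool
                   if f.resolution <= 2.5)
        assert decoy.score == best

    def test_ab_initio_signal_when_no_length_match(self, family, fragment_stores,
                                                   defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][3][0])
        staged = {"L2": FragmentStore([], "L2"), "fv": FragmentStore(
            [f for f in fragment_stores["fv"].fragments if f.length != 8], "fv")}
        with pytest.raises(AbInitioRequired) as exc:
            model_cdr(model, target, "L", 2, staged, defs)
        assert exc.value.cdr == "CDRL2"
        assert exc.value.closest is not None
        assert exc.value.closest.length != 8


class TestModelingOrder:
    def test_paired_target_order(self, family, fragment_stores, defs):
        model = family[0][0][0].copy()
        target = FvSequence.from_structure(family[0][4][0])
        _out, provenance = model_all_cdrs(model, target, fragment_stores, defs)
        assert [p[0] for p in provenance] == ["L2", "H2", "L1", "H1", "L3", "H3"]

    def test_vhh_target_order(self, family, fragment_stores):
        defs = fx.CdrDefinitionTable.load("north")
        vhh_native = syn.make_idealized_fv(chains="H", seed=19)
        target = FvSequence.from_structure(vhh_native)
        _out, provenance = model_all_cdrs(vhh_native.copy(), target,
                                          fragment_stores, defs)
        assert [p[0] for p in provenance] == ["H2", "H1", "H3"]

    def test_light_only_target_order(self, family, fragment_stores, defs):
        vl_native = syn.make_idealized_fv(chains="L", seed=20)
        target = FvSequence.from_structure(vl_native)
        _out, provenance = model_all_cdrs(vl_native.copy(), target,
                                          fragment_stores, defs)
        assert [p[0] for p in provenance] == ["L2", "L1", "L3"]

    def test_order_constant_matches_contract(self):
        assert LOOP_ORDER == (("L", 2), ("H", 2), ("L", 1), ("H", 1),
                              ("L", 3), ("H", 3))


def test_self_recovery_across_all_loops(family, fragment_stores, defs):
    """A target whose own structure populates the stores is reproduced exactly."""
    fv = family[0][6][0]
    target = FvSequence.from_structure(fv)
    out, provenance = model_all_cdrs(fv.copy(), target, fragment_stores, defs)
    assert all(stage == "cdr-db" for _cdr, stage, _d in provenance)
    for ct in "HL":
        for k in (1, 2, 3):
            assert fx.cdr_rmsd(out, fv, ct, k).rmsd < 0.05
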