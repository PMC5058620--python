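"""Superposition, RMSD protocols and torsion machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fvforge as fx
from fvforge import synthetic as syn
from fvforge.geometry import (GeometryError, circular_difference, dihedral,
                              kabsch_superpose, residue_chi, rmsd_between)
from conftest import quaternion_superpose


def _rigid(coords, angle_deg=37.0, axis=(0, 0, 1.0), shift=(1.0, -2.0, 3.0)):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
    return coords @ rot.T + np.asarray(shift)


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tf, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered_exactly(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        moved = _rigid(pts, 90.0)
        _tf, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_perturbed_points(self):
        ref = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 2.5]], float)
        mob = ref.copy()
        mob[2, 1] += 0.6
        _tf, rmsd = kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(quaternion_superpose(mob, ref), abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(np.random.default_rng(2).normal(size=(4, 3)), line)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rmsd_invariant_under_rigid_motion_of_either_input(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.3, size=(6, 3))
        base = kabsch_superpose(a, b)[1]
        angle = float(rng.uniform(0, 360))
        assert kabsch_superpose(_rigid(a, angle), b)[1] == pytest.approx(base, abs=1e-8)
        assert kabsch_superpose(a, _rigid(b, angle))[1] == pytest.approx(base, abs=1e-8)


class TestRegionRmsd:
    def test_self_comparison_is_zero_everywhere(self, ideal_fv):
        assert fx.fv_rmsd(ideal_fv, ideal_fv).rmsd == pytest.approx(0.0, abs=1e-9)
        for ct in "HL":
            assert fx.framework_rmsd(ideal_fv, ideal_fv, ct).rmsd == \
                pytest.approx(0.0, abs=1e-9)
            for k in (1, 2, 3):
                assert fx.cdr_rmsd(ideal_fv, ideal_fv, ct, k).rmsd == \
                    pytest.approx(0.0, abs=1e-9)

    def test_fv_rmsd_of_isotropic_noise(self, ideal_fv):
        rng = np.random.default_rng(5)
        noisy = ideal_fv.copy()
        for ct in "HL":
            for r in noisy.domain(ct):
                for a in r.atoms:
                    a.coord = a.coord + rng.normal(0.0, 0.1, 3)
        report = fx.fv_rmsd(noisy, ideal_fv)
        # sqrt(3) * sigma with a small fit absorption
        assert 0.17 * 0.8 <= report.rmsd <= 0.17 * 1.2
        n_res = len(ideal_fv.domain("H")) + len(ideal_fv.domain("L"))
        assert report.atom_count == 4 * n_res

    def test_cdr_perturbation_leaves_framework_rmsd_unchanged(self, ideal_fv):
        perturbed = ideal_fv.copy()
        for r in perturbed.domain("H"):
            if r.region == "CDR3":
                for a in r.atoms:
                    a.coord = a.coord + np.array([1.0, 0.0, 0.0])
        assert fx.framework_rmsd(perturbed, ideal_fv, "H").rmsd == \
            pytest.approx(0.0, abs=1e-9)
        report = fx.cdr_rmsd(perturbed, ideal_fv, "H", 3)
        assert report.rmsd == pytest.approx(1.0, abs=1e-9)

    def test_framework_rmsd_equals_direct_kabsch_on_fw_atoms(self, family):
        a, b = family[0][0][0], family[0][3][0]
        report = fx.framework_rmsd(a, b, "H")
        coords_a, coords_b = [], []
        bmap = b.residue_map("H")
        for r in a.domain("H"):
            other = bmap.get(r.position)
            if r.region == "FW" and other is not None and other.region == "FW" \
                    and r.has_backbone() and other.has_backbone():
                coords_a.append(r.backbone_coords())
                coords_b.append(other.backbone_coords())
        _tf, expected = kabsch_superpose(np.vstack(coords_a), np.vstack(coords_b))
        assert report.rmsd == pytest.approx(expected, abs=1e-12)

    def test_loop_length_mismatch_is_an_error(self, ideal_fv):
        shorter = ideal_fv.copy()
        loop = [r for r in shorter.domain("H") if r.region == "CDR3"]
        shorter.heavy = [r for r in shorter.heavy if r is not loop[0]]
        with pytest.raises(GeometryError, match="mismatch"):
            fx.cdr_rmsd(shorter, ideal_fv, "H", 3)

    def test_both_chain_fit_penalizes_interdomain_reorientation(self, ideal_fv):
        rotated = ideal_fv.copy()
        # rigidly reorient the whole light domain
        centroid = np.mean([a.coord for r in rotated.domain("L") for a in r.atoms],
                           axis=0)
        for r in rotated.domain("L"):
            for a in r.atoms:
                a.coord = _rigid(a.coord[None] - centroid, 10.0)[0] + centroid
        single = fx.cdr_rmsd(rotated, ideal_fv, "L", 1, both_chains_fit=False)
        both = fx.cdr_rmsd(rotated, ideal_fv, "L", 1, both_chains_fit=True)
        assert single.rmsd == pytest.approx(0.0, abs=1e-6)
        assert both.rmsd > 0.5


class TestDihedral:
    def test_cis_trans_and_quarter_twist(self):
        p1, p2, p3 = [0, 1.0, 0], [0, 0, 0], [1.5, 0, 0]
        assert dihedral(p1, p2, p3, [1.5, 1.0, 0]) == pytest.approx(0.0, abs=1e-9)
        assert dihedral(p1, p2, p3, [1.5, -1.0, 0]) == pytest.approx(180.0, abs=1e-9)
        # right-handed quarter twist is +90 under the IUPAC convention
        assert dihedral(p1, p2, p3, [1.5, 0, -1.0]) == pytest.approx(90.0, abs=1e-9)
        assert dihedral(p1, p2, p3, [1.5, 0, 1.0]) == pytest.approx(-90.0, abs=1e-9)


class TestChi1Accuracy:
    def test_identical_structures_are_100_percent(self, ideal_fv):
        assert fx.chi1_accuracy(ideal_fv, ideal_fv) == 100.0

    @pytest.mark.parametrize("offset,correct", [(39.0, True), (41.0, False),
                                                (350.0, True)])
    def test_40_degree_boundary_and_circular_wrap(self, ideal_fv, offset, correct):
        from fvforge.chem import CHI_ATOMS
        from fvforge.side_chains import _rebuild_residue
        modified = ideal_fv.copy()
        rotatable = [r for r in modified.domain("H") if CHI_ATOMS.get(r.aa)]
        res = rotatable[0]
        chi = residue_chi(res, 1)
        n = len(CHI_ATOMS[res.aa])
        _rebuild_residue(res, (chi + offset,) + (180.0,) * (n - 1))
        expected_wrong = 0 if correct else 1
        total = sum(1 for ct in "HL" for r in modified.domain(ct)
                    if CHI_ATOMS.get(r.aa))
        acc = fx.chi1_accuracy(modified, ideal_fv)
        assert acc == pytest.approx(100.0 * (total - expected_wrong) / total, abs=1e-6)

    def test_accuracy_decreases_with_angular_noise(self, ideal_fv):
        from fvforge.chem import CHI_ATOMS
        from fvforge.side_chains import _rebuild_residue
        rng = np.random.default_rng(9)
        accs = []
        for scale in (5.0, 45.0, 120.0):
            noisy = ideal_fv.copy()
            for ct in "HL":
                for r in noisy.domain(ct):
                    quads = CHI_ATOMS.get(r.aa)
                    if not quads:
                        continue
                    chis = tuple(residue_chi(r, k) + rng.normal(0, scale)
                                 for k in range(1, len(quads) + 1))
                    _rebuild_residue(r, chis)
            accs.append(fx.chi1_accuracy(noisy, ideal_fv))
        assert accs[0] >= accs[1] >= accs[2]
        assert accs[0] > 95.0

    def test_no_comparable_residues_is_an_error(self):
        gly = syn.make_idealized_fv(chains="H", seed=4)
        for r in gly.heavy:
            r.aa = "G"
            r.strip_side_chain()
        with pytest.raises(GeometryError):
            fx.chi1_accuracy(gly, gly)


def test_circular_difference_wraps():
    assert circular_difference(170.0, -170.0) == pytest.approx(20.0)
    assert circular_difference(10.0, 360.0 + 10.0) == pytest.approx(0.0)
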