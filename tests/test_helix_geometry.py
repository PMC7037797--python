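import numpy as np
import pytest

from helixcm import build_ideal_helix, compute_kink, fit_helix_axis, kabsch_rmsd
from helixcm._geom import rotation_matrix
from helixcm.helix_geometry import (KinkGeometry, format_kink_table,
                                    trajectory_rmsd)
from helixcm.synthetic_data import KinkConstruction, build_kinked_helix


def parametric_helix(n, axis_frame=np.eye(3), radius=2.3, rise=1.5, phase=100.0):
    """Independent construction oracle: points on an exact cylinder helix."""
    t = np.radians(phase) * np.arange(n)
    local = np.stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)], axis=1)
    return local @ axis_frame.T


class TestAxisFit:
    def test_ideal_segment_axis_matches_construction(self):
        pts = parametric_helix(12)
        axis = fit_helix_axis(pts)
        assert axis.residual < 0.1
        angle = np.degrees(np.arccos(abs(axis.direction @ np.array([0.0, 0.0, 1.0]))))
        assert angle < 1.0
        assert axis.phase_per_residue == pytest.approx(100.0, abs=0.5)

    def test_direction_is_equivariant_under_rotation(self):
        pts = parametric_helix(10)
        R = rotation_matrix([1.0, 0.5, -0.2], 63.0)
        a0 = fit_helix_axis(pts)
        a1 = fit_helix_axis(pts @ R.T)
        assert np.allclose(a1.direction, R @ a0.direction, atol=1e-6)

    def test_collinear_points_flagged_degenerate(self):
        pts = np.outer(np.arange(8), [0.0, 0.0, 1.5])
        with pytest.warns(UserWarning, match="degenerate"):
            axis = fit_helix_axis(pts)
        assert axis.degenerate
        assert axis.residual < 1e-9

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            fit_helix_axis(parametric_helix(4))


class TestComputeKink:
    def test_straight_helix_has_no_kink(self):
        h = build_ideal_helix("A" * 24)
        k = compute_kink(h, 11)
        assert k.bend_deg < 1.0
        assert abs(k.face_shift_deg) < 2.0
        assert not k.wobble_reliable  # wobble is meaningless without a bend

    @pytest.mark.parametrize("bend, wobble, face", [(20.0, 0.0, 0.0),
                                                    (20.0, 90.0, 30.0),
                                                    (10.0, -120.0, -30.0)])
    def test_recovers_constructed_kink(self, bend, wobble, face):
        h, truth = build_kinked_helix(
            KinkConstruction(true_bend_deg=bend, true_wobble_deg=wobble,
                             true_face_shift_deg=face))
        k = compute_kink(h, truth["hinge_position"])
        assert k.bend_deg == pytest.approx(bend, abs=0.5)
        assert abs((k.wobble_deg - wobble + 180) % 360 - 180) < 5.0
        assert abs((k.face_shift_deg - face + 180) % 360 - 180) < 2.0

    def test_descriptors_invariant_under_rigid_motion(self, rng):
        h, truth = build_kinked_helix(KinkConstruction(true_bend_deg=25.0,
                                                       true_wobble_deg=40.0))
        k0 = compute_kink(h, truth["hinge_position"])
        g = h.copy()
        R = rotation_matrix(rng.normal(size=3), 111.0)
        g.set_coords(g.coords() @ R.T + rng.normal(size=3) * 8.0)
        k1 = compute_kink(g, truth["hinge_position"])
        assert k1.bend_deg == pytest.approx(k0.bend_deg, abs=1e-6)
        assert k1.wobble_deg == pytest.approx(k0.wobble_deg, abs=1e-6)
        assert k1.face_shift_deg == pytest.approx(k0.face_shift_deg, abs=1e-6)

    def test_hinge_near_terminus_rejected(self):
        h = build_ideal_helix("A" * 24)
        with pytest.raises(ValueError):
            compute_kink(h, 2)
        with pytest.raises(ValueError):
            compute_kink(h, 21)


class TestKabschRMSD:
    def test_identical_sets_are_zero(self, rng):
        a = rng.normal(size=(6, 3))
        assert kabsch_rmsd(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_is_removed(self, rng):
        a = rng.normal(size=(7, 3))
        b = a @ rotation_matrix([1, 1, 0], 40.0).T + np.array([3.0, -2.0, 1.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_unsuperposed_rmsd_matches_direct_formula(self):
        a = np.zeros((4, 3))
        b = np.tile([1.0, 2.0, 2.0], (4, 1))  # each atom displaced by 3 A
        assert kabsch_rmsd(a, b, superpose=False) == pytest.approx(3.0)

    def test_matches_grid_search_over_rotations(self, rng):
        # oracle: exhaustive search over rotation space on a 5-atom instance
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(5, 3))
        b = a + rng.normal(scale=0.4, size=(5, 3))
        ac, bc = a - a.mean(0), b - b.mean(0)
        grid = Rotation.create_group("O")  # octahedral seeds
        best = np.inf
        for seed_rot in grid:
            for _ in range(400):
                pert = Rotation.from_rotvec(rng.normal(scale=0.35, size=3))
                R = (pert * seed_rot).as_matrix()
                rmsd = np.sqrt(np.mean(np.sum((ac - bc @ R.T) ** 2, axis=1)))
                best = min(best, rmsd)
        assert kabsch_rmsd(a, b) <= best + 1e-3

    def test_mismatched_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestTrajectoryRMSD:
    def test_constant_trajectory_is_all_zeros(self):
        h = build_ideal_helix("A" * 10)
        tab = trajectory_rmsd([h.copy() for _ in range(5)])
        assert len(tab) == 5
        assert np.allclose(tab["rmsd_angstrom"], 0.0, atol=1e-12)

    def test_gaussian_noise_gives_sigma_sqrt3(self, rng):
        h = build_ideal_helix("A" * 16)
        sigma = 0.25
        frames = [h]
        for _ in range(60):
            f = h.copy()
            f.set_coords(h.coords() + rng.normal(0.0, sigma, (h.n_atoms, 3)))
            frames.append(f)
        tab = trajectory_rmsd(frames)
        assert tab["rmsd_angstrom"][0] == pytest.approx(0.0, abs=1e-12)
        mean = tab["rmsd_angstrom"][1:].mean()
        assert abs(mean - sigma * np.sqrt(3)) / (sigma * np.sqrt(3)) < 0.10

    def test_row_per_frame(self):
        h = build_ideal_helix("A" * 8)
        tab = trajectory_rmsd([h.copy() for _ in range(50)], selection=(1, 6))
        assert list(tab["frame"]) == list(range(50))


class TestKinkTable:
    def test_row_formatting_matches_report_layout(self):
        text = format_kink_table([("TMH1", "T1.44", KinkGeometry(13.0, 172.4, 3.0))])
        lines = text.strip().splitlines()
        assert lines[0] == "Helix\tHinge Residue\tBend\tWobble\tFaceShift"
        assert lines[1] == "TMH1\tT1.44\t13.0\t172.4\t3.0"

    def test_empty_input_yields_header_only(self):
        assert format_kink_table([]) == "Helix\tHinge Residue\tBend\tWobble\tFaceShift\n"

    def test_one_decimal_rounding(self):
        text = format_kink_table([("TMH6", "T6.43", KinkGeometry(9.94, 113.04, 5.85))])
        assert "9.9" in text and "113.0" in text
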