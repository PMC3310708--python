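"""Fixed-axis hinge fitting: orientation sampling, optimal angle, recovery."""

import numpy as np
import pytest

import hingescan as hs
from hingescan._geometry import rotation_about_axis
from hingescan.axisfit import _superpose_on_core, combined_fixed_axis_fit
from hingescan.qrd import fit_rigid_domains, select_reference


def grid_search_angle(ref_points, frame_points, anchor, orientation, step=0.01):
    """Independent oracle: scan angles on a grid, return the best (degrees)."""
    angles = np.arange(-180.0, 180.0, step)
    x = ref_points - anchor
    y = frame_points - anchor
    best, best_cost = 0.0, np.inf
    for ang in angles:
        R = rotation_about_axis(orientation, ang)
        cost = ((x @ R.T - y) ** 2).sum()
        if cost < best_cost:
            best, best_cost = ang, cost
    return best


class TestSampleOrientations:
    def test_unit_norm_and_determinism(self):
        u1 = hs.sample_orientations(50, seed=4)
        u2 = hs.sample_orientations(50, seed=4)
        assert np.abs(np.linalg.norm(u1, axis=1) - 1.0).max() < 1e-12
        assert np.array_equal(u1, u2)

    def test_mean_vanishes_for_large_n(self):
        u = hs.sample_orientations(10_000, seed=0)
        assert np.linalg.norm(u.mean(axis=0)) < 0.05


class TestOptimalAngle:
    def test_planted_rotation_recovered_exactly(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, (8, 3)) + np.array([10.0, 0, 0])
        anchor = np.array([2.0, 1.0, -1.0])
        u = np.array([0.0, 0.0, 1.0])
        R = rotation_about_axis(u, 25.0)
        rotated = (pts - anchor) @ R.T + anchor
        assert hs.optimal_angle(pts, rotated, anchor, u) == pytest.approx(25.0, abs=1e-6)

    def test_identity_gives_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, (6, 3)) + np.array([8.0, 0, 0])
        assert hs.optimal_angle(pts, pts, np.zeros(3), np.array([0, 1.0, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_search_oracle_under_perturbation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-6, 6, (10, 3)) + np.array([12.0, 0, 0])
        anchor = rng.uniform(-2, 2, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        R = rotation_about_axis(u, -41.3)
        target = (pts - anchor) @ R.T + anchor + rng.normal(scale=0.3, size=pts.shape)
        got = hs.optimal_angle(pts, target, anchor, u)
        oracle = grid_search_angle(pts, target, anchor, u)
        assert abs(got - oracle) <= 0.01

    def test_points_on_axis_rejected(self):
        pts = np.array([[0, 0, 1.0], [0, 0, 2.0], [0, 0, 3.0]])
        with pytest.raises(ValueError):
            hs.optimal_angle(pts, pts, np.zeros(3), np.array([0, 0, 1.0]))


class TestFitFixedAxis:
    def test_planted_axis_recovered(self, two_body_hinge):
        traj, truth = two_body_hinge
        part = hs.Partition(assignment=truth.assignment, q=2)
        hinge = truth.hinges[0]
        ax = hs.fit_fixed_axis(traj, part, core=0, moving=1, n_orientations=500, seed=5,
                               reference_frame=0)
        planted_u = np.array(hinge.orientation, dtype=float)
        planted_u /= np.linalg.norm(planted_u)
        cosang = abs(float(ax.orientation @ planted_u))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0
        assert np.abs(ax.per_frame_angle - np.asarray(hinge.angles_deg)).max() < 0.5
        assert ax.captured_fraction >= 0.99

    def test_static_moving_domain_flagged_degenerate(self, caplog):
        import logging

        spec = hs.SyntheticSpec(n_residues_per_domain=[12, 10], n_frames=5, seed=9)
        traj, truth = hs.generate(spec)
        part = hs.Partition(assignment=truth.assignment, q=2)
        with caplog.at_level(logging.WARNING, logger="hingescan.axisfit"):
            ax = hs.fit_fixed_axis(traj, part, core=0, moving=1, n_orientations=20, seed=0)
        assert np.isnan(ax.captured_fraction)
        assert np.abs(ax.per_frame_angle).max() < 1e-8

    def test_matches_brute_force_reimplementation(self):
        # small instance: 8 residues, all anchors, 50 orientations
        spec = hs.SyntheticSpec(n_residues_per_domain=[5, 3], n_frames=6,
                                hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=1,
                                                     orientation=(0, 1, 0),
                                                     angles_deg=tuple(np.linspace(0, 25, 6)))],
                                noise_sigma=0.2, seed=13)
        traj, truth = hs.generate(spec)
        part = hs.Partition(assignment=truth.assignment, q=2)
        ax = hs.fit_fixed_axis(traj, part, core=0, moving=1, n_orientations=50, seed=17,
                               refine=False, reference_frame=0)
        # independent brute force over the same anchor x orientation grid
        core_idx = part.domain_indices(0)
        mov_idx = part.domain_indices(1)
        fixed = _superpose_on_core(traj, core_idx, 0)
        ref = fixed[0]
        U = hs.sample_orientations(50, seed=17)
        best = (np.inf, None, None)
        for a in range(traj.n_residues):
            for u in U:
                cost = 0.0
                try:
                    for t in range(traj.n_frames):
                        ang = hs.optimal_angle(ref[mov_idx], fixed[t, mov_idx], ref[a], u)
                        R = rotation_about_axis(u, ang)
                        cost += (((ref[mov_idx] - ref[a]) @ R.T + ref[a] - fixed[t, mov_idx]) ** 2).sum()
                except ValueError:
                    continue
                if cost < best[0]:
                    best = (cost, a, u)
        norm = traj.n_frames * mov_idx.size * 3
        assert ax.discrete_residual_msf == pytest.approx(best[0] / norm, rel=1e-9)
        assert ax.anchor_residue == best[1]

    def test_recovery_improves_with_more_orientations(self, two_body_hinge):
        traj, truth = two_body_hinge
        part = hs.Partition(assignment=truth.assignment, q=2)
        planted_u = np.array(truth.hinges[0].orientation, dtype=float)
        errs = []
        for n in (10, 100, 1000):
            ax = hs.fit_fixed_axis(traj, part, core=0, moving=1, n_orientations=n, seed=1,
                                   refine=False, reference_frame=0)
            cosang = abs(float(ax.orientation @ planted_u))
            errs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        assert errs[2] <= errs[0]
        assert min(errs) == errs[2]

    def test_same_domain_rejected(self, two_body_hinge):
        traj, truth = two_body_hinge
        part = hs.Partition(assignment=truth.assignment, q=2)
        with pytest.raises(ValueError):
            hs.fit_fixed_axis(traj, part, core=1, moving=1)


class TestTwoHinges:
    def test_both_planted_axes_recovered(self, small_three_body):
        traj, truth, spec = small_three_body
        part = hs.Partition(assignment=truth.assignment, q=3)
        axes, combined = hs.fit_two_hinges(traj, part, core=1, n_orientations=500, seed=2,
                                           reference_frame=0)
        assert len(axes) == 2
        for ax in axes:
            hinge = next(h for h in truth.hinges if h.moving == ax.moving_domain)
            planted_u = np.array(hinge.orientation, dtype=float)
            cosang = abs(float(ax.orientation @ planted_u))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0
        assert combined >= 0.99

    def test_static_side_domain_flagged_other_recovered(self):
        n_frames = 10
        spec = hs.SyntheticSpec(
            n_residues_per_domain=[12, 14, 12], n_frames=n_frames,
            hinges=[hs.HingeSpec(moving=0, core=1, anchor_residue=18, orientation=(0, 1, 0),
                                 angles_deg=tuple(np.linspace(0, 30, n_frames)))],
            noise_sigma=0.0, seed=19)
        traj, truth = hs.generate(spec)
        part = hs.Partition(assignment=truth.assignment, q=3)
        axes, _ = hs.fit_two_hinges(traj, part, core=1, n_orientations=100, seed=3,
                                    reference_frame=0)
        by_dom = {ax.moving_domain: ax for ax in axes}
        assert np.isnan(by_dom[2].captured_fraction)  # static side domain
        assert by_dom[0].captured_fraction > 0.99

    def test_restriction_never_beats_free_fit(self, small_three_body):
        traj, truth, _spec = small_three_body
        part = hs.Partition(assignment=truth.assignment, q=3)
        ref = select_reference(traj)
        free = fit_rigid_domains(traj, part, ref)
        axes, combined = hs.fit_two_hinges(traj, part, core=1, n_orientations=100, seed=4,
                                           reference_frame=ref)
        assert combined <= free.captured_fraction + 1e-9
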