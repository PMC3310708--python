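"""Quasi-rigid domain decomposition: fits, initialization, search, q-scan."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.metrics import rand_score

import hingescan as hs
from hingescan._geometry import rotation_about_axis
from hingescan.qrd import MIN_DOMAIN_SIZE, fit_rigid_domains, select_reference

from .test_fluctuation import make_traj, random_rigid_copies


def exhaustive_best_bipartition(traj, reference_frame):
    """Enumerate all 2-partitions with >= MIN_DOMAIN_SIZE per part."""
    N = traj.n_residues
    best = (np.inf, None)
    for k in range(MIN_DOMAIN_SIZE, N - MIN_DOMAIN_SIZE + 1):
        for members in combinations(range(N), k):
            if 0 not in members:  # fix residue 0 in part 0 to halve the space
                continue
            assignment = np.ones(N, dtype=int)
            assignment[list(members)] = 0
            part = hs.Partition(assignment=assignment, q=2)
            fit = fit_rigid_domains(traj, part, reference_frame)
            if fit.residual_msf < best[0]:
                best = (fit.residual_msf, part)
    return best


class TestSelectReference:
    def test_frame_equal_to_mean_is_selected(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 20, (8, 3))
        # frames: base plus symmetric distortions, and base itself in the middle
        d = rng.normal(scale=1.0, size=(8, 3))
        coords = np.array([base + d, base, base - d])
        traj = make_traj(coords)
        assert select_reference(traj) == 1

    def test_matches_brute_force_scan(self, random_walk_traj):
        got = select_reference(random_walk_traj)
        # brute force: superpose all frames to their iterated mean, pick min RMSD
        from hingescan._geometry import rigid_fit_residuals
        from hingescan.qrd import _superpose_all

        coords = random_walk_traj.coords
        mean = coords[0]
        for _ in range(200):
            aligned = _superpose_all(coords, mean)
            new_mean = aligned.mean(axis=0)
            if np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()) < 1e-9:
                mean = new_mean
                break
            mean = new_mean
        ssd, _, _ = rigid_fit_residuals(mean, coords)
        assert got == int(np.argmin(ssd))

    def test_duplicating_frames_keeps_selected_structure(self, random_walk_traj):
        i0 = select_reference(random_walk_traj)
        doubled = make_traj(np.concatenate([random_walk_traj.coords] * 2, axis=0))
        i1 = select_reference(doubled)
        assert np.allclose(doubled.coords[i1], random_walk_traj.coords[i0])


class TestFitRigidDomains:
    def test_globally_rigid_single_domain_degenerate(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 15, (9, 3))
        traj = make_traj(random_rigid_copies(base, 5, seed=2))
        part = hs.Partition(assignment=np.zeros(9, dtype=int), q=1)
        fit = fit_rigid_domains(traj, part, 0)
        assert fit.residual_msf < 1e-12
        assert fit.captured_fraction == 1.0  # total_msf ~ 0 -> pinned to 1

    def test_true_partition_fits_planted_bodies_exactly(self, three_body_noiseless):
        traj, truth = three_body_noiseless
        part = hs.Partition(assignment=truth.assignment, q=3)
        fit = fit_rigid_domains(traj, part, select_reference(traj))
        assert fit.residual_msf < 1e-10

    def test_wrong_partition_fits_worse(self, three_body_noiseless):
        traj, truth = three_body_noiseless
        ref = select_reference(traj)
        good = fit_rigid_domains(traj, hs.Partition(assignment=truth.assignment, q=3), ref)
        # split one planted body across two domains
        bad_assign = truth.assignment.copy()
        dom0 = np.flatnonzero(truth.assignment == 0)
        bad_assign[dom0[: len(dom0) // 2]] = 1
        bad = fit_rigid_domains(traj, hs.Partition(assignment=bad_assign, q=3), ref)
        assert bad.residual_msf > good.residual_msf

    def test_rotations_proper_orthogonal(self, three_body_search):
        traj, truth, part, fit = three_body_search
        R = fit.rotations.reshape(-1, 3, 3)
        eye = np.einsum("tij,tkj->tik", R, R)
        assert np.abs(eye - np.eye(3)).max() < 1e-8
        assert np.abs(np.linalg.det(R) - 1.0).max() < 1e-8

    def test_rmsd_consistent_with_residual(self, three_body_search):
        traj, truth, part, fit = three_body_search
        assert np.mean(fit.per_frame_rmsd**2) == pytest.approx(3.0 * fit.residual_msf, abs=1e-10)

    def test_collinear_domain_rejected(self):
        coords = np.zeros((2, 6, 3))
        coords[:, :, 0] = np.arange(6)  # all residues on a line
        coords[1] += 0.5
        traj = make_traj(coords)
        part = hs.Partition(assignment=np.array([0, 0, 0, 1, 1, 1]), q=2)
        with pytest.raises(ValueError, match="domain"):
            fit_rigid_domains(traj, part, 0)


class TestInitialPartition:
    def test_recovers_two_body_split(self, two_body_hinge):
        traj, truth = two_body_hinge
        part = hs.initial_partition(traj, q=2, seed=0)
        assert rand_score(truth.assignment, part.assignment) >= 0.9

    def test_more_domains_than_bodies_refines_bodies(self, small_three_body):
        traj, truth, _spec = small_three_body
        part = hs.initial_partition(traj, q=5, seed=0)
        # noiseless case: no returned domain may straddle two planted bodies.
        # Residues exactly on a planted axis (the anchors) are rigid with
        # respect to both bodies, so their membership is undefined; skip them.
        anchors = {h.anchor_residue for h in truth.hinges}
        for lab in range(part.q):
            idx = [i for i in part.domain_indices(lab) if i not in anchors]
            bodies = np.unique(truth.assignment[idx])
            assert len(bodies) == 1

    def test_deterministic_given_seed(self, two_body_hinge):
        traj, _ = two_body_hinge
        p1 = hs.initial_partition(traj, q=2, seed=7)
        p2 = hs.initial_partition(traj, q=2, seed=7)
        assert np.array_equal(p1.assignment, p2.assignment)

    def test_rigid_input_rejected(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0, 15, (12, 3))
        traj = make_traj(np.repeat(base[None], 5, axis=0))
        with pytest.raises(ValueError, match="rigid|degenerate"):
            hs.initial_partition(traj, q=2)


class TestSearchPartition:
    def test_exact_recovery_noiseless(self, three_body_search):
        traj, truth, part, fit = three_body_search
        assert rand_score(truth.assignment, part.assignment) == 1.0
        assert fit.residual_msf < 1e-10

    def test_q1_short_circuits(self, two_body_hinge):
        traj, _ = two_body_hinge
        part, fit = hs.search_partition(traj, 1)
        assert part.q == 1
        assert fit.captured_fraction == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration_small(self):
        # 12 residues, 2 planted bodies, 10 frames
        spec = hs.SyntheticSpec(
            n_residues_per_domain=[6, 6], n_frames=10,
            hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=2, orientation=(0, 1, 0),
                                 angles_deg=tuple(np.linspace(0, 30, 10)))],
            noise_sigma=0.3, seed=5)
        traj, _ = hs.generate(spec)
        ref = select_reference(traj)
        best_eps2, _ = exhaustive_best_bipartition(traj, ref)
        _, fit = hs.search_partition(traj, 2, hs.SearchConfig(seed=9), reference_frame=ref)
        assert fit.residual_msf == pytest.approx(best_eps2, abs=1e-9)

    def test_invalid_q_raises(self, two_body_hinge):
        traj, _ = two_body_hinge
        with pytest.raises(ValueError):
            hs.search_partition(traj, 0)

    def test_noise_floor_regime(self):
        # planted rigid motion + isotropic sigma: epsilon^2 approaches the
        # 2*sigma^2 floor (per coordinate), asserted loosely
        sigma = 0.4
        spec = hs.SyntheticSpec(
            n_residues_per_domain=[40, 40], n_frames=60,
            hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=10, orientation=(0, 0, 1),
                                 angles_deg=tuple(np.linspace(0, 45, 60)))],
            noise_sigma=sigma, seed=21)
        traj, truth = hs.generate(spec)
        fit = fit_rigid_domains(traj, hs.Partition(assignment=truth.assignment, q=2),
                                select_reference(traj))
        assert sigma**2 <= fit.residual_msf <= 3 * sigma**2


class TestScanQ:
    def test_captured_fraction_plateaus_at_true_body_count(self, small_three_body):
        traj, truth, _spec = small_three_body
        res = hs.scan_q(traj, [1, 2, 3, 4], hs.SearchConfig(seed=13))
        caps = [row["captured_fraction"] for row in res["table"]]
        assert all(b >= a - 1e-12 for a, b in zip(caps, caps[1:]))  # non-decreasing
        assert caps[2] - caps[1] > 0.05  # jump at q = 3
        assert caps[3] - caps[2] < 0.05  # plateau beyond
        assert res["suggested_q"] == 3

    def test_single_q1_row(self, two_body_hinge):
        traj, _ = two_body_hinge
        res = hs.scan_q(traj, [1])
        assert len(res["table"]) == 1
        assert res["table"][0]["captured_fraction"] == pytest.approx(0.0, abs=1e-12)
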