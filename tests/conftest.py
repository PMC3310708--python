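"""Shared fixtures: the planted study trajectories.

The heavy synthetic scenarios are session-scoped so the partition searches
run once and are reused by unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import hingescan as hs

THREE_BODY_SIZES = [60, 50, 70]
THREE_BODY_FRAMES = 100
THREE_BODY_AMP = 50.0  # deg; large-amplitude domain motion
TWO_BODY_SIZES = [40, 35]
TWO_BODY_FRAMES = 30
TWO_BODY_AMP = 15.0  # deg; modest hinge breathing


def three_body_spec(seed: int, sigma: float) -> hs.SyntheticSpec:
    """Three planted rigid bodies, two hinges fixed in the middle (core) body.

    Anchors sit in the core interior so no planted axis passes near a
    cross-domain residue (an on-axis residue has a genuinely undefined
    domain label).
    """
    return hs.SyntheticSpec(
        n_residues_per_domain=THREE_BODY_SIZES,
        n_frames=THREE_BODY_FRAMES,
        hinges=[
            hs.HingeSpec(moving=0, core=1, anchor_residue=85, orientation=(0, 1, 0),
                         angles_deg=tuple(np.linspace(0, THREE_BODY_AMP, THREE_BODY_FRAMES))),
            hs.HingeSpec(moving=2, core=1, anchor_residue=95, orientation=(0, 0, 1),
                         angles_deg=tuple(np.linspace(0, -THREE_BODY_AMP, THREE_BODY_FRAMES))),
        ],
        noise_sigma=sigma,
        seed=seed,
    )


def two_body_spec(seed: int, amp: float = TWO_BODY_AMP, n_frames: int = TWO_BODY_FRAMES,
                  sigma: float = 0.0) -> hs.SyntheticSpec:
    """One moving body rotating about an axis anchored at the interface,
    where physical hinges sit — the strain/axis-recovery scenario."""
    base = hs.SyntheticSpec(n_residues_per_domain=TWO_BODY_SIZES, n_frames=1, seed=seed)
    _, truth0 = hs.generate(base)
    core_idx = truth0.domain_indices[0]
    xcut = truth0.reference_coords[truth0.domain_indices[1]][:, 0].min()
    anchor = int(core_idx[np.argmin(np.abs(truth0.reference_coords[core_idx, 0] - xcut))])
    return hs.SyntheticSpec(
        n_residues_per_domain=TWO_BODY_SIZES,
        n_frames=n_frames,
        hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=anchor, orientation=(0, 0, 1),
                             angles_deg=tuple(np.linspace(0.0, amp, n_frames)))],
        noise_sigma=sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def three_body_noiseless():
    traj, truth = hs.generate(three_body_spec(seed=7, sigma=0.0))
    return traj, truth


@pytest.fixture(scope="session")
def three_body_search(three_body_noiseless):
    traj, truth = three_body_noiseless
    part, fit = hs.search_partition(traj, 3, hs.SearchConfig(seed=11))
    return traj, truth, part, fit


@pytest.fixture(scope="session")
def two_body_hinge():
    traj, truth = hs.generate(two_body_spec(seed=42))
    return traj, truth


@pytest.fixture(scope="session")
def small_three_body():
    """Scaled-down three-body system for q-scans and two-hinge fits."""
    n_frames = 40
    spec = hs.SyntheticSpec(
        n_residues_per_domain=[20, 18, 22],
        n_frames=n_frames,
        hinges=[
            hs.HingeSpec(moving=0, core=1, anchor_residue=28, orientation=(0, 1, 0),
                         angles_deg=tuple(np.linspace(0, 40, n_frames))),
            hs.HingeSpec(moving=2, core=1, anchor_residue=32, orientation=(0, 0, 1),
                         angles_deg=tuple(np.linspace(0, -35, n_frames))),
        ],
        noise_sigma=0.0,
        seed=3,
    )
    traj, truth = hs.generate(spec)
    return traj, truth, spec


@pytest.fixture(scope="session")
def random_walk_traj():
    """A 30-residue, 20-frame random trajectory (no planted structure)."""
    rng = np.random.default_rng(123)
    base = rng.uniform(0, 30, size=(30, 3))
    coords = base[None] + rng.normal(scale=1.0, size=(20, 30, 3))
    ids = [("rand", "A", i + 1, "GLY") for i in range(30)]
    return hs.CalphaTrajectory(coords=coords, residue_ids=ids, source="random")
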