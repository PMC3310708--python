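"""Distance-fluctuation matrix of a planted two-domain hinge.

Builds a synthetic two-body trajectory (one domain rotating about a planted
hinge axis), computes the matrix A of pairwise C-alpha distance variances,
and shows its block structure: near-zero within each rigid body, large
across them.
"""

import numpy as np

import hingescan as hs

angles = tuple(float(a) for a in np.linspace(0, 25, 40))
spec = hs.SyntheticSpec(
    n_residues_per_domain=[30, 25],
    n_frames=40,
    hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=5, orientation=(0, 0, 1),
                         angles_deg=angles)],
    noise_sigma=0.0,
    seed=1,
)
traj, truth = hs.generate(spec)

A = hs.distance_fluctuation_matrix(traj)
d0, d1 = truth.domain_indices

intra0 = hs.block_summary(A, d0, d0)
intra1 = hs.block_summary(A, d1, d1)
cross = hs.block_summary(A, d0, d1)

print(f"mean A within domain 0:  {intra0:.6f} A^2")
print(f"mean A within domain 1:  {intra1:.6f} A^2")
print(f"mean A across domains:   {cross:.3f} A^2")
print()
print("Rigid bodies fluctuate ~0 internally; all the distance variance sits")
print("in the cross-domain block -- the signature a quasi-rigid decomposition")
print("looks for.")

series = hs.min_distance_series(traj, "resid:1-30", "resid:31-55")
print()
print(f"closest inter-domain C-alpha pair: avg {series.average_value:.2f} A, "
      f"final {series.final_value:.2f} A over {traj.n_frames} frames")
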