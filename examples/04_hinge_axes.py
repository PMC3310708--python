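"""Fixed-axis description of domain motion.

Given a partition, the side domain's motion is reduced to one degree of
freedom per frame: a rotation angle about a single time-independent axis
anchored on a C-alpha and fixed in the core-domain frame.  The exhaustive
anchor x orientation search recovers the planted axis.
"""

import numpy as np

import hingescan as hs

angles = tuple(float(a) for a in np.linspace(0, 30, 25))
spec = hs.SyntheticSpec(
    n_residues_per_domain=[30, 25], n_frames=25,
    hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=8, orientation=(0, 1, 0),
                         angles_deg=angles)],
    noise_sigma=0.0, seed=11,
)
traj, truth = hs.generate(spec)
part = hs.Partition(assignment=truth.assignment, q=2)

axis = hs.fit_fixed_axis(traj, part, core=0, moving=1, n_orientations=500, seed=7,
                         reference_frame=0)

planted = np.asarray(truth.hinges[0].orientation, dtype=float)
cos = abs(float(axis.orientation @ planted))
err = np.degrees(np.arccos(np.clip(cos, -1, 1)))

print(f"planted anchor residue:   {truth.hinges[0].anchor_residue}")
print(f"recovered anchor residue: {axis.anchor_residue}")
print(f"orientation error:        {err:.4f} deg")
print(f"max per-frame angle error: {np.abs(axis.per_frame_angle - np.array(angles)).max():.4f} deg")
print(f"captured fraction of the moving domain's fluctuation: {axis.captured_fraction:.4f}")
print()
print("A single fixed axis plus one angle per frame reproduces the whole")
print("motion -- the minimal mechanical description of a hinge.")
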