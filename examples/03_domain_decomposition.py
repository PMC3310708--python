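"""Quasi-rigid domain decomposition with an unknown number of domains.

Generates three planted rigid bodies with two hinges, scans q = 1..4, and
shows the captured fraction of mean-square fluctuation saturating at the
true body count.
"""

import numpy as np
from sklearn.metrics import rand_score

import hingescan as hs

n_frames = 40
spec = hs.SyntheticSpec(
    n_residues_per_domain=[20, 18, 22], n_frames=n_frames,
    hinges=[
        hs.HingeSpec(moving=0, core=1, anchor_residue=28, orientation=(0, 1, 0),
                     angles_deg=tuple(float(a) for a in np.linspace(0, 40, n_frames))),
        hs.HingeSpec(moving=2, core=1, anchor_residue=32, orientation=(0, 0, 1),
                     angles_deg=tuple(float(a) for a in np.linspace(0, -35, n_frames))),
    ],
    noise_sigma=0.0, seed=3,
)
traj, truth = hs.generate(spec)

scan = hs.scan_q(traj, [1, 2, 3, 4], hs.SearchConfig(seed=13))
print("q   captured_fraction   epsilon^2 (A^2)")
for row in scan["table"]:
    print(f"{row['q']}   {row['captured_fraction']:#.4f}             {row['epsilon2']:.3g}")
print(f"\nsuggested q (marginal gain < 0.05): {scan['suggested_q']}")

part, fit = scan["results"][scan["suggested_q"]]
print(f"Rand index vs planted bodies: {rand_score(truth.assignment, part.assignment):.3f}")
print()
print("The captured fraction jumps as q reaches the number of genuinely rigid")
print("bodies, then plateaus: extra domains buy almost nothing.")
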