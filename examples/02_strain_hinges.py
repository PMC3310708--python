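"""Geometric strain pinpoints the hinge region.

The strain of residue i sums the distance variance A_ij over its ~5 A
contact neighbourhood: p_i = sum_j A_ij * f(<d_ij>).  Residues whose local
contacts straddle two relatively moving domains accumulate strain; rigid
interiors do not.
"""

import numpy as np

import hingescan as hs

# two-body hinge anchored at the domain interface, modest 15 deg sweep
base = hs.SyntheticSpec(n_residues_per_domain=[40, 35], n_frames=1, seed=42)
_, truth0 = hs.generate(base)
core = truth0.domain_indices[0]
xcut = truth0.reference_coords[truth0.domain_indices[1]][:, 0].min()
anchor = int(core[np.argmin(np.abs(truth0.reference_coords[core, 0] - xcut))])

spec = hs.SyntheticSpec(
    n_residues_per_domain=[40, 35], n_frames=30,
    hinges=[hs.HingeSpec(moving=1, core=0, anchor_residue=anchor, orientation=(0, 0, 1),
                         angles_deg=tuple(float(a) for a in np.linspace(0, 15, 30)))],
    seed=42,
)
traj, truth = hs.generate(spec)

profile = hs.strain_profile(traj)
top5 = profile.top_residues(5)
in_interface = np.isin(top5, truth.interface_residues)

print(f"top-5 strain residues (0-based): {top5.tolist()}")
print(f"all at the planted domain interface: {bool(in_interface.all())}")
enrich = (profile.per_residue[truth.interface_residues].mean()
          / profile.per_residue[truth.interior_residues].mean())
print(f"interface / interior mean strain: {enrich:.1f}x")
print()
print("Strain peaks mark residues whose contact network deforms -- the hinge")
print("region between quasi-rigid domains, candidate mechanical/allosteric sites.")
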