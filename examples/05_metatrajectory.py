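"""Joint decomposition of several proteins via a meta-trajectory.

Three synthetic "homologues" share a three-domain architecture but sample
different hinge-angle ranges (think different ligand states).  Their frames,
reduced to corresponding residues, are concatenated and decomposed jointly;
the per-source report then shows how well the shared rigid-domain model fits
each protein.
"""

import numpy as np

import hingescan as hs
from hingescan.qrd import select_reference

sizes = [25, 20, 25]
n_frames = 30
sweeps = [((0, 35), (0, -30)), ((10, 45), (-5, -40)), ((-15, 15), (15, -15))]


def make_source(k, h1, h2):
    spec = hs.SyntheticSpec(
        n_residues_per_domain=sizes, n_frames=n_frames,
        hinges=[
            hs.HingeSpec(moving=0, core=1, anchor_residue=32, orientation=(0, 1, 0),
                         angles_deg=tuple(float(a) for a in np.linspace(*h1, n_frames))),
            hs.HingeSpec(moving=2, core=1, anchor_residue=38, orientation=(0, 0, 1),
                         angles_deg=tuple(float(a) for a in np.linspace(*h2, n_frames))),
        ],
        noise_sigma=0.3, seed=50, noise_seed=90 + k,  # shared fold, fresh noise
    )
    traj, truth = hs.generate(spec)
    tag = f"prot{k}"
    ids = [(tag, c, n, r) for (_t, c, n, r) in traj.residue_ids]
    return (hs.CalphaTrajectory(coords=traj.coords, residue_ids=ids), tag), spec, truth


sources, specs = [], []
for k, (h1, h2) in enumerate(sweeps):
    (traj, tag), spec, truth = make_source(k, h1, h2)
    sources.append((traj, tag, ["APO", "ATP", "ADP"][k]))
    specs.append((spec, tag))

table = hs.make_correspondence(specs, overlap_fraction=1.0)
meta = hs.build_metatrajectory(sources, table)
print(f"meta-trajectory: {meta.trajectory.n_frames} frames x "
      f"{meta.trajectory.n_residues} corresponding residues")

part, fit = hs.search_partition(meta.trajectory, 3, hs.SearchConfig(seed=5))
print(f"q=3 joint decomposition: captured fraction {fit.captured_fraction:.3f}, "
      f"epsilon^2 {fit.residual_msf:.3f} A^2")

report = hs.per_source_fit_report(meta, fit.per_frame_rmsd, threshold=4.0)
print("\nper-source fit quality:")
print(report.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print("One shared set of quasi-rigid domains fits every source: the same")
print("coarse mechanical architecture underlies all three 'proteins'.")
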