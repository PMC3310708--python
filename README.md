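# hingescan

Multiscale analysis of protein internal dynamics from Cα trajectories:
per-residue-pair **distance-fluctuation maps**, **geometric strain** profiles
that pinpoint hinges, **quasi-rigid domain decomposition**, and **fixed-axis
hinge fitting** — on a single trajectory or on a combined *meta-trajectory*
of corresponding residues across homologous proteins.

## Who it is for

Researchers analysing MD (or other conformational-ensemble) data of
multi-domain proteins who want a coarse mechanical description of the
motion: how many effectively rigid units are there, where are the hinges,
and how much of the observed fluctuation does a few-degree-of-freedom
rigid-body model explain. The approach was designed for large-amplitude
systems (e.g. Hsp90-family chaperones) where linear mode reconstructions
distort the structure.

## The quantities

**Distance fluctuations.** For residues *i, j* with instantaneous Cα
distance *d<sub>ij</sub>(t)*,

&nbsp;&nbsp;&nbsp;&nbsp;*A<sub>ij</sub>* = ⟨(*d<sub>ij</sub>* − ⟨*d<sub>ij</sub>*⟩)²⟩ &nbsp;&nbsp;[Å²],

a superposition-free flexibility map. Quasi-rigid domains appear as
low-*A* blocks.

**Geometric strain.** *p<sub>i</sub>* = Σ<sub>j≠i</sub> *A<sub>ij</sub>* ·
*f*(⟨*d<sub>ij</sub>*⟩), with *f* a logistic switch (midpoint 5 Å, width
0.5 Å) restricting the sum to the local contact network. Strain peaks mark
residues whose neighbourhood deforms — the hinges between domains.

**Quasi-rigid decomposition.** A partition of the residues into *q* domains
is scored by the rigid-fit error ε²: for every frame and domain, the
reference domain is placed by optimal least-squares rigid superposition
(Kabsch, full rotation matrices) and ε² is the mean squared deviation per
residue, frame and coordinate. A stochastic search (essential-dynamics /
fluctuation-matrix seeding, simulated annealing over single-residue
relabels, greedy polish) minimizes ε²; the *captured fraction*
1 − ε²/ε²<sub>global</sub> measures what domain-relative rigid motion
explains beyond a single whole-molecule superposition.

**Fixed-axis hinges.** Each side domain's motion is further restricted to a
pure rotation about one *time-independent* axis, anchored on a Cα and fixed
in the core-domain frame; the per-frame angle is the only remaining degree
of freedom and has a closed form. The axis is found by an exhaustive scan
over all Cα anchors × orientations sampled uniformly on the sphere (500 by
default), plus a local continuous refinement.

**Meta-trajectory.** Trajectories of several proteins/ligand states are
reduced to a table of corresponding residues (e.g. from a flexible
structure alignment) and concatenated, so one joint decomposition describes
them all; per-source reports show how well the shared model fits each
protein.

## Worked example

```bash
python examples/03_domain_decomposition.py
```

prints (three planted rigid bodies, two hinges, no noise):

```
q   captured_fraction   epsilon^2 (A^2)
1   0.0000             0.199
2   0.7610             0.0475
3   1.0000             1.55e-15
4   1.0000             9.79e-16

suggested q (marginal gain < 0.05): 3
Rand index vs planted bodies: 0.979
```

The captured fraction jumps as *q* reaches the number of genuinely rigid
bodies and then plateaus; ε² at the true partition is numerically zero.
The other examples (`examples/01…05`) walk through the fluctuation matrix,
strain-based hinge detection, single-axis recovery and the meta-trajectory
analysis, each printing the numbers it computes and what they mean.

## Command line

```bash
hingescan synth   --spec toy.yaml --out-dir run/       # planted test data
hingescan dfmat   --structure run/synthetic.pdb --out-dir run/
hingescan strain  --structure run/synthetic.pdb --cutoff 5 --width 0.5 --out-dir run/
hingescan qrd     --structure run/synthetic.pdb --scan 1:4 --seed 1 --out-dir run/
hingescan axisfit --structure run/synthetic.pdb --partition run/partition_q3.json \
                  --core 1 --n-orient 500 --seed 7 --out-dir run/
hingescan report  --spec toy.yaml --seed 3 --out-dir run/   # whole pipeline
```

Trajectories are multi-model PDB, or XTC/DCD/TRR with a PDB/GRO topology
(`--traj`); all internal units are Å. Selections use
`tag:<protein> chain:<id> resid:<a>-<b>` terms joined by whitespace (AND)
and `|` (OR). Every run writes a `manifest.json` with sha256 hashes and the
config that produced each artifact; reruns with the same seeds are
byte-identical.

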