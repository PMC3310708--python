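# Methods

This note records the models, conventions and design choices behind
hingescan, in enough detail to reproduce or audit any number the package
prints.

## Distance fluctuations and strain

The fluctuation matrix uses the population variance over the analysed
frames: `A_ij = mean(d_ij^2) - mean(d_ij)^2`, accumulated in frame chunks
so memory stays at O(chunk · N²). `A` is exactly invariant under per-frame
global roto-translations, so no superposition is performed. A `frame_range`
argument (and the CLI's `--discard-frames`) supports dropping an
equilibration transient; the default is all frames.

Strain is the contact-weighted row sum `p_i = Σ_j A_ij · f(⟨d_ij⟩)`. Two
choices here were genuinely open:

* **Form of the switching function.** Only the ~5 Å contact scale is
  physically meaningful; we use the logistic
  `f(x) = 1/(1 + exp((x − cutoff)/width))` with midpoint `cutoff = 5 Å`
  and `width = 0.5 Å` (both exposed). As `width → 0` this reduces to a
  hard 5 Å cutoff (verified against a hard-cutoff oracle in the tests).
* **Argument of the switch.** We evaluate `f` on the *time-mean* distance,
  which fixes the neighbour set for the analysis window and makes `p` a
  weighted row sum of `A`; an instantaneous-distance variant
  (`instantaneous=True`) averages `f(d_ij(t))` over frames instead.

Time-resolved strain uses non-overlapping windows (default 10% of the
trajectory, minimum 2 frames), each evaluated with window-local averages; a
trailing partial window is dropped.

## Rigid-fit objective and normalization

A partition of the N residues into q domains is scored in displacement
form: for each frame and domain, the reference-structure domain is placed
onto the frame by the optimal least-squares rigid transform (Kabsch with
proper rotations, computed by batched 3×3 SVD) and the residual is the
squared deviation of placed vs actual positions, summed over residues,
frames and domains. This is the full-rotation (not small-angle) objective;
a velocity-based formulation is equivalent up to finite differencing and is
not used.

**Normalization convention.** The reported ε² (`residual_msf`) is the mean
squared deviation *per degree of freedom* — per residue, per frame, per
Cartesian coordinate, in Å². With planted rigid motion plus i.i.d.
Gaussian noise of σ per coordinate on both the frames and the (noisy)
reference frame, ε² approaches `2σ²·(1 − O(1/n))`; this noise floor is a
test invariant. `per_frame_rmsd` stays the conventional per-atom RMSD, so
`mean(per_frame_rmsd²) = 3·ε²`.

**Captured fraction.** `1 − ε²/ε²_global`, where ε²_global comes from a
single whole-molecule superposition per frame. The baseline deliberately
removes global drift, so the captured fraction measures what
*domain-relative* rigid motion explains; it is 0 for q = 1 by construction
and pinned to 1 when the baseline itself is ~0 (globally rigid input).
The fixed-axis combined fit uses the same baseline, which makes the
restricted and free captured fractions directly comparable and guarantees
the nesting inequality (restricted ≤ free).

**Reference structure.** `select_reference` superposes all frames onto a
running mean until the mean moves < 1e-6 Å RMSD, then returns the frame
closest to the converged mean (ties to the lowest index). Axis-fit angles
are reported relative to this reference conformation unless an explicit
`reference_frame` is given.

## Partition search

* **Seeding.** Two deterministic candidates are scored by the actual
  rigid-fit objective and the better one kept: (i) average-linkage
  hierarchical clustering of the distance-fluctuation matrix — pairs with
  small distance variance merge first, the intra-domain-rigidity criterion
  directly; (ii) k-means (fixed seed) on essential-dynamics features, each
  residue's components on the top 3 covariance eigenvectors scaled by
  √eigenvalue. The mode features capture correlated motion directions but
  tend to split a rotating domain by displacement amplitude when the hinge
  sweep is gentle; the fluctuation-matrix seed is robust there, which is
  why both are tried. Domains below the 3-residue minimum are repaired by
  pulling the nearest residues in feature space.
* **Annealing.** Single-residue relabel moves; with probability 0.8 the
  move picks a residue with a cross-domain contact (< 8 Å in the
  reference) and proposes a neighbouring domain's label, otherwise a
  uniform random move. Metropolis acceptance on the normalized ε² with
  geometric cooling from 0.2 to 1e-5 Å² over the move budget (default
  50·q·N moves); the best partition seen is kept. Move evaluation is O(T)
  via incrementally maintained Kabsch sufficient statistics per domain
  (coordinate sums and the 3×3 cross matrix per frame), needing only
  singular values and a determinant sign per proposal.
* **Polish and ties.** A greedy pass over boundary residues accepts strict
  improvements until a fixed point. Finally, residues whose relabelling
  changes the objective by ~0 (relative tolerance 1e-9) adopt the majority
  label of their contact neighbours: a residue lying exactly on a hinge
  axis is rigid with respect to *both* adjacent domains, so its label is
  undefined by the data and spatial coherence is the only meaningful
  tie-break.
* **q-scan.** For each q the search runs fresh and, for q > 1, also
  warm-started from the best (q−1) partition with its worst-fitting domain
  bisected; the unrefined warm split itself is kept as a candidate, which
  guarantees the captured fraction is non-decreasing in q (a refinement of
  a partition never fits worse). The suggested q is the smallest whose
  marginal captured-fraction gain falls below 0.05 (configurable) — a
  stand-in figure of merit; inspect the whole table for real systems.
* Domains may be sequence-discontiguous (they are spatial objects); the
  minimum domain size is 3 residues and collinear reference domains are
  rejected (Kabsch well-posedness). Mass weighting is uniform (Cα only).

## Fixed-axis hinge fit

Frames are first superposed onto the reference by the core domain, making
"fixed with respect to the core" literal. For a candidate axis (anchor
point a, unit orientation u) and anchored coordinates x = p − a (reference)
and y = q − a (frame), the summed squared deviation under rotation by θ is
minimized in closed form at `θ* = atan2(S, C)` with
`C = Σ(y·x − (u·x)(u·y))` and `S = Σ y·(u×x)`; the residual needs only
`√(C² + S²)`. The search is the exhaustive product of every Cα anchor
(subsampling optional) × n orientations uniform on the sphere (default
500, seeded), fully vectorized over frames and orientations with chunking
to bound memory. The best discrete axis is then refined by Nelder-Mead on
the two spherical angles (anchor stays on its Cα); both discrete and
refined residuals are reported. The orientation sign is chosen so the mean
angle is non-negative. A static moving domain makes every axis equivalent:
the fit returns zero angles, `captured_fraction = NaN` and a warning.
Per-domain captured fraction is relative to the moving domain's total
mean-square fluctuation in core-fixed coordinates; the *combined* two-hinge
captured fraction predicts the whole molecule (core at reference, side
domains rotated by their fitted angles) against the global-superposition
baseline above.

## Synthetic generator

The generator is the package's ground-truth instrument; it emulates the
geometry of multi-domain proteins, not their physics.

* **Reference geometry.** One compact self-avoiding blob (uniform in a
  sphere, minimum pair distance 3.5 Å ≈ Cα packing) is sliced into slabs
  along x, one per domain. Slicing a single blob — rather than abutting
  independent blobs, which touch at a point — gives extended planar
  interfaces with many cross-domain contacts under 5 Å, the situation the
  strain analysis probes.
* **Motion.** Each frame applies the scheduled rotation of every moving
  domain about its planted axis (a line through a chosen core residue),
  then adds i.i.d. Gaussian noise σ per coordinate (optionally from a
  separate `noise_seed`, so several "homologues" can share one fold while
  sampling independently). Ground truth records the partition, axes,
  per-frame angles and the interface set (residues with a cross-domain
  neighbour < 5 Å in the reference).
* **Study conditions.** The partition-recovery scenario uses three bodies
  of 60/50/70 residues, 100 frames, two hinges with ~50° sweeps anchored
  on core-interior residues, and σ ∈ {0, 0.5 Å}. The sweep amplitude is
  chosen at the scale of large-amplitude chaperone-like domain motions;
  it also sets the radius of the genuinely ambiguous shell around each
  axis (where rigid displacement ≲ noise) — at gentle amplitudes no
  method can label those residues from the data. Core-interior anchors
  keep the planted axes away from cross-domain residues for the same
  reason. The strain scenario uses a two-body hinge anchored *at* the
  interface (where physical hinges sit) with a modest 15° sweep. The
  acceptance study scales the meta-trajectory to 3 sources × 50 frames ×
  120 residues.
* **Not modelled:** chain connectivity, secondary structure, correlated
  (breathing) fluctuations, side chains, solvent. Passing tests therefore
  demonstrate correct recovery of rigid-body kinematics under isotropic
  noise, not robustness to the internally deformable motions of real
  proteins.

## Numerical details and edge cases

* Kabsch uses SVD with the determinant-sign correction; rotations are
  proper to 1e-8 and residuals are clipped at 0 against round-off.
* The fluctuation variance is clipped at 0 and symmetrized; the diagonal
  is exactly 0.
* `optimal_angle` raises if all points lie on the axis (angle undefined);
  `fit_rigid_domains` raises on domains with < 3 residues or collinear
  reference geometry, naming the domain.
* Degenerate covariance (all frames identical) aborts initialization with
  a hint that the input is rigid.
* All stochastic components (orientation sampling, annealing, k-means)
  take explicit seeds; identical seeds give byte-identical artifacts, which
  the pipeline manifest (sha256 per artifact) makes checkable.

## Known limitations

* The annealing move budget (50·q·N) is a heuristic; pathological
  landscapes may need restarts or larger budgets (both configurable).
* The marginal-gain rule for choosing q is a convenience threshold, not a
  statistical test.
* Fixed-axis fitting excludes screw motion (no translation along the
  axis) by design.
* The meta-trajectory weights all sources by their frame counts; optional
  subsampling to equalize contributions is left to the caller.
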