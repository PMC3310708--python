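"""Quasi-rigid domain decomposition of C-alpha trajectories.

A partition of the residues into q domains is scored by the rigid-fit error:
for every frame and every domain, the reference-structure domain is placed
onto the frame by an optimal least-squares rigid superposition (Kabsch, full
rotation matrices — no small-angle linearization), and the residual is the
mean squared deviation between placed and actual positions.  Minimizing this
error over partitions yields domains whose internal geometry is nearly
preserved, i.e. whose motion is almost purely roto-translational.

The search starts from an essential-dynamics seed (clustering residues by
their components on the top covariance eigenvectors) and refines it by
simulated annealing over single-residue relabelling moves, followed by a
greedy polish.

Normalization convention: ``residual_msf`` (the reported epsilon^2) is the
mean squared deviation per degree of freedom — per residue, per frame, per
Cartesian coordinate, in A^2 — so for planted rigid motion plus isotropic
Gaussian noise of sigma per coordinate it approaches the 2*sigma^2 noise
floor.  ``per_frame_rmsd`` is the conventional per-atom RMSD, so
``mean(per_frame_rmsd^2) == 3 * residual_msf``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._geometry import kabsch_batch, rigid_fit_residuals
from .trajectory_io import CalphaTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "RigidFitResult",
    "SearchConfig",
    "select_reference",
    "fit_rigid_domains",
    "initial_partition",
    "search_partition",
    "scan_q",
]

MIN_DOMAIN_SIZE = 3  # rigid fit needs >=3 non-collinear points


@dataclass
class Partition:
    """Assignment of every residue to one of q domain labels (0..q-1)."""

    assignment: np.ndarray
    q: int
    contiguity_required: bool = False

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels, counts = np.unique(self.assignment, return_counts=True)
        if not np.array_equal(labels, np.arange(self.q)):
            raise ValueError(f"assignment must use every label 0..{self.q - 1}")
        if counts.min() < MIN_DOMAIN_SIZE:
            small = labels[counts < MIN_DOMAIN_SIZE]
            raise ValueError(f"domain(s) {small.tolist()} have fewer than {MIN_DOMAIN_SIZE} residues")

    def domain_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == label)

    def to_json(self, path: str | Path, residue_ids=None, extra: Optional[dict] = None) -> None:
        payload = {"q": int(self.q), "assignment": self.assignment.tolist()}
        if residue_ids is not None:
            payload["residue_ids"] = [list(r) for r in residue_ids]
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "Partition":
        payload = json.loads(Path(path).read_text())
        return Partition(assignment=np.array(payload["assignment"]), q=int(payload["q"]))


@dataclass
class RigidFitResult:
    """Per-frame, per-domain rigid placements of the reference and residuals.

    ``rotations[f][l]`` / ``translations[f][l]`` place reference domain l onto
    frame f.  ``residual_msf`` is epsilon^2 per degree of freedom (A^2);
    ``raw_ssd`` is the unnormalized total squared deviation.
    ``captured_fraction = 1 - residual_msf / total_msf`` where total_msf uses
    a single whole-molecule superposition per frame, so it measures what
    domain-relative rigid motion explains beyond a global fit.
    """

    rotations: np.ndarray  # (T, q, 3, 3)
    translations: np.ndarray  # (T, q, 3)
    residual_msf: float
    total_msf: float
    captured_fraction: float
    per_frame_rmsd: np.ndarray  # (T,), per-atom RMSD in A
    reference_frame: int
    raw_ssd: float = 0.0
    per_frame_ssd: np.ndarray = field(default_factory=lambda: np.empty(0))


def _superpose_all(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ref (whole molecule, uniform weights)."""
    R, t = kabsch_batch(ref, coords)
    # place frames onto ref: invert the fit
    Rt = np.swapaxes(R, 1, 2)
    return np.einsum("tij,tnj->tni", Rt, coords - t[:, None, :])


def select_reference(traj: CalphaTrajectory, tol: float = 1e-6, max_iter: int = 100) -> int:
    """Index of the frame closest to the (iteratively converged) mean structure.

    All frames are superposed onto a running mean structure until the mean
    changes by less than ``tol`` A RMSD; the returned frame has minimal RMSD
    to the converged mean, ties broken by lowest index.
    """
    if traj.n_frames < 2:
        raise ValueError("select_reference needs at least 2 frames")
    coords = traj.coords
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = _superpose_all(coords, mean)
        new_mean = aligned.mean(axis=0)
        shift = np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean())
        mean = new_mean
        if shift < tol:
            break
    ssd, _, _ = rigid_fit_residuals(mean, coords)
    rmsd = np.sqrt(ssd / traj.n_residues)
    return int(np.argmin(rmsd))


def _partition_ssd_per_frame(ref: np.ndarray, coords: np.ndarray, assignment: np.ndarray, q: int) -> np.ndarray:
    """Summed squared deviation per frame under per-domain rigid fits."""
    total = np.zeros(coords.shape[0])
    for label in range(q):
        idx = np.flatnonzero(assignment == label)
        ssd, _, _ = rigid_fit_residuals(ref[idx], coords[:, idx, :])
        total += ssd
    return total


def fit_rigid_domains(traj: CalphaTrajectory, partition: Partition, reference_frame: int) -> RigidFitResult:
    """Evaluate the rigid-fit error of a partition with full Kabsch fits."""
    if not (0 <= reference_frame < traj.n_frames):
        raise ValueError("reference_frame out of range")
    if len(partition.assignment) != traj.n_residues:
        raise ValueError("partition does not match trajectory residue count")
    T, N = traj.n_frames, traj.n_residues
    ref = traj.coords[reference_frame]
    rotations = np.zeros((T, partition.q, 3, 3))
    translations = np.zeros((T, partition.q, 3))
    per_frame_ssd = np.zeros(T)
    for label in range(partition.q):
        idx = partition.domain_indices(label)
        dom_ref = ref[idx]
        if np.linalg.matrix_rank(dom_ref - dom_ref.mean(axis=0), tol=1e-8) < 2:
            raise ValueError(f"domain {label}: collinear reference geometry, rigid fit ill-posed")
        ssd, R, t = rigid_fit_residuals(dom_ref, traj.coords[:, idx, :])
        rotations[:, label] = R
        translations[:, label] = t
        per_frame_ssd += ssd

    raw_ssd = float(per_frame_ssd.sum())
    residual_msf = raw_ssd / (T * N * 3)
    per_frame_rmsd = np.sqrt(per_frame_ssd / N)

    global_ssd, _, _ = rigid_fit_residuals(ref, traj.coords)
    total_msf = float(global_ssd.sum()) / (T * N * 3)
    if total_msf < 1e-12:
        captured = 1.0
    else:
        captured = float(np.clip(1.0 - residual_msf / total_msf, 0.0, 1.0))
    return RigidFitResult(
        rotations=rotations,
        translations=translations,
        residual_msf=residual_msf,
        total_msf=total_msf,
        captured_fraction=captured,
        per_frame_rmsd=per_frame_rmsd,
        reference_frame=reference_frame,
        raw_ssd=raw_ssd,
        per_frame_ssd=per_frame_ssd,
    )


def _mode_features(traj: CalphaTrajectory, reference_frame: int, n_modes: int) -> np.ndarray:
    """Per-residue essential-dynamics features: top covariance eigenvectors
    scaled by sqrt(eigenvalue), reshaped to (N, 3*n_modes)."""
    ref = traj.coords[reference_frame]
    aligned = _superpose_all(traj.coords, ref)
    T, N, _ = aligned.shape
    X = aligned.reshape(T, 3 * N)
    X = X - X.mean(axis=0)
    cov_spectrum_rank = min(T - 1, 3 * N)
    if cov_spectrum_rank < 1:
        raise ValueError("not enough frames for covariance analysis")
    # SVD of the centered data matrix: right singular vectors = covariance eigenvectors
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / T
    if eigvals[0] < 1e-12:
        raise ValueError("degenerate covariance: all frames identical (rigid input?)")
    k = min(n_modes, len(eigvals))
    feats = Vt[:k].reshape(k, N, 3) * np.sqrt(eigvals[:k])[:, None, None]
    return np.transpose(feats, (1, 0, 2)).reshape(N, 3 * k)


def _repair_small_domains(assignment: np.ndarray, q: int, feats: np.ndarray) -> np.ndarray:
    """Ensure every label 0..q-1 owns >= MIN_DOMAIN_SIZE residues by pulling
    the nearest residues (feature space) from domains that can spare them."""
    assignment = assignment.copy()
    for label in range(q):
        while (assignment == label).sum() < MIN_DOMAIN_SIZE:
            members = np.flatnonzero(assignment == label)
            centroid = feats[members].mean(axis=0) if members.size else feats.mean(axis=0)
            counts = np.bincount(assignment, minlength=q)
            donors = np.flatnonzero((counts > MIN_DOMAIN_SIZE) & (np.arange(q) != label))
            cand = np.flatnonzero(np.isin(assignment, donors))
            if cand.size == 0:
                raise ValueError("cannot repair partition: not enough residues")
            dist = ((feats[cand] - centroid) ** 2).sum(axis=1)
            assignment[cand[np.argmin(dist)]] = label
    return assignment


def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Deterministic label order regardless of the clustering backend."""
    remap, nxt = {}, 0
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        out[i] = remap[lab]
    return out


def initial_partition(traj: CalphaTrajectory, q: int, n_modes: int = 3, seed: int = 0) -> Partition:
    """Seed partition for the stochastic search.

    Two deterministic candidates are built and the one with the lower
    rigid-fit error is returned:

    * hierarchical average-linkage clustering of the distance-fluctuation
      matrix (residue pairs with small distance variance merge first — the
      intra-domain-rigidity criterion directly);
    * k-means on the essential-dynamics features (each residue's components
      on the top covariance modes, scaled by sqrt eigenvalue).

    The mode features capture correlated directions of motion; the
    fluctuation matrix captures pairwise rigidity.  Which seed is better
    depends on the geometry, so both are scored.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    from sklearn.cluster import KMeans

    from .fluctuation import distance_fluctuation_matrix

    if q < 2:
        raise ValueError("initial_partition requires q >= 2")
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if traj.n_frames <= n_modes:
        raise ValueError("need more frames than modes")
    reference_frame = select_reference(traj)
    feats = _mode_features(traj, reference_frame, n_modes)  # raises on rigid input

    candidates = []
    A = distance_fluctuation_matrix(traj).values
    Z = linkage(squareform(A, checks=False), method="average")
    candidates.append(_relabel_first_occurrence(fcluster(Z, t=q, criterion="maxclust") - 1))

    km = KMeans(n_clusters=q, random_state=seed, n_init=10)
    candidates.append(_relabel_first_occurrence(km.fit_predict(feats)))

    best: tuple[float, Optional[np.ndarray]] = (np.inf, None)
    ref = traj.coords[reference_frame]
    for cand in candidates:
        if len(np.unique(cand)) != q:
            continue
        cand = _repair_small_domains(cand, q, feats)
        ssd = _partition_ssd_per_frame(ref, traj.coords, cand, q).sum()
        if ssd < best[0]:
            best = (float(ssd), cand)
    if best[1] is None:
        raise ValueError(f"could not build an initial partition with q={q}")
    # resolve objective-neutral residues (e.g. exactly on a hinge axis)
    obj = _PartitionObjective(ref, traj.coords, best[1], q)
    counts = np.bincount(obj.assignment, minlength=q)
    neigh = _neighbor_lists(ref, cutoff=8.0)
    _tie_pass(obj, counts, neigh, q, tie_tol=1e-9 * traj.coords.shape[0] * traj.n_residues * 3)
    return Partition(assignment=obj.assignment, q=q)


@dataclass
class SearchConfig:
    """Stochastic partition-search settings.

    ``moves`` defaults to 50 * q * N.  Temperatures are in the units of the
    objective (A^2 per degree of freedom); geometric cooling.
    ``boundary_bias`` is the probability of proposing a relabel of a residue
    that touches (within ``contact_cutoff`` A in the reference) another
    domain, toward a neighbouring domain's label.
    """

    seed: int = 0
    moves: Optional[int] = None
    t_start: float = 0.2
    t_end: float = 1e-5
    boundary_bias: float = 0.8
    contact_cutoff: float = 8.0
    n_modes: int = 3
    polish_rounds: int = 20


class _PartitionObjective:
    """Incremental evaluation of the rigid-fit objective under relabels.

    Per domain l it maintains the sufficient statistics of the Kabsch
    problem over all frames — residue count n, sum of reference coordinates
    sx, sum of squared reference coordinates sxx, per-frame coordinate sums
    sy and squared sums syy, and the per-frame raw cross matrix
    M_t = sum_i x_i y_ti^T — so relabelling one residue is an O(T) update.
    The summed squared deviation then needs only singular *values*:

        H_t = M_t - sx sy_t^T / n
        ssd_t = (sxx - |sx|^2/n) + (syy_t - |sy_t|^2/n)
                - 2 (s1 + s2 + sign(det H_t) s3)
    """

    def __init__(self, ref: np.ndarray, coords: np.ndarray, assignment: np.ndarray, q: int):
        self.ref = ref
        self.coords = coords  # (T, N, 3)
        self.q = q
        self.assignment = assignment.copy()
        T, N, _ = coords.shape
        # per-residue building blocks
        self._y_sq = (coords**2).sum(axis=2)  # (T, N)
        self._outer = np.einsum("na,tnb->tnab", ref, coords)  # (T, N, 3, 3)
        self._x_sq = (ref**2).sum(axis=1)  # (N,)
        self._stats = [self._collect(np.flatnonzero(self.assignment == lab)) for lab in range(q)]
        self.domain_ssd = np.array([self._ssd_from_stats(st) for st in self._stats])

    def _collect(self, idx: np.ndarray) -> dict:
        return {
            "n": int(idx.size),
            "sx": self.ref[idx].sum(axis=0),
            "sxx": float(self._x_sq[idx].sum()),
            "sy": self.coords[:, idx, :].sum(axis=1),
            "syy": self._y_sq[:, idx].sum(axis=1),
            "M": self._outer[:, idx].sum(axis=1),
        }

    @staticmethod
    def _shifted(st: dict, sign: float, sx_i, sxx_i, sy_i, syy_i, M_i) -> dict:
        return {
            "n": st["n"] + int(sign),
            "sx": st["sx"] + sign * sx_i,
            "sxx": st["sxx"] + sign * sxx_i,
            "sy": st["sy"] + sign * sy_i,
            "syy": st["syy"] + sign * syy_i,
            "M": st["M"] + sign * M_i,
        }

    def _ssd_from_stats(self, st: dict) -> float:
        n = st["n"]
        if n == 0:
            return 0.0
        H = st["M"] - np.einsum("a,tb->tab", st["sx"] / n, st["sy"])
        s = np.linalg.svd(H, compute_uv=False)
        s[:, 2] *= np.sign(np.linalg.det(H))
        e0 = (st["sxx"] - st["sx"] @ st["sx"] / n) + (st["syy"] - (st["sy"] ** 2).sum(axis=1) / n)
        return float(np.maximum(e0 - 2.0 * s.sum(axis=1), 0.0).sum())

    @property
    def total(self) -> float:
        return float(self.domain_ssd.sum())

    def _residue_blocks(self, residue: int):
        return (
            self.ref[residue],
            float(self._x_sq[residue]),
            self.coords[:, residue, :],
            self._y_sq[:, residue],
            self._outer[:, residue],
        )

    def try_move(self, residue: int, new_label: int):
        """Objective delta if residue is relabelled; returns (delta, state)."""
        old_label = int(self.assignment[residue])
        blocks = self._residue_blocks(residue)
        st_old = self._shifted(self._stats[old_label], -1.0, *blocks)
        st_new = self._shifted(self._stats[new_label], +1.0, *blocks)
        ssd_old = self._ssd_from_stats(st_old)
        ssd_new = self._ssd_from_stats(st_new)
        delta = (ssd_old + ssd_new) - (self.domain_ssd[old_label] + self.domain_ssd[new_label])
        return delta, (old_label, new_label, st_old, st_new, ssd_old, ssd_new)

    def commit(self, residue: int, state) -> None:
        old_label, new_label, st_old, st_new, ssd_old, ssd_new = state
        self.assignment[residue] = new_label
        self._stats[old_label] = st_old
        self._stats[new_label] = st_new
        self.domain_ssd[old_label] = ssd_old
        self.domain_ssd[new_label] = ssd_new


def _tie_pass(obj: "_PartitionObjective", counts: np.ndarray, neigh: list[np.ndarray],
              q: int, tie_tol: float, rounds: int = 2) -> None:
    """Resolve objective-neutral labels by contact-neighbour majority.

    Residues exactly on a hinge axis (or otherwise motionless relative to
    two domains) change the objective by ~0 under relabelling; spatial
    coherence is the only meaningful criterion left for them.
    """
    N = len(obj.assignment)
    for _ in range(rounds):
        changed = False
        for res in range(N):
            old_label = obj.assignment[res]
            if counts[old_label] <= MIN_DOMAIN_SIZE or not neigh[res].size:
                continue
            labs = obj.assignment[neigh[res]]
            majority = int(np.bincount(labs, minlength=q).argmax())
            if majority == old_label:
                continue
            delta, state = obj.try_move(res, majority)
            if abs(delta) <= tie_tol:
                obj.commit(res, state)
                counts[old_label] -= 1
                counts[majority] += 1
                changed = True
        if not changed:
            break


def _neighbor_lists(ref: np.ndarray, cutoff: float) -> list[np.ndarray]:
    from scipy.spatial import cKDTree

    tree = cKDTree(ref)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    neigh = [[] for _ in range(len(ref))]
    for i, j in pairs:
        neigh[i].append(j)
        neigh[j].append(i)
    return [np.array(v, dtype=int) for v in neigh]


def search_partition(
    traj: CalphaTrajectory,
    q: int,
    config: SearchConfig = SearchConfig(),
    start: Optional[Partition] = None,
    reference_frame: Optional[int] = None,
) -> tuple[Partition, RigidFitResult]:
    """Minimize the rigid-fit error over partitions by simulated annealing.

    Starts from ``start`` (default: the essential-dynamics seed), proposes
    single-residue relabels with boundary residues preferred, anneals on the
    normalized epsilon^2, keeps the best partition seen, then polishes
    greedily until no single-residue move improves.  Deterministic given
    ``config.seed``.  q = 1 short-circuits to the trivial partition.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    N = traj.n_residues
    if reference_frame is None:
        reference_frame = select_reference(traj)
    if q == 1:
        part = Partition(assignment=np.zeros(N, dtype=int), q=1)
        return part, fit_rigid_domains(traj, part, reference_frame)
    if q * MIN_DOMAIN_SIZE > N:
        raise ValueError(f"q={q} needs at least {q * MIN_DOMAIN_SIZE} residues")

    rng = np.random.default_rng(config.seed)
    if start is None:
        start = initial_partition(traj, q, n_modes=config.n_modes, seed=config.seed)
    ref = traj.coords[reference_frame]
    coords = traj.coords
    obj = _PartitionObjective(ref, coords, start.assignment, q)
    neigh = _neighbor_lists(ref, config.contact_cutoff)

    n_moves = config.moves if config.moves is not None else 50 * q * N
    norm = coords.shape[0] * N * 3
    best_assignment = obj.assignment.copy()
    best_total = obj.total
    counts = np.bincount(obj.assignment, minlength=q)

    temps = config.t_start * (config.t_end / config.t_start) ** (np.arange(n_moves) / max(n_moves - 1, 1))
    for step in range(n_moves):
        if rng.random() < config.boundary_bias:
            # boundary move: residue with a cross-domain contact -> neighbour label
            res = int(rng.integers(N))
            labs = obj.assignment[neigh[res]] if neigh[res].size else np.empty(0, dtype=int)
            other = np.unique(labs[labs != obj.assignment[res]])
            if other.size == 0:
                continue
            new_label = int(rng.choice(other))
        else:
            res = int(rng.integers(N))
            new_label = int(rng.integers(q))
        old_label = obj.assignment[res]
        if new_label == old_label or counts[old_label] <= MIN_DOMAIN_SIZE:
            continue
        delta, state = obj.try_move(res, new_label)
        if delta <= 0 or rng.random() < np.exp(-delta / norm / max(temps[step], 1e-300)):
            obj.commit(res, state)
            counts[old_label] -= 1
            counts[new_label] += 1
            if obj.total < best_total - 1e-12:
                best_total = obj.total
                best_assignment = obj.assignment.copy()

    # greedy polish from the best state: boundary moves, strict improvement only
    obj = _PartitionObjective(ref, coords, best_assignment, q)
    counts = np.bincount(obj.assignment, minlength=q)
    for _ in range(config.polish_rounds):
        improved = False
        for res in range(N):
            old_label = obj.assignment[res]
            if counts[old_label] <= MIN_DOMAIN_SIZE:
                continue
            labs = obj.assignment[neigh[res]] if neigh[res].size else np.empty(0, dtype=int)
            for new_label in np.unique(labs[labs != old_label]):
                delta, state = obj.try_move(res, int(new_label))
                if delta < -1e-12:
                    obj.commit(res, state)
                    counts[old_label] -= 1
                    counts[new_label] += 1
                    improved = True
                    break
        if not improved:
            break

    _tie_pass(obj, counts, neigh, q, tie_tol=1e-9 * norm)

    part = Partition(assignment=obj.assignment, q=q)
    return part, fit_rigid_domains(traj, part, reference_frame)


def _split_worst_domain(
    traj: CalphaTrajectory, part: Partition, fit: RigidFitResult, seed: int, n_modes: int
) -> Optional[Partition]:
    """Candidate (q+1)-partition: bisect the domain with the largest residual."""
    from sklearn.cluster import KMeans

    ref = traj.coords[fit.reference_frame]
    worst, worst_ssd = -1, -1.0
    for label in range(part.q):
        idx = part.domain_indices(label)
        if idx.size < 2 * MIN_DOMAIN_SIZE:
            continue
        ssd, _, _ = rigid_fit_residuals(ref[idx], traj.coords[:, idx, :])
        if ssd.sum() > worst_ssd:
            worst, worst_ssd = label, float(ssd.sum())
    if worst < 0:
        return None
    idx = part.domain_indices(worst)
    feats = _mode_features(traj, fit.reference_frame, n_modes)[idx]
    labels = KMeans(n_clusters=2, random_state=seed, n_init=10).fit_predict(feats)
    if min((labels == 0).sum(), (labels == 1).sum()) < MIN_DOMAIN_SIZE:
        return None
    assignment = part.assignment.copy()
    assignment[idx[labels == 1]] = part.q
    return Partition(assignment=assignment, q=part.q + 1)


def scan_q(
    traj: CalphaTrajectory,
    q_values: Sequence[int],
    config: SearchConfig = SearchConfig(),
    gain_threshold: float = 0.05,
) -> dict:
    """Run the partition search over a range of q and pick the smallest q
    whose marginal captured-fraction gain falls below ``gain_threshold``.

    q+1 is warm-started by bisecting the worst domain of the best q result,
    which guarantees captured_fraction is non-decreasing in q.
    """
    q_values = sorted(set(int(v) for v in q_values))
    if not q_values or q_values[0] < 1:
        raise ValueError("q_values must be non-empty, each >= 1")
    reference_frame = select_reference(traj)
    rows = []
    results: dict[int, tuple[Partition, RigidFitResult]] = {}
    prev: Optional[tuple[Partition, RigidFitResult]] = None
    for q in q_values:
        candidates: list[tuple[Partition, RigidFitResult]] = []
        if q == 1:
            candidates.append(search_partition(traj, 1, config, reference_frame=reference_frame))
        else:
            try:
                candidates.append(search_partition(traj, q, config, reference_frame=reference_frame))
            except ValueError as exc:
                logger.warning("fresh search failed for q=%d: %s", q, exc)
            if prev is not None and prev[0].q == q - 1:
                warm = _split_worst_domain(traj, prev[0], prev[1], config.seed, config.n_modes)
                if warm is not None:
                    candidates.append(
                        search_partition(traj, q, config, start=warm, reference_frame=reference_frame)
                    )
                    # the unrefined warm split itself is also a valid candidate and
                    # certifies monotonicity (a refinement of q never fits worse)
                    candidates.append((warm, fit_rigid_domains(traj, warm, reference_frame)))
        if not candidates:
            raise ValueError(f"no valid partition for q={q}")
        best = min(candidates, key=lambda c: c[1].residual_msf)
        results[q] = best
        rows.append({"q": q, "captured_fraction": best[1].captured_fraction, "epsilon2": best[1].residual_msf})
        prev = best

    suggested = q_values[-1]
    for i in range(1, len(rows)):
        if rows[i]["captured_fraction"] - rows[i - 1]["captured_fraction"] < gain_threshold:
            suggested = rows[i - 1]["q"]
            break
    return {"table": rows, "suggested_q": suggested, "results": results}
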