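"""Distance-fluctuation matrices and minimum-distance time series.

The central object is the matrix A of pairwise distance fluctuations:
``A_ij = <(d_ij - <d_ij>)^2>`` where ``d_ij`` is the instantaneous C-alpha
distance of residues i and j and angle brackets are time averages over the
analysed frames.  A is invariant under per-frame global roto-translations,
so no superposition is performed or needed.  Quasi-rigid domains show up as
low-fluctuation blocks of A.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .trajectory_io import AtomSelection, CalphaTrajectory

__all__ = [
    "DistanceFluctuationMatrix",
    "DistanceSeries",
    "distance_fluctuation_matrix",
    "mean_distance_matrix",
    "block_summary",
    "min_distance_series",
]

_FRAME_CHUNK = 64  # frames per accumulation block; bounds the frames x pairs working set


@dataclass
class DistanceFluctuationMatrix:
    """Symmetric residue x residue matrix of distance variances (A^2)."""

    values: np.ndarray
    residue_ids: list[tuple[str, str, int, str]]
    frame_range: tuple[int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("values must be symmetric within 1e-10")
        if np.abs(np.diag(v)).max() > 1e-10 or v.min() < -1e-12:
            raise ValueError("diagonal must be zero and entries non-negative")
        self.values = v

    def save_tsv(self, path: str | Path) -> None:
        """Upper triangle as ``i<TAB>j<TAB>A_ij`` (0-based residue indices)."""
        n = self.values.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        with open(path, "w") as fh:
            fh.write("i\tj\tA_ij\n")
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{self.values[i, j]:.10g}\n")


@dataclass
class DistanceSeries:
    """Per-frame minimum distance between two residue selections (A)."""

    per_frame_min: np.ndarray
    selection_a: AtomSelection
    selection_b: AtomSelection

    @property
    def final_value(self) -> float:
        return float(self.per_frame_min[-1])

    @property
    def average_value(self) -> float:
        return float(self.per_frame_min.mean())


def _resolve_range(traj: CalphaTrajectory, frame_range: Optional[tuple[int, int]]) -> tuple[int, int]:
    if frame_range is None:
        return 0, traj.n_frames - 1
    first, last = frame_range
    if not (0 <= first <= last < traj.n_frames):
        raise ValueError(f"frame_range {frame_range} outside trajectory of {traj.n_frames} frames")
    return first, last


def _pairwise_distances(frame_coords: np.ndarray) -> np.ndarray:
    diff = frame_coords[:, :, None, :] - frame_coords[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def distance_fluctuation_matrix(
    traj: CalphaTrajectory, frame_range: Optional[tuple[int, int]] = None
) -> DistanceFluctuationMatrix:
    """Compute A over the selected frames (population variance per pair).

    Accumulates first and second moments of d_ij in frame chunks, so memory
    stays at O(chunk * N^2) for N residues.
    """
    first, last = _resolve_range(traj, frame_range)
    n_frames = last - first + 1
    if n_frames < 2:
        raise ValueError("need at least 2 frames to compute distance fluctuations")
    n = traj.n_residues
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    for start in range(first, last + 1, _FRAME_CHUNK):
        stop = min(start + _FRAME_CHUNK, last + 1)
        d = _pairwise_distances(traj.coords[start:stop])
        s1 += d.sum(axis=0)
        s2 += (d**2).sum(axis=0)
    mean = s1 / n_frames
    var = s2 / n_frames - mean**2
    var = np.maximum(var, 0.0)  # clip tiny negative round-off
    var = 0.5 * (var + var.T)
    np.fill_diagonal(var, 0.0)
    return DistanceFluctuationMatrix(values=var, residue_ids=list(traj.residue_ids), frame_range=(first, last))


def mean_distance_matrix(
    traj: CalphaTrajectory, frame_range: Optional[tuple[int, int]] = None
) -> np.ndarray:
    """Time-mean C-alpha distance matrix over the selected frames (A)."""
    first, last = _resolve_range(traj, frame_range)
    n_frames = last - first + 1
    n = traj.n_residues
    s1 = np.zeros((n, n))
    for start in range(first, last + 1, _FRAME_CHUNK):
        stop = min(start + _FRAME_CHUNK, last + 1)
        s1 += _pairwise_distances(traj.coords[start:stop]).sum(axis=0)
    return s1 / n_frames


def block_summary(matrix: DistanceFluctuationMatrix, range_a, range_b) -> float:
    """Mean of A_ij over i in range_a, j in range_b (0-based index iterables).

    Diagonal entries are excluded when the ranges overlap.
    """
    ia = np.asarray(list(range_a), dtype=int)
    ib = np.asarray(list(range_b), dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("block_summary ranges must be non-empty")
    sub = matrix.values[np.ix_(ia, ib)]
    mask = ia[:, None] != ib[None, :]
    if not mask.any():
        raise ValueError("block_summary ranges contain only diagonal entries")
    return float(sub[mask].mean())


def min_distance_series(
    traj: CalphaTrajectory, sel_a: AtomSelection | str, sel_b: AtomSelection | str
) -> DistanceSeries:
    """Per-frame minimum distance between the closest pair across selections."""
    if isinstance(sel_a, str):
        sel_a = AtomSelection.resolve(sel_a, traj)
    if isinstance(sel_b, str):
        sel_b = AtomSelection.resolve(sel_b, traj)
    ia, ib = sel_a.resolved_indices, sel_b.resolved_indices
    if np.intersect1d(ia, ib).size:
        raise ValueError("min_distance_series selections must be disjoint")
    a = traj.coords[:, ia, :]
    b = traj.coords[:, ib, :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DistanceSeries(per_frame_min=d.min(axis=(1, 2)), selection_a=sel_a, selection_b=sel_b)
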