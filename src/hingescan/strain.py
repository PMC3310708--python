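"""Per-residue geometric strain profiles.

The strain of residue i measures how much its local (~5 A) contact network
deforms over the trajectory:

    p_i = sum_{j != i} A_ij * f(<d_ij>)

where A is the distance-fluctuation matrix, <d_ij> the time-mean C-alpha
distance and f a logistic switching function with midpoint at the contact
cutoff.  Hinge regions between quasi-rigid domains show up as strain peaks:
their neighbourhood straddles domains whose relative motion stretches and
compresses the local contacts.

Weighting by the *time-mean* distance fixes the neighbour set once per
analysis window, which makes p a weighted row-sum of A; an
instantaneous-distance variant is available via ``instantaneous=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .fluctuation import _FRAME_CHUNK, _pairwise_distances, distance_fluctuation_matrix, mean_distance_matrix
from .trajectory_io import CalphaTrajectory

__all__ = ["SigmoidParams", "StrainProfile", "sigmoid_weight", "strain_profile", "strain_time_resolved"]


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic contact weight f(x) = 1 / (1 + exp((x - cutoff) / width)).

    ``cutoff`` (A) is the midpoint — contacts within about this distance
    contribute; ``width`` (A) sets the softness of the boundary.
    """

    cutoff: float = 5.0
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.width <= 0:
            raise ValueError("cutoff and width must be positive")


@dataclass
class StrainProfile:
    """Per-residue geometric strain (A^2), optionally time-resolved."""

    per_residue: np.ndarray
    sigmoid: SigmoidParams
    per_residue_per_window: Optional[np.ndarray] = None
    window_length_frames: Optional[int] = None

    def top_residues(self, k: int = 5) -> np.ndarray:
        """Indices of the k highest-strain residues, descending."""
        order = np.argsort(self.per_residue)[::-1]
        return order[:k]

    def save_tsv(self, path: str | Path, residue_ids=None) -> None:
        with open(path, "w") as fh:
            fh.write("residue_number\tp_i\n")
            for i, p in enumerate(self.per_residue):
                num = residue_ids[i][2] if residue_ids is not None else i + 1
                fh.write(f"{num}\t{p:.10g}\n")


def sigmoid_weight(x, params: SigmoidParams = SigmoidParams()):
    """Contact weight in [0, 1]; 0.5 at the cutoff, ~1 near zero distance."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> weight 0, exact
        return 1.0 / (1.0 + np.exp((x - params.cutoff) / params.width))


def strain_profile(
    traj: CalphaTrajectory,
    params: SigmoidParams = SigmoidParams(),
    frame_range: Optional[tuple[int, int]] = None,
    instantaneous: bool = False,
) -> StrainProfile:
    """Time-averaged strain profile p_i over the selected frames.

    With ``instantaneous=True`` the contact weight is evaluated on the
    instantaneous distance in every frame and averaged, instead of on the
    time-mean distance.
    """
    if instantaneous:
        p = _strain_instantaneous(traj, params, frame_range)
        return StrainProfile(per_residue=p, sigmoid=params)
    A = distance_fluctuation_matrix(traj, frame_range)
    dmean = mean_distance_matrix(traj, frame_range)
    w = sigmoid_weight(dmean, params)
    np.fill_diagonal(w, 0.0)
    return StrainProfile(per_residue=(A.values * w).sum(axis=1), sigmoid=params)


def _strain_instantaneous(traj, params, frame_range):
    from .fluctuation import _resolve_range

    first, last = _resolve_range(traj, frame_range)
    n_frames = last - first + 1
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    A = distance_fluctuation_matrix(traj, (first, last)).values
    n = traj.n_residues
    wsum = np.zeros((n, n))
    for start in range(first, last + 1, _FRAME_CHUNK):
        stop = min(start + _FRAME_CHUNK, last + 1)
        wsum += sigmoid_weight(_pairwise_distances(traj.coords[start:stop]), params).sum(axis=0)
    w = wsum / n_frames
    np.fill_diagonal(w, 0.0)
    return (A * w).sum(axis=1)


def strain_time_resolved(
    traj: CalphaTrajectory,
    params: SigmoidParams = SigmoidParams(),
    window_frames: Optional[int] = None,
) -> StrainProfile:
    """Strain evaluated per non-overlapping window of frames.

    Each window uses only its own frames for both the fluctuation matrix and
    the mean distances, so the profile tracks slow changes in the deformation
    pattern.  ``window_frames`` defaults to 10% of the trajectory (>= 2).
    A trailing remainder shorter than a full window is dropped.
    """
    if window_frames is None:
        window_frames = max(2, traj.n_frames // 10)
    if window_frames < 2 or window_frames > traj.n_frames:
        raise ValueError(f"window_frames={window_frames} out of range for {traj.n_frames} frames")
    n_windows = traj.n_frames // window_frames
    rows = []
    for w in range(n_windows):
        first = w * window_frames
        prof = strain_profile(traj, params, frame_range=(first, first + window_frames - 1))
        rows.append(prof.per_residue)
    per_window = np.vstack(rows)
    overall = strain_profile(traj, params)
    return StrainProfile(
        per_residue=overall.per_residue,
        sigmoid=params,
        per_residue_per_window=per_window,
        window_length_frames=window_frames,
    )
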