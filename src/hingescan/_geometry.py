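"""Rigid-body geometry primitives: Kabsch superposition and axis rotations.

All routines operate on coordinates in Angstroms.  The batch Kabsch variant
is the inner loop of the quasi-rigid fit, so it is fully vectorized over
frames (one batched 3x3 SVD instead of a Python loop).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch",
    "kabsch_batch",
    "rigid_fit_residuals",
    "apply_rigid",
    "rotation_about_axis",
]


def kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ ref_i + t ~= mov_i.

    Least-squares over points with uniform weights; R is proper
    (det R = +1, reflections excluded).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    H = (ref - cr).T @ (mov - cm)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cm - R @ cr
    return R, t


def kabsch_batch(ref: np.ndarray, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch of one reference point set onto every frame.

    Parameters
    ----------
    ref : (n, 3) reference coordinates.
    frames : (T, n, 3) per-frame coordinates.

    Returns
    -------
    R : (T, 3, 3) proper rotations, t : (T, 3) translations, such that
    ``R[f] @ ref_i + t[f]`` best matches ``frames[f, i]``.
    """
    ref = np.asarray(ref, dtype=float)
    frames = np.asarray(frames, dtype=float)
    cr = ref.mean(axis=0)
    cf = frames.mean(axis=1)
    refc = ref - cr
    framec = frames - cf[:, None, :]
    H = np.einsum("ni,tnj->tij", refc, framec)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("tij,tkj->tik", np.swapaxes(Vt, 1, 2), np.swapaxes(U, 1, 2)))
    D = np.repeat(np.eye(3)[None], len(frames), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("tji,tjk,tlk->til", Vt, D, U)
    t = cf - np.einsum("tij,j->ti", R, cr)
    return R, t


def rigid_fit_residuals(ref: np.ndarray, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame summed squared residual of the optimal rigid fit.

    Returns ``(ssd, R, t)`` where ``ssd[f] = sum_i |R[f] ref_i + t[f] - frames[f,i]|^2``.
    Uses the trace identity ssd = E0 - 2 * sum(corrected singular values),
    avoiding materializing the placed coordinates.
    """
    ref = np.asarray(ref, dtype=float)
    frames = np.asarray(frames, dtype=float)
    cr = ref.mean(axis=0)
    cf = frames.mean(axis=1)
    refc = ref - cr
    framec = frames - cf[:, None, :]
    H = np.einsum("ni,tnj->tij", refc, framec)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("tij,tkj->tik", np.swapaxes(Vt, 1, 2), np.swapaxes(U, 1, 2)))
    S_corr = S.copy()
    S_corr[:, 2] *= np.sign(det)
    E0 = (refc**2).sum() + (framec**2).sum(axis=(1, 2))
    ssd = np.maximum(E0 - 2.0 * S_corr.sum(axis=1), 0.0)
    D = np.repeat(np.eye(3)[None], len(frames), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("tji,tjk,tlk->til", Vt, D, U)
    t = cf - np.einsum("tij,j->ti", R, cr)
    return ssd, R, t


def apply_rigid(R: np.ndarray, t: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply rotation+translation to an (n, 3) or (T, n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        return coords @ np.asarray(R).T + t
    return np.einsum("tij,tnj->tni", R, coords) + np.asarray(t)[:, None, :]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle in degrees."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
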