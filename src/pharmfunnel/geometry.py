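"""Rigid-body geometry: Kabsch superposition and transform application.

All coordinates are in Angstrom. Rotations returned here are always proper
(det = +1); reflections are explicitly disallowed because pharmacophore
matching must distinguish enantiomeric feature arrangements.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "apply_transform", "rmsd"]


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``P`` onto ``Q``.

    Solves ``min_{R,t} sum_i ||R @ P_i + t - Q_i||^2`` over proper rotations
    (det R = +1) by SVD of the covariance matrix, with the usual sign
    correction that forbids reflections.

    Parameters
    ----------
    P, Q : (n, 3) arrays
        Paired coordinates, n >= 3, finite.

    Returns
    -------
    rotation : (3, 3) array
        Proper rotation matrix.
    translation : (3,) array
        Translation vector; the transform is ``x -> R @ x + t``.
    rmsd : float
        Root-mean-square deviation of the superposed points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects matched (n, 3) coordinate arrays")
    if P.shape[0] < 3:
        raise ValueError("kabsch requires at least 3 point pairs")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("coordinates must be finite")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    value = rmsd(moved, Q)
    return R, t, value


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R @ x + t`` to an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    return coords @ np.asarray(rotation).T + np.asarray(translation)


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Plain (unweighted) RMSD between paired coordinate arrays."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
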