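"""Planar geometry and angle arithmetic shared across the package.

All angles are in degrees, measured counterclockwise from the positive
x-axis (east). Signed angles (turns, local directions) live on the
half-open interval (-180, 180]; absolute directions on [0, 360).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_signed_deg",
    "wrap_unsigned_deg",
    "direction_deg",
    "unit_vector",
    "rotation_matrix",
    "rigid_superpose",
]


def wrap_signed_deg(angle):
    """Normalize an angle (scalar or array) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    # a % 360 lies in [0, 360); shifting the (180, 360) part keeps 180 itself.
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def wrap_unsigned_deg(angle):
    """Normalize an angle (scalar or array) to the interval [0, 360)."""
    w = np.mod(np.asarray(angle, dtype=float), 360.0)
    # guard against -1e-16 % 360 -> 360.0 under rounding
    w = np.where(w >= 360.0, w - 360.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def direction_deg(p, q) -> float:
    """Global direction of the vector from point ``p`` to point ``q``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    if not np.any(d):
        raise ValueError("direction undefined for coincident points")
    return float(np.degrees(np.arctan2(d[1], d[0])))


def unit_vector(heading_deg: float) -> np.ndarray:
    """Unit vector pointing along ``heading_deg``."""
    r = np.radians(heading_deg)
    return np.array([np.cos(r), np.sin(r)])


def rotation_matrix(angle_deg: float) -> np.ndarray:
    r = np.radians(angle_deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


def rigid_superpose(P: np.ndarray, Q: np.ndarray, allow_reflection: bool = False):
    """Optimal rigid superposition of point set ``P`` onto ``Q`` (Kabsch).

    Finds rotation ``R`` (orthogonal; a proper rotation unless
    ``allow_reflection``) and translation ``t`` minimizing
    ``sum_i || R p_i + t - q_i ||^2``. No scaling is applied.

    Returns
    -------
    R : (2, 2) ndarray
    t : (2,) ndarray
    rmsd : float
        Root-mean-square residual distance after superposition.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("point sets must both be (n, 2) arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    V = Vt.T
    D = np.eye(2)
    if not allow_reflection and np.linalg.det(V @ U.T) < 0:
        D[1, 1] = -1.0
    R = V @ D @ U.T
    t = qc - R @ pc
    resid = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rmsd
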