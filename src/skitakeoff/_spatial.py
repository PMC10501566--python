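"""Spatial (6-D) vector algebra for rigid-body dynamics.

Plücker coordinates with the angular component first: a motion vector is
``[omega; v]`` and a force vector ``[n; f]``, both expressed in a body-fixed
frame at the body origin.  Conventions follow Featherstone's *Rigid Body
Dynamics Algorithms* (motion transform ``X`` maps parent-frame motion vectors
into the child frame; forces transform with ``X.T`` in the opposite
direction).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "skew",
    "rot_axis",
    "xform",
    "crm",
    "crf",
    "spatial_inertia",
]


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ u == np.cross(v, u)."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rot_axis(axis: np.ndarray, q: float) -> np.ndarray:
    """Rotation matrix about a unit axis by angle q (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    K = skew(a)
    return np.eye(3) + np.sin(q) * K + (1.0 - np.cos(q)) * (K @ K)


def xform(E: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Motion transform child <- parent.

    ``E`` rotates parent coordinates into child coordinates and ``r`` is the
    child origin expressed in the parent frame.
    """
    X = np.zeros((6, 6))
    X[:3, :3] = E
    X[3:, 3:] = E
    X[3:, :3] = -E @ skew(r)
    return X


def crm(v: np.ndarray) -> np.ndarray:
    """Spatial cross product operator for motion vectors (v x m)."""
    w, vo = v[:3], v[3:]
    M = np.zeros((6, 6))
    M[:3, :3] = skew(w)
    M[3:, 3:] = skew(w)
    M[3:, :3] = skew(vo)
    return M


def crf(v: np.ndarray) -> np.ndarray:
    """Spatial cross product operator for force vectors (v x* f)."""
    return -crm(v).T


def spatial_inertia(mass: float, com: np.ndarray, I_com: np.ndarray) -> np.ndarray:
    """6x6 spatial inertia about the body origin.

    ``com`` is the centre of mass offset in body coordinates and ``I_com`` the
    rotational inertia about the centre of mass in body coordinates.
    """
    C = skew(com)
    I = np.zeros((6, 6))
    I[:3, :3] = I_com + mass * (C @ C.T)
    I[:3, 3:] = mass * C
    I[3:, :3] = mass * C.T
    I[3:, 3:] = mass * np.eye(3)
    return I
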