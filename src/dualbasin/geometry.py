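"""Vectorized bond/angle/dihedral geometry shared by builder, energy and analysis."""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_lengths",
    "bend_angles",
    "torsion_angles",
    "wrap_angle",
    "rotation_matrix",
    "random_rotation",
]


def bond_lengths(positions: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Distances |r_j - r_i| for index pairs ``idx`` of shape (n, 2)."""
    idx = np.asarray(idx, int).reshape(-1, 2)
    d = positions[idx[:, 1]] - positions[idx[:, 0]]
    return np.linalg.norm(d, axis=-1)


def bend_angles(positions: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Angles i-j-k in radians for index triples ``idx`` of shape (n, 3)."""
    idx = np.asarray(idx, int).reshape(-1, 3)
    u = positions[idx[:, 0]] - positions[idx[:, 1]]
    v = positions[idx[:, 2]] - positions[idx[:, 1]]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cos = np.einsum("ij,ij->i", u, v) / np.clip(nu * nv, 1e-300, None)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def torsion_angles(positions: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Dihedral angles i-j-k-l in radians (atan2 convention, range (-pi, pi])."""
    idx = np.asarray(idx, int).reshape(-1, 4)
    b1 = positions[idx[:, 1]] - positions[idx[:, 0]]
    b2 = positions[idx[:, 2]] - positions[idx[:, 1]]
    b3 = positions[idx[:, 3]] - positions[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.clip(np.linalg.norm(b2, axis=-1, keepdims=True), 1e-300, None))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (-pi, pi]."""
    return np.mod(np.asarray(delta) + np.pi, 2.0 * np.pi) - np.pi


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` (need not be normalized)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
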