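"""Small geometric utilities shared across modules."""

from __future__ import annotations

import numpy as np


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly distributed unit vectors (golden-spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def normalized_inertia(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Sorted principal moments of inertia, normalized to sum to one."""
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        masses = np.ones(len(coords))
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    x = coords - com
    r2 = (x**2).sum(axis=1)
    I = np.diag((masses * r2).sum() * np.ones(3)) - (masses[:, None, None] *
                                                     x[:, :, None] * x[:, None, :]).sum(axis=0)
    vals = np.sort(np.linalg.eigvalsh(I))
    total = vals.sum()
    if total <= 0:
        return np.full(3, 1 / 3)
    return vals / total
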