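"""Small vector-geometry helpers shared across modules (angstrom units)."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def angle_between(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in radians."""
    u = unit(p1 - p2)
    v = unit(p3 - p2)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion p1-p2-p3-p4 in radians, in (-pi, pi]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return float(np.arctan2(y, x))


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    a = unit(np.asarray(axis, dtype=float))
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising |R@moving + t - target|.

    Both arrays are (n, 3).  The returned rotation always has det(R) = +1,
    so handedness is preserved (mirrors must be applied explicitly).
    """
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    H = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def wrap_angle(theta: float) -> float:
    """Map an angle in radians into (-pi, pi]."""
    wrapped = (theta + np.pi) % (2.0 * np.pi) - np.pi
    if wrapped == -np.pi:
        wrapped = np.pi
    return float(wrapped)
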