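"""Low-level 3-D geometry: internal-coordinate atom placement and frame fitting.

All coordinates are Cartesian, in Angstrom, right-handed. Angles are taken
and returned in degrees at the API boundary (the field convention for
phi/psi/chi) and converted to radians internally.
"""

from __future__ import annotations

import numpy as np

Vec3 = np.ndarray


def distance(a: Vec3, b: Vec3) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def bond_angle(a: Vec3, b: Vec3, c: Vec3) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: Vec3, p1: Vec3, p2: Vec3, p3: Vec3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(-y, x)))


def place_atom(a: Vec3, b: Vec3, c: Vec3, bond: float, angle: float,
               torsion: float) -> Vec3:
    """Position atom D from reference atoms A, B, C (NeRF construction).

    D is placed at distance ``bond`` from C, with angle(B, C, D) = ``angle``
    and dihedral(A, B, C, D) = ``torsion`` (degrees).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    # local displacement in the frame where C is origin, BC along -x
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t) such that mobile @ R.T + t approximates target.
    Proper rotation only (no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    t = tc - r @ mc
    return r, t


def rotation_aligning(u: Vec3, v: Vec3) -> np.ndarray:
    """Rotation matrix sending unit direction of u onto unit direction of v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return rotation_about(axis, 180.0)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    ang = np.degrees(np.arctan2(s, c))
    return rotation_about(axis, ang)


def rotation_about(axis: Vec3, angle_deg: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
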