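"""Small rigid-body geometry helpers shared by the builder and the
trajectory metrics: internal-coordinate atom placement, Kabsch
superposition, and the signed xz-plane angle convention.

Angle convention: all channel-frame angles are signed about the +y axis
with the right-hand rule, i.e. ``signed_angle_xz(rotate_y(theta) @ v, v)``
returns ``+theta``; results are wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "rotation_about_y",
    "rotation_between",
    "signed_angle_xz",
    "nerf_place",
    "kabsch",
]


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def rotation_about_y(deg: float) -> np.ndarray:
    """Right-handed rotation matrix about +y."""
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking direction ``a`` onto direction ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any axis normal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 0.0, 1.0])
        axis /= np.linalg.norm(axis)
        vx = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * vx @ vx
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1.0 - c) / s**2)


def signed_angle_xz(u: np.ndarray, ref: np.ndarray, tol: float = 1e-8) -> float | None:
    """Signed angle (degrees) between the xz-projections of two vectors.

    Positive in the right-hand sense about +y.  Returns ``None`` when
    either projection is degenerate (near-zero norm).
    """
    ux, uz = float(u[0]), float(u[2])
    rx, rz = float(ref[0]), float(ref[2])
    if np.hypot(ux, uz) < tol or np.hypot(rx, rz) < tol:
        return None
    return wrap_angle(np.degrees(np.arctan2(ux * rz - uz * rx, ux * rx + uz * rz)))


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom ``d`` so that |cd|=bond, angle(b,c,d)=angle and
    torsion(a,b,c,d)=torsion (natural extension reference frame)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= norm
    m = np.cross(n, bc)
    local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + local[0] * bc + local[1] * m + local[2] * n


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R @ P.T + t ~ Q.

    Rows of ``P`` and ``Q`` are corresponding points.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc
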