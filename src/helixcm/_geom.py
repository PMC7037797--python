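"""Low-level vector geometry: angles, dihedrals, NeRF atom placement, rotations.

All angles are in degrees; coordinates in Angstrom. Dihedrals follow the
IUPAC sign convention and are wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "bond_angle",
    "dihedral",
    "place_atom",
    "rotation_matrix",
    "rotate_about_axis",
]


def wrap_angle(x):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    w = np.asarray(x, dtype=float)
    w = -np.mod(-w + 180.0, 360.0) + 180.0
    return float(w) if np.ndim(x) == 0 else w


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector in geometry computation")
    return v / n


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u = _unit(np.asarray(a, float) - b)
    v = _unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = _unit(b1)
    # components perpendicular to the central bond
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    x = v @ w
    y = np.cross(b1u, v) @ w
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c such that |cd| = length, angle(b,c,d) = angle_deg
    and dihedral(a,b,c,d) = torsion_deg (NeRF extension)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(theta),
            length * np.sin(theta) * np.cos(phi),
            length * np.sin(theta) * np.sin(phi),
        ]
    )
    # frame columns: bc, m, n
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    u = _unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def rotate_about_axis(coords: np.ndarray, point, axis, angle_deg: float) -> np.ndarray:
    """Rotate coordinates about the line through `point` with direction `axis`."""
    R = rotation_matrix(axis, angle_deg)
    p = np.asarray(point, float)
    return (np.asarray(coords, float) - p) @ R.T + p
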