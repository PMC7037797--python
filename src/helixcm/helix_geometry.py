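"""Helix shape descriptors: axis fitting, kink geometry, superposition, RMSD.

A kinked transmembrane helix is described by three angles about its hinge
residue (the ProKink-style descriptors):

* bend - angle between the axes fitted to the segments preceding and
  following the hinge (0..180 deg);
* wobble - azimuthal direction of the distal (post-hinge) axis around the
  proximal axis, measured right-handedly (about the N->C proximal direction)
  from the reference direction pointing from the proximal axis to the hinge
  C-alpha;
* face shift - change of helical rotational phase across the hinge relative
  to the proximal segment's own periodicity (~100 deg/residue for an ideal
  alpha helix): the distal segment is rigidly "unbent" onto the proximal
  axis, and the mean excess azimuth of its C-alphas over the phase
  extrapolated from the proximal segment is reported.

Wobble is ill-conditioned as bend -> 0 and is flagged accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._geom import rotation_matrix, wrap_angle

IDEAL_PHASE_PER_RESIDUE = 100.0  # deg, ideal alpha-helical periodicity
WOBBLE_BEND_THRESHOLD = 10.0  # deg, below which wobble is flagged unreliable

# 4-residue sliding-window weights that cancel the helical circle component
# exactly at the ideal periodicity of 100 deg/residue: sum w_k e^(i k delta)=0
_W = None


def _window_weights(delta_deg: float = IDEAL_PHASE_PER_RESIDUE) -> np.ndarray:
    global _W
    if _W is None:
        d = np.radians(delta_deg)
        # symmetric weights (a, b, b, a): 2a cos(1.5 d) + 2b cos(0.5 d) = 0
        ratio = -np.cos(0.5 * d) / np.cos(1.5 * d)  # a / b
        b = 1.0 / (2.0 * ratio + 2.0)
        a = ratio * b
        _W = np.array([a, b, b, a])
    return _W


@dataclass
class HelixAxis:
    point: np.ndarray  # a point on the axis (Angstrom)
    direction: np.ndarray  # unit vector, N -> C
    phase_per_residue: float  # deg, fitted helical periodicity
    residual: float  # rms distance of window centers from the line
    degenerate: bool = False  # set when the input is not helical (collinear)

    def foot(self, p: np.ndarray) -> np.ndarray:
        """Orthogonal projection of a point onto the axis."""
        return self.point + ((p - self.point) @ self.direction) * self.direction


@dataclass
class KinkGeometry:
    bend_deg: float
    wobble_deg: float
    face_shift_deg: float
    wobble_reliable: bool = True

    def __post_init__(self):
        if not 0.0 <= self.bend_deg <= 180.0:
            raise ValueError("bend must be in [0, 180]")


def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Least-squares helix axis through >= 5 consecutive C-alpha positions.

    Local helix centers are taken as phase-weighted means over 4-residue
    sliding windows (weights tuned to cancel the helical component at the
    ideal 100 deg/residue periodicity); the axis is the principal line
    through the centers, oriented N -> C.
    """
    ca = np.asarray(ca_coords, float)
    if ca.ndim != 2 or ca.shape[0] < 5 or ca.shape[1] != 3:
        raise ValueError("axis fitting needs at least 5 C-alpha positions")
    w = _window_weights()
    centers = np.array([w @ ca[i : i + 4] for i in range(len(ca) - 3)])
    mean = centers.mean(axis=0)
    u, s, vt = np.linalg.svd(centers - mean, full_matrices=False)
    direction = vt[0]
    if (centers[-1] - centers[0]) @ direction < 0:
        direction = -direction
    residual = float(np.sqrt(np.maximum(s[1] ** 2 + s[2] ** 2, 0.0) / len(centers)))

    # per-residue azimuthal phase about the fitted axis
    ref = ca[0] - (mean + ((ca[0] - mean) @ direction) * direction)
    degenerate = bool(np.linalg.norm(ref) < 1e-6)
    if degenerate:
        warnings.warn("degenerate (collinear) segment: no helical phase", stacklevel=2)
        phase_rate = 0.0
    else:
        e1 = ref / np.linalg.norm(ref)
        e2 = np.cross(direction, e1)
        radial = ca - mean - np.outer((ca - mean) @ direction, direction)
        phases = np.degrees(np.arctan2(radial @ e2, radial @ e1))
        phases = np.unwrap(phases, period=360.0)
        phase_rate = float(np.polyfit(np.arange(len(ca)), phases, 1)[0])
    return HelixAxis(mean, direction, phase_rate, residual, degenerate)


def _phases_about(axis: HelixAxis, points: np.ndarray, e1: np.ndarray, e2: np.ndarray):
    radial = points - axis.point - np.outer((points - axis.point) @ axis.direction, axis.direction)
    return np.degrees(np.arctan2(radial @ e2, radial @ e1))


def compute_kink(
    h,
    hinge_pos: int,
    phase_per_residue: float | None = None,
) -> KinkGeometry:
    """Bend/wobble/face-shift about the hinge residue (0-based position).

    The proximal segment is residues 0..hinge (inclusive), the distal segment
    hinge+1..end; both sides need >= 5 residues. `phase_per_residue` fixes
    the reference periodicity for the face-shift extrapolation; by default it
    is fitted from the proximal segment itself (an ideal helix gives
    ~100 deg/residue).
    """
    ca = h if isinstance(h, np.ndarray) else h.ca_coords()
    n = len(ca)
    if hinge_pos < 4 or n - hinge_pos - 1 < 5:
        raise ValueError("hinge too close to a terminus (need >= 5 residues per side)")
    prox = fit_helix_axis(ca[: hinge_pos + 1])
    dist = fit_helix_axis(ca[hinge_pos + 1 :])

    cosb = float(np.clip(prox.direction @ dist.direction, -1.0, 1.0))
    bend = float(np.degrees(np.arccos(cosb)))

    # reference frame perpendicular to the proximal axis, anchored at the
    # hinge C-alpha
    hinge_ca = ca[hinge_pos]
    r0 = hinge_ca - prox.foot(hinge_ca)
    if np.linalg.norm(r0) < 1e-9:
        raise ValueError("hinge C-alpha lies on the proximal axis; wobble undefined")
    e1 = r0 / np.linalg.norm(r0)
    e2 = np.cross(prox.direction, e1)
    d_perp = dist.direction - (dist.direction @ prox.direction) * prox.direction
    if np.linalg.norm(d_perp) < 1e-12:
        wobble = 0.0
    else:
        wobble = float(np.degrees(np.arctan2(d_perp @ e2, d_perp @ e1)))
    reliable = bend >= WOBBLE_BEND_THRESHOLD

    # face shift: rigidly un-bend the distal segment onto the proximal axis
    # direction (minimal rotation, about the hinge C-alpha), then compare
    # distal azimuths with the phase extrapolated from the proximal segment
    axis_vec = np.cross(dist.direction, prox.direction)
    if np.linalg.norm(axis_vec) < 1e-12:
        unbent = ca[hinge_pos + 1 :]
    else:
        R = rotation_matrix(axis_vec, bend)
        unbent = (ca[hinge_pos + 1 :] - hinge_ca) @ R.T + hinge_ca
    rate = phase_per_residue if phase_per_residue is not None else prox.phase_per_residue
    idx_prox = np.arange(hinge_pos + 1)
    obs_prox = np.unwrap(_phases_about(prox, ca[: hinge_pos + 1], e1, e2), period=360.0)
    # anchor the extrapolation at the proximal segment (least-squares intercept)
    intercept = float(np.mean(obs_prox - rate * idx_prox))
    idx_dist = np.arange(hinge_pos + 1, n)
    obs_dist = _phases_about(prox, unbent, e1, e2)
    resid = np.radians(obs_dist - (intercept + rate * idx_dist))
    face_shift = float(wrap_angle(np.degrees(np.arctan2(np.sin(resid).mean(),
                                                        np.cos(resid).mean()))))
    return KinkGeometry(bend, wrap_angle(wobble), face_shift, reliable)


# --------------------------------------------------------------------- RMSD

def kabsch_rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True,
                return_transform: bool = False):
    """RMSD between coordinate sets, optionally after optimal rigid
    superposition of b onto a (Kabsch). With `return_transform`, also returns
    (R, t) such that b @ R.T + t best fits a."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must have identical (n, 3) shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms")
    if not superpose:
        rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
        return (rmsd, (np.eye(3), np.zeros(3))) if return_transform else rmsd
    ac = a.mean(axis=0)
    bc = b.mean(axis=0)
    H = (b - bc).T @ (a - ac)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ac - R @ bc
    moved = b @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))
    return (rmsd, (R, t)) if return_transform else rmsd


def trajectory_rmsd(frames, selection=None, reference: int = 0,
                    atom_names=("N", "CA", "C")) -> "pd.DataFrame":
    """Backbone RMSD of every frame against a reference frame.

    `frames` is a list of structures; `selection` an optional inclusive
    (start, end) 0-based residue range. Each frame is superposed on the
    selection before the RMSD is taken. Returns a DataFrame with columns
    (frame, rmsd_angstrom)."""
    import pandas as pd

    if not frames:
        raise ValueError("empty trajectory")
    sl = slice(None) if selection is None else slice(selection[0], selection[1] + 1)
    coords = [f.backbone_coords(atom_names=atom_names, residue_slice=sl) for f in frames]
    if coords[0].size == 0:
        raise ValueError("empty atom selection")
    ref = coords[reference]
    rows = [(i, kabsch_rmsd(ref, c, superpose=True)) for i, c in enumerate(coords)]
    return pd.DataFrame(rows, columns=["frame", "rmsd_angstrom"])


def format_kink_table(rows) -> str:
    """TSV report of kink descriptors, one decimal place.

    `rows` is an iterable of (helix label, hinge label, KinkGeometry)."""
    out = ["Helix\tHinge Residue\tBend\tWobble\tFaceShift"]
    for helix, hinge, k in rows:
        out.append(f"{helix}\t{hinge}\t{k.bend_deg:.1f}\t{k.wobble_deg:.1f}\t{k.face_shift_deg:.1f}")
    return "\n".join(out) + "\n"


def write_kink_table(path, rows) -> None:
    Path(path).write_text(format_kink_table(rows))
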