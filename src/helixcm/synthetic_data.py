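"""Ground-truth fixture generators: ideal/kinked helices and toy complexes.

Every generator is deterministic under an explicit seed and returns a
machine-readable truth record alongside the structure, so each analysis
stage can be tested against constructions with exactly known answers
instead of unreleased experimental models. Sequences are synthetic
(poly-Ala with motif residues at declared anchors) rather than any real
receptor sequence; the numbering and microswitch logic only need anchored
motifs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ._geom import rotation_matrix
from .helix_geometry import fit_helix_axis
from .structure import AtomRecord, HelixStructure, Residue, build_from_internal

IDEAL_PHI = -63.0
IDEAL_PSI = -42.0


def build_ideal_helix(sequence, phi: float = IDEAL_PHI, psi: float = IDEAL_PSI,
                      chi1=None, start_index: int = 1) -> HelixStructure:
    """Ideal alpha helix of the given sequence (1-letter string or 3-letter
    list); side chains are placed at the requested chi1 (default: the ideal
    rotamer of the residue template)."""
    return build_from_internal(sequence, phi=phi, psi=psi, omega=180.0,
                               chi1=chi1, start_index=start_index)


@dataclass(frozen=True)
class KinkConstruction:
    """Recipe for a synthetic kinked helix with exactly known geometry."""

    sequence: str = "A" * 24
    hinge_position: int = 11  # 0-based
    true_bend_deg: float = 20.0
    true_wobble_deg: float = 0.0
    true_face_shift_deg: float = 0.0
    noise_sigma: float = 0.0

    def truth(self) -> dict:
        return asdict(self)


def build_kinked_helix(spec: KinkConstruction, seed: int = 0):
    """Construct a helix whose distal segment is rigidly kinked by exactly
    the requested bend/wobble/face-shift about the hinge C-alpha.

    The distal segment (residues after the hinge) is rotated by `true_bend`
    about the in-plane direction at azimuth `true_wobble` (right-handed about
    the proximal axis, zero at the hinge-C-alpha direction), then by
    `true_face_shift` about its own displaced axis. Optional isotropic
    Gaussian noise of the stated sigma is added to all coordinates.
    Returns (structure, truth record)."""
    n = len(spec.sequence)
    hp = spec.hinge_position
    if hp < 6 or n - hp - 1 < 6:
        raise ValueError("hinge must be at least 6 residues from each terminus")
    h = build_ideal_helix(spec.sequence)
    ca = h.ca_coords()
    prox = fit_helix_axis(ca[: hp + 1])
    hinge_ca = ca[hp]
    r0 = hinge_ca - prox.foot(hinge_ca)
    e1 = r0 / np.linalg.norm(r0)
    e2 = np.cross(prox.direction, e1)
    azim = np.radians(spec.true_wobble_deg)
    tilt_dir = np.cos(azim) * e1 + np.sin(azim) * e2
    bend_axis = np.cross(prox.direction, tilt_dir)

    if abs(spec.true_bend_deg) > 90.0:
        import warnings

        warnings.warn("bend > 90 deg: construction may produce steric overlap")

    # atoms of residues strictly after the hinge move rigidly
    first_moved = sum(len(r.atoms) for r in h.residues[: hp + 1])
    xyz = h.coords()
    R_bend = rotation_matrix(bend_axis, spec.true_bend_deg) if spec.true_bend_deg else np.eye(3)
    xyz[first_moved:] = (xyz[first_moved:] - hinge_ca) @ R_bend.T + hinge_ca
    if spec.true_face_shift_deg:
        # the distal segment's own axis: the original helix axis, transported
        # by the bend rotation
        axis_point = (prox.foot(hinge_ca) - hinge_ca) @ R_bend.T + hinge_ca
        axis_dir = R_bend @ prox.direction
        R_face = rotation_matrix(axis_dir, spec.true_face_shift_deg)
        xyz[first_moved:] = (xyz[first_moved:] - axis_point) @ R_face.T + axis_point
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(0.0, spec.noise_sigma, xyz.shape)
    h.set_coords(xyz)
    h.measure_internal()
    return h, spec.truth()


def build_toy_complex(n_pocket_residues: int = 4, charge_pattern=(-1.0, 1.0),
                      seed: int = 0, shell_radius: float = 5.0):
    """Toy ligand-pocket complex with a closed-form expected interaction table.

    A single-atom ligand probe (+1 e) sits at the origin; `n_pocket_residues`
    one-atom pocket "residues" are placed at deterministic distances/
    directions with charges cycling through `charge_pattern`. The expected
    per-residue Coulomb/LJ terms are computed here by an independent direct
    double-loop sum (the oracle) and returned with the fixture.

    Returns (ligand atoms, pocket structure, expected table dict).
    """
    if n_pocket_residues < 1:
        raise ValueError("need at least one pocket residue")
    rng = np.random.default_rng(seed)
    ligand = [
        AtomRecord("L1", "C", 1, "LIG", "L", np.zeros(3), partial_charge=1.0,
                   lj_params=(0.1, 4.0))
    ]
    residues = []
    expected_rows = {}
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for k in range(n_pocket_residues):
        r = 3.32 + 0.8 * (k % 4) + 0.05 * rng.random()
        theta = np.arccos(1.0 - 2.0 * (k + 0.5) / n_pocket_residues)
        phi = golden * k
        pos = r * np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        q = float(charge_pattern[k % len(charge_pattern)])
        res = Residue(k + 1, "PKT", "P",
                      [AtomRecord("P1", "C", k + 1, "PKT", "P", pos,
                                  partial_charge=q, lj_params=(0.1, 4.0))])
        residues.append(res)
        # independent direct-sum oracle with the documented cutoffs and
        # dielectric eps(r) = 2r
        dist = float(np.linalg.norm(pos))
        coulomb = 332.0636 * 1.0 * q / (2.0 * dist * dist) if dist <= 20.0 else 0.0
        if dist <= 8.0:
            x6 = (4.0 / dist) ** 6
            lj = 0.1 * (x6 * x6 - 2.0 * x6)
        else:
            lj = 0.0
        if dist <= shell_radius:
            expected_rows[k + 1] = {"coulomb": coulomb, "vdw": lj, "sum": coulomb + lj}
    pocket = HelixStructure(residues)
    expected = {
        "rows": expected_rows,
        "total_interaction": sum(r["sum"] for r in expected_rows.values()),
        "shell_radius": shell_radius,
    }
    return ligand, pocket, expected
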