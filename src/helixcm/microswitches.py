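"""GPCR functional-microswitch analysis on a static structure.

Class A GPCRs carry a small set of conserved, state-diagnostic interactions:

* the "ionic lock" between residues 3.50 and 6.30 at the intracellular helix
  ends (in GPR6 an Arg-Thr hydrogen bond rather than a salt bridge), formed
  in the inactive state;
* the binding-pocket "toggle switch" rotamer pair/triad (F3.36, W6.48,
  optionally F5.47) whose coordinated chi1 changes accompany activation -
  in the inactive state W6.48 is g+ and F3.36 trans;
* the sodium-coordinating polar pocket (N1.50, D2.50, S3.39, N7.49, Y7.53);
* conserved inter-helical hydrogen-bond networks and aromatic stacks.

This module classifies chi1 rotamers (g+/g-/trans), detects the ionic lock,
classifies aromatic ring-ring contacts and audits arbitrary expected-contact
lists against a structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import bond_angle
from .structure import HelixStructure
from .structure_io import BWMap

# chi1 windows (degrees); the staggered rotamers sit near -60 (g+), +60 (g-)
# and 180 (trans)
DEFAULT_CHI1_WINDOWS = {"g+": (-120.0, 0.0), "g-": (0.0, 120.0)}

HBOND_DISTANCE = 3.5  # Angstrom, donor-acceptor heavy-atom cutoff
HBOND_ANGLE = 120.0  # deg, minimum angle at the donor heavy atom
AROMATIC_CENTROID_CUTOFF = 7.0  # Angstrom

# side-chain polar atoms usable as H-bond donors/acceptors
_POLAR_SIDECHAIN = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["OD1", "ND2"], "GLN": ["OE1", "NE2"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"],
    "HIS": ["ND1", "NE2"], "TRP": ["NE1"],
}

_RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],  # 6-membered ring
}


@dataclass(frozen=True)
class RotamerState:
    label: str  # g+ | g- | trans
    chi1_deg: float


def classify_chi1(chi1_deg: float, windows: dict | None = None) -> RotamerState:
    """Classify a chi1 dihedral into g+/g-/trans.

    Windows partition the circle: g+ on [-120, 0), g- on [0, 120), trans
    elsewhere (configurable)."""
    windows = windows or DEFAULT_CHI1_WINDOWS
    x = float(chi1_deg)
    if not -180.0 < x <= 180.0:
        raise ValueError("chi1 must be in (-180, 180]")
    for label, (lo, hi) in windows.items():
        if lo <= x < hi:
            return RotamerState(label, x)
    return RotamerState("trans", x)


@dataclass
class IonicLockResult:
    status: str  # formed | broken | indeterminate
    distance: float | None
    donor_atom: str | None
    acceptor_atom: str | None
    angle_deg: float | None
    warning: str | None = None

    @property
    def formed(self) -> bool:
        return self.status == "formed"


def _residue_by_bw(structure: HelixStructure, bw: BWMap, label):
    abs_idx = bw.index_of(label)
    for r in structure.residues:
        if r.index == abs_idx:
            return r
    raise KeyError(f"residue {label} (absolute {abs_idx}) not in structure")


def _polar_atoms(res):
    names = _POLAR_SIDECHAIN.get(res.name, [])
    return [res.atom(n) for n in names if res.has_atom(n)]


def _antecedent(res, atom_name: str):
    """Heavy atom bonded to a side-chain polar atom (for the donor angle)."""
    from .residues import residue_template

    try:
        tmpl = residue_template(res.name)
    except KeyError:
        return None
    for a, b in tmpl.bonds:
        other = b if a == atom_name else (a if b == atom_name else None)
        if other and res.has_atom(other) and not other.startswith("H"):
            return res.atom(other)
    return None


def detect_ionic_lock(
    structure: HelixStructure,
    bw: BWMap,
    donor: str = "3.50",
    acceptor: str = "6.30",
    max_distance: float = HBOND_DISTANCE,
    min_angle: float = HBOND_ANGLE,
) -> IonicLockResult:
    """Detect the 3.50-6.30 intracellular lock (formed/broken + geometry).

    Formed iff the minimum heavy-atom donor-acceptor distance is <=
    `max_distance` (inclusive) and the angle at the donor atom (antecedent-
    donor-acceptor) is >= `min_angle` (inclusive)."""
    don_res = _residue_by_bw(structure, bw, donor)
    acc_res = _residue_by_bw(structure, bw, acceptor)
    don_atoms = _polar_atoms(don_res)
    acc_atoms = _polar_atoms(acc_res)
    if not don_atoms or not acc_atoms:
        return IonicLockResult(
            "indeterminate", None, None, None, None,
            warning=f"missing side-chain atoms on {don_res.name}{don_res.index} or "
                    f"{acc_res.name}{acc_res.index}",
        )
    best = None
    for da in don_atoms:
        for aa in acc_atoms:
            d = float(np.linalg.norm(da.coords - aa.coords))
            if best is None or d < best[0]:
                best = (d, da, aa)
    d, da, aa = best
    ante = _antecedent(don_res, da.name)
    ang = bond_angle(ante.coords, da.coords, aa.coords) if ante is not None else 180.0
    formed = d <= max_distance and ang >= min_angle
    return IonicLockResult("formed" if formed else "broken", d, da.name, aa.name, ang)


@dataclass
class AromaticContact:
    partners: tuple[str, str]
    centroid_distance: float
    interplanar_angle: float  # deg, folded to [0, 90]
    contact_class: str  # parallel | tilted-T | T-stack | edge-to-face | none


def _ring_plane(ring: np.ndarray):
    ring = np.asarray(ring, float)
    if ring.shape[0] < 5:
        raise ValueError("a ring needs at least 5 atoms")
    centroid = ring.mean(axis=0)
    _, s, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    out_of_plane = float(np.abs((ring - centroid) @ normal).max())
    if out_of_plane > 0.3:
        raise ValueError(f"ring not planar: max out-of-plane deviation {out_of_plane:.2f} A")
    return centroid, normal


def classify_aromatic(ring_a, ring_b, labels=("ringA", "ringB"),
                      cutoff: float = AROMATIC_CENTROID_CUTOFF) -> AromaticContact:
    """Classify a ring-ring contact by centroid distance and interplanar angle.

    parallel for angle <= 30 deg, tilted-T for 30-60, and for 60-90 a T-stack
    when one ring's centroid sits over the other ring's face (inter-centroid
    vector within 40 deg of a ring normal), edge-to-face otherwise. Beyond
    the centroid cutoff the class is "none"."""
    ca, na = _ring_plane(ring_a)
    cb, nb = _ring_plane(ring_b)
    d = float(np.linalg.norm(ca - cb))
    ang = float(np.degrees(np.arccos(np.clip(abs(na @ nb), 0.0, 1.0))))
    if d > cutoff:
        cls = "none"
    elif ang <= 30.0:
        cls = "parallel"
    elif ang <= 60.0:
        cls = "tilted-T"
    else:
        v = (cb - ca) / d
        over_face = min(
            np.degrees(np.arccos(np.clip(abs(v @ na), 0.0, 1.0))),
            np.degrees(np.arccos(np.clip(abs(v @ nb), 0.0, 1.0))),
        )
        cls = "T-stack" if over_face <= 40.0 else "edge-to-face"
    return AromaticContact(tuple(labels), d, ang, cls)


def residue_ring(res) -> np.ndarray:
    """Coordinates of the (6-membered, for Trp) aromatic ring of a residue."""
    names = _RING_ATOMS.get(res.name)
    if not names:
        raise ValueError(f"{res.name} has no aromatic ring")
    return np.array([res.atom(n).coords for n in names])


# ------------------------------------------------------------- contact audit

@dataclass(frozen=True)
class ContactSpec:
    kind: str  # hbond | aromatic
    a: str  # BW label
    b: str

    @classmethod
    def chain(cls, kind: str, *labels: str) -> list["ContactSpec"]:
        """Expand a network like N1.50-D2.50-N7.49 into consecutive pairs."""
        return [cls(kind, labels[i], labels[i + 1]) for i in range(len(labels) - 1)]


@dataclass
class ContactResult:
    spec: ContactSpec
    status: str  # satisfied | unsatisfied | unresolvable
    measured_distance: float | None = None
    detail: str | None = None


@dataclass
class SwitchReport:
    """Aggregate microswitch state of one structure."""

    ionic_lock: IonicLockResult | None = None
    toggle: dict[str, RotamerState] = field(default_factory=dict)
    sodium_pocket: dict[str, bool] = field(default_factory=dict)
    contact_audit: list[ContactResult] = field(default_factory=list)

    @property
    def contacts_satisfied(self) -> tuple[int, int]:
        n_ok = sum(1 for c in self.contact_audit if c.status == "satisfied")
        return n_ok, len(self.contact_audit)

    def to_dict(self) -> dict:
        return {
            "ionic_lock": None if self.ionic_lock is None else {
                "status": self.ionic_lock.status,
                "distance": self.ionic_lock.distance,
                "atoms": [self.ionic_lock.donor_atom, self.ionic_lock.acceptor_atom],
                "angle_deg": self.ionic_lock.angle_deg,
            },
            "toggle": {k: {"label": v.label, "chi1": v.chi1_deg} for k, v in self.toggle.items()},
            "sodium_pocket": self.sodium_pocket,
            "contact_audit": [
                {
                    "kind": c.spec.kind, "pair": [c.spec.a, c.spec.b],
                    "status": c.status, "distance": c.measured_distance,
                    "detail": c.detail,
                }
                for c in self.contact_audit
            ],
            "contacts_satisfied": list(self.contacts_satisfied),
        }


def _min_polar_distance(res_a, res_b):
    pa, pb = _polar_atoms(res_a), _polar_atoms(res_b)
    if not pa or not pb:
        return None
    return min(float(np.linalg.norm(x.coords - y.coords)) for x in pa for y in pb)


def contact_audit(structure: HelixStructure, bw: BWMap,
                  expected: list[ContactSpec]) -> list[ContactResult]:
    """Evaluate a list of expected interactions against the structure.

    Hydrogen bonds use the heavy-atom distance criterion (<= 3.5 A between
    side-chain polar atoms); aromatic contacts use the ring classifier. A BW
    label absent from the map or residues/atoms absent from the structure
    yield an "unresolvable" entry, never an exception."""
    out = []
    for spec in expected:
        try:
            ra = _residue_by_bw(structure, bw, spec.a)
            rb = _residue_by_bw(structure, bw, spec.b)
        except KeyError as e:
            out.append(ContactResult(spec, "unresolvable", detail=str(e)))
            continue
        if spec.kind == "hbond":
            d = _min_polar_distance(ra, rb)
            if d is None:
                out.append(ContactResult(spec, "unresolvable",
                                         detail="no side-chain polar atoms"))
            else:
                status = "satisfied" if d <= HBOND_DISTANCE else "unsatisfied"
                out.append(ContactResult(spec, status, measured_distance=d))
        elif spec.kind == "aromatic":
            try:
                contact = classify_aromatic(residue_ring(ra), residue_ring(rb),
                                            labels=(spec.a, spec.b))
            except (ValueError, KeyError) as e:
                out.append(ContactResult(spec, "unresolvable", detail=str(e)))
                continue
            status = "satisfied" if contact.contact_class != "none" else "unsatisfied"
            out.append(ContactResult(spec, status,
                                     measured_distance=contact.centroid_distance,
                                     detail=contact.contact_class))
        else:
            out.append(ContactResult(spec, "unresolvable", detail=f"unknown kind {spec.kind!r}"))
    return out


SODIUM_POCKET = ("1.50", "2.50", "3.39", "7.49", "7.53")
DEFAULT_TOGGLE = ("3.36", "6.48", "5.47")


def switch_report(structure: HelixStructure, bw: BWMap,
                  toggle: tuple[str, ...] = DEFAULT_TOGGLE,
                  expected_contacts: list[ContactSpec] | None = None) -> SwitchReport:
    """Full microswitch report: ionic lock, toggle chi1 rotamers, sodium-pocket
    residue presence and an optional expected-contact audit."""
    report = SwitchReport()
    try:
        report.ionic_lock = detect_ionic_lock(structure, bw)
    except KeyError:
        report.ionic_lock = None
    structure.measure_internal()
    pos_by_abs = {r.index: i for i, r in enumerate(structure.residues)}
    for label in toggle:
        try:
            abs_idx = bw.index_of(label)
            chi1 = structure.chi1[pos_by_abs[abs_idx]]
        except KeyError:
            continue
        if np.isfinite(chi1):
            res = structure.residues[pos_by_abs[abs_idx]]
            report.toggle[f"{res.name}{label}"] = classify_chi1(chi1)
    for label in SODIUM_POCKET:
        try:
            abs_idx = bw.index_of(label)
            report.sodium_pocket[label] = abs_idx in pos_by_abs
        except KeyError:
            report.sodium_pocket[label] = False
    if expected_contacts:
        report.contact_audit = contact_audit(structure, bw, expected_contacts)
    return report
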