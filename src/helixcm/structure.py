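"""Polymer-chain container holding both Cartesian atoms and internal coordinates.

A `HelixStructure` carries, per residue, the backbone dihedrals (phi, psi,
omega), the N-CA-C bond angle and optionally chi1, alongside the Cartesian
atom records. Conversion in both directions is provided: internal
coordinates are measured from Cartesian geometry, and Cartesian coordinates
are rebuilt from internal ones by sequential NeRF extension seeded on the
first residue's N/CA/C atoms (so a rebuild preserves the global frame).

Covalent bond lengths/angles other than the N-CA-C angle are taken from the
fixed ideal-geometry tables in `residues`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import residues as rt
from ._geom import bond_angle, dihedral, place_atom, wrap_angle


@dataclass
class AtomRecord:
    """A single atom: label, element, parent residue and position (Angstrom).

    `partial_charge` (e) and `lj_params` (well depth kcal/mol, r_min Angstrom)
    are populated lazily by the energy backend when a force field is attached.
    """

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    partial_charge: float | None = None
    lj_params: tuple[float, float] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


@dataclass
class Residue:
    index: int
    name: str
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


class HelixStructure:
    """Ordered residue chain with synchronized Cartesian and internal coordinates.

    Internal coordinate arrays have one entry per residue; entries that are
    undefined at a terminus (phi of the first residue, psi/omega involving a
    missing neighbour) are NaN. Dihedrals live in (-180, 180], bond angles in
    (0, 180).
    """

    def __init__(self, residues: list[Residue]):
        if not residues:
            raise ValueError("empty structure")
        self.residues = residues
        n = len(residues)
        self.phi = np.full(n, np.nan)
        self.psi = np.full(n, np.nan)
        self.omega = np.full(n, np.nan)
        self.n_ca_c = np.full(n, rt.ANGLE_N_CA_C)
        self.chi1 = np.full(n, np.nan)
        self._atom_offsets = None

    # ------------------------------------------------------------------ basics
    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> list[str]:
        return [r.name for r in self.residues]

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain_id

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self):
        for r in self.residues:
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """All-atom coordinate array, residues in order, file/template atom order."""
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(self.atoms(), xyz):
            a.coords = c.copy()

    def backbone_coords(self, atom_names=("N", "CA", "C"), residue_slice=None) -> np.ndarray:
        res = self.residues if residue_slice is None else self.residues[residue_slice]
        return np.array([r.atom(n).coords for r in res for n in atom_names if r.has_atom(n)])

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coords for r in self.residues])

    def copy(self) -> "HelixStructure":
        new = HelixStructure(
            [
                Residue(
                    r.index,
                    r.name,
                    r.chain_id,
                    [
                        AtomRecord(a.name, a.element, a.residue_index, a.residue_name,
                                   a.chain_id, a.coords.copy(), a.partial_charge, a.lj_params)
                        for a in r.atoms
                    ],
                )
                for r in self.residues
            ]
        )
        for attr in ("phi", "psi", "omega", "n_ca_c", "chi1"):
            setattr(new, attr, getattr(self, attr).copy())
        return new

    # ---------------------------------------------------------------- topology
    def atom_index(self, residue_pos: int, atom_name: str) -> int:
        """Global atom index (0-based) of an atom; residue_pos is 0-based."""
        off = 0
        for i, r in enumerate(self.residues):
            if i == residue_pos:
                for j, a in enumerate(r.atoms):
                    if a.name == atom_name:
                        return off + j
                raise KeyError(f"residue {r.name}{r.index} has no atom {atom_name!r}")
            off += len(r.atoms)
        raise IndexError(residue_pos)

    def bonds(self) -> list[tuple[int, int]]:
        """Covalent bond list as global atom index pairs (template-derived)."""
        out = []
        for i, r in enumerate(self.residues):
            present = {a.name for a in r.atoms}
            try:
                tmpl_bonds = rt.residue_template(r.name).bonds
            except KeyError:
                tmpl_bonds = ()
            for a, b in tmpl_bonds:
                if a in present and b in present:
                    out.append((self.atom_index(i, a), self.atom_index(i, b)))
            if i + 1 < len(self.residues):
                nxt = self.residues[i + 1]
                if r.has_atom("C") and nxt.has_atom("N"):
                    out.append((self.atom_index(i, "C"), self.atom_index(i + 1, "N")))
        return out

    # ------------------------------------------------- internal <-> Cartesian
    def measure_internal(self) -> None:
        """Populate phi/psi/omega/N-CA-C/chi1 arrays from Cartesian geometry."""
        res = self.residues
        for i, r in enumerate(res):
            N, CA, C = r.atom("N").coords, r.atom("CA").coords, r.atom("C").coords
            self.n_ca_c[i] = bond_angle(N, CA, C)
            if i > 0:
                Cp = res[i - 1].atom("C").coords
                CAp = res[i - 1].atom("CA").coords
                self.phi[i] = dihedral(Cp, N, CA, C)
                self.omega[i] = dihedral(CAp, Cp, N, CA)
            if i + 1 < len(res):
                Nn = res[i + 1].atom("N").coords
                self.psi[i] = dihedral(N, CA, C, Nn)
            tmpl = rt.residue_template(r.name) if r.name in rt.THREE_TO_ONE else None
            if tmpl and tmpl.chi1_atom and r.has_atom("CB") and r.has_atom(tmpl.chi1_atom):
                self.chi1[i] = dihedral(N, CA, r.atom("CB").coords, r.atom(tmpl.chi1_atom).coords)

    def rebuild_cartesian(self) -> None:
        """Rebuild all Cartesian coordinates from the internal coordinates.

        Seeded on the current first-residue N/CA/C positions, so the global
        frame is preserved and an unchanged internal state round-trips the
        coordinates identically.
        """
        res = self.residues
        n = len(res)
        for i in range(1, n):
            for name, val in (("psi", self.psi[i - 1]), ("omega", self.omega[i])):
                if not np.isfinite(val):
                    raise ValueError(
                        f"missing {name} dihedral for non-terminal residue "
                        f"{res[i - 1].name}{res[i - 1].index}/{res[i].name}{res[i].index}"
                    )
            if i < n - 1 and not np.isfinite(self.phi[i]):
                raise ValueError(f"missing phi dihedral for residue {res[i].name}{res[i].index}")

        N = [None] * n
        CA = [None] * n
        C = [None] * n
        N[0] = res[0].atom("N").coords.copy()
        CA[0] = res[0].atom("CA").coords.copy()
        C[0] = _place_c0(N[0], CA[0], res[0].atom("C").coords, self.n_ca_c[0])
        for i in range(1, n):
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], rt.BOND_C_N,
                              rt.ANGLE_CA_C_N, self.psi[i - 1])
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], rt.BOND_N_CA,
                               rt.ANGLE_C_N_CA, self.omega[i])
            phi = self.phi[i] if np.isfinite(self.phi[i]) else -63.0
            C[i] = place_atom(C[i - 1], N[i], CA[i], rt.BOND_CA_C, self.n_ca_c[i], phi)

        for i, r in enumerate(res):
            pos = {"N": N[i], "CA": CA[i], "C": C[i]}
            if r.has_atom("O"):
                o_tor = wrap_angle(self.psi[i] + 180.0) if np.isfinite(self.psi[i]) else 180.0
                pos["O"] = place_atom(N[i], CA[i], C[i], rt.BOND_C_O, rt.ANGLE_CA_C_O, o_tor)
            tmpl = rt.residue_template(r.name) if r.name in rt.THREE_TO_ONE else None
            if tmpl:
                chi1 = self.chi1[i] if np.isfinite(self.chi1[i]) else tmpl.default_chi1
                for row in tmpl.sidechain:
                    if not r.has_atom(row.name):
                        continue
                    if not all(ref in pos for ref in row.refs):
                        continue
                    tor = row.torsion if row.chi_offset is None else chi1 + row.chi_offset
                    pos[row.name] = place_atom(pos[row.refs[0]], pos[row.refs[1]],
                                               pos[row.refs[2]], row.length, row.angle, tor)
            for a in r.atoms:
                if a.name in pos:
                    a.coords = np.asarray(pos[a.name], float)


def _place_c0(N, CA, C_old, angle_n_ca_c):
    """Re-place the first carbonyl C at the ideal CA-C length and the stored
    N-CA-C angle, keeping its original torsional orientation about N-CA."""
    u = C_old - CA
    bc = (CA - N) / np.linalg.norm(CA - N)
    perp = u - (u @ bc) * bc
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(bc, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    theta = np.radians(angle_n_ca_c)
    return CA + rt.BOND_CA_C * (-np.cos(theta) * bc + np.sin(theta) * perp)


def build_from_internal(
    sequence,
    phi=None,
    psi=None,
    omega=None,
    n_ca_c=None,
    chi1=None,
    start_index: int = 1,
    chain_id: str = "A",
) -> HelixStructure:
    """Construct a chain from scratch given a sequence and internal coordinates.

    `sequence` is a list of 3-letter codes or a 1-letter string. Dihedral
    arguments may be scalars (broadcast) or per-residue arrays; defaults are
    an ideal alpha helix (phi -63, psi -42, omega 180).
    """
    if isinstance(sequence, str):
        try:
            seq3 = [rt.ONE_TO_THREE[c] for c in sequence.upper()]
        except KeyError as e:
            raise KeyError(f"unknown residue code {e.args[0]!r}") from None
    else:
        seq3 = [s.upper() for s in sequence]
        for s in seq3:
            if s not in rt.THREE_TO_ONE:
                raise KeyError(f"unknown residue code {s!r}")
    n = len(seq3)
    if n < 1:
        raise ValueError("sequence must contain at least one residue")

    def expand(x, default):
        arr = np.full(n, default, dtype=float) if x is None else np.broadcast_to(
            np.asarray(x, float), (n,)
        ).copy()
        return arr

    phi_a = expand(phi, -63.0)
    psi_a = expand(psi, -42.0)
    omega_a = expand(omega, 180.0)
    ang_a = expand(n_ca_c, rt.ANGLE_N_CA_C)
    chi_a = expand(chi1, np.nan)

    residues = []
    for i, name in enumerate(seq3):
        tmpl = rt.residue_template(name)
        atom_names = ["N", "CA", "C", "O"] + [row.name for row in tmpl.sidechain]
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        elements.update({row.name: row.element for row in tmpl.sidechain})
        atoms = [
            AtomRecord(a, elements[a], start_index + i, name, chain_id, np.zeros(3))
            for a in atom_names
        ]
        residues.append(Residue(start_index + i, name, chain_id, atoms))

    h = HelixStructure(residues)
    h.phi[:] = phi_a
    h.psi[:] = psi_a
    h.omega[:] = omega_a
    h.phi[0] = np.nan
    h.psi[-1] = np.nan
    h.omega[0] = np.nan
    h.n_ca_c[:] = ang_a
    h.chi1[:] = [
        chi_a[i] if rt.residue_template(s).chi1_atom else np.nan for i, s in enumerate(seq3)
    ]
    # canonical seed frame: N at origin, CA on +x, C in the xy-plane
    h.residues[0].atom("N").coords = np.zeros(3)
    h.residues[0].atom("CA").coords = np.array([rt.BOND_N_CA, 0.0, 0.0])
    th = np.radians(ang_a[0])
    h.residues[0].atom("C").coords = h.residues[0].atom("CA").coords + rt.BOND_CA_C * np.array(
        [-np.cos(th), np.sin(th), 0.0]
    )
    h.rebuild_cartesian()
    return h
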