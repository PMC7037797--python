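"""Systematic small-molecule torsion scanning and conformational-cost accounting.

Conformer enumeration follows the standard 2-fold/3-fold protocol: every
rotatable bond is started at 360/fold-degree increments from the input
conformer, each grid point is locally minimized on the torsional coordinates,
and the deduplicated, energy-sorted set is returned with its global minimum.
The conformational cost of a docked pose is the single-point energy of the
pose minus the energy of the (re-relaxed) global-minimum conformer - the
energetic price a ligand pays to adopt its bound conformation.

The energy over the scan coordinates is the cosine torsion series of the
force-field parameter set (class "generic2"/"generic3" by default, or an
explicit per-bond term list).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import energy as en
from ._geom import dihedral, rotate_about_axis, wrap_angle


class TopologyError(ValueError):
    pass


@dataclass
class SmallMolecule:
    """Minimal small-molecule container with explicit bonds."""

    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self._adj = [[] for _ in self.atom_names]
        for i, j in self.bonds:
            self._adj[i].append(j)
            self._adj[j].append(i)

    def copy(self) -> "SmallMolecule":
        return SmallMolecule(list(self.atom_names), list(self.elements),
                             self.coords.copy(), list(self.bonds))

    def moved_side(self, j: int, k: int) -> np.ndarray:
        """Atom indices on the k-side of bond j-k; error if j-k is in a ring."""
        seen = {j, k}
        stack = [k]
        while stack:
            x = stack.pop()
            for y in self._adj[x]:
                if x == k and y == j:
                    continue
                if y == j:
                    raise TopologyError(
                        f"bond {j}-{k} is part of a ring and cannot be rotated"
                    )
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        seen.discard(j)
        seen.discard(k)
        return np.array(sorted(seen | {k}), dtype=int)

    def torsion(self, quad) -> float:
        i, j, k, l = quad
        return dihedral(self.coords[i], self.coords[j], self.coords[k], self.coords[l])

    def set_torsion(self, quad, value: float) -> None:
        i, j, k, l = quad
        delta = wrap_angle(value - self.torsion(quad))
        moved = self.moved_side(j, k)
        moved = moved[moved != k]
        axis = self.coords[k] - self.coords[j]
        self.coords[moved] = rotate_about_axis(self.coords[moved], self.coords[k],
                                               axis, delta)

    @classmethod
    def from_sdf(cls, path) -> "SmallMolecule":
        from rdkit import Chem

        mol = next(m for m in Chem.SDMolSupplier(str(path), removeHs=False) if m)
        conf = mol.GetConformer()
        return cls(
            atom_names=[f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in mol.GetAtoms()],
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            coords=np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]),
            bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
        )

    def to_sdf(self, path, name: str = "conformer") -> None:
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rw = Chem.RWMol()
        for el in self.elements:
            rw.AddAtom(Chem.Atom(el))
        for i, j in self.bonds:
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        conf = Chem.Conformer(len(self.elements))
        for i, c in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(*c))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        mol.SetProp("_Name", name)
        with Chem.SDWriter(str(path)) as w:
            w.write(mol)


@dataclass(frozen=True)
class RotatableBond:
    quad: tuple[int, int, int, int]  # atom quadruple defining the torsion
    fold: int  # 2 or 3
    terms: tuple[tuple[float, int, float], ...] | None = None  # torsion series

    def __post_init__(self):
        if self.fold not in (2, 3):
            raise ValueError("fold must be 2 or 3")


@dataclass
class ScanSpec:
    rotatable_bonds: list[RotatableBond]
    start_conformer: SmallMolecule

    def __post_init__(self):
        n = len(self.start_conformer.atom_names)
        bonded = {frozenset(b) for b in self.start_conformer.bonds}
        for rb in self.rotatable_bonds:
            i, j, k, l = rb.quad
            if not all(0 <= x < n for x in rb.quad):
                raise TopologyError(f"torsion quadruple {rb.quad} references missing atoms")
            for pair in ((i, j), (j, k), (k, l)):
                if frozenset(pair) not in bonded:
                    raise TopologyError(f"torsion quadruple {rb.quad} atoms are not bonded")
            self.start_conformer.moved_side(j, k)  # ring check


@dataclass
class ConformerSet:
    conformers: list[SmallMolecule]
    energies: np.ndarray
    torsions: np.ndarray  # (n_conformers, n_bonds) minimized torsion values
    global_min_index: int
    dedup_threshold: float

    def __len__(self):
        return len(self.conformers)

    @property
    def global_min(self) -> SmallMolecule:
        return self.conformers[self.global_min_index]


def _bond_terms(spec: ScanSpec, params: en.ForceFieldParams):
    out = []
    for rb in spec.rotatable_bonds:
        if rb.terms is not None:
            out.append(list(rb.terms))
        else:
            out.append(params.torsion_terms[f"generic{rb.fold}"])
    return out


def _scan_energy(angles, terms_per_bond) -> float:
    return sum(en.torsion_energy(a, t) for a, t in zip(angles, terms_per_bond))


def _scan_gradient(angles, terms_per_bond) -> np.ndarray:
    # dE/dtheta of sum A (1 + cos(n theta - delta)), per degree
    g = np.zeros(len(angles))
    for b, (a, terms) in enumerate(zip(angles, terms_per_bond)):
        th = np.radians(a)
        for amp, n, delta in terms:
            g[b] += -amp * n * np.sin(n * th - np.radians(delta)) * np.pi / 180.0
    return g


def enumerate_and_minimize(
    spec: ScanSpec,
    params: en.ForceFieldParams | None = None,
    dedup_threshold: float = 20.0,
    grad_tol: float = 1e-4,
    extra_starts: int = 0,
) -> ConformerSet:
    """Enumerate the fold-rotamer grid, minimize each start on the torsional
    coordinates (to |grad| < `grad_tol` kcal/mol/deg), deduplicate (two
    conformers are the same if every torsion agrees within
    `dedup_threshold`), and return the energy-sorted set.

    `extra_starts` adds that many midpoint seedings per bond (finer seeding
    can only lower or keep the global minimum)."""
    params = params or en.ForceFieldParams.default()
    terms = _bond_terms(spec, params)
    if not spec.rotatable_bonds:
        return ConformerSet([spec.start_conformer.copy()], np.zeros(1),
                            np.empty((1, 0)), 0, dedup_threshold)
    start = np.array([spec.start_conformer.torsion(rb.quad) for rb in spec.rotatable_bonds])

    grids = []
    for rb, s in zip(spec.rotatable_bonds, start):
        step = 360.0 / rb.fold
        vals = [wrap_angle(s + m * step) for m in range(rb.fold)]
        if extra_starts:
            fine = 360.0 / (rb.fold * (extra_starts + 1))
            vals += [wrap_angle(s + m * fine) for m in range(rb.fold * (extra_starts + 1))]
        grids.append(vals)

    candidates = []
    for combo in _product(grids):
        x0 = np.array(combo)
        res = minimize(
            _scan_energy, x0, args=(terms,), jac=_scan_gradient, method="L-BFGS-B",
            options={"gtol": grad_tol * 0.1, "ftol": 1e-14},
        )
        angles = np.array([wrap_angle(v) for v in res.x])
        if np.max(np.abs(_scan_gradient(angles, terms))) > grad_tol:
            continue
        candidates.append((float(_scan_energy(angles, terms)), angles))

    candidates.sort(key=lambda c: (c[0], tuple(np.round(c[1], 6))))
    kept: list[tuple[float, np.ndarray]] = []
    for e, angles in candidates:
        dup = any(
            np.all(np.abs([wrap_angle(a - b) for a, b in zip(angles, prev)]) <= dedup_threshold)
            for _, prev in kept
        )
        if not dup:
            kept.append((e, angles))
    if not kept:
        kept = [(float(_scan_energy(start, terms)), start)]

    conformers = []
    for _, angles in kept:
        m = spec.start_conformer.copy()
        for rb, a in zip(spec.rotatable_bonds, angles):
            m.set_torsion(rb.quad, a)
        conformers.append(m)
    energies = np.array([e for e, _ in kept])
    torsions = np.array([a for _, a in kept]) if kept else np.empty((0, 0))
    return ConformerSet(conformers, energies, torsions, int(np.argmin(energies)),
                        dedup_threshold)


def _product(grids):
    if not grids:
        yield ()
        return
    for head in grids[0]:
        for rest in _product(grids[1:]):
            yield (head,) + tuple(rest)


def conformational_cost(
    docked_pose: SmallMolecule,
    global_min: SmallMolecule,
    spec: ScanSpec,
    params: en.ForceFieldParams | None = None,
    relax_grad: float = 0.01,
) -> float:
    """Energy cost of the docked conformation over the global minimum.

    cost = E_singlepoint(docked) - E(global minimum re-relaxed on the scan
    torsions to |grad| < `relax_grad`). Both structures must share the
    topology of the scan's start conformer."""
    for m in (docked_pose, global_min):
        if (m.elements != spec.start_conformer.elements
                or sorted(map(tuple, map(sorted, m.bonds)))
                != sorted(map(tuple, map(sorted, spec.start_conformer.bonds)))):
            raise TopologyError("pose topology does not match the scan specification")
    params = params or en.ForceFieldParams.default()
    terms = _bond_terms(spec, params)
    docked_angles = [docked_pose.torsion(rb.quad) for rb in spec.rotatable_bonds]
    e_docked = _scan_energy(docked_angles, terms)
    x0 = np.array([global_min.torsion(rb.quad) for rb in spec.rotatable_bonds])
    res = minimize(_scan_energy, x0, args=(terms,), jac=_scan_gradient,
                   method="L-BFGS-B", options={"gtol": relax_grad * 0.1, "ftol": 1e-14})
    e_min = float(res.fun)
    return float(e_docked - e_min)
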