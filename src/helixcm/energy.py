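"""Simplified molecular-mechanics energy backend.

Provides the three terms the sampler, torsion scans and interaction
decomposition need:

* Coulomb electrostatics, E = 332.0636 q_i q_j / (eps(r) r), with either a
  constant dielectric or the distance-dependent model eps(r) = c * r;
* 12-6 Lennard-Jones with per-element (epsilon, r_min) classes combined by
  Lorentz-Berthelot rules;
* cosine torsion series E(theta) = sum_k A_k (1 + cos(n_k theta - delta_k)).

Nonbonded terms use separate van der Waals and electrostatic cutoffs and
exclude 1-2 and 1-3 bonded pairs (1-4 pairs are included at full weight by
default; a scale factor is exposed). This is deliberately a minimal,
fully-documented parameter set: the package's analyses are validated against
closed forms and constructions, not against absolute energies of any
published force field.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

COULOMB_CONSTANT = 332.0636  # kcal/mol * Angstrom / e^2
KB = 0.0019872  # Boltzmann constant, kcal/(mol K)

DEFAULT_CUTOFF_NONBONDED = 8.0  # Angstrom
DEFAULT_CUTOFF_ELECTROSTATIC = 20.0  # Angstrom
HBOND_CUTOFF = 4.0  # Angstrom, reporting criterion only


class ParameterError(KeyError):
    pass


class SingularityError(ValueError):
    pass


@dataclass
class ForceFieldParams:
    """Charges, LJ classes, torsion series and the dielectric model."""

    partial_charges: dict[tuple[str, str], float]
    lj: dict[str, tuple[float, float]]  # element -> (epsilon, r_min)
    torsion_terms: dict[str, list[tuple[float, int, float]]]
    dielectric_model: tuple[str, float] = ("distance", 1.0)
    scale_14: float = 1.0

    def __post_init__(self):
        for elem, (eps, rmin) in self.lj.items():
            if eps < 0:
                raise ValueError(f"LJ epsilon for {elem} must be >= 0")
            if rmin <= 0:
                raise ValueError(f"LJ r_min for {elem} must be > 0")
        for cls, terms in self.torsion_terms.items():
            for amp, n, delta in terms:
                if int(n) < 1:
                    raise ValueError(f"torsion periodicity in class {cls} must be positive")
        model, value = self.dielectric_model
        if model not in ("constant", "distance") or value <= 0:
            raise ValueError(f"invalid dielectric model {self.dielectric_model}")

    # -- parameter resolution ------------------------------------------------
    def charge_of(self, residue_name: str, atom_name: str) -> float:
        for key in ((residue_name, atom_name), ("*", atom_name)):
            if key in self.partial_charges:
                return self.partial_charges[key]
        return 0.0

    def lj_of(self, element: str) -> tuple[float, float]:
        try:
            return self.lj[element]
        except KeyError:
            raise ParameterError(
                f"no Lennard-Jones class for element {element!r}"
            ) from None

    @classmethod
    def from_toml(cls, source) -> "ForceFieldParams":
        if isinstance(source, (str, Path)):
            data = tomllib.loads(Path(source).read_text())
        else:
            data = source
        charges = {}
        for key, q in data.get("charges", {}).items():
            res, atom = key.split(":")
            charges[(res, atom)] = float(q)
        lj = {el: (float(v[0]), float(v[1])) for el, v in data.get("lj", {}).items()}
        torsions = {
            cls_: [(float(t[0]), int(t[1]), float(t[2])) for t in terms]
            for cls_, terms in data.get("torsions", {}).items()
        }
        die = data.get("dielectric", {"model": "distance", "coeff": 1.0})
        if die["model"] == "constant":
            model = ("constant", float(die.get("eps", 1.0)))
        else:
            model = ("distance", float(die.get("coeff", 1.0)))
        return cls(charges, lj, torsions, model)

    @classmethod
    def default(cls) -> "ForceFieldParams":
        text = resources.files("helixcm.data").joinpath("default_ff.toml").read_text()
        return cls.from_toml(tomllib.loads(text))


@dataclass
class EnergyBreakdown:
    torsional: float = 0.0
    lennard_jones: float = 0.0
    coulomb: float = 0.0

    @property
    def total(self) -> float:
        return self.torsional + self.lennard_jones + self.coulomb


def torsion_energy(angle_deg, terms) -> float:
    """Cosine-series torsion energy, E = sum A (1 + cos(n theta - delta))."""
    if not terms:
        raise ValueError("torsion term list is empty")
    theta = np.radians(np.asarray(angle_deg, dtype=float))
    e = np.zeros_like(theta)
    for amp, n, delta in terms:
        e = e + amp * (1.0 + np.cos(n * theta - np.radians(delta)))
    return float(e) if np.ndim(angle_deg) == 0 else e


def _excluded_pairs(bonds, n_atoms: int):
    """Sets of 1-2/1-3 pairs (excluded) and 1-4 pairs (scaled)."""
    adj = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excl, pairs14 = set(), set()
    for i in range(n_atoms):
        for j in adj[i]:
            if i < j:
                excl.add((i, j))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
                    for l in adj[k]:
                        if l not in (i, j):
                            pairs14.add((min(i, l), max(i, l)))
    return excl, pairs14 - excl


@dataclass
class NonbondedSystem:
    """Precompiled pair lists and per-atom parameters for fast evaluation."""

    q: np.ndarray
    eps: np.ndarray
    rmin: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_scale: np.ndarray
    qq: np.ndarray = field(init=False)
    eps_ij: np.ndarray = field(init=False)
    rmin_ij: np.ndarray = field(init=False)

    def __post_init__(self):
        self.qq = self.q[self.pair_i] * self.q[self.pair_j]
        self.eps_ij = np.sqrt(self.eps[self.pair_i] * self.eps[self.pair_j])
        self.rmin_ij = 0.5 * (self.rmin[self.pair_i] + self.rmin[self.pair_j])


def _atom_params(atoms, params: ForceFieldParams):
    q = np.empty(len(atoms))
    eps = np.empty(len(atoms))
    rmin = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        q[k] = a.partial_charge if a.partial_charge is not None else params.charge_of(
            a.residue_name, a.name
        )
        if a.lj_params is not None:
            eps[k], rmin[k] = a.lj_params
        else:
            try:
                eps[k], rmin[k] = params.lj_of(a.element)
            except ParameterError:
                raise ParameterError(
                    f"unparameterized atom ({a.residue_name}{a.residue_index}, {a.name})"
                ) from None
    return q, eps, rmin


def compile_intra(structure, params: ForceFieldParams) -> NonbondedSystem:
    """Pair list for all intra-structure nonbonded interactions."""
    atoms = list(structure.atoms())
    n = len(atoms)
    q, eps, rmin = _atom_params(atoms, params)
    excl, p14 = _excluded_pairs(structure.bonds(), n)
    pi, pj, sc = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            pi.append(i)
            pj.append(j)
            sc.append(params.scale_14 if (i, j) in p14 else 1.0)
    return NonbondedSystem(q, eps, rmin, np.array(pi, int), np.array(pj, int),
                           np.array(sc, float))


def compile_pair(atoms_a, atoms_b, params: ForceFieldParams) -> NonbondedSystem:
    """Pair list between two disjoint atom groups (all cross pairs)."""
    atoms = list(atoms_a) + list(atoms_b)
    na, nb = len(atoms_a), len(atoms_b)
    q, eps, rmin = _atom_params(atoms, params)
    pi = np.repeat(np.arange(na), nb)
    pj = na + np.tile(np.arange(nb), na)
    return NonbondedSystem(q, eps, rmin, pi, pj, np.ones(na * nb))


try:  # jit-compiled hot path; the pure-numpy branch below is the reference
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _nb_kernel(coords, qq, eps_ij, rmin_ij, scale, pi, pj,
                   cut_nb2, cut_el2, die_distance, die_value):  # pragma: no cover
        e_lj = 0.0
        e_coul = 0.0
        min_r2 = 1e30
        for k in range(pi.shape[0]):
            dx = coords[pi[k], 0] - coords[pj[k], 0]
            dy = coords[pi[k], 1] - coords[pj[k], 1]
            dz = coords[pi[k], 2] - coords[pj[k], 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < min_r2:
                min_r2 = r2
            if r2 < 1e-12:  # singularity; reported by the caller
                continue
            if r2 <= cut_nb2:
                x2 = rmin_ij[k] * rmin_ij[k] / r2
                x6 = x2 * x2 * x2
                e_lj += scale[k] * eps_ij[k] * (x6 * x6 - 2.0 * x6)
            if qq[k] != 0.0 and r2 <= cut_el2:
                if die_distance:
                    denom = die_value * r2
                else:
                    denom = die_value * np.sqrt(r2)
                e_coul += scale[k] * COULOMB_CONSTANT * qq[k] / denom
        return e_lj, e_coul, min_r2

except ImportError:  # pragma: no cover
    _nb_kernel = None


def nonbonded_energy(
    system: NonbondedSystem,
    coords: np.ndarray,
    dielectric: tuple[str, float],
    cutoff_nonbonded: float = DEFAULT_CUTOFF_NONBONDED,
    cutoff_electrostatic: float = DEFAULT_CUTOFF_ELECTROSTATIC,
) -> tuple[float, float]:
    """(lennard_jones, coulomb) over the compiled pair list, in kcal/mol."""
    if cutoff_nonbonded <= 0 or cutoff_electrostatic <= 0:
        raise ValueError("cutoffs must be positive")
    model, value = dielectric
    if _nb_kernel is not None:
        e_lj, e_coul, min_r2 = _nb_kernel(
            np.ascontiguousarray(coords, dtype=np.float64),
            system.qq, system.eps_ij, system.rmin_ij, system.pair_scale,
            system.pair_i, system.pair_j,
            cutoff_nonbonded**2, cutoff_electrostatic**2,
            model == "distance", value,
        )
        if system.pair_i.size and min_r2 < 1e-12:
            raise SingularityError("zero interatomic distance in energy evaluation")
        return e_lj, e_coul
    d = coords[system.pair_i] - coords[system.pair_j]
    r2 = np.einsum("ij,ij->i", d, d)
    if system.pair_i.size and r2.min() < 1e-12:
        raise SingularityError("zero interatomic distance in energy evaluation")
    lj_mask = r2 <= cutoff_nonbonded**2
    x6 = (system.rmin_ij[lj_mask] ** 2 / r2[lj_mask]) ** 3
    e_lj = float(
        np.sum(system.pair_scale[lj_mask] * system.eps_ij[lj_mask] * (x6 * x6 - 2.0 * x6))
    )
    el_mask = (r2 <= cutoff_electrostatic**2) & (system.qq != 0.0)
    model, value = dielectric
    if model == "constant":
        denom = value * np.sqrt(r2[el_mask])
    else:  # eps(r) = coeff * r  =>  eps(r) * r = coeff * r^2
        denom = value * r2[el_mask]
    e_coul = float(
        np.sum(system.pair_scale[el_mask] * COULOMB_CONSTANT * system.qq[el_mask] / denom)
    )
    return e_lj, e_coul


def evaluate_energy(
    target,
    params: ForceFieldParams,
    cutoff_nonbonded: float = DEFAULT_CUTOFF_NONBONDED,
    cutoff_electrostatic: float = DEFAULT_CUTOFF_ELECTROSTATIC,
    torsions: list[tuple[float, str]] | None = None,
) -> EnergyBreakdown:
    """Evaluate the energy of a structure or of an atom-group pair.

    `target` is either a `HelixStructure` (intramolecular mode: all pairs
    excluding 1-2/1-3) or a 2-tuple of atom lists (group-pair mode: cross
    pairs only). `torsions` optionally lists (angle_deg, class) dihedrals to
    score with the parameter set's torsion series; in intramolecular mode it
    defaults to all defined backbone phi/psi/omega dihedrals.
    """
    if isinstance(target, tuple):
        system = compile_pair(target[0], target[1], params)
        coords = np.array([a.coords for a in list(target[0]) + list(target[1])])
        tors = torsions or []
    else:
        system = compile_intra(target, params)
        coords = target.coords()
        if torsions is None:
            tors = []
            for name in ("phi", "psi", "omega"):
                vals = getattr(target, name)
                tors += [(v, name) for v in vals[np.isfinite(vals)]]
        else:
            tors = torsions
    e_lj, e_coul = nonbonded_energy(system, coords, params.dielectric_model,
                                    cutoff_nonbonded, cutoff_electrostatic)
    e_tors = 0.0
    for angle, cls_ in tors:
        terms = params.torsion_terms.get(cls_)
        if terms:
            e_tors += torsion_energy(angle, terms)
    return EnergyBreakdown(torsional=e_tors, lennard_jones=e_lj, coulomb=e_coul)
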