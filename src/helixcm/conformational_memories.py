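"""Conformational Memories: two-phase Monte-Carlo/simulated-annealing sampling
of transmembrane-helix hinge conformations.

The method explores the conformations a helix-bending "hinge" region (the
hinge residue plus the four residues preceding it) can adopt at biological
temperature. Phase 1 (exploratory) anneals from a high temperature down to
310 K; at each temperature a fixed number of Metropolis MC steps is applied,
each step re-drawing two of the free backbone dihedrals uniformly within
their allowed ranges and perturbing one free N-CA-C bond angle within +/-8
degrees of ideal. Accepted states populate per-dihedral histograms - the
"memories". Phase 2 (biased) anneals again from a lower starting
temperature, drawing dihedral proposals only within the retained
(highly-populated) histogram bins, and the output ensemble is taken from
evenly spaced accepted states at the final (310 K) temperature.

Defaults follow the standard CM protocol: exploratory 3000 K -> 310 K in 18
temperature steps, biased 749.4 K -> 310 K in 9 steps, 50,000 MC steps per
temperature, 112 output conformers. Proline hinges restrict the proline
backbone to -120 < phi < 40, -70 < psi < 0, -160 < omega < 160 (omega is
otherwise held fixed at 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import energy as en
from .helix_geometry import kabsch_rmsd
from .residues import ANGLE_N_CA_C
from .structure import HelixStructure

KB = en.KB

DEFAULT_EXPLORATORY = (3000.0, 310.0, 18)
DEFAULT_BIASED = (749.4, 310.0, 9)
DEFAULT_MC_STEPS = 50_000
DEFAULT_N_OUTPUT = 112

PROLINE_RANGES = {"phi": (-120.0, 40.0), "psi": (-70.0, 0.0), "omega": (-160.0, 160.0)}


class EmptyMemoryError(RuntimeError):
    pass


class NoAcceptedStatesError(RuntimeError):
    pass


# ------------------------------------------------------------------ schedule

@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric cooling ladder from t_start to t_end (Kelvin)."""

    t_start: float
    t_end: float
    n_steps: int
    mc_steps_per_temperature: int = DEFAULT_MC_STEPS

    def __post_init__(self):
        if self.t_end <= 0 or self.t_start < self.t_end:
            raise ValueError("require t_start >= t_end > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_steps == 1 and self.t_start != self.t_end:
            raise ValueError("a single-step schedule requires t_start == t_end")

    def temperatures(self) -> np.ndarray:
        if self.n_steps == 1 or self.t_start == self.t_end:
            return np.full(self.n_steps, float(self.t_end))
        i = np.arange(self.n_steps)
        return self.t_start * (self.t_end / self.t_start) ** (i / (self.n_steps - 1))


def make_schedule(t_start: float, t_end: float, n_steps: int,
                  mc_steps_per_temperature: int = DEFAULT_MC_STEPS) -> AnnealingSchedule:
    return AnnealingSchedule(t_start, t_end, n_steps, mc_steps_per_temperature)


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/kT))."""
    import math

    if not math.isfinite(delta_e):
        raise ValueError("non-finite energy difference")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / (KB * temperature))


# ----------------------------------------------------------------- hinge spec

@dataclass(frozen=True)
class FreeDihedral:
    residue_pos: int  # 0-based position within the structure
    name: str  # phi | psi | omega
    lo: float = -180.0
    hi: float = 180.0
    torsion_class: str | None = None  # override torsion-term class for energy

    def __post_init__(self):
        if not (-180.0 <= self.lo < self.hi <= 180.0):
            raise ValueError(f"dihedral range ({self.lo}, {self.hi}) not within (-180, 180]")


@dataclass(frozen=True)
class FreeBondAngle:
    residue_pos: int
    center: float = ANGLE_N_CA_C
    halfwidth: float = 8.0


@dataclass(frozen=True)
class HingeSpec:
    """Which coordinates the sampler may vary, and within what ranges."""

    hinge_residue: int  # 0-based position of the hinge residue
    free_dihedrals: tuple[FreeDihedral, ...]
    free_bond_angles: tuple[FreeBondAngle, ...]

    @property
    def region(self) -> tuple[int, ...]:
        """Hinge residue plus the four residues preceding it."""
        return tuple(range(self.hinge_residue - 4, self.hinge_residue + 1))

    @classmethod
    def for_hinge(cls, structure: HelixStructure, hinge_pos: int,
                  free_omega_for_proline: bool = True) -> "HingeSpec":
        """Standard spec: free phi/psi (plus N-CA-C angle) on the hinge residue
        and the four preceding residues; a proline hinge additionally frees
        omega and narrows its ranges to the database-derived proline windows."""
        if hinge_pos < 4 or hinge_pos >= structure.n_residues:
            raise ValueError("hinge must have at least four preceding residues")
        dihedrals: list[FreeDihedral] = []
        angles: list[FreeBondAngle] = []
        for pos in range(hinge_pos - 4, hinge_pos + 1):
            is_pro = structure.residues[pos].name == "PRO"
            for name in ("phi", "psi"):
                if not np.isfinite(getattr(structure, name)[pos]):
                    continue
                lo, hi = PROLINE_RANGES[name] if is_pro else (-180.0, 180.0)
                dihedrals.append(FreeDihedral(pos, name, lo, hi))
            if is_pro and free_omega_for_proline and np.isfinite(structure.omega[pos]):
                lo, hi = PROLINE_RANGES["omega"]
                dihedrals.append(FreeDihedral(pos, "omega", lo, hi))
            angles.append(FreeBondAngle(pos))
        return cls(hinge_pos, tuple(dihedrals), tuple(angles))


# ----------------------------------------------------------------- memory map

@dataclass
class MemoryMap:
    """Per-dihedral population histograms of accepted exploratory states."""

    dihedrals: tuple[FreeDihedral, ...]
    bin_width: float
    edges: list[np.ndarray]
    counts: list[np.ndarray]
    retention_fraction: float

    @property
    def n_accepted(self) -> int:
        return int(self.counts[0].sum()) if self.counts else 0

    def retained(self, i: int) -> np.ndarray:
        """Boolean mask of retained (highly populated) bins for dihedral i."""
        c = self.counts[i]
        return c >= max(1.0, self.retention_fraction * c.sum())

    def retained_intervals(self, i: int) -> list[tuple[float, float]]:
        mask = self.retained(i)
        e = self.edges[i]
        return [(float(e[k]), float(e[k + 1])) for k in np.flatnonzero(mask)]

    def to_tsv(self, path) -> None:
        lines = ["dihedral\tbin_start\tbin_end\tcount\tretained"]
        for i, d in enumerate(self.dihedrals):
            ret = self.retained(i)
            for k in range(len(self.counts[i])):
                lines.append(
                    f"res{d.residue_pos}:{d.name}\t{self.edges[i][k]:.1f}\t"
                    f"{self.edges[i][k + 1]:.1f}\t{int(self.counts[i][k])}\t{int(ret[k])}"
                )
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def _make_memory(dihedrals, samples: np.ndarray, bin_width: float,
                 retention_fraction: float) -> MemoryMap:
    edges, counts = [], []
    for i, d in enumerate(dihedrals):
        e = np.arange(d.lo, d.hi, bin_width, dtype=float)
        e = np.append(e, d.hi)
        c, _ = np.histogram(samples[:, i], bins=e) if samples.size else (
            np.zeros(len(e) - 1, int), e)
        edges.append(e)
        counts.append(c.astype(float))
    return MemoryMap(tuple(dihedrals), bin_width, edges, counts, retention_fraction)


# ------------------------------------------------------------------ ensembles

@dataclass
class ConformerEnsemble:
    frames: list[HelixStructure]
    energies: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) != len(self.energies):
            raise ValueError("frames and energies length mismatch")

    def __len__(self) -> int:
        return len(self.frames)


def superpose_ensemble(ensemble: ConformerEnsemble, anchor: tuple[int, int]) -> ConformerEnsemble:
    """Rigid-body superpose every frame onto frame 0 over the anchor backbone.

    `anchor` is an inclusive (start, end) pair of 0-based residue positions;
    the least-squares fit uses the anchor N/CA/C atoms.
    """
    lo, hi = anchor
    if hi - lo + 1 < 3:
        raise ValueError("anchor must span at least 3 residues")
    sl = slice(lo, hi + 1)
    ref = ensemble.frames[0].backbone_coords(residue_slice=sl)
    out_frames = []
    for f in ensemble.frames:
        g = f.copy()
        mob = g.backbone_coords(residue_slice=sl)
        _, (R, t) = kabsch_rmsd(ref, mob, superpose=True, return_transform=True)
        g.set_coords(g.coords() @ R.T + t)
        out_frames.append(g)
    return ConformerEnsemble(out_frames, ensemble.energies.copy(), dict(ensemble.provenance))


# ----------------------------------------------------------- sampler internals

class _CMState:
    """Compact mutable sampler state over one helix topology.

    Moves are applied as rigid rotations of the atoms downstream of the
    varied coordinate, which is equivalent to rebuilding from internal
    coordinates but costs one small matrix product.
    """

    def __init__(self, helix: HelixStructure, spec: HingeSpec, params: en.ForceFieldParams,
                 cutoff_nonbonded: float = en.DEFAULT_CUTOFF_NONBONDED,
                 cutoff_electrostatic: float = en.DEFAULT_CUTOFF_ELECTROSTATIC):
        self.template = helix.copy()
        self.template.measure_internal()
        self.spec = spec
        self.params = params
        self.cut_nb = cutoff_nonbonded
        self.cut_el = cutoff_electrostatic
        self.system = en.compile_intra(self.template, params)
        self.coords = self.template.coords()
        self.n_atoms = self.coords.shape[0]

        self._dih_info = [self._dihedral_move_info(d) for d in spec.free_dihedrals]
        self._ang_info = [self._angle_move_info(a) for a in spec.free_bond_angles]
        self.dih_values = np.array(
            [getattr(self.template, d.name)[d.residue_pos] for d in spec.free_dihedrals]
        )
        self.ang_values = np.array(
            [self.template.n_ca_c[a.residue_pos] for a in spec.free_bond_angles]
        )
        self._dih_terms = [
            params.torsion_terms.get(d.torsion_class or d.name, []) for d in spec.free_dihedrals
        ]
        # flattened torsion-term arrays for vectorized evaluation
        t_idx, t_amp, t_n, t_delta = [], [], [], []
        for k, terms in enumerate(self._dih_terms):
            for amp, n, delta in terms:
                t_idx.append(k)
                t_amp.append(amp)
                t_n.append(n)
                t_delta.append(np.radians(delta))
        self._t_idx = np.array(t_idx, int)
        self._t_amp = np.array(t_amp)
        self._t_n = np.array(t_n, float)
        self._t_delta = np.array(t_delta)
        self.energy = self._full_energy(self.coords, self.dih_values)

    # -- topology helpers ---------------------------------------------------
    def _downstream(self, first_res: int, first_atoms: tuple[str, ...]) -> np.ndarray:
        """Global indices of atoms that move when a coordinate at `first_res`
        changes: the listed atoms of that residue plus all later residues."""
        h = self.template
        idx = [h.atom_index(first_res, n) for n in first_atoms
               if h.residues[first_res].has_atom(n)]
        off = sum(len(r.atoms) for r in h.residues[: first_res + 1])
        idx += list(range(off, self.n_atoms))
        return np.array(sorted(idx), dtype=int)

    def _dihedral_move_info(self, d: FreeDihedral):
        h = self.template
        i = d.residue_pos
        res = h.residues[i]
        side = [a.name for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
        if d.name == "phi":  # axis N->CA; moves C, O and the side chain of i
            axis = (h.atom_index(i, "N"), h.atom_index(i, "CA"))
            moved = self._downstream(i, tuple(["C", "O"] + side))
        elif d.name == "psi":  # axis CA->C; moves O of i and later residues
            axis = (h.atom_index(i, "CA"), h.atom_index(i, "C"))
            moved = self._downstream(i, ("O",))
        else:  # omega: axis C(i-1)->N(i); moves everything from CA(i) on
            axis = (h.atom_index(i - 1, "C"), h.atom_index(i, "N"))
            moved = self._downstream(i, tuple(["CA", "C", "O"] + side))
        return axis, moved

    def _angle_move_info(self, a: FreeBondAngle):
        # N-CA-C angle: rotate C (and everything downstream of it) about the
        # normal of the N-CA-C plane through CA
        h = self.template
        i = a.residue_pos
        side = [x.name for x in h.residues[i].atoms if x.name not in ("N", "CA", "C", "O")]
        moved = self._downstream(i, ("C", "O"))
        return (h.atom_index(i, "N"), h.atom_index(i, "CA"), h.atom_index(i, "C")), moved

    # -- energy -------------------------------------------------------------
    def _full_energy(self, coords: np.ndarray, dih_values: np.ndarray) -> float:
        e_lj, e_coul = en.nonbonded_energy(self.system, coords, self.params.dielectric_model,
                                           self.cut_nb, self.cut_el)
        if self._t_idx.size:
            th = np.radians(dih_values[self._t_idx])
            e_tors = float(np.sum(self._t_amp * (1.0 + np.cos(self._t_n * th - self._t_delta))))
        else:
            e_tors = 0.0
        return e_lj + e_coul + e_tors

    # -- move application ---------------------------------------------------
    def apply_dihedral(self, coords: np.ndarray, k: int, old: float, new: float) -> None:
        (ia, ib), moved = self._dih_info[k]
        delta = new - old  # rotations are 360-periodic; no wrap needed
        if delta == 0.0:
            return
        R = _fast_rotation(coords[ib] - coords[ia], delta)
        pivot = coords[ib]
        coords[moved] = (coords[moved] - pivot) @ R.T + pivot

    def apply_angle(self, coords: np.ndarray, k: int, old: float, new: float) -> None:
        (iN, iCA, iC), moved = self._ang_info[k]
        delta = new - old
        if delta == 0.0:
            return
        a = coords[iN] - coords[iCA]
        b = coords[iC] - coords[iCA]
        normal = (a[1] * b[2] - a[2] * b[1], a[2] * b[0] - a[0] * b[2],
                  a[0] * b[1] - a[1] * b[0])
        R = _fast_rotation(normal, delta)
        pivot = coords[iCA]
        coords[moved] = (coords[moved] - pivot) @ R.T + pivot

    # -- conformer export ---------------------------------------------------
    def structure_for(self, dih_values: np.ndarray, ang_values: np.ndarray) -> HelixStructure:
        h = self.template.copy()
        for d, v in zip(self.spec.free_dihedrals, dih_values):
            getattr(h, d.name)[d.residue_pos] = v
        for a, v in zip(self.spec.free_bond_angles, ang_values):
            h.n_ca_c[a.residue_pos] = v
        h.rebuild_cartesian()
        return h


def _fast_rotation(axis, angle_deg: float) -> np.ndarray:
    import math

    ux, uy, uz = float(axis[0]), float(axis[1]), float(axis[2])
    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / norm, uy / norm, uz / norm
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
            [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
            [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
        ]
    )


def _bias_intervals(memory: MemoryMap) -> list[list[tuple[float, float]]]:
    intervals = []
    for k, d in enumerate(memory.dihedrals):
        iv = memory.retained_intervals(k)
        if not iv:
            raise EmptyMemoryError(
                f"no retained memory bins for res{d.residue_pos}:{d.name}; "
                "lower the retention threshold"
            )
        intervals.append(iv)
    return intervals


def propose_move(state: _CMState, rng: np.random.Generator,
                 memory: MemoryMap | None = None, bias_intervals=None):
    """One CM move: re-draw two free dihedrals (uniform in range, or within
    retained memory bins) and perturb one free bond angle. Returns
    (coords, dih_values, ang_values) of the candidate."""
    spec = state.spec
    if memory is not None and bias_intervals is None:
        bias_intervals = _bias_intervals(memory)
    coords = state.coords.copy()
    dih = state.dih_values.copy()
    ang = state.ang_values.copy()
    nd = len(spec.free_dihedrals)
    if nd == 1:
        chosen = (0,)
    else:
        k1 = int(rng.integers(nd))
        k2 = int(rng.integers(nd - 1))
        if k2 >= k1:
            k2 += 1
        chosen = (k1, k2) if k1 < k2 else (k2, k1)
    for k in chosen:
        d = spec.free_dihedrals[k]
        if bias_intervals is None:
            new = rng.uniform(d.lo, d.hi)
        else:
            iv = bias_intervals[k]
            lo, hi = iv[int(rng.integers(len(iv)))] if len(iv) > 1 else iv[0]
            new = rng.uniform(lo, hi)
        state.apply_dihedral(coords, k, dih[k], new)
        dih[k] = new
    if spec.free_bond_angles:
        k = int(rng.integers(len(spec.free_bond_angles)))
        a = spec.free_bond_angles[k]
        new = rng.uniform(a.center - a.halfwidth, a.center + a.halfwidth)
        state.apply_angle(coords, k, ang[k], new)
        ang[k] = new
    return coords, dih, ang


def _run_phase(state: _CMState, schedule: AnnealingSchedule, rng,
               memory: MemoryMap | None, record_final_t: bool):
    """Anneal through one schedule. Returns (accepted dihedral samples over
    the whole phase, accepted (dih, ang, E) states at the final temperature,
    acceptance-rate trace)."""
    accepted_samples = []
    final_states = []
    acc_trace = []
    intervals = _bias_intervals(memory) if memory is not None else None
    temps = schedule.temperatures()
    for t_index, T in enumerate(temps):
        is_final = t_index == len(temps) - 1
        n_acc = 0
        for _ in range(schedule.mc_steps_per_temperature):
            coords, dih, ang = propose_move(state, rng, None, intervals)
            e_new = state._full_energy(coords, dih)
            if metropolis_accept(e_new - state.energy, T, rng):
                state.coords, state.dih_values, state.ang_values = coords, dih, ang
                state.energy = e_new
                n_acc += 1
                accepted_samples.append(dih.copy())
                if is_final and record_final_t:
                    final_states.append((dih.copy(), ang.copy(), e_new))
        acc_trace.append(n_acc / schedule.mc_steps_per_temperature)
    return np.array(accepted_samples), final_states, acc_trace


def run_cm(
    helix: HelixStructure,
    spec: HingeSpec,
    params: en.ForceFieldParams | None = None,
    exploratory: AnnealingSchedule | None = None,
    biased: AnnealingSchedule | None = None,
    n_output: int = DEFAULT_N_OUTPUT,
    seed: int = 0,
    bin_width: float = 10.0,
    retention_fraction: float = 0.01,
) -> tuple[MemoryMap, ConformerEnsemble]:
    """Run both CM phases and return the memory map and output ensemble.

    Deterministic for a fixed seed. The ensemble holds `n_output` conformers
    drawn at evenly spaced accepted states of the biased phase's final
    (310 K) temperature, with their sampled energies.
    """
    params = params or en.ForceFieldParams.default()
    exploratory = exploratory or make_schedule(*DEFAULT_EXPLORATORY)
    biased = biased or make_schedule(*DEFAULT_BIASED)
    rng = np.random.default_rng(seed)

    state = _CMState(helix, spec, params)
    samples, _, trace1 = _run_phase(state, exploratory, rng, memory=None,
                                    record_final_t=False)
    memory = _make_memory(spec.free_dihedrals, samples, bin_width, retention_fraction)

    # biased phase restarts from the template conformation
    state2 = _CMState(helix, spec, params)
    _, final_states, trace2 = _run_phase(state2, biased, rng, memory=memory,
                                         record_final_t=True)
    if not final_states:
        raise NoAcceptedStatesError(
            "no accepted states at the final temperature; acceptance-rate trace: "
            f"exploratory={np.round(trace1, 4).tolist()}, biased={np.round(trace2, 4).tolist()}"
        )
    pick = np.unique(np.linspace(0, len(final_states) - 1, min(n_output, len(final_states))
                                 ).round().astype(int))
    frames = []
    energies = []
    for k in pick:
        dih, ang, e = final_states[k]
        frames.append(state2.structure_for(dih, ang))
        energies.append(e)
    ensemble = ConformerEnsemble(
        frames,
        np.array(energies),
        provenance={
            "seed": seed,
            "exploratory": (exploratory.t_start, exploratory.t_end, exploratory.n_steps,
                            exploratory.mc_steps_per_temperature),
            "biased": (biased.t_start, biased.t_end, biased.n_steps,
                       biased.mc_steps_per_temperature),
            "bin_width": bin_width,
            "retention_fraction": retention_fraction,
            "n_output": n_output,
            "acceptance_trace": {"exploratory": trace1, "biased": trace2},
        },
    )
    return memory, ensemble


def sample_fixed_temperature(
    helix: HelixStructure,
    spec: HingeSpec,
    params: en.ForceFieldParams | None = None,
    temperature: float = 310.0,
    n_steps: int = 50_000,
    seed: int = 0,
    burn_in: int = 1_000,
) -> np.ndarray:
    """Fixed-temperature Metropolis sampling; returns the chain's free-dihedral
    values at every post-burn-in step (shape (n_steps, n_free_dihedrals)).

    Used for Boltzmann-recovery checks against analytic 1-D potentials."""
    params = params or en.ForceFieldParams.default()
    rng = np.random.default_rng(seed)
    state = _CMState(helix, spec, params)
    out = np.empty((n_steps, len(spec.free_dihedrals)))
    for step in range(burn_in + n_steps):
        coords, dih, ang = propose_move(state, rng, memory=None)
        e_new = state._full_energy(coords, dih)
        if metropolis_accept(e_new - state.energy, temperature, rng):
            state.coords, state.dih_values, state.ang_values = coords, dih, ang
            state.energy = e_new
        if step >= burn_in:
            out[step - burn_in] = state.dih_values
    return out
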