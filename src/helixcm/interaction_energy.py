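"""Per-residue ligand-receptor interaction-energy decomposition.

For a docked ligand-receptor complex, the ligand atoms form one group and
each binding-site residue with at least one atom within the shell radius
(default 5 A) of any ligand atom forms the other; the pairwise Coulombic and
van der Waals energies are evaluated per residue with an extended cutoff
scheme (nonbonded 8.0 A, electrostatic 20.0 A) and the distance-dependent
dielectric eps(r) = 2r, and reported most-stabilizing first together with
the total. Atom pairs within the 4.0 A hydrogen-bonding cutoff are flagged
as potential hydrogen bonds (a reporting criterion; the energy model has no
separate H-bond term).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import energy as en

DEFAULT_SHELL_RADIUS = 5.0  # Angstrom
INTERACTION_DIELECTRIC = ("distance", 2.0)  # eps(r) = 2r


@dataclass
class InteractionTable:
    """Per-residue interaction terms (kcal/mol), most stabilizing first."""

    table: pd.DataFrame  # columns: residue, coulomb, vdw, sum
    total_interaction: float
    shell_radius: float
    hbond_flags: list[tuple[str, str, float]]  # (ligand atom, residue atom, distance)

    def __post_init__(self):
        if abs(self.table["sum"].sum() - self.total_interaction) > 1e-8:
            raise AssertionError("per-residue sums do not add up to the total")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def summary(self) -> dict:
        return {
            "total_interaction_kcal_mol": self.total_interaction,
            "shell_radius_angstrom": self.shell_radius,
            "n_residues": int(len(self.table)),
            "potential_hbonds": [
                {"ligand_atom": a, "residue_atom": b, "distance": d}
                for a, b, d in self.hbond_flags
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def pairwise_interaction(
    ligand_atoms,
    receptor,
    params: en.ForceFieldParams | None = None,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
    cutoff_nonbonded: float = en.DEFAULT_CUTOFF_NONBONDED,
    cutoff_electrostatic: float = en.DEFAULT_CUTOFF_ELECTROSTATIC,
    dielectric: tuple[str, float] = INTERACTION_DIELECTRIC,
) -> InteractionTable:
    """Decompose the ligand-receptor interaction energy per residue.

    `ligand_atoms` is a non-empty list of `AtomRecord`; `receptor` a
    structure whose residues are screened against the shell radius. Residues
    without any atom inside the shell do not appear in the table.
    """
    ligand_atoms = list(ligand_atoms)
    if not ligand_atoms:
        raise ValueError("ligand group is empty")
    params = params or en.ForceFieldParams.default()
    params_for_pair = en.ForceFieldParams(
        params.partial_charges, params.lj, params.torsion_terms, dielectric,
        params.scale_14,
    )
    lig_ids = {id(a) for a in ligand_atoms}
    lig_xyz = np.array([a.coords for a in ligand_atoms])

    rows = []
    hbonds = []
    for res in receptor.residues:
        res_atoms = [a for a in res.atoms if id(a) not in lig_ids]
        if not res_atoms:
            continue
        xyz = np.array([a.coords for a in res_atoms])
        dmin = np.sqrt(((lig_xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1))
        if dmin.min() > shell_radius:
            continue
        system = en.compile_pair(ligand_atoms, res_atoms, params_for_pair)
        coords = np.vstack([lig_xyz, xyz])
        e_lj, e_coul = en.nonbonded_energy(system, coords, dielectric,
                                           cutoff_nonbonded, cutoff_electrostatic)
        rows.append((f"{res.name}{res.index}", e_coul, e_lj, e_coul + e_lj))
        for i, la in enumerate(ligand_atoms):
            for j, ra in enumerate(res_atoms):
                if dmin[i, j] <= en.HBOND_CUTOFF and la.element in "NO" and ra.element in "NO":
                    hbonds.append((la.name, f"{res.name}{res.index}:{ra.name}",
                                   float(dmin[i, j])))

    table = pd.DataFrame(rows, columns=["residue", "coulomb", "vdw", "sum"])
    table = table.sort_values("sum", kind="stable", ignore_index=True)
    return InteractionTable(table, float(table["sum"].sum()), shell_radius, hbonds)
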