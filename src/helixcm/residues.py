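"""Per-residue-type covalent templates.

Side-chain internal coordinates (bond lengths, angles, torsions and the
atom-name connectivity) are extracted once per residue type from the ideal
CCD conformers bundled with biotite, converted to a Z-matrix rooted at CA.
The first heavy atom bonded to CB is tagged as the chi1-defining atom, so a
structure can be rebuilt with an arbitrary chi1 while deeper side-chain
torsions stay at their ideal-conformer values.

Backbone covalent geometry is fixed at a single ideal table; the sampler
varies only dihedrals and the N-CA-C bond angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._geom import bond_angle, dihedral

# ideal backbone covalent geometry (lengths in Angstrom, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class ZRow:
    """One side-chain atom placement: d bonded to ref c, with angle(b,c,d)
    and dihedral(a,b,c,d); `chi_offset` is set when the torsion rides on chi1
    (actual torsion = chi1 + chi_offset)."""

    name: str
    element: str
    refs: tuple[str, str, str]  # (a, b, c)
    length: float
    angle: float
    torsion: float
    chi_offset: float | None = None


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    sidechain: tuple[ZRow, ...]
    bonds: tuple[tuple[str, str], ...]  # heavy-atom bonds within the residue
    chi1_atom: str | None  # gamma heavy atom defining chi1 (N-CA-CB-X)
    default_chi1: float | None


def _heavy_template(resname: str):
    import biotite.structure.info as info

    arr = info.residue(resname)
    if arr is None:
        raise KeyError(f"unknown residue code {resname!r}")
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    return arr[keep]


@lru_cache(maxsize=None)
def residue_template(resname: str) -> ResidueTemplate:
    """Build (and cache) the side-chain Z-matrix for a residue type."""
    resname = resname.upper()
    if resname not in THREE_TO_ONE:
        raise KeyError(f"unknown residue code {resname!r}")
    arr = _heavy_template(resname)
    names = list(arr.atom_name)
    coords = {n: arr.coord[i] for i, n in enumerate(names)}
    adj: dict[str, list[str]] = {n: [] for n in names}
    bonds = []
    for i, j, _ in arr.bonds.as_array():
        ni, nj = names[int(i)], names[int(j)]
        adj[ni].append(nj)
        adj[nj].append(ni)
        bonds.append((ni, nj))

    # BFS from CA into the side chain, keeping template atom order
    order_key = {n: k for k, n in enumerate(names)}
    parent = {"CA": "N", "N": "C"}
    placed = ["C", "N", "CA"]
    queue = ["CA"]
    rows: list[ZRow] = []
    chi1_atom = None
    default_chi1 = None
    while queue:
        c = queue.pop(0)
        children = sorted(
            (x for x in adj[c] if x not in placed and x not in BACKBONE_ATOMS),
            key=lambda n: order_key[n],
        )
        first_cb_child = True
        for d in children:
            b = parent[c]
            a = parent[b]
            torsion = dihedral(coords[a], coords[b], coords[c], coords[d])
            chi_offset = None
            if c == "CB":
                if first_cb_child:
                    chi1_atom, default_chi1 = d, torsion
                chi_offset = torsion - default_chi1
            rows.append(
                ZRow(
                    name=d,
                    element=str(arr.element[order_key[d]]),
                    refs=(a, b, c),
                    length=float(np.linalg.norm(coords[d] - coords[c])),
                    angle=bond_angle(coords[b], coords[c], coords[d]),
                    torsion=float(torsion),
                    chi_offset=None if chi_offset is None else float(chi_offset),
                )
            )
            parent[d] = c
            placed.append(d)
            queue.append(d)
            if c == "CB":
                first_cb_child = False
    return ResidueTemplate(
        name=resname,
        sidechain=tuple(rows),
        bonds=tuple(bonds),
        chi1_atom=chi1_atom,
        default_chi1=None if default_chi1 is None else float(default_chi1),
    )


def chi1_atom(resname: str) -> str | None:
    """Name of the gamma heavy atom defining chi1, or None (GLY/ALA)."""
    return residue_template(resname).chi1_atom
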