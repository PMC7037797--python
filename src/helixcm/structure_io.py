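"""Structure and sequence IO plus Ballesteros-Weinstein residue numbering.

PDB reading/writing is delegated to biotite; this module adds line-level
validation (so malformed ATOM records are reported with their line number),
deterministic handling of alternate locations (first kept) and conversion to
the package's `HelixStructure` container. Sequences are read with Biopython.

Ballesteros-Weinstein (BW) numbering labels each transmembrane-helix (TMH)
residue as helix.NN, anchored at the most conserved residue of the helix,
which is defined to be x.50; residues k positions before/after the anchor are
x.(50-k)/x.(50+k). Residues outside every TMH (loops, termini) have no BW
label and are conventionally written with their absolute number, e.g. R(220).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .structure import AtomRecord, HelixStructure, Residue


class PDBParseError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


class BWConfigError(ValueError):
    pass


# ----------------------------------------------------------------- PDB input

def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
            try:
                [float(line[i:j]) for i, j in ((30, 38), (38, 46), (46, 54))]
                int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed ATOM/HETATM record: {line.rstrip()!r}"
                ) from None


def _to_structures(atoms: bst.AtomArray, include_hetero: bool) -> list[HelixStructure]:
    if not include_hetero:
        atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise EmptyStructureError("no polymer ATOM records in selection")
    out = []
    for chain_id in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == chain_id]
        residues: list[Residue] = []
        starts = bst.get_residue_starts(sub, add_exclusive_stop=True)
        for s, e in zip(starts[:-1], starts[1:]):
            res_id = int(sub.res_id[s])
            res_name = str(sub.res_name[s])
            res = Residue(res_id, res_name, str(chain_id))
            for k in range(s, e):
                res.atoms.append(
                    AtomRecord(
                        name=str(sub.atom_name[k]),
                        element=str(sub.element[k]),
                        residue_index=res_id,
                        residue_name=res_name,
                        chain_id=str(chain_id),
                        coords=sub.coord[k].astype(float),
                    )
                )
            residues.append(res)
        h = HelixStructure(residues)
        try:
            h.measure_internal()
        except KeyError:
            pass  # non-protein chains keep NaN internals
        out.append(h)
    return out


def read_pdb(path, model: int | None = None, include_hetero: bool = False):
    """Read a PDB file into `HelixStructure` objects.

    Single-model files (or an explicit `model`) return a list of structures,
    one per chain, in file order. Multi-model files with `model=None` return
    a frame list: one list of chain structures per MODEL record. The first
    alternate location is kept; HETATM records are dropped unless
    `include_hetero`.
    """
    text = Path(path).read_text()
    if "ATOM" not in text and "HETATM" not in text:
        raise EmptyStructureError(f"{path}: file contains no ATOM records")
    _validate_pdb_lines(text)
    pdb_file = bpdb.PDBFile.read(_io.StringIO(text))
    n_models = pdb_file.get_model_count()
    if model is not None or n_models == 1:
        atoms = pdb_file.get_structure(model=model or 1, altloc="first")
        return _to_structures(atoms, include_hetero)
    stack = pdb_file.get_structure(altloc="first")
    return [_to_structures(stack[i], include_hetero) for i in range(stack.stack_depth())]


def _to_atom_array(h: HelixStructure) -> bst.AtomArray:
    arr = bst.AtomArray(h.n_atoms)
    for k, a in enumerate(h.atoms()):
        arr.coord[k] = a.coords
        arr.atom_name[k] = a.name
        arr.element[k] = a.element
        arr.res_id[k] = a.residue_index
        arr.res_name[k] = a.residue_name
        arr.chain_id[k] = a.chain_id
        arr.hetero[k] = False
    return arr


def write_pdb(path, structures) -> None:
    """Write one structure, a list of chains, or a list of frames (multi-model).

    A flat list of `HelixStructure` is written as chains of one model; a list
    of lists (or list of structures given `frames=True`-like nesting) becomes
    a multi-model trajectory.
    """
    if isinstance(structures, HelixStructure):
        models = [[structures]]
    elif structures and isinstance(structures[0], HelixStructure):
        models = [list(structures)]
    else:
        models = [list(m) if not isinstance(m, HelixStructure) else [m] for m in structures]

    pdb_file = bpdb.PDBFile()
    if len(models) == 1:
        arrays = [_to_atom_array(c) for c in models[0]]
        merged = arrays[0]
        for extra in arrays[1:]:
            merged += extra
        pdb_file.set_structure(merged)
    else:
        stack_arrays = []
        for frame in models:
            arrays = [_to_atom_array(c) for c in frame]
            merged = arrays[0]
            for extra in arrays[1:]:
                merged += extra
            stack_arrays.append(merged)
        stack = bst.stack(stack_arrays)
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_trajectory_pdb(path, frames) -> None:
    """Write a list of single-chain structures as a multi-model PDB."""
    write_pdb(path, [[f] for f in frames])


# --------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read sequences as {record id: one-letter sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------- Ballesteros-Weinstein

@dataclass(frozen=True, order=True)
class BWLabel:
    helix: int
    position: int

    def __str__(self) -> str:
        return f"{self.helix}.{self.position}"

    @classmethod
    def parse(cls, text: str) -> "BWLabel":
        helix, pos = text.split(".")
        return cls(int(helix), int(pos))


@dataclass
class BWMap:
    """Bidirectional map between absolute residue indices and BW labels."""

    entries: dict[int, BWLabel] = field(default_factory=dict)
    anchors: dict[int, int] = field(default_factory=dict)  # helix -> abs index of x.50

    def __post_init__(self):
        self._reverse = {lab: idx for idx, lab in self.entries.items()}

    def label_of(self, abs_index: int) -> BWLabel | None:
        """BW label of a residue, or None for residues not in any TMH."""
        return self.entries.get(abs_index)

    def index_of(self, label) -> int:
        if isinstance(label, str):
            label = BWLabel.parse(label)
        try:
            return self._reverse[label]
        except KeyError:
            raise KeyError(f"BW label {label} not present in map") from None

    def describe(self, abs_index: int, one_letter: str = "") -> str:
        """Render a residue the GPCR-literature convention: 'N1.50' inside a TMH,
        'R(220)' for loop/terminus residues."""
        lab = self.label_of(abs_index)
        return f"{one_letter}{lab}" if lab else f"{one_letter}({abs_index})"

    def to_tsv(self, path) -> None:
        lines = ["absolute_index\tbw_label"]
        lines += [f"{i}\t{lab}" for i, lab in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "BWMap":
        entries = {}
        anchors = {}
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            idx, lab = line.split("\t")
            label = BWLabel.parse(lab)
            entries[int(idx)] = label
            if label.position == 50:
                anchors[label.helix] = int(idx)
        return cls(entries, anchors)


def assign_bw_numbers(sequence, anchors: dict[int, int], spans: dict[int, tuple[int, int]] | None = None) -> BWMap:
    """Assign BW labels given per-helix anchor residues (the x.50 positions).

    `sequence` is a residue list or its length; `anchors` maps helix number to
    the 1-based absolute index of its x.50 residue. `spans` optionally gives
    explicit (start, end) absolute-index bounds per helix; without it, each
    helix extends to the midpoint toward its neighbouring anchors (clipped to
    the sequence).
    """
    n = sequence if isinstance(sequence, int) else len(sequence)
    if len(set(anchors.values())) != len(anchors):
        raise BWConfigError("two helices share the same anchor residue")
    seen: dict[int, int] = {}
    for helix, idx in anchors.items():
        if helix in seen:
            raise BWConfigError(f"two anchors given for helix {helix}")
        if not 1 <= idx <= n:
            raise BWConfigError(f"anchor for helix {helix} ({idx}) outside sequence 1..{n}")
        seen[helix] = idx

    if spans is None:
        spans = {}
        ordered = sorted(anchors.items(), key=lambda kv: kv[1])
        for pos, (helix, idx) in enumerate(ordered):
            lo = 1 if pos == 0 else (ordered[pos - 1][1] + idx) // 2 + 1
            hi = n if pos == len(ordered) - 1 else (idx + ordered[pos + 1][1]) // 2
            spans[helix] = (lo, hi)

    entries: dict[int, BWLabel] = {}
    for helix, idx in anchors.items():
        lo, hi = spans[helix]
        if not lo <= idx <= hi:
            raise BWConfigError(f"anchor of helix {helix} outside its span")
        for abs_i in range(max(1, lo), min(n, hi) + 1):
            entries[abs_i] = BWLabel(helix, 50 + (abs_i - idx))
    return BWMap(entries, dict(anchors))
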