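# helixcm

Conformational Memories sampling and geometric analysis of transmembrane
helices (TMHs) in class A G-protein-coupled receptors.

## The problem

Inactive-state models of orphan receptors such as GPR6 hinge — literally —
on how helix-bending residues (Ser/Thr with a gauche chi1, Gly, Pro) shape
individual TMHs, and on a handful of conserved "microswitch" interactions
that diagnose the receptor state: the intracellular ionic lock between
residues 3.50 and 6.30 (in GPR6 an R3.50–T6.30 hydrogen bond), the
binding-pocket toggle switch (F3.36 trans / W6.48 g+ in the inactive state,
optionally F5.47), the sodium-coordinating polar pocket, and conserved
inter-helical hydrogen-bond networks and aromatic stacks. `helixcm`
implements the computational toolkit around such a model:

* **Conformational Memories (CM)** — a two-phase Monte-Carlo/simulated-
  annealing search over a hinge region (the hinge residue plus the four
  preceding residues). Phase 1 anneals geometrically from 3000 K to 310 K
  in 18 temperature steps, 50,000 Metropolis MC steps per temperature; each
  step re-draws two free backbone dihedrals within ±180° (a proline hinge
  is restricted to −120° < φ < 40°, −70° < ψ < 0°, −160° < ω < 160°) and
  perturbs one N–Cα–C bond angle within ±8°. Accepted states populate
  per-dihedral histograms (the "memories"). Phase 2 re-anneals from 749.4 K
  to 310 K in nine steps, proposing only within the retained
  (highly-populated) bins, and emits 112 conformers from evenly spaced
  accepted states at 310 K.
* **Helix kink geometry** — ProKink-style bend, wobble and face-shift
  angles about a hinge, from least-squares helix-axis fits.
* **Ballesteros–Weinstein numbering** — helix.position labels anchored at
  the most conserved residue (x.50) of each TMH.
* **Microswitch classification** — chi1 rotamers (g+/g−/trans), ionic-lock
  detection, aromatic-contact classes (parallel, tilted-T, T-stack,
  edge-to-face), contact audits.
* **Torsion scans** — systematic 2-fold/3-fold conformer enumeration and
  the conformational cost of a docked pose over the global minimum.
* **Interaction decomposition** — per-residue Coulomb/van-der-Waals terms
  of a ligand against all pocket residues within a 5 Å shell, with extended
  cutoffs (nonbonded 8 Å, electrostatic 20 Å) and the distance-dependent
  dielectric ε(r) = 2r.

Energies come from a deliberately minimal, fully documented
molecular-mechanics parameter set (`helixcm/data/default_ff.toml`); every
quantitative claim is validated against closed forms and synthetic
constructions with exactly known answers, not against absolute energies of
any published force field. See `docs/methods.md` for the model details.

## Worked example

```python
import numpy as np
from helixcm import (HingeSpec, build_ideal_helix, run_cm, compute_kink,
                     superpose_ensemble, format_kink_table)
from helixcm.conformational_memories import make_schedule

# 18-residue helix with an SGT bending motif; hinge Thr at position 6
helix = build_ideal_helix("AAAASGTAAAAAAAAAAA")
spec = HingeSpec.for_hinge(helix, 6)

memory, ensemble = run_cm(
    helix, spec,
    exploratory=make_schedule(3000, 310, 18, mc_steps_per_temperature=2000),
    biased=make_schedule(749.4, 310, 9, mc_steps_per_temperature=2000),
    seed=3,
)
print(len(ensemble), "conformers")
ensemble = superpose_ensemble(ensemble, anchor=(10, 17))

kinks = [("TMH1", "T7", compute_kink(f, 6)) for f in ensemble.frames[:2]]
print(format_kink_table(kinks))
```

prints (kink rows vary with the sampled conformers; this is the seed-3 run):

```
112 conformers
Helix   Hinge Residue   Bend    Wobble  FaceShift
TMH1    T7      6.3     -158.2  -2.0
TMH1    T7      14.8    122.8   -91.8
```

112 is the configured ensemble size; each row reports the bend angle
between the pre- and post-hinge helix axes, the azimuthal wobble of the
distal segment about the proximal axis, and the helical-phase face shift
across the hinge, in degrees to one decimal.

## Command line

```sh
helixcm sample --pdb helix.pdb --hinge 7 --seed 42 --out ensemble.pdb
helixcm kink --pdb helix.pdb --hinge 11
helixcm switches --pdb model.pdb --bw map.tsv --out report.json
helixcm interact --pdb complex.pdb --ligand LIG --out table.tsv
helixcm scan --mol ligand.sdf --bonds bonds.toml --out conformers.sdf
helixcm synth kink --seed 1 --out fixtures/
```
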