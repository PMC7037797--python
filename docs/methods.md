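# Methods

## Scope and design

`helixcm` implements the analysis toolkit around an inactive-state class A
GPCR transmembrane-helix (TMH) model: conformational sampling of
helix-bending hinge regions, quantitative kink geometry, residue numbering,
microswitch-state classification, torsion scanning, and ligand-receptor
interaction decomposition. Everything operates on a single structure
container (`HelixStructure`) that keeps Cartesian atoms and internal
coordinates (backbone phi/psi/omega, N-CA-C bond angles, side-chain chi1)
mutually consistent, so the sampler can work in torsion space while all
geometric analyses work in Cartesian space.

## Structure building and internal coordinates

Chains are (re)built by sequential NeRF extension with fixed ideal covalent
geometry (N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A, C=O 1.231 A; angles
CA-C-N 116.2 deg, C-N-CA 121.7 deg, N-CA-C 111.2 deg by default). Only
dihedrals and the N-CA-C bond angle are ever varied, so fixed bond lengths
lose no generality for the sampler. Side-chain internal coordinates are
extracted at import time from the ideal CCD residue conformers bundled with
biotite and stored as a Z-matrix rooted at CA; chi1 is a free parameter
(deeper side-chain torsions stay at ideal-conformer values). Rebuilds are
seeded on the current first-residue N/CA/C positions, which makes
internal -> Cartesian -> internal round trips the exact identity (tested to
1e-6 A RMSD; in practice ~1e-14). Carbonyl O atoms are placed anti to the
next amide nitrogen (torsion psi + 180 deg); the C-terminal O, whose psi is
undefined, uses 180 deg by convention.

For structures read from PDB files the measured internal coordinates are
exact, but a rebuild replaces the experimental covalent geometry with the
ideal table - rebuilding is therefore an idealization for external
structures and an identity only for structures the package built.

## The energy model

The backend is a minimal, fully documented molecular-mechanics parameter
set (`src/helixcm/data/default_ff.toml`), not a reimplementation of any
published force field: per-(residue, atom) partial charges with a wildcard
backbone set, one Lennard-Jones class per element combined by
Lorentz-Berthelot rules, cosine torsion series per class, and two
dielectric models - constant eps, or the distance-dependent eps(r) = c*r.
Coulomb energies use E = 332.0636 q1 q2 / (eps(r) r) kcal/mol; with
eps(r) = c*r the denominator is c*r^2. Nonbonded terms use separate van der
Waals (default 8 A) and electrostatic (default 20 A) cutoffs; 1-2 and 1-3
bonded pairs are excluded and 1-4 pairs enter at full weight (a scale
factor is exposed). Sampling defaults to eps(r) = 1r; interaction
decomposition uses eps(r) = 2r. Pairs within 4.0 A between N/O atoms are
flagged as potential hydrogen bonds in interaction reports - a reporting
criterion only, as the energy model has no separate H-bond term.

Because the parameter set is synthetic, absolute energies are meaningful
only within this package; every quantitative claim in the test suite is
against closed forms (Coulomb/LJ point evaluations), independent
double-loop sums, dense-grid searches, or Boltzmann densities obtained by
numerical quadrature - never against absolute energies of external force fields, which
were produced by commercial force fields on unreleased coordinates.

## Conformational Memories

The sampler explores a hinge region: the hinge residue plus the four
preceding residues. Free coordinates are phi/psi of each region residue
(omega is fixed at 180 deg unless explicitly freed; a proline hinge frees
omega and narrows its backbone ranges to -120 < phi < 40, -70 < psi < 0,
-160 < omega < 160 deg) and the five N-CA-C bond angles within +-8 deg of
ideal. One MC move re-draws two distinct free dihedrals uniformly within
their allowed ranges and one bond angle uniformly within its window -
an independence proposal, so the plain Metropolis rule
min(1, exp(-dE/kT)) with kB = 0.0019872 kcal/(mol K) leaves the Boltzmann
distribution invariant. Moves are applied as rigid rotations of the atoms
downstream of the varied coordinate, which is numerically identical to a
rebuild from internal coordinates (verified to ~1e-14 A) at a fraction of
the cost.

Phase 1 (exploratory) anneals geometrically T_i =
T_start (T_end/T_start)^(i/(n-1)) from 3000 K to 310 K in 18 temperature
steps, 50,000 MC steps each; accepted states populate per-dihedral
histograms with 10-deg bins. Phase 2 (biased) re-anneals from 749.4 K to
310 K in nine steps, drawing dihedral proposals only within retained bins
(those holding >= 1% of a dihedral's accepted samples; threshold and bin
width configurable). The output ensemble is 112 conformers taken at evenly
spaced accepted states of the final 310 K temperature, rebuilt exactly from
their internal coordinates, with the energies recorded at acceptance. The
cooling law, bin width, retention threshold and the uniform choice of which
dihedrals to vary are this package's choices where the protocol fixes only
endpoints, step counts and move ranges. Runs are bit-reproducible under a
fixed seed (one PCG64 stream drives both phases).

The 18-residue poly-Ala helix with an SGT motif used by the tests and the
acceptance script keeps a full default run (1.35 million MC steps, ~90
atoms) at roughly four minutes on one CPU; the per-temperature step count
scales the cost linearly and is exposed for quicker runs.

## Kink geometry

Helix axes are least-squares lines through sliding 4-residue window centers
of C-alpha positions, with window weights chosen to cancel the helical
circle component exactly at the ideal periodicity of 100 deg/residue
(plain means leave a ~0.26 A residual spiral; the weighted centers reduce
the axis-fit residual to ~0.02 A). Axis direction is oriented N -> C; the
per-residue azimuthal phase about the axis is fitted by linear regression
on the unwrapped phases.

About a hinge at 0-based position h (proximal segment 0..h, distal
h+1..end, each side >= 5 residues):

* **bend** = angle between the proximal and distal axis directions;
* **wobble** = azimuth of the distal direction's projection into the plane
  perpendicular to the proximal axis, measured right-handedly about the
  proximal (N -> C) direction from the reference direction proximal-axis ->
  hinge C-alpha. Wobble is ill-conditioned as bend -> 0; it is always
  reported but flagged unreliable below a 10-deg bend;
* **face shift** = the distal segment is rigidly "unbent" (minimal rotation
  mapping the distal onto the proximal direction, about the hinge C-alpha),
  and the circular mean of (observed azimuth - azimuth extrapolated from
  the proximal segment) over the distal residues is reported.

The face-shift extrapolation uses the proximal segment's own fitted
periodicity rather than a fixed 100 deg/residue: an ideal helix built at
phi = -63, psi = -42 deg has ~99.3 deg/residue, and a fixed reference would
accumulate ~0.7 deg/residue of systematic face shift on a perfectly
straight helix - more than the 2-deg recovery tolerance. A fixed reference
remains available via the `phase_per_residue` argument.

These definitions are stated operationally and validated against synthetic
constructions (`build_kinked_helix`) whose truth is the applied rigid
transform: across bend 5-40 deg and face shift 0/+-30/+-90 deg, recovery is
within 1 deg (bend), 2 deg (face shift) and 5 deg (wobble, bend >= 10 deg).
The wobble sign convention (right-handed about N -> C) and the hinge-CA
azimuth reference are this package's documented choices; published kink
tables from other tools need not share them.

## Microswitches

chi1 rotamers use windows g+ = [-120, 0), g- = [0, 120), trans elsewhere
(centers -60/+60/180 deg; windows configurable and partitioning the
circle). The ionic lock (default 3.50 donor, 6.30 acceptor) is formed iff
the minimum side-chain heavy-atom donor-acceptor distance is <= 3.5 A and
the angle at the donor atom is >= 120 deg, both inclusive - the common
structural-biology default for a "good" hydrogen bond; missing side-chain
atoms give an indeterminate status with a warning rather than an error.
Aromatic ring contacts classify by centroid distance (cutoff 7 A) and
interplanar angle folded to [0, 90]: parallel <= 30 deg, tilted-T 30-60
deg; in the perpendicular 60-90 deg window the contact is a T-stack when
the inter-centroid vector lies within 40 deg of either ring normal (one
ring sits over the other's face) and edge-to-face otherwise. Contact audits
evaluate arbitrary expected-interaction lists (hydrogen-bond networks,
aromatic stacks) and return per-spec satisfied/unsatisfied/unresolvable
statuses; sodium-pocket audits check presence of the 1.50/2.50/3.39/7.49/
7.53 polar set.

## Torsion scans and conformational cost

Conformer enumeration seeds the Cartesian product of 360/fold-degree
rotations per rotatable bond from the input conformer, minimizes each start
on the torsion coordinates (L-BFGS-B with the analytic gradient of the
cosine series, to |grad| < 1e-4 kcal/mol/deg), deduplicates at a 20-deg
max-over-torsions threshold (coarser than minimization noise, finer than
the 120-deg grid), and sorts by energy. Bonds inside rings are rejected.
The conformational cost of a docked pose is its single-point energy minus
the energy of the global minimum re-relaxed to |grad| < 0.01; with a
verified global minimum the cost is non-negative by construction.

## Synthetic data and what passing tests show

All fixtures are generated, never downloaded: ideal alpha helices
(phi = -63, psi = -42 deg) of arbitrary sequence with placeable chi1;
kinked helices built by exact rigid transforms of the distal segment
(recorded as the truth record), optionally with isotropic Gaussian
coordinate noise; and toy ligand-pocket complexes of point-charge probes
whose expected interaction tables are computed by an independent direct
double-loop sum at generation time. Sequences are synthetic poly-Ala with
motif residues at declared anchors - numbering and switch logic need only
anchored motifs, not any real receptor sequence.

These fixtures exercise the geometry and statistics of every stage with
exactly known answers. They do not emulate real data in other respects: no
membrane environment, no experimental coordinate error structure beyond
isotropic Gaussian noise, no real force field, and no docking poses.
Passing tests therefore demonstrate correctness of the algorithms -
Boltzmann sampling, geometric recovery, energy bookkeeping - not agreement
with any particular receptor model built with commercial tools.

## Numerical choices and edge cases

* Dihedrals live in (-180, 180]; rotations are applied unwrapped (they are
  360-periodic). Bond angles in (0, 180).
* Degenerate inputs: collinear C-alpha segments fit an axis with a warning
  and a `degenerate` flag; a hinge C-alpha on the proximal axis makes
  wobble undefined (error); zero interatomic distance raises a singularity
  error; a single-step schedule requires equal endpoint temperatures.
* PDB parsing keeps the first alternate location and, for single-model
  reads, the first model; malformed ATOM records report their line number.
  Coordinates round-trip at the format's 3-decimal precision.
* The nonbonded kernel is JIT-compiled (numba) with a pure-numpy reference
  branch; both produce identical sums pair-for-pair.
* Ensemble selection uses `np.linspace` over accepted 310 K states; if
  fewer accepted states exist than requested conformers, the ensemble is
  the accepted states themselves.

## Known limitations

* The energy model is intentionally minimal: no explicit hydrogens, no
  bond/angle strain terms, no solvation or membrane model, no CMAP-style
  backbone correction. Absolute energies and energy gaps are not
  comparable to published force-field values.
* chi2+ side-chain torsions are frozen at ideal-conformer values; rotamer
  analysis beyond chi1 is out of scope.
* Kink descriptors depend on the documented axis/reference conventions;
  cross-tool numerical agreement is not expected beyond the bend angle.
* The sampler treats a single helix in vacuum; inter-helical packing
  constraints enter only through downstream analyses.
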