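# Minimal documented molecular-mechanics parameter set for helixcm.
#
# Units: partial charges in elementary charge units, Lennard-Jones well
# depth (epsilon) in kcal/mol, r_min in Angstrom (pair minimum-distance via
# Lorentz-Berthelot combination), torsion amplitudes in kcal/mol, phases in
# degrees.  Charges resolve by (residue, atom) with "*" as residue wildcard;
# atoms without an entry default to 0.  LJ classes are chemical elements.

[charges]
"*:N" = -0.35
"*:CA" = 0.10
"*:C" = 0.45
"*:O" = -0.45
"*:CB" = 0.0
# polar side-chain heavy atoms
"SER:OG" = -0.40
"SER:CB" = 0.20
"THR:OG1" = -0.40
"THR:CB" = 0.20
"ASN:OD1" = -0.45
"ASN:ND2" = -0.30
"ASN:CG" = 0.55
"ASP:OD1" = -0.55
"ASP:OD2" = -0.55
"ASP:CG" = 0.40
"GLU:OE1" = -0.55
"GLU:OE2" = -0.55
"GLU:CD" = 0.40
"GLN:OE1" = -0.45
"GLN:NE2" = -0.30
"GLN:CD" = 0.55
"ARG:NE" = -0.30
"ARG:CZ" = 0.50
"ARG:NH1" = -0.25
"ARG:NH2" = -0.25
"LYS:NZ" = -0.10
"HIS:ND1" = -0.35
"HIS:NE2" = -0.35
"TRP:NE1" = -0.30
"TYR:OH" = -0.40
"CYS:SG" = -0.20

[lj]
# element = [epsilon_kcal_per_mol, r_min_angstrom]
C = [0.10, 4.00]
N = [0.20, 3.60]
O = [0.21, 3.40]
S = [0.45, 4.00]
H = [0.046, 1.00]

[torsions]
# class = list of [amplitude, periodicity, phase_deg]
phi = [[0.2, 3, 0.0]]
psi = [[0.2, 3, 0.0]]
omega = [[8.0, 2, 180.0]]
chi1 = [[0.3, 3, 0.0]]
generic2 = [[1.0, 2, 180.0]]
generic3 = [[1.0, 3, 0.0]]

[dielectric]
# "constant" with value eps, or "distance" with eps(r) = coeff * r
model = "distance"
coeff = 1.0
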