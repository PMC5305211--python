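# Residue and modification chemistry, version 1.
#
# Residue entries give the elemental composition of the amino-acid residue
# (amino acid minus water) and its monoisotopic mass in Da.  The two are
# redundant on purpose: the loader verifies that each stated mass agrees
# with the mass computed from the composition to within 1e-5 Da.
version: 1
residues:
  G: {composition: {C: 2,  H: 3,  N: 1, O: 1},       mass: 57.02146}
  A: {composition: {C: 3,  H: 5,  N: 1, O: 1},       mass: 71.03711}
  S: {composition: {C: 3,  H: 5,  N: 1, O: 2},       mass: 87.03203}
  P: {composition: {C: 5,  H: 7,  N: 1, O: 1},       mass: 97.05276}
  V: {composition: {C: 5,  H: 9,  N: 1, O: 1},       mass: 99.06841}
  T: {composition: {C: 4,  H: 7,  N: 1, O: 2},       mass: 101.04768}
  C: {composition: {C: 3,  H: 5,  N: 1, O: 1, S: 1}, mass: 103.00919}
  L: {composition: {C: 6,  H: 11, N: 1, O: 1},       mass: 113.08406}
  I: {composition: {C: 6,  H: 11, N: 1, O: 1},       mass: 113.08406}
  N: {composition: {C: 4,  H: 6,  N: 2, O: 2},       mass: 114.04293}
  D: {composition: {C: 4,  H: 5,  N: 1, O: 3},       mass: 115.02694}
  Q: {composition: {C: 5,  H: 8,  N: 2, O: 2},       mass: 128.05858}
  K: {composition: {C: 6,  H: 12, N: 2, O: 1},       mass: 128.09496}
  E: {composition: {C: 5,  H: 7,  N: 1, O: 3},       mass: 129.04259}
  M: {composition: {C: 5,  H: 9,  N: 1, O: 1, S: 1}, mass: 131.04049}
  H: {composition: {C: 6,  H: 7,  N: 3, O: 1},       mass: 137.05891}
  F: {composition: {C: 9,  H: 9,  N: 1, O: 1},       mass: 147.06841}
  R: {composition: {C: 6,  H: 12, N: 4, O: 1},       mass: 156.10111}
  Y: {composition: {C: 9,  H: 9,  N: 1, O: 2},       mass: 163.06333}
  W: {composition: {C: 11, H: 10, N: 2, O: 1},       mass: 186.07931}

# Photo-reactive residues written inline in peptide sequences:
#   B = p-benzoyl-p-phenylalanine (Bpa): phenylalanine plus a benzoyl group
#       (C7H4O, +104.0262 Da).  Its benzophenone inserts into a nearby C-H
#       bond under 365 nm UV with zero mass change.
#   X = cysteine derivatized with 4-(N-maleimido)benzophenone: Cys plus the
#       maleimide-benzophenone adduct C17H11NO3 (+277.0739 Da).
special_residues:
  B: {base: F, delta_composition: {C: 7,  H: 4,  O: 1}}
  X: {base: C, delta_composition: {C: 17, H: 11, N: 1, O: 3}}

# Positional modifications, written as SEQ[name] after the residue letter.
modifications:
  ox:  {targets: [M], delta_composition: {O: 1}}            # +15.9949 Da
  cam: {targets: [C], delta_composition: {C: 2, H: 3, N: 1, O: 1}}  # +57.0215 Da

# Carbamidomethylation of every cysteine that is not the benzophenone-
# labeled X residue is applied as a fixed modification by default: the
# alkylation is part of standard gel-band sample preparation, and the
# crosslink masses involving Cys-containing peptides only reconcile with
# the +57.0215 Da adduct in place.
fixed_modifications: [cam]
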