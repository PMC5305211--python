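# xlmap

Mapping benzophenone photo-crosslinks between a chromatin remodeler and
the histone H4 tail — and turning them into structural and kinetic
conclusions.

`xlmap` is a reusable implementation of the computational chain behind a
residue-level interaction study of the ISWI remodeler: identifying
crosslinked peptide pairs in LC-MS/MS data, converting the mapped sites
into distance restraints, filtering docked structure ensembles against
those restraints, computing contact-probability surfaces over the
surviving model family, and reducing ATPase / nucleosome-remodeling time
courses to rate constants and fold-stimulation metrics. It is written for
people analysing photo-crosslinking (Bpa or maleimide-benzophenone)
experiments who want the entire pipeline scriptable, testable and free of
point-and-click steps.

## The core calculus

Benzophenone photo-insertion into a C–H bond adds **zero mass**, so a
crosslinked species made of peptides α (carrying the photo residue) and β
satisfies

```
M(αβ) = M(α) + M(β)
```

with each peptide mass the sum of monoisotopic residue masses, positional
modification deltas and water. Special residues are written inline:
`B` = *p*-benzoyl-*p*-phenylalanine (Phe + C7H4O, +104.0262 Da),
`X` = 4-(N-maleimido)benzophenone-labeled Cys (Cys + C17H11NO3,
+277.0739 Da), `M[ox]` = oxidized Met (+15.9949 Da); unlabeled cysteines
carry the fixed carbamidomethyl adduct (+57.0215 Da). Identification then
proceeds by ±10 ppm precursor matching, ±15 ppm b/y fragment matching
(fragments spanning the link carry the full partner mass), site
localization to the smallest interval consistent with the discriminating
ions, UV-dependence quantification (+UV/−UV intensity ratio), and a
high/medium/low reliability rubric. Each unique residue linkage becomes
an upper-bound restraint (Cα–Cα ≤ 20 Å) used to filter docked ensembles;
contact probability of a residue pair is the fraction of surviving models
with minimum heavy-atom distance ≤ 5 Å.

Kinetics: ATP turnover from the NADH-coupled assay is
(−slope)/(ε·l·[E]) with ε = 6220 M⁻¹cm⁻¹; remodeling time courses fit
y(t) = y∞ + (y0 − y∞)·e^(−k_obs·t); H4-tail stimulation is the ratio of
the k_obs values on wild-type vs tail-less H4 chromatin.

## Worked example

Verify a published crosslink mass — the H4 T1-Bpa peptide (`BGR`) linked
to the remodeler peptide `LDGQTPHEDR`:

```python
from xlmap import parse_peptide, crosslink_mass, ppm_error, mz

xl = crosslink_mass(parse_peptide("BGR"), parse_peptide("LDGQTPHEDR"))
print(f"theoretical mass : {xl.mass:.4f} Da")
print(f"error vs observed: {ppm_error(1648.7601, xl.mass):+.2f} ppm")
print(f"m/z at z=3       : {mz(xl.mass, 3):.4f}")
```

prints

```
theoretical mass : 1648.7594 Da
error vs observed: +0.45 ppm
m/z at z=3       : 550.5937
```

i.e. the sequence-derived mass agrees with the observed neutral mass well
inside the ±10 ppm search window, and the species would appear at m/z
550.59 as a 3+ ion. The same calculus reproduces all sixteen published
crosslink masses within 10 ppm (largest deviation 6.5 ppm).

End-to-end on a seeded synthetic dataset from the command line:

```sh
xlmap simulate xlms --seed 1 --out sim
xlmap search --fasta sim/proteins.fasta --ms1 sim/ms1_features.tsv \
             --mgf sim/spectra.mgf --out crosslinks.tsv
```

```
3 crosslink matches -> crosslinks.tsv

id   mass_da    ppm   alpha  site  beta         site  frags  uv    tier
XL1  1868.8442  1.04  BGR    1     HLDNQTPYEDR  33    3/19   20.0  high
XL2  1356.6608 -1.22  BGR    1     NVIEMGGR     41    4/13   20.0  high
XL3  1209.6506  1.08  BGR    1     SPTKPAK      47    4/10   20.0  high
```

All three planted crosslinks are recovered with single-residue
localization at the true sites, 20-fold UV enrichment, and high
reliability; the random decoy features in the same input produce no
matches. `xlmap run --config run.yaml` chains search → restraints →
ensemble filtering → contact surface and writes a JSON report;
`xlmap kinetics fit-exp|atpase|h4dep` covers the kinetic reductions;
`xlmap simulate ensemble|kinetics` generates the other synthetic inputs.

## Layout

| module | contents |
|--------|----------|
| `xlmap.chemistry`  | residue/modification tables, peptide & crosslink masses, ppm / m/z, isotope patterns |
| `xlmap.search`     | digestion, candidate enumeration, MS1/MS2 matching, localization, UV dependence, tiers |
| `xlmap.restraints` | distance restraints, ensemble filtering, contact surfaces, B-factor export |
| `xlmap.kinetics`   | NADH-assay turnover, single-exponential fits, fold changes, saturation checks |
| `xlmap.simulate`   | seeded generators for MS data, docked ensembles and kinetic traces, with planted truth |
| `xlmap.pipeline` / `xlmap.cli` | YAML-configured orchestration and the `xlmap` command |

`docs/methods.md` documents the models, defaults and their rationale.
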