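# Methods

## The problem

Benzophenone photo-crosslinking identifies residue-level contacts inside
protein complexes: a photo-reactive group — either the genetically encoded
amino acid *p*-benzoyl-*p*-phenylalanine (Bpa, written `B` in sequences) or
a 4-(N-maleimido)benzophenone adduct on an engineered cysteine (written
`X`) — inserts into a C–H bond of whatever residue it touches during 365 nm
irradiation. The insertion changes no mass, so a crosslinked tryptic
peptide pair is recognized in MS data purely by additivity: its neutral
monoisotopic mass is exactly the sum of the two peptide masses. This
package implements the complete computational chain around that fact, for
the system in which it was developed — the ISWI chromatin remodeler, whose
N-terminal region and whose substrate (the histone H4 tail) both dock onto
ATPase Lobe 2 — together with the enzyme-kinetics reductions used to
quantify the regulatory consequences.

## Mass calculus (`xlmap.chemistry`)

Residue elemental compositions and monoisotopic masses follow the standard
IUPAC table; the loader cross-validates each stated mass against the mass
computed from its composition (tolerance 1e-5 Da), and `peptide_mass` is
additionally tested against the independent composition route (1e-4 Da).
Element isotope masses and abundances come from the NIST table shipped
with pyteomics. Electron mass is neglected in neutral-mass arithmetic
(≤0.5 ppm at these masses).

Modifications:

| name | target | delta (Da) | role |
|------|--------|-----------|------|
| `B`  | replaces Phe | +104.0262 (C7H4O) | Bpa photo-residue |
| `X`  | replaces Cys | +277.0739 (C17H11NO3) | benzophenone-maleimide label |
| `cam` | Cys | +57.0215 | fixed (alkylation during sample prep) |
| `ox` | Met | +15.9949 | variable, ≤1 per peptide |

Carbamidomethylation is applied as a *fixed* modification to every
cysteine that is not the labeled `X` residue: the published masses of the
Cys-containing pairs only reconcile within the ppm window with the adduct
in place. Met oxidation is a variable modification expanded during
candidate enumeration, because the data contain both forms of the same
peptide (and two entries whose printed masses require an unannotated
oxidation).

The bundled machine-readable crosslink table reproduces all 16 published
pair masses within 10 ppm (largest magnitude 6.5 ppm). The computed error
signs come out uniformly opposite to the printed ones — the printed signs
are not consistent with any single convention over a standard mass table —
so this package fixes the convention (observed − theoretical)/theoretical
and compares magnitudes where published values are involved.

Isotope patterns are computed by exact polynomial convolution of elemental
isotope-abundance vectors (binary exponentiation per element, truncation
to the requested peak count, renormalization). No averagine approximation
is used anywhere: compositions are always fully known here.

## Crosslink search (`xlmap.search`)

Tryptic digestion cleaves C-terminal of K/R except before Pro, with ≤2
missed cleavages and peptide lengths 2–30 by default (the published
peptides require ≥1 missed cleavage and uncut K.P/R.P sites). Candidates
are bait×prey pairs — the bait peptide must carry exactly one photo
residue — expanded over oxidation variants and deduplicated.

MS1 features (neutral mass, or m/z + charge) match candidates within a
±10 ppm window. MS2 scoring matches theoretical b/y ladders at fragment
charges 1..(precursor charge − 1) within ±15 ppm; a fragment spanning the
crosslinked residue carries the full partner-peptide mass as a rigid
addition. Because the photo-insertion is chemically indiscriminate, every
prey residue is a potential site: scoring evaluates one ladder hypothesis
per site, and localization reports the smallest contiguous interval
covering the hypotheses that tie for the maximal matched count — a single
residue for a complete discriminating ladder, the whole peptide when no
site-discriminating ion matched. The bait-chain site is pinned to the
photo residue. Neutral losses are ignored.

UV dependence is the ratio of summed matched MS1 intensity with vs.
without irradiation, floored at 1% of the +UV signal; ≥5-fold flags the
species as UV-dependent. Reliability tiers codify the manual validation
the original analysis performed by eye: **high** needs ≥3 matched
fragments on *both* chains, UV dependence, and |MS1 error| ≤5 ppm;
**medium** needs ≥3 fragments on one chain; everything else is **low**.
All thresholds are exposed in configuration.

Candidates supported only by an MS1 mass coincidence (zero matched
fragments) are not reported: with random decoy features at realistic
densities, mass coincidence alone carries no identification information.
For error control the package supports searching a Fisher–Yates-shuffled
prey sequence as a decoy; on synthetic data the decoy search yields
essentially zero matches.

## Restraints, filtering, contact surfaces (`xlmap.restraints`)

Each localized crosslink becomes an upper-bound distance restraint,
default 20 Å, measured between Cα atoms (configurable); an ambiguous site
interval makes the restraint ambiguous with any-of semantics, since the
chemistry marks exactly one unknown residue in the range. Redundant
crosslinks collapsing to the same residue linkage are deduplicated — the
five high-confidence H4-tail crosslinks define exactly three unique
amino-acid linkages. The original docking applied these as upper harmonic
potentials inside the docking engine; the post-hoc filter implemented here
is the hard satisfaction test (distance ≤ bound), which is what filtering
a refined ensemble requires.

`filter_ensemble` keeps exactly the models satisfying every restraint
(idempotent; monotone in the bound and antitone in the restraint set).
Contact probability between peptide residue *i* and receptor residue *j*
is the fraction of models with minimum heavy-atom distance ≤5 Å; both the
pairwise map and the per-receptor-residue marginal (contact with *any*
peptide residue) are emitted, since published color scales can be read
either way. Surfaces are written into the PDB B-factor column scaled
0–100 for visualization, and round-trip within 0.01.

The number of models surviving the published filter (383) depends on that
study's stochastic docking run and is not a reproducible quantity; only
the filtering semantics are testable, and they are tested exactly on
constructed ensembles.

## Kinetics (`xlmap.kinetics`)

ATP hydrolysis: in the NADH-coupled assay each hydrolyzed ATP consumes one
NADH, so turnover = (−slope)/(ε·l·[E]) with ε = 6220 M⁻¹cm⁻¹ at 340 nm and
l = 1 cm (standard values for the assay). The slope is taken over the
longest window with linear R² ≥ 0.995 covering ≥30% of points, ties broken
toward earlier windows; this skips coupling-system lag but can retain a
little lag tail, a known mild bias of longest-window rules.

Remodeling: time courses fit y(t) = y∞ + (y0 − y∞)·exp(−k_obs·t) by
least squares with deterministic initialization (y∞ from the final 10% of
points, k₀ from log-linear regression of the residual). Non-convergence
and flat traces raise with diagnostics rather than returning silently.

H4-tail stimulation is the ratio k_obs(WT)/k_obs(tail-less) with
propagated standard errors; when the denominator measurement was not
enzyme-saturated its true rate may be higher, so the ratio is flagged as
an upper bound ("<n-fold"). Replicate convention: s.d. for
n ≥ 3, min/max for n = 2. Saturation over a concentration series (≥3
points spanning ≥4-fold) requires the top two rates to agree within 20%.

## Synthetic data (`xlmap.simulate`)

The generators define the conditions under which the pipeline is tested:

* **XL-MS**: bait = the 24 N-terminal H4 residues with Bpa at position 1;
  prey = a synthetic 71-residue receptor whose tryptic map mimics a
  remodeler fragment (4–14-mer peptides, internal K.P sites, one Met, one
  Cys). Three crosslinks planted at prey residues 33, 41 and 47; MS1
  masses perturbed with σ = 3 ppm Gaussian error; 20-fold UV enrichment;
  decoys at 0.2 features/Da; b/y ladders at 90% completeness plus
  Poisson(20) noise peaks.
* **Ensembles**: the receptor is an ideal α-helix (rise 1.5 Å, radius
  2.3 Å, 100°/residue), Cα-only, 60 residues; the 8-residue peptide is
  laid 4 Å outside the helix surface along pocket residues 36–43 in a
  fraction f = 0.7 of 20 models and displaced 60–90 Å away in the rest, so
  restraint satisfaction and contact counts are known by construction. The
  pocket location was chosen so the restraints derived from the simulated
  MS experiment (prey sites 33/41/47) are geometrically satisfiable by the
  in-pocket models — the two generators describe one coherent system and
  the whole pipeline can be tested end to end.
* **Kinetics**: exponential traces (k = 0.05 s⁻¹ default, 60 points over
  5/k) and linear NADH traces (turnover 2.5 s⁻¹ at [E] = 1 µM, A₀ = 0.8)
  with Gaussian noise of 5% amplitude.

What the generators do **not** emulate: chromatographic profiles,
retention time, isotope envelopes in MS1 (features arrive deisotoped, as
from upstream deconvolution), co-eluting chimeric spectra, real docking
geometry or side-chain packing, and instrument-specific noise structure.
Passing tests therefore demonstrate the correctness of the calculus,
matching, filtering and fitting logic under realistic error magnitudes —
not performance on raw instrument files.

## Numerical choices and limits

* Masses compared in ppm space; MS1/MS2 windows are the published ±10/±15
  ppm; candidate matching uses binary search over sorted masses and is
  tested against the brute-force all-pairs oracle.
* Localization ties are resolved by reporting the covering interval, never
  a point estimate; peptide pairs whose chains end in the same residue
  share y1 (and b_{n−1}+partner) masses exactly — such ambiguity is
  physical and surfaces as wider intervals.
* Exponential fits can fail on pathological data; they raise `FitError`
  with diagnostics. The rate is constrained non-negative by rejection, not
  clamping.
* Ensemble models must share topology; mixed-topology inputs are rejected
  on construction.
* Problem sizes in the test suite (proteins ≤72 aa, ensembles of 10–50
  models, 20-seed repetitions) were chosen so each property is exercised
  with meaningful statistics while the whole suite stays interactive.
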