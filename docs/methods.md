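# Methods

## Cleavage-site profiling pipeline

### Filter cascade

Input is one identification list per MS run: the test protease reaction,
a catalytically inactive control, a mock (buffer) control, and the
unprocessed peptide library.  The cascade applies, in order:

1. **Biotin filter** — keep peptides flagged as N-terminally biotinylated
   (cleavage products acquire the label on their neo-N-terminus).  The flag
   is taken at face value; whether other modifications co-occur is not
   examined.
2. **Confidence filter** — keep test-run peptides with confidence strictly
   greater than 80% and control-run peptides strictly greater than 10%.
   "Over" is read literally: a peptide at exactly the threshold is dropped.
   The permissive control threshold deliberately over-collects background
   so that subtraction errs toward removing, not keeping.
3. **Control subtraction** — drop any test peptide whose *sequence* occurs
   in either filtered control list.  Matching is by exact sequence, not
   sequence+modification: the controls cannot contain enzyme-generated
   biotinylated neo-termini by construction, so a shared sequence is
   background whatever its flags.
4. **Library removal** — drop test peptides identified in the unprocessed
   library run (uncleaved library members are the dominant contaminant).

Duplicate sequences within one run are collapsed to their
highest-confidence instance before filtering.  A `FilterReport` records
the count after every stage; counts are non-increasing by construction.

### Proteome back-mapping

MS observes only the prime side of each scissile bond.  Each surviving
peptide is located in the proteome by exact substring search (no I/L
equivalence, no tolerant matching); occurrences are enumerated in sorted
(protein id, position) order so results are independent of FASTA entry
order.  The five residues preceding an occurrence form the candidate
non-prime window:

* exactly one **distinct** preceding 5-mer → assigned (duplicate loci with
  an identical context collapse to one);
* several distinct preceding 5-mers → the non-prime side is ambiguous and
  excluded, but the peptide's prime side is kept and still contributes to
  the prime-side frequency columns (this interpretation is switchable in
  the sense that ambiguous windows are marked and can be dropped by the
  caller);
* zero occurrences → the peptide is dropped and counted in the mapping
  report.

Windows truncated at a protein N-terminus, and prime windows from peptides
shorter than five residues, are padded with a gap symbol `-`.  Gaps are
excluded from both the counts and the column totals of the specificity
matrix, so boundary effects never dilute a genuine preference.
`cut_position` is the 1-based index of the P1 residue in the parent
protein (absent when the bond coincides with the protein N-terminus).

### Specificity matrix

Counts are tallied per residue and subsite over all windows (skipping gaps
and the non-prime half of ambiguous windows) and normalized per column.
Columns with zero observations are all-zero and flagged rather than NaN.
Raw frequencies are the primary output; an enrichment table
(frequency / library background frequency) is available when a background
composition is supplied, with zero-background entries undefined.  The TSV
export carries `# n_windows=` metadata so an empty matrix round-trips with
its flag; an optional stacked-letter logo is drawn with matplotlib.

## Synthetic data

The generator emulates the study conditions rather than raw spectra:

* **Proteome** — i.i.d. residues over the 20-letter alphabet, uniform
  composition by default, 100 proteins of 200–400 residues at screen scale.
* **Library** — tryptic digest (cleave after K/R, not before P), lengths
  5–40, the standard choice for proteome-derived libraries; the digest rule
  is configurable since the library protease is a protocol detail.
* **Cleavage** — each internal bond of each library peptide is cleaved
  independently with probability efficiency × Π over subsites of
  (weight / max weight).  Normalizing by the per-subsite maximum makes a
  perfect motif match cleave with probability `efficiency`, and a strict
  one-hot motif forbid everything else.  Subsites falling outside the
  peptide contribute a neutral factor (no information either way).  The
  prime-side fragment is emitted biotin-flagged with confidence drawn from
  Uniform(85, 100).
* **Noise** — background identifications are library members (plus a 10%
  fraction of shuffled decoys) with Uniform(0, 100) confidences and a 30%
  biotin-flag rate, drawn **once** and copied verbatim into the test and
  both control runs; this mirrors the fact that real contaminants recur
  across runs and is what makes control subtraction meaningful.  With
  efficiency 0 the test run is identical to the mock run, so the pipeline
  reproduces a null outcome exactly.
* What it does **not** emulate: spectra, retention times, search-engine
  scoring, missed identifications that differ between runs, or chemically
  incomplete amine protection.  Passing tests therefore demonstrate the
  correctness of the analysis logic, not robustness to every failure mode
  of a real MS experiment.

## ITC analysis

### Forward model

Concentrations are in μM, volumes in mL/μL, heats in μcal, normalized
heats and enthalpies in kcal/mol.  Per injection of volume dV into active
volume V0, species already in the cell are diluted by
(1 − dV/2V0)/(1 + dV/2V0) and the fresh ligand enters at
`syringe_conc · (dV/V0) / (1 + dV/2V0)` — the standard perfusion-cell
convention for an overfilled cell (the displaced aliquot leaves with the
mean of pre- and post-injection composition).  Bound-ligand
concentrations come from the exact mass-balance solutions: the stable
quadratic root for one site class, Brent's method on the monotone cubic
balance for two.  The cumulative heat is `Q_i = V0 Σ_s ΔH_s [ML_s]_i`; the
observed injection heat adds the displaced-volume correction
`(dV_i/V0)(Q_i + Q_{i−1})/2`, and is normalized per mole of injectant with
an optional constant baseline.

Simulations default to 30 injections of 9 μL, which carries every
protocol used here past molar ratio 2; temperature defaults to 298.15 K.

### Fitting

χ² = Σ (observed − model)² over the normalized heats.  The one-site fit
varies N, K_d and ΔH (N can be fixed; a constant dilution baseline can
optionally float, and the first injection can optionally be excluded —
both off by default).  The two-site fit fixes one site of each class per
macromolecule (N1 = N2 = 1) and varies K_d1, K_d2, ΔH1, ΔH2 and the
baseline; the site-label exchange symmetry is resolved by reporting
K_d1 ≤ K_d2, and a near-equal pair (|ln ratio| < 0.05) is flagged
degenerate rather than treated as an error.  Optimization is bounded
trust-region least squares (scipy) with tight tolerances; when no start is
given, a coarse grid over N ∈ {0.5, 1, 2} and K_d ∈ M0·{0.05..20} seeds
it.  A fit whose amplitude is indistinguishable from baseline (|ΔH| ≈ 0)
is flagged `kd_identifiable = False`.

Round-trip identifiability was checked across Wiseman c = N·M0/K_d from 1
to 1000: noiseless simulate-then-refit recovers all parameters within 1%
from a 1.5× perturbed start.  One caveat worth knowing: refitting a
*two-site* isotherm with unequal constants (e.g. 175/575 μM at c ≈ 0.6)
using the *one-site* model recovers an apparent K_d near the geometric
mean but an apparent N ≈ 1.4, not 2 — with low curvature the one-site
reduction absorbs site heterogeneity into N.  Real instruments' noise and
baseline handling can push that apparent N toward 2; the noiseless model
reduction does not.

### χ² profile

Because the normalized heats are exactly linear in (ΔH1, ΔH2, baseline),
profiling over a (K_d1, K_d2) lattice re-optimizes the nuisance parameters
at each node by closed-form linear least squares.  The acceptance region
is the sub-level set χ² ≤ threshold; the threshold is a *user input* in
the fit's own χ² units — instrument-software χ² values are weighted by
per-point uncertainties that cannot be reconstructed from published
summaries, so no particular printed χ² level is hard-coded.  Profile
regions grow monotonically with the threshold and per-parameter ranges are
reported as the min/max of each K_d over the region.

### Thermodynamics

ΔG = RT ln(K_d/1 M) with R = 1.987204259×10⁻³ kcal/(mol·K);
ΔΔG = RT ln(fold change).  A 3-fold K_d ratio at 298.15 K is
0.651 kcal/mol (0.7 at one decimal).

## Degenerate inputs and numerical choices

* Zero ligand or zero macromolecule → zero bound ligand, no division
  performed.
* Two equal site classes collapse exactly (≤ 1e-10) onto one site class
  with N = 2 — used as a consistency test.
* Mass conservation holds to 1e-10 relative at every injection; both
  solvers agree with an independent bisection oracle to 1e-8 over ≥ 1000
  random draws.
* Empty peptide lists, empty window lists and all-zero matrices are valid
  inputs that propagate to flagged-empty outputs, never errors.
* All randomness flows through a single integer seed per generator call;
  identical arguments give bit-identical outputs.

## Known limitations

* Exact substring mapping only; peptides spanning sequence variants or
  carrying modifications will not map.
* No FDR re-estimation; confidence scores are taken as given.
* No ΔCp, displacement or sequential-sites ITC models; no peak
  integration from raw power traces.
* Specificity matrices carry no significance statistics (no iceLogo-style
  Z-tests); frequencies and optional background enrichment only.
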