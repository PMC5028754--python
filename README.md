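# picsfit

Tools for two workhorse analyses in protein biochemistry:

1. **Protease substrate-specificity profiling** in the PICS style
   (Proteomic Identification of protease Cleavage Sites).  A protease is
   incubated with an amine-protected, proteome-derived peptide library;
   cleavage products acquire a biotinylated neo-N-terminus and are
   identified by MS.  The analysis filters the identification lists
   (biotin flag, confidence thresholds, subtraction of mock and
   catalytically-inactive controls, removal of unprocessed-library
   peptides), maps each surviving prime-side peptide back onto the
   proteome to reconstruct the non-prime residues, and tallies the
   20 x 10 substrate-specificity matrix over subsites P5..P1, P1'..P5'
   (Schechter–Berger nomenclature; P1–P1' flank the scissile bond).
2. **Isothermal titration calorimetry (ITC)** isotherm analysis: forward
   models and least-squares fits for a single class of N identical sites
   and for two independent sites per macromolecule, chi-square profiles
   over the two dissociation constants, and affinity/free-energy
   conversions (ΔG = RT ln K_d, ΔΔG = RT ln ratio).

Because screens of this kind often ship without raw data, the package
includes a first-class synthetic-data module: a random proteome, a tryptic
digest library, in-silico cleavage by a protease with a *planted* subsite
motif plus MS-like identification noise, and forward-simulated titrations.
Every downstream stage is therefore testable end-to-end, including the two
qualitative outcomes that matter in practice — recovery of a planted motif
at frequency 1.0, and a clean "no cleavage detected" null.

## The models

For one class of `N` identical sites per macromolecule at cell
concentration `M_t` and titrant concentration `L_t`, the bound ligand
`[ML]` solves the mass-balance quadratic
`[ML]^2 − (N·M_t + L_t + K_d)[ML] + N·M_t·L_t = 0`.
For two independent sites the free ligand `L` solves
`L_t = L + M_t·L/(K_d1+L) + M_t·L/(K_d2+L)`.
Injection heats follow from the cumulative heat content
`Q_i = V0 · Σ_s ΔH_s · [occupied site s]` with the perfusion-cell
displaced-volume correction
`q_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`, normalized per mole of
injectant.  χ² is the unweighted sum of squared residuals in normalized
heat units; the two-site χ² profile re-optimizes both enthalpies and the
baseline at each (K_d1, K_d2) node by an exact linear solve.

## Worked example

```sh
picsfit simulate --outdir demo
picsfit pics --runs demo/runs.tsv --proteome demo/proteome.fasta --outdir demo/pics
picsfit itc-fit --titration demo/titration_full_length.tsv --model one_site --out demo/fit.json
```

The default configuration simulates a 100-protein proteome, digests it with
a tryptic rule (cleave after K/R, not before P, lengths 5–40), cleaves the
library with a fully efficient protease whose planted motif is P1 = F, and
simulates one titration (30 x 9 μL of 1.42 mM ligand into 1.43 mL at 97 μM,
one-site ground truth N = 2, K_d = 320 μM, ΔH = −5 kcal/mol).  It prints:

```
1031 cleavage windows
one_site: N=2 Kd=320 uM dH=-5 kcal/mol chi2=1.638e-18
```

`demo/pics/report.json` records every cascade stage (here 1031 identified
products in, 885 mapped unambiguously, 146 with ambiguous non-prime side,
0 unmapped), and `demo/pics/specificity_matrix.tsv` holds the frequency
matrix — its P1 column puts frequency 1.0 on F, the planted residue, and 0
elsewhere.  The ITC fit recovers the generating parameters to machine
precision on noiseless data.  Setting `protease_efficiency: 0.0` in a
config file drives the same pipeline to `no cleavage detected (0 windows)`.

From Python:

```python
import picsfit as pf

prot = pf.InjectionProtocol.uniform(30, 9.0, 1.43, 64.8, 796.0)
tit = pf.simulate_isotherm(prot, pf.OneSiteParams(N=1, Kd=43.0, dH=-5.0))
fit = pf.fit_one_site(tit, init=pf.OneSiteParams(1.5, 64.5, -7.5))
print(fit.params.Kd)          # 43.000000000000924
print(pf.ddg_ratio(3.0))      # 0.6509112467240942 kcal/mol for a 3-fold Kd ratio
```

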