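# ssbnmr

Quantitative analysis of solution-state NMR and biophysical data for
single-stranded-DNA-binding (SSB) proteins — small OB-fold domains whose
β-barrel loops form the ssDNA-binding surface.  The package was built
around the characterization workflow for a thermostable archaeal SSB
studied at elevated temperature: backbone dynamics, binding-surface
mapping, structural-ensemble statistics, and thermal/binding
thermodynamics, plus a synthetic-data generator so every stage can be
verified by parameter recovery without any external downloads.

## What it computes

**Backbone relaxation (`ssbnmr.relax`).**  Per-residue ¹⁵N R₁ and R₂ from
single-exponential fits of peak height versus relaxation delay,
I(t) = I₀·exp(−R·t), with Monte-Carlo rate errors; heteronuclear NOE as
the saturated/unsaturated peak-height ratio; flexibility flags for
residues more than 2 SD below the profile mean (R₁, R₂) or with
hetNOE < 0.6; and the rotational correlation time from the R₂/R₁ ratio

    τ_c = 1/(4π·ν_N) · sqrt(6·R₂/R₁ − 7),

valid where R₂/R₁ > 7/6, with ν_N the ¹⁵N resonance frequency
(default 60.81 MHz, i.e. a 600 MHz ¹H spectrometer).

**Chemical-shift perturbation (`ssbnmr.csp`).**  Combined amide
perturbations Δδ_avg = sqrt((Δδ_N/5.88)² + Δδ_H²) between apo and
ligand-bound shift tables (Trp side-chain Nε–H sites included),
classified against the profile mean and SD (> mean+1 SD, > mean+2 SD),
titration trajectories under fast exchange, and B-factor painting of the
perturbations onto a structure.

**Ensemble structure analytics (`ssbnmr.struct`).**  Multi-model PDB
ingestion, XPLOR-dialect `assign` distance-restraint parsing, restraint
classification by residue separation |i−j| (intra 0 / sequential 1 /
medium 2–5 / long > 5, hydrogen bonds apart), Kabsch least-squares
superposition, pairwise ensemble RMSD over residue/atom selections, and
probe-atom displacement between superposed ensembles.

**Thermodynamics (`ssbnmr.thermo`).**  Two-state scaled DSC fits
(excess heat capacity A·ΔH²/(RT²)·K/(1+K)² with van 't Hoff K(T) and a
polynomial baseline), independent-site (Wiseman) ITC fits with
exponential-dilution volume bookkeeping yielding K_d, n and ΔH, CD molar
ellipticity [θ] = θ_mdeg/(10·c·l), and thermal-melt analysis with a
reversibility score.

**Synthetic data (`ssbnmr.simulate`).**  Generators for every input type
with serialized ground truth (`ground_truth.json`) and seeded, hash-stable
output; at zero noise each output is an exact forward-model evaluation.

## Worked example

Generate a synthetic dataset and run every stage:

```
$ ssbnmr simulate --seed 7 --out-dir data
$ ssbnmr relax --r1 data/r1_decays.tsv --r2 data/r2_decays.tsv \
               --hetnoe data/hetnoe.tsv --out-dir run
tau_c (per-residue mean): 4.943 ns
tau_c (from mean rates):  4.909 ns
flagged flexible residues: [32, 34, 35, 36, 97, 98, 99, 110, 114]
```

The tumbling time near 5 ns is what a ~13 kDa protein shows when it
tumbles fast (here: study conditions at 50 °C); the flagged residues are
exactly the loop/terminus set the generator planted as flexible.

```
$ ssbnmr csp --apo data/shifts_ratio_0.tsv --bound data/shifts_ratio_2.tsv --out-dir run
mean 0.0255 ppm, SD 0.0840 ppm
perturbed residues (> mean+1 SD): [15, 30, 31, 32, 40, 54, 75, 79]
```

The recovered binding surface equals the planted site set (residue 75 via
its Trp side-chain Nε–H).

```
$ ssbnmr thermo dsc data/dsc_full_length.csv
T_m     84.15 C (357.30 K)
dH_vH   100.1 kcal/mol
scale   0.9972
$ ssbnmr thermo itc data/itc.csv
K_d     1.650 uM
n       1.010
dH      -9.95 kcal/mol
$ ssbnmr thermo cd data/cd_melt.csv
total_change    -449,161 deg cm2 dmol-1
midpoint        65.82 C
reversibility   0.995
$ ssbnmr struct rmsd data/ensemble.pdb --selection "3-97,104-113:backbone"
models  20
pairwise_rmsd_A 1.000 +/- 0.022
```

Each fit recovers the generator's truth (T_m 84.16 °C, K_d 1.75 μM,
n 1.009, ΔH −10 kcal/mol, dispersion 1.0 Å) within the noise of a 1%
measurement; `ssbnmr report --run-dir run` aggregates the stage outputs
into a single JSON report.

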