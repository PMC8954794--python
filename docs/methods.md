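# Methods

This note records the models implemented in `ssbnmr`, the defaults and
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Backbone relaxation

Peak-height decays are fitted per residue to a two-parameter single
exponential I(t) = I₀·exp(−R·t) by nonlinear least squares
(`scipy.optimize.curve_fit`).  Initial guesses are I₀ = max height and
R = ln(I_first/I_last)/(t_last − t_first), clipped to (10⁻³, 10³) Hz; an
all-constant series is reported as a converged fit pinned at the lower
clip with a warning rather than an error, and optimizer failure yields
`converged=False` rather than an exception so one bad residue never
aborts a profile.  Rate errors come from 200 Monte-Carlo refits of the
best-fit curve plus Gaussian noise scaled to the fit-residual RMS (or the
supplied height errors), with a fixed internal seed (1234) so repeated
analyses of the same table agree byte-for-byte.

Two delay schedules are shipped as presets: 20–1600 ms (10 points) for
R₁ and 16.96–547.72 ms (10 points) for R₂, matching a standard pseudo-3D
acquisition on a 600 MHz instrument.

hetNOE is the ratio I_sat/I_unsat per residue with quadrature error
propagation.  A zero unsaturated height marks the residue invalid rather
than producing an infinity.

Profile statistics (means, SDs) are computed over usable residues only:
converged in both fits and not flagged as overlapped in the input table.
Flexibility flags: R₁ or R₂ more than 2 SD from the profile mean is
detected two-sided, but only the low side is reported as flexible
(`low_r1`/`low_r2`; the high side is kept in `high_*` columns);
hetNOE < 0.6 flags fast ps–ns motion.  Both thresholds are arguments.

The tumbling time is τ_c = sqrt(6·R₂/R₁ − 7)/(4π·ν_N).  The estimate is
undefined for R₂/R₁ ≤ 7/6 and is returned as an explicitly flagged
undefined result, never a silent NaN.  Because averaging per-residue
τ_c values and evaluating τ_c on mean rates differ by ~1% on realistic
profiles, `profile_tau_c` reports both conventions (with optional
symmetric trimming for the per-residue mean) and labels each.  The
default ν_N of 60.81 MHz corresponds to ¹⁵N on a 600 MHz ¹H spectrometer
and is overridable everywhere.  No model-free (Lipari–Szabo) analysis is
attempted; the pipeline stops at R₁/R₂/hetNOE/τ_c, and exchange
contributions to R₂ are not modelled.

## Chemical-shift perturbation

Δδ_avg = sqrt((Δδ_N/5.88)² + Δδ_H²).  Matching between tables is strictly
by (residue id, site); sites present in only one table (e.g. broadened
beyond detection on binding) are listed as unmatched rather than dropped
or imputed.  Backbone amides and Trp side-chain Nε–H sites are pooled in
the profile mean/SD by default (configurable), since side-chain
perturbations belong to the same binding surface.  Classification is
one-sided above the mean (perturbations are non-negative by
construction): `gt2sd` above mean + 2 SD, `gt1sd` above mean + 1 SD.
Titration trajectories reference every table to the ratio-0 apo table
and flag sites whose CSP decreases by more than a noise floor
(default 0.005 ppm) between consecutive ratios, which under fast exchange
indicates tracking problems.  Structure painting writes model 1 with
per-residue CSP × 100 in the B-factor column (two-decimal PDB precision).

## Ensemble structure analytics

"Backbone" means N, CA, C (carbonyl O excluded) and "heavy" means all
non-hydrogen atoms; both conventions vary between validation suites, so
the atom class is part of the selection syntax
(`3-97,104-113:backbone`).  Pairwise ensemble RMSD superposes each of the
C(n,2) model pairs independently on the selection (not RMSD to a mean
structure) and reports mean ± sample SD.  Superposition is the Kabsch
SVD solution with reflection correction, so the rotation is always
proper; fewer than 3 selected pairs or a collinear selection is an
error.  Probe-atom displacement superposes every model pair of two
ensembles on a chosen frame and reports the probe distance for all
combinations plus the model-1 × model-1 value; residue numbering must
agree between ensembles — there is no alignment-based renumbering, and a
missing counterpart fails loudly.

Restraint files use the XPLOR `assign (resid I and name A)(resid J and
name B) d d⁻ d⁺` dialect.  OR-group (ambiguous) selections count as one
restraint, taking the first selection pair and setting an `ambiguous`
flag.  A `!` comment mentioning hydrogen bonds opens a block in which
amide-donor→oxygen pairs are labelled `hbond`; any other comment closes
it.  Unparseable statements are collected with line numbers into a
report on the returned list and never abort parsing.  Categories by
|i−j|: intra 0, sequential 1, medium 2–5, long > 5; hydrogen bonds are
counted apart so the four NOE categories always partition the NOE total.

## Thermodynamics

**DSC.**  Cp(T) = poly(T − T̄) + A·ΔH²/(R_gas·T²)·K/(1+K)² with
K(T) = exp(−(ΔH/R_gas)(1/T − 1/T_m)) and
R_gas = 1.98720425 × 10⁻³ kcal mol⁻¹ K⁻¹ throughout.  ΔH is the van 't
Hoff enthalpy; the dimensionless scale A absorbs the calorimetric/van 't
Hoff discrepancy, in the style of instrument-vendor "two-state scaled"
fits.  The baseline polynomial (default degree 2) is fitted jointly; T_m
is initialized at the grid maximum of the edge-detrended signal and the
fit refuses to start when no interior peak rises above 5× the edge
residual RMS.  Note that the *maximum* of the excess Cp sits ~0.07 K
below T_m because of the 1/T² prefactor; the fitted T_m parameter itself
is recovered exactly on noiseless data.  Temperatures are Kelvin
internally; I/O uses °C.

**ITC.**  Independent-site model with exponential-dilution bookkeeping
for a perfusion cell: after cumulative injected volume ΔV,
M = M₀·e^(−ΔV/V₀) and X = X_syr·(1 − e^(−ΔV/V₀)).  The complex
concentration is the closed-form smaller root of the binding quadratic,
cumulative heat Q_k = ΔH·V₀·[PX]_k, and the measured heat corrects for
displaced volume, q_k = Q_k − Q_{k−1} + (v_k/V₀)(Q_k + Q_{k−1})/2, plus a
constant per-injection dilution offset fitted jointly (no blank
titration is assumed).  K_d is fitted in log₁₀ space; first-injection
discard is off by default and available as a flag.  Exothermic heats are
negative.  A titrant that cannot saturate the cell produces a warning,
not an error.

**CD.**  [θ] = θ_mdeg/(10·c·l) in deg cm² dmol⁻¹ with c in mol/L and l
in cm.  This is per-protein molar ellipticity, not mean-residue; divide
by the residue count for MRE.  Melt analysis reports [θ](T) at the
requested wavelength, the endpoint-to-endpoint change, a two-state
van 't Hoff sigmoid midpoint (constant folded/unfolded baselines), and
reversibility = 1 − |[θ]_cooled,final − [θ]_initial|/|total change| when a
cooling branch exists (1 = fully reversible, 0 = stuck at the hot
endpoint).

## Synthetic-data generator

The generator's defaults encode the study conditions of a ~13 kDa
thermostable OB-fold SSB at 50 °C: 114 residues; rigid-core rates drawn
around R₁ = 1.928 Hz, R₂ = 6.862 Hz, hetNOE ≈ 0.79 with a planted
flexible set (residues 32, 34–36, 97–99, 110, 114 — the β1–β2 loop,
the loop after the last strand, and the C terminus) at distinctly lower
values; an 8-residue binding surface (15, 30, 31, 32, 40, 54, 75, 79;
residue 75 as a Trp side chain) with saturation CSP amplitudes of
0.15–0.45 ppm; DSC truths of 84.16 °C/100 kcal/mol (full length) and
53.12 °C/80 kcal/mol (N-terminal truncation; the enthalpies are generic
protein-unfolding magnitudes, as the calorimetric enthalpies were not
part of the summary statistics); ITC truth K_d = 1.75 μM, n = 1.009,
ΔH = −10 kcal/mol under the titration protocol 24 × 10 μL of 500 μM
ligand into 1.0 mL of 50 μM protein at 25 °C; a CD melt with midpoint
66 °C and an amplitude of 475,900 deg cm² dmol⁻¹ chosen so the observed
20→80 °C change is ≈452,000 (the two-state curve traverses ~95% of its
amplitude in that window); and a coordinate ensemble dispersion target
of 1.0 Å.

Noise is additive Gaussian with SD quoted as a fraction of each signal's
reference amplitude — peak I₀ for decays and hetNOE pairs, the excess-Cp
peak height for DSC, the largest injection heat for ITC, the
folded-to-unfolded amplitude for CD — a single knob matching how
spectral noise is usually quoted.  Shift-table noise is absolute:
0.002 ppm (¹H) and 0.01 ppm (¹⁵N), typical assignment precision.  The
default fractional noise is 1%.  Titration shifts move linearly with the
fractional saturation from the closed-form one-site quadratic (fast
exchange); the ¹H/¹⁵N split of each site's endpoint is randomized under
the constraint that the combined CSP at saturation equals the true
amplitude.

Ensembles add independent isotropic Gaussian displacements of SD
dispersion/√6 per coordinate to a deterministic solenoid-backbone
reference model (N, CA, C, O per residue; smooth and non-collinear but
with no claim to stereochemistry), which makes the expected
post-superposition pairwise RMSD ≈ the requested dispersion (the
superposition removes 6 of ~3N degrees of freedom, a ≪1% correction at
this size).  Rigid-transformed copies are available for superposition
tests.

Every generator draws from a deterministic substream of the configured
seed, so a fixed `SimulationConfig` reproduces byte-identical files;
the ground truth is serialized as JSON next to each dataset and recovery
tests read truth only from that file.

What the generator does **not** emulate: raw FIDs, spectra, peak picking
or assignment; slow/intermediate-exchange lineshapes and exchange
broadening; anisotropic tumbling (rates are generated residue-wise, not
from a diffusion tensor); correlated or multiplicative noise;
temperature-dependent baselines beyond a low-order polynomial; and real
protein stereochemistry in the coordinate ensembles.  Passing recovery
tests therefore demonstrates the correctness and calibration of the
estimators under idealized noise, not robustness to the artifacts of
real spectra.

## Problem sizes and determinism

Tests and the acceptance script use the full 114-residue profile, 0.1 K
DSC grids, 24-injection isotherms, 20-model ensembles, 50-titration
sensitivity sweeps and a 1000-instance superposition cross-check; the
complete suite runs in well under a minute on one CPU.  All randomness
flows through explicit seeds (simulation seed per dataset; fixed
internal seed for Monte-Carlo fit errors), and re-running any stage on
the same inputs is byte-identical.

## Known limitations

* R₂ is treated as pure transverse relaxation; chemical-exchange
  contributions would bias τ_c upward.
* The τ_c expression assumes isotropic tumbling and neglects
  high-frequency spectral-density terms; it is a ratio estimate, not a
  diffusion-tensor fit.
* The CSP classifier's mean/SD are contaminated by true binding-site
  signal (as in common practice); very large binding surfaces would
  raise the thresholds and cost sensitivity.
* The ITC model is a single independent-site class; cooperative or
  multi-site binding is out of scope, and K_d precision at 1% heat noise
  is intrinsically limited (~4% median error at c ≈ 29 with 24
  injections).
* The DSC model is strictly two-state with a shared baseline; multi-state
  deconvolution is out of scope.
* Cross-entry structure comparisons require consistent residue numbering;
  no sequence-alignment-based mapping is performed.
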