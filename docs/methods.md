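# Methods

## Signal model

The spherical-mean (powder-average) signal is a three-compartment
mixture. Per shell of b-value b (internal unit ms/μm²; bval files in
s/mm² are divided by 1000 on ingestion so diffusivities stay O(1)):

* **Neurites** — zero-radius sticks with axial diffusivity D_in:
  S = √(π/(4·b·D_in))·erf(√(b·D_in)), the closed form of the
  orientation average of exp(−b·D_in·cos²θ). Verified against direct
  quadrature of that integral to 1e-6.
* **Somas** — impermeable spheres of radius R_soma with internal
  diffusivity D_soma, attenuated per the Gaussian-phase-distribution
  (GPD) approximation: ln S is the Murday–Cotts series over the roots
  μ_m of j₁′(x)=0 (first root 2.0815759778…), truncated at 20 roots
  with a 1e-8 tail check; the roots are found by bracketed bisection to
  ~1e-13. The gradient amplitude is inferred from
  b = γ²G²δ²(Δ−δ/3) with γ = 2.6752×10⁸ rad s⁻¹ T⁻¹.
* **Extracellular water** — isotropic Gaussian, exp(−b·D_e).

Signal fractions live on the simplex (f_extracellular = 1 − f_neurite
− f_soma) and the total signal is exactly linear in them. D_soma is
fixed at 3.0 μm²/ms (free water at body temperature) and not fitted,
the convention for this model class.

**Validity of the GPD approximation.** A random-walk simulator
(reflecting impermeable sphere, PGSE phase accumulation by midpoint
rule; `cortexdev.montecarlo`) provides an independent reference. At
moderate attenuation the series and the random walk agree to a few
tenths of a percent across radii, confirming the implementation (GPD
is exact to second order in the phase). At strong attenuation the
phase distribution is no longer Gaussian and the series overestimates
the signal; at the default protocol's strongest shell (b = 6 ms/μm²,
δ=7 ms, Δ=23.3 ms, D_soma=3) the deviation is ≈ +1% already at
R_soma = 5 μm and grows rapidly for larger spheres. The GPD form is
retained regardless — it is the standard forward model for this
imaging method — but tests document where it bends, and the
random-walk oracle is available for any protocol.

The random walk subdivides the δ+Δ window into 10⁴ base steps,
simulating the gradient-off gap at 4× coarser steps (no phase
accumulates there and the step stays ≪ R, so the wall bias is
unchanged to leading order). Walkers start uniform in the sphere;
rejection sampling at the wall preserves that equilibrium. The
remaining step-size bias is O(step/R) and visible below the half
percent level; a convergence sweep is how we separated it from true
GPD error.

## Parameter estimation

`SandiModel.fit` is bounded trust-region least squares over
(f_neurite, f_soma, R_soma, D_in, D_e) with bounds [0,1], [0,1],
[1,12] μm, (0.1,3], (0.1,3] μm²/ms. Initialization is a 5×5×5 grid
over (f_neurite, f_soma, R_soma) with diffusivities started at 2.0 and
0.75 μm²/ms; the objective is evaluated at every admissible grid point
(fraction sum ≤ 0.95), the best five starts are polished, and the
lowest final residual wins with ties broken toward smaller R_soma.
Fractions are renormalized onto the simplex after fitting; fitted
f_soma < 0.05 flags R_soma as unidentifiable (the soma compartment
then contributes too little signal to pin down a radius).

**Identifiability.** Six shell means carry limited information about
five parameters. The model has an almost flat ridge coupling f_neurite
to the diffusivities: parameter sets far apart in f_neurite reproduce
the shell means to a few 1e-4, so under any realistic noise the fully
free maximum-likelihood estimate slides along the ridge and is biased,
and finding deeper optima makes it worse, not better — a property of
the likelihood, not of the optimizer. The noise-free round trip is
exact because the ridge still has a unique zero. For noisy data the
package therefore offers a constrained mode, `fit(fixed={"d_in": 2.0,
"d_e": 0.75})`, which pins the diffusivities at conventional values
and recovers signal fractions with bias ≈ 0.01 at SNR 50; the recovery
experiment exposes both modes. Whether to fit or fix diffusivities is
genuinely open for this model family; both are provided, with the
constrained mode recommended for per-voxel noisy fits.

**Noise.** Rician corruption is |S + (n₁+i·n₂)/SNR| with SNR defined
at b=0 per acquired volume. The acquisition-level generator corrupts
every direction independently and then takes the per-shell arithmetic
mean, so shell means carry noise σ/√n_directions and a small Rician
floor; results are renormalized to the measured b=0 mean as with real
data. Recovery experiments sweep SNR ∈ {25, 50, 100} since an in vivo
SNR is not pinned down.

## Soma-composition simulator

A 1 mm³ voxel holds per-type cell counts with Gaussian radius laws
(baseline: microglia 6,500 at 2.0±0.5 μm; astrocytes 15,700 and
oligodendrocytes 12,500 at 5.5±1.5 μm; neurons 92,000 at 8.0±2.0 μm;
endothelial cells 0.35×neurons at 9.0±0.5 μm). Radii are sampled per
cell (truncated at zero by resampling, a <1e-6 effect at these laws)
and pooled; the MR apparent radius is (⟨R⁵⟩/⟨R³⟩)^½. A closed-form
oracle uses the Gaussian raw moments E[R³] = μ³+3μσ² and
E[R⁵] = μ⁵+10μ³σ²+15μσ⁴, count-weighted; Monte Carlo and oracle agree
within sampling error (0.3% at 10⁶ radii) and the percent change is
invariant to global count rescaling.

Ageing modulates counts linearly, count(age) = count(ref)·(1 +
slope·(age−ref)), with the slope pattern taken from the fitted
cell-type expression trajectories (expression assumed proportional to
cell number), neurons held flat, and the free proportionality constant
anchored so oligodendrocyte counts rise 10% across ages 8–19. Both a
sampling mode (one or several voxel realizations per age) and the
analytic mode are provided, since either reading of "simulate per age"
is defensible.

**Sensitivity of the moment ratio.** The ⟨R⁵⟩/⟨R³⟩ radius of the
baseline mixture is 9.241 μm and is dominated by the neuron pool
(~65% of ⟨R³⟩, ~70% of ⟨R⁵⟩; neuron-only value 9.526 μm). Because the
neuron radius law has the heaviest tail, every other pool — including
the nominally large endothelial cells (9.0±0.5 μm, moment-ratio value
9.10 μm) — is *smaller* than the mixture in moment-ratio terms.
Consequences, all verified by the analytic oracle in the test suite:
an oligodendrocyte rise of 10% across the age range moves the
apparent radius by only about −0.07%; adding proportional declines of
astrocytes, microglia and endothelial cells pushes the change back
toward zero or slightly positive (the astrocyte term, same radius law
but 1.26× the oligodendrocyte count, opposes the oligodendrocyte
term); and a −1% change requires a severalfold (≈ +300%) rise in
oligodendrocyte counts with neurons held fixed. In other words, at
these counts and radius laws the mechanism has the right sign but is
two orders of magnitude too weak at a 10% oligodendrocyte rise; the
anchor scale is exposed in the config precisely because it is the one
free and unmeasured constant of this simulation.

## Expression trajectories

The smooth is a cubic B-spline with k=5 basis functions (knots at age
quantiles), reparametrized by a sum-to-zero constraint so it
represents deviations around the intercept, with a second-difference
penalty (P-spline). The penalty weight is chosen by generalized
cross-validation on a 41-point log grid (1e-4…1e6), solved through a
Demmler–Reinsch eigendecomposition so thousands of genes sharing one
design are fitted in a few matrix products. Curves and first
derivatives are evaluated on a 0.1-year grid over the observed range.

**Smooth-term p-value.** Selection inference uses the exact F-test of
the full (unpenalized) k-basis smooth against the covariate-only
model. Under Gaussian noise its null distribution is exactly uniform,
which keeps Benjamini–Hochberg selection calibrated — GCV-selected
penalties would distort the null. The penalized fit is used for
curves, derivatives, peak-growth and crossover statistics, where
smoothness, not calibration, matters. With only centered covariates in
the null block, a constant response yields p→1 and an essentially flat
curve.

The RNA-seq dialect adds RIN, sex and region dummies as linear
confounders and a donor random intercept via a linear mixed model
(spline + confounders as fixed effects; Wald χ² on the spline block).
Donor-mean centering is *not* a valid fallback here: each donor has a
single age, so centering would remove the age signal with the donor
effects.

Cell-type trajectories standardize genes (z-score, or demean only),
average within the set, and spline-fit the mean profile; standardized
modes re-center the fitted curve on the age grid. Peak growth is the
grid age maximizing the first derivative (ties to the youngest age;
boundary maxima and non-positive peaks are flagged; peak *level* is
available as an option since "peak growth" is ambiguous). With k=5 the
derivative peak of a logistic-shaped trajectory is localized to about
±1 year over a 30-year range — the basis, not the grid, limits
resolution. Crossover of two curves is the first sign change of their
difference, linearly interpolated between grid points; in log₂
expression space a curve difference is the log expression ratio, so
this is the age at which the expression ratio crosses 1 without the
instability of a literal division.

Enrichment of an age-gene list in cell-type sets is the one-sided
hypergeometric tail (exact, matched to an exhaustive tail-sum oracle
to 1e-12 in tests) with the sample odds ratio, BH-corrected across
sets; gene selection is BH-corrected across genes, the two families
separately.

## Cohort statistics

Outcome and continuous covariates are z-scored, sex coded ±0.5, the
puberty-by-sex interaction formed from the coded columns. The
candidate mean structures {age; age+sex; age+sex+PDSS;
age+sex+PDSS+sex:PDSS} are fitted by OLS and the lowest-AIC candidate
reported with standardized β, Wald 95% CIs (profile CIs would differ
only in tiny samples) and adjusted R²; α = 0.005 throughout. Note AIC
is not a consistent selector: an irrelevant covariate lowers AIC
whenever its χ²₁ improvement exceeds 2 (probability ≈ 0.16), so even
with a pure age effect the minimal model is selected only ~75% of the
time — tests assert the age term always survives rather than perfect
minimality. Percent change across the age range is computed from the
same mean structure refitted on the original scale,
100·(ŷ(a_hi)−ŷ(a_lo))/ŷ(a_lo), with sex at its midpoint and puberty at
the sample mean; it is flagged undefined if the younger-age prediction
is not positive.

Scan-rescan repeatability is the two-way consistency ICC(3,1) =
(BMS−EMS)/(BMS+(k−1)·EMS) from ANOVA mean squares, with the F-test of
the between-subject effect; subjects missing sessions are excluded
with a warning, and an exactly-zero within-subject error (identical
sessions) is clamped against floating-point residue so ICC = 1
exactly. The estimator has a small-sample downward bias (≈ −0.03 at 6
subjects × 5 sessions for a true value 0.9); the large-sample check in
the test suite therefore uses 30 subjects, while 6×5 remains the
scan-rescan design default.

## Synthetic data

The imaging cohort plants per-measure linear percent changes across
ages 8–19 (defaults: f_neurite +11.91%, R_soma −1%, soma and
extracellular fractions −2%, cortical thickness −5%, grey-matter
volume −4%, surface area flat with a male>female shift) with noise
levels chosen so the age R² of the microstructural measures lands in
the ~0.45–0.55 regime at n=88. Pubertal stage is
round(clip(1 + 4·sigmoid((age−12)/1.5) + N(0, 0.6²))), giving an
age–PDSS R² around 0.75. Measures are generated independently — the
real-data covariance between, say, f_neurite and cortical thickness is
unknown and not emulated — so passing recovery tests demonstrates
estimator correctness, not robustness to correlated confounding.

Expression modules assign linear age trajectories per cell type
(oligodendrocyte and excitatory up, astrocyte/microglia/
endothelial/OPC down, inhibitory flat); on the log₂RPKM scale the
baselines are the study-reported cell-type means and the
oligodendrocyte/astrocyte slopes are chosen so those two curves cross
at age 20, the observed glial ratio shift. The RNA-seq dialect adds a
donor intercept (σ=0.3), a RIN effect (0.15 per unit), region offsets
(σ=0.1) and residual noise σ=0.35; the microarray dialect uses
Z-scale values with σ=1. Linear (rather than saturating) trajectories
are a simplification: they make planted slopes unambiguous for
recovery tests but do not emulate the early-life expression surge of
real developmental data.

Repeatability tables are value_ij = μ + u_i + e_ij with planted
variance components. All generators are pure functions of
(config, seed) and byte-reproducible.

## Problem sizes and numerical choices

Simulation sizes used by the test and acceptance suites: 10⁶ radii for
Monte-Carlo/analytic agreement; 10⁵ walkers × 10⁴ base steps for the
random-walk oracle; 100 Rician replicates at SNR 50 for estimator
bias; 2000 genes for null calibration (KS at α=0.01) and 20 replicates
of a 100-planted/1900-null mixture for empirical FDR; 100 replicates
for crossover recovery and percent-change recovery; 200 replicates for
the ICC closed form. Tolerances: GPD tail 1e-8; least-squares
xtol 1e-10; simplex preserved to 1e-9; BH and hypergeometric checks to
1e-12.

## Known limitations

* GPD misestimates strong-attenuation sphere signals (documented
  above); no water exchange between compartments is modelled.
* The five-parameter spherical-mean fit is practically unidentifiable
  at realistic SNR without constraining diffusivities.
* The composition simulator links expression to counts by direct
  proportionality with a single free scale; it does not couple
  composition to the diffusion signal fractions.
* k=5 smooths cannot localize features sharper than ~1 year, and
  GCV-based curves are slightly rougher than REML-based ones would be.
* Synthetic data are Gaussian, independent across measures and linear
  in age; real developmental data are none of these.
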