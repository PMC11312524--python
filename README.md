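# cortexdev

Toolkit for studying adolescent cortical microstructure with
soma-and-neurite density imaging (SANDI) diffusion MRI, and for linking
those imaging readouts to cell-type-specific gene-expression
trajectories from post-mortem cortex. It is aimed at microstructure
imaging and imaging-transcriptomics researchers who want a tested,
scriptable implementation of this analysis chain that runs end to end
on synthetic data.

## What it implements

**Signal model.** The direction-averaged (spherical-mean) diffusion
signal of cortical tissue is modelled as three non-exchanging
compartments,

S(b) = f_neurite · S_stick(b) + f_soma · S_sphere(b) + f_extracellular · e^(−b·D_e),

with S_stick(b) = √(π/(4·b·D_in))·erf(√(b·D_in)) for zero-radius
neurites, and S_sphere the Gaussian-phase-distribution (Murday–Cotts)
attenuation for water restricted in an impermeable sphere of radius
R_soma (intra-soma diffusivity fixed at 3 μm²/ms). The gradient
amplitude follows from b = γ²G²δ²(Δ−δ/3). Fitting is bounded nonlinear
least squares with multi-start grid initialization
(`SandiModel(...).fit()` → results object with estimates, residuals,
identifiability flags); a Monte Carlo random walk in an impermeable
sphere serves as an independent oracle for the sphere signal, and a
Rician noise model plus recovery experiments quantify estimator bias
and RMSE.

**Soma-composition simulator.** A cortical voxel is described by
per-cell-type counts (microglia 6,500; astrocytes 15,700;
oligodendrocytes 12,500; neurons 92,000; endothelial cells
0.35 × neurons per mm³) with Gaussian radius laws (2.0±0.5, 5.5±1.5,
5.5±1.5, 8.0±2.0, 9.0±0.5 μm). The MR apparent soma radius of the
pooled radius distribution is the moment ratio
R_soma = (⟨R⁵⟩/⟨R³⟩)^½. Counts are modulated linearly with age in
proportion to fitted cell-type expression slopes, yielding an apparent
radius trajectory (Monte Carlo sampling or exact Gaussian-moment
arithmetic).

**Expression trajectories.** Penalized cubic-spline (k=5) models of
expression against age, with RIN/sex/region confounders and a donor
random intercept for the RNA-seq dialect; per-gene smooth-term F-tests
with Benjamini–Hochberg control select age-associated genes; cell-type
mean trajectories, peak-growth ages, trajectory crossover ages (the
log-ratio crossing), and hypergeometric cell-type enrichment follow.

**Cohort statistics.** Parcel-to-network aggregation; age/sex/puberty
linear models (z-standardized, AIC candidate selection, Wald 95% CIs,
α = 0.005); model-predicted percent change across the age range; and
scan-rescan repeatability as the consistency ICC(3,1) =
(BMS − EMS)/(BMS + (k−1)·EMS).

**Synthetic data.** Generators for an imaging cohort (n=88, ages 8–19,
planted percent changes: f_neurite +11.91%, R_soma −1%), two
expression-dataset dialects with cell-type gene modules (microarray
Z-scores over ages 0.5–72; log₂RPKM with donor repeats over 0.5–40),
and scan-rescan tables with planted variance components — all pure
functions of (config, seed), with ground-truth labels so every
estimator is testable.

## Worked example

```python
import numpy as np
from cortexdev import (connectom_protocol, SandiParams, sandi_signal,
                       SandiModel, generate_imaging_cohort,
                       fit_linear_models, percent_change_over_age)

prot = connectom_protocol()          # δ=7 ms, Δ=23.3 ms, b=0…6 ms/μm²
truth = SandiParams(f_neurite=0.45, f_soma=0.30, r_soma=7.0, d_in=2.0, d_e=0.8)
signal = sandi_signal(prot, truth)
print(np.round(signal, 4))
# [1.     0.7656 0.5625 0.3749 0.2527 0.1762]

print(SandiModel(prot, signal).fit().summary())
# SANDI spherical-mean fit
#   shells: [0.0, 0.5, 1.2, 2.4, 4.0, 6.0] ms/um^2, delta=7.0 ms, Delta=23.3 ms
#   n_obs: 1
#    f_neurite  f_soma  r_soma  d_in  d_e  f_extracellular  residual_norm  ...
# 0       0.45     0.3     7.0   2.0  0.8             0.25            0.0  ...

table = generate_imaging_cohort(seed=0)        # synthetic n=88 cohort
fit = fit_linear_models(table, "f_neurite")
print(fit.summary())
# selected (lowest AIC): age
# adj. R^2 = 0.459
#              beta   ci_lo   ci_hi    p
# intercept  0.0000 -0.1559  0.1559  1.0
# age        0.6821  0.5254  0.8389  0.0
print(f"{percent_change_over_age(fit, 8, 19):.2f}%")
# 10.84%
```

The noise-free forward-then-fit round trip recovers the generating
parameters exactly; on the synthetic cohort the AIC-selected model is
age-only, the standardized age coefficient is ≈0.68, and the predicted
f_neurite change across ages 8–19 for this seed (10.84%) scatters
around the planted 11.91%.

A command-line layer wraps the same functions:

```bash
cortexdev generate-data imaging --seed 1 --outdir data/
cortexdev cohort-stats --table data/cohort.csv --outcomes f_neurite,r_soma --out models.json
cortexdev simulate-soma --seed 1 --out trajectory.csv
```

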