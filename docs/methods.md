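# Methods

This note documents the models in `woodprod`, the choices made where the
design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Screening

Annualized growth is G = (D₂−D₁)/Δt. Two report-only rules flag gross
measurement errors: G ≥ 4 cm yr⁻¹ (threshold inclusive) and a raw
diameter decrease of strictly more than 0.5 cm between censuses (on the
raw decrease, not annualized — a transcription error does not shrink
with the census interval). Small negative growth is kept: stems shrink
under low xylem hydrostatic pressure in dry periods. Flagged stems stay
in the dataset; only their *measured* increments are distrusted, and
their contribution to AWP is model-imputed. Plots losing strictly more
than 50% of census-1 stems are removed from all downstream analyses;
such mass mortality reflects a catastrophic disturbance, not the
steady-state dynamics the growth model describes. Screening is
idempotent and every exclusion carries exactly one reason code.

## Growth model

G = ρ₀·g·D^ρ₁·exp(ρ₂D) / (1 + ρ₃·exp(ρ₄·B_L)), with D the census-1
diameter (cm) and B_L the summed basal area (m² ha⁻¹) of strictly larger
stems in the plot. The numerator is a modified power law (growth can
rise, saturate, or peak and decline with size); the denominator is the
asymmetric-competition term — only larger neighbours shade a stem's
crown, and their effect compounds as B_L grows. Equal-diameter
neighbours are excluded (strict inequality). Neighbours enter B_L at
their per-hectare expansion weight by default (subplot stems count ×80,
full-plot stems ×8) so that B_L is a density; a raw-sum convention is
available (`expansion_scaled=False`). For recruits, whose first
observation is at census 2, B_L is built from the census-2 diameters of
their neighbours.

**Genus effect.** The genus deviation g is multiplicative on ρ₀ with
log g ~ N(0, σ_g²). Placing the random effect on ρ₀ only is the minimal
identifiable choice; per-genus growth *rates* differ far more than
per-genus size exponents at these sample sizes. Fitting maximizes the
marginal likelihood, integrating g out by adaptive Gauss–Hermite
quadrature (15 nodes recentred and rescaled at each genus's conditional
mode). The genus effect touches the likelihood only through per-genus
sufficient statistics (Σm·G, Σm², ΣG²), so one evaluation costs
O(n + #genera·nodes) — full-likelihood fitting of thousands of stems
takes seconds. Reported genus deviations are posterior modes, centred so
their logs sum to zero (the grand mean folds into ρ₀).

**Numerics.** Parameters are optimized as (log ρ₀, ρ₁, ρ₂, log ρ₃, ρ₄,
log σ, log σ_g) by Nelder–Mead from a competition-free power-law pre-fit
(log G ~ log ρ₀ + ρ₁ log D + ρ₂ D on positive increments). The
fixed-effects variant profiles σ out analytically, which keeps it exact
on noise-free data where the RSS vanishes. If σ_g collapses below 10⁻³
the fit falls back to fixed effects with a logged warning. A two-stage
alternative (fixed-effects fit, then shrunken per-genus growth-ratio
deviations) is selectable. Residuals are Gaussian with constant σ by
default; `het_exponent=k` switches to σ·D^k.

**Identifiability.** ρ₀ and ρ₃ trade off along a likelihood ridge: at
large B_L the denominator is ≈ ρ₃·exp(ρ₄B_L) and only ρ₀/ρ₃ is sharply
determined; the separation comes from stems with B_L near zero (the
largest stems in each plot). At the validation scale (~5000 stems, 30
genera, σ = 0.08 cm yr⁻¹) all five parameters are typically recovered
within 10% relative error, but individual datasets can miss ρ₀ and ρ₃ by
2–3× that while pinning their ratio — this is sampling variability of
the MLE itself, not an optimizer artifact (the likelihood at the
estimate exceeds the likelihood at the truth in such runs).

**Prediction.** Every census-1 stem — survivors, screened outliers and
deaths alike — gets a one-year projection D(t+1) = D + G·1yr from the
fitted model; recruits are projected from their census-2 diameter.
A one-year horizon, not the census interval, defines the increment.

## Allometry

Height: H = a·(1 − exp(−b·D^c)), a Weibull-type saturating curve with
defaults a = 79.9 m, b = 0.011, c = 0.74; refittable by nonlinear least
squares with grid-seeded restarts. Biomass: AGB = 0.0673·(D²HW)^0.976 kg
with wood density W in g cm⁻³, matched species → genus mean → family
mean → dataset mean (unweighted; the resolution level is recorded per
lookup). Carbon is 47% of dry mass. Heights are always model-predicted
from diameter — measured heights never enter AWP.

## AWP

Plot AWP sums each census-1 stem's annual biomass increment times its
expansion factor (8 ha⁻¹ outer, 80 ha⁻¹ inner), converted to MgC.
Recruits are excluded by default (they were not present at census 1;
`include_recruits=True` adds them). The field-based cross-check uses
measured increments for surviving screened-in stems and substitutes the
median measured growth of surviving same-stratum plot members for
screened-out and dead stems — a deliberately simple gap-filling rule
meant as an internal consistency check, not a literature-faithful
re-implementation of published gap-filling protocols.

## Stand metrics

BA, QMD and stem density are expansion-weighted so that
BA = π/4·(QMD/100)²·n_stems holds exactly (residual < 10⁻⁹ enforced in
tests); this identity is what allows BA to enter the SEM as an exact
composite. Effective species number exp(−Σpᵢ ln pᵢ) uses *unexpanded*
plot-level basal-area shares, because diversity does not scale linearly
with area; unidentified stems are kept in BA/QMD but dropped (with
renormalization) from diversity shares. The self-thinning boundary is a
τ = 0.99 quantile regression of log QMD on log n_stems (pinball loss,
via `statsmodels.QuantReg`).

## Soil phosphorus

Total soil P (mg kg⁻¹) on the measured subset is modelled as intercept +
distance-to-stream + slope + elevation with a transect random intercept,
fitted by REML (`statsmodels MixedLM`); covariates are standardized
internally and coefficients reported on original scales. Singular fits
fall back to OLS with transect SD 0. Predictions add the fitted transect
intercept when the transect was observed. Classes: <300 → low,
300–500 (both bounds included, the only reading consistent with three
exhaustive intervals) → medium, >500 → high. A measured plot always
keeps its measured class.

## Structural equation model

The engine handles recursive path models over observed variables:
Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ, minimizing the Wishart ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p (Cholesky-based, which doubles as the
positive-definiteness guard). χ² = (N−1)·F_min by default (switchable to
N); df = p(p+1)/2 − #free parameters. Free parameters: path
coefficients, all variances, declared covariances, and all pairwise
covariances among exogenous variables. Optimization: BFGS then a
Nelder–Mead polish, from per-equation least-squares starting values
computed from S, with two jittered restarts (seeded). Standard errors
are delta-method: cov(θ) = 2/(N−1)·H⁻¹ with H the numerical Hessian of
F. RMSEA = √(max(χ²−df,0)/(df(N−1))) (0 when df = 0); CFI against the
independence baseline (whose MLE is diag(S), so F_baseline = −ln|R|);
SRMR is the RMS residual between sample and implied *correlation*
matrices over the unique triangle.

**Composite BA.** Since log BA = 2·log QMD + log n_stems + const
exactly, BA is a deterministic fixed-weight combination — not a latent
variable. A path BA→AWP contributes one free coefficient β, expanded
internally to 2β on log QMD and β on log n_stems; the sample covariance
never contains the (collinear) BA column. The reported QMD→BA and
n_stems→BA "paths" are the standardized fixed weights and carry no
p-values (they are not estimated). A free-loading variant (first weight
fixed for identification) exists for methodological comparison and can
only fit better (one more parameter, one fewer df).

**Default drivers model.** log AWP ← BA + diversity + soil class;
diversity ← log n_stems + soil class + logging; log QMD ← logging +
slope; covariance log n_stems ↔ log QMD. Ordinal soil class (1/2/3) and
the logging flag (0/1) enter as numeric covariates; AWP, QMD and
n_stems are log-transformed; listwise deletion for incomplete rows.

## Synthetic plot networks

The generator emulates a 140-plot network of 0.125-ha circular plots
(stems ≥30 cm) with 0.0125-ha central subplots (stems ≥10 cm) on 14
transects, ~62% of plots historically logged. Conditions and defaults:

- **Stand structure:** Poisson(12) outer stems per plot with diameters
  30 + Exp(11 cm), Poisson(4.6) subplot stems at 10 + (Exp(8) mod 20) cm
  — about 17 census-1 stems per plot.
- **Taxa:** 167 species with log-series abundances (x = 0.985) grouped
  into 60 genera; species drawn per stem, so denser plots are naturally
  richer (the species-accumulation confound the SEM's
  n_stems → diversity path controls for). 90% of stems labelled to
  species, 94% to genus.
- **Growth truth:** ρ = (0.35, 0.4, −0.008, 1.2, 0.04), σ_g = 0.2,
  σ = 0.08 cm yr⁻¹, giving increments of ~0.2–0.5 cm yr⁻¹. Plot-level
  multipliers exp(0.10·z_diversity + 0.10·z_soilP) build in the positive
  diversity and soil effects the SEM should recover.
- **Dynamics:** Δt ~ U(5, 7) yr; mortality 1.2% yr⁻¹; recruitment 1.8%
  per stem-year; two catastrophe plots with per-stem death probability
  0.85 to exercise the >50% mortality screen.
- **Logging:** size-biased removal with probability
  sigmoid((D − D₀)/8 cm); D₀ is calibrated by bisection against a
  Monte-Carlo stand so the *expected* QMD deficit of logged plots equals
  the 5 cm target. Removal probability always rises with diameter.
- **Soil:** P = 455 + 0.4·dist − 4·slope − 0.3·elev + transect(SD 60) +
  ε(SD 80) mg kg⁻¹, measured on 48 plots, spanning all three classes.
- **Pathology:** 1% of surviving stems get injected gross errors (half
  extreme growth ≥4 cm yr⁻¹, half shrinkage >0.5 cm); diameters are
  recorded to 0.1 cm (rounding can be disabled for exactness tests).

Everything is reproducible from the seed, and the generator returns the
latent truth (parameters, genus deviations, per-stem latent growth,
plot soil P, injected-error ids) for recovery testing.

**What the synthetic validation shows — and does not.** Passing tests
demonstrate internal correctness: the estimators recover the generating
process when the data follow the model. Real inventories violate the
generator in known ways — spatially clustered rather than independent
stems, diameter-dependent and spatially correlated measurement error,
non-random mortality (large or suppressed stems die more), buttress
remeasurement drift, taxonomic misidentification — so recovery here
bounds, but does not establish, performance on field data.

## Problem sizes in the validation suite

Growth-parameter recovery uses ~5000 stems in 30 genera (420 plots);
the SEM calibration uses 200 replicates of N = 140 plots; estimator
consistency uses one 140-plot network; the quantile-regression oracle
uses 50 points against a 161×161 grid search. The acceptance script
runs the same computations at the same sizes.

## Known limitations

- Only the single growth form above; no alternative growth functions or
  Bayesian estimation.
- The SEM engine covers recursive observed-variable models with
  composites — no latent measurement models, robust estimators, or
  multi-group fitting.
- Wald (delta-method) intervals; at N = 140 their empirical coverage in
  the calibration study runs ~0.90–0.96 against the nominal 0.95.
- Diversity is Hill number of order 1 only; no rarefaction.
- The field-based AWP gap-filling is a simplification (above).
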