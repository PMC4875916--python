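# woodprod

Estimating **aboveground wood production** (AWP, MgC ha⁻¹ yr⁻¹) from
repeat-census forest inventory data, and analysing what drives it.

The package is aimed at forest ecologists working with permanent-plot
networks: two censuses of stem diameters a few years apart, nested
circular plots (large stems over the full plot, small stems in a central
subplot), patchy soil sampling, and a historical disturbance layer. It
implements the full chain from raw census tables to a fitted structural
equation model, plus a synthetic plot-network generator with known
ground truth for validating every step.

## What it computes

**1. Screening.** Annualized growth G = (D₂−D₁)/Δt per stem; stems with
G ≥ 4 cm yr⁻¹ or shrinkage > 0.5 cm are flagged as gross measurement
errors and withheld from model fitting (small shrinkage is biologically
real and kept). Plots that lost more than half their stems are dropped.

**2. Growth model.** Diameter growth with asymmetric competition:

    G = ρ₀ · g · D^ρ₁ · exp(ρ₂ D) / (1 + ρ₃ · exp(ρ₄ · B_L))

where B_L is the per-hectare basal area of strictly larger stems in the
plot and g is a log-normal genus deviation. Fitted by marginal maximum
likelihood (adaptive Gauss–Hermite quadrature over the genus effect).
Growth is then *predicted* for every census-1 stem — including stems
that died — so measurement error does not propagate into AWP.

**3. Allometry.** Height from a Weibull curve
H = 79.9·(1 − exp(−0.011·D^0.74)); stem biomass from the pan-tropical
equation AGB = 0.0673·(D²·H·WD)^0.976 with wood density WD looked up
by species → genus → family → dataset mean; carbon at 47% of dry mass.

**4. AWP.** Each stem's biomass increment over one projected year,
summed over the plot with per-hectare expansion factors (×8 for the
0.125-ha plot, ×80 for the 0.0125-ha subplot). A field-measurement-based
variant (measured increments, median gap-filling) serves as cross-check.

**5. Stand metrics.** Basal area decomposes exactly as
BA = π/4·(QMD/100)²·n_stems; tree diversity is the effective number of
species exp(−Σ pᵢ ln pᵢ) on basal-area shares; a 99th-quantile log–log
regression traces the self-thinning boundary.

**6. Soil P.** A transect-random-intercept linear model predicts soil
phosphorus where unsampled; values are classed low (<300), medium
(300–500) or high (>500 mg kg⁻¹).

**7. SEM.** A built-in maximum-likelihood structural-equation engine
(Wishart discrepancy, composite variables, RMSEA/CFI/SRMR, standardized
paths, R²) fits the drivers model: AWP ← BA + diversity + soil P, with
BA a fixed-weight composite of log QMD and log stem density, diversity
← stem density + soil P + logging, QMD ← logging + slope.

## Worked example

```bash
woodprod run-all out/ --seed 11 --scale small
cat out/report.txt
```

which prints (numbers from this exact command):

```
Drivers of aboveground wood production
========================================

N plots: 29

Standardized paths:
  BA->AWP                  +0.961 *** (p=2.93e-104)
  diversity->AWP           +0.020     (p=0.653)
  soilP->AWP               +0.039     (p=0.296)
  n_stems->diversity       +0.244     (p=0.108)
  ...
R^2: AWP=0.964, QMD=0.475, diversity=0.367
chi2=9.86 df=6 p=0.131 RMSEA=0.152 CFI=0.970 SRMR=0.037
AWP MgC/ha/yr: min=0.38 mean=1.18 max=2.45
```

Reading: one 30-plot synthetic network was generated (seed 11), screened
and fitted; basal area is by far the strongest standardized driver of
wood production (+0.96), logging depresses mean stem size
(logged→QMD < 0), and each plot produces 0.4–2.4 MgC ha⁻¹ yr⁻¹. The
`out/` directory holds every intermediate artifact (screening report,
fitted growth model, per-plot AWP table, stand summaries, SEM fit) with
a provenance manifest.

The same stages are available individually (`simulate`, `screen`,
`fit-growth`, `fit-allometry`, `awp`, `metrics`, `fit-soil`, `sem`,
`report`) and as library functions (`woodprod.fit_growth_model`,
`woodprod.plot_awp_model`, `woodprod.fit_ml`, ...).

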