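# Methods

This note documents the models, parameter choices and numerical
conventions behind `winternit`, and what the synthetic-data generators do
and do not emulate.

## Tracer rate model

The estimator assumes a single well-mixed ammonium pool whose atom % ¹⁵N
is set by two-component mixing of the ambient pool (at natural abundance)
and the enriched spike, and that every atom of ¹⁵N excess recovered in
the nitrate pool originated from oxidation of that amended pool. Carrier
nitrate and the Devarda's-alloy blank are taken to be exactly at natural
abundance; under that assumption their contribution cancels from the
excess-mass bookkeeping, which the test suite verifies as an exact
invariance (carrier dilution changes the measured atom % but not the
recovered rate). Negative rates arise when the measured atom % falls
below the natural-abundance reference and are reported as-is — they are
analytical noise around zero, and the censoring step, not clamping,
handles them.

Key parameters:

| parameter | default | units | rationale |
|---|---|---|---|
| natural abundance | 0.3663 | atom % ¹⁵N | atmospheric N₂ standard |
| spike fraction | 0.10 | of ambient NH₄⁺ | tracer-level addition; keeps pool perturbation small |
| spike enrichment | 98 | atom % | commercial ¹⁵NH₄Cl |
| incubation | 2.5 | days (60 h) | sensitivity at 4 °C winter temperatures |
| MDL confidence | 0.99 | one-sided | conventional MDL definition; the t-quantile level is not otherwise pinned down |
| global rate LOQ | 0.11 | µg N L⁻¹ d⁻¹ | highest sample-specific LOQ in the survey |
| NH₄⁺ / NO₃⁻ MDL | 86 / 57 | µg N L⁻¹ | survey analytical method limits |

The sample LOQ defaults to the *literal* conversion — atom % MDL × total
trapped N mass, normalized by volume and time — which reproduces the
printed LOQ semantics of the survey tables. A `label_normalized` mode
additionally divides by the label excess fraction, making the LOQ
dimensionally identical to the rate; it is exposed because the literal
form understates the quantifiable rate by that factor, and the choice
between them cannot be settled from the published tables alone. When
ambient NH₄⁺ is below its MDL, the MDL value stands in as the ambient
concentration for spike sizing and pool mixing.

## Gas solubility and headspace inversion

Solubility uses the standard oceanographic ln-polynomial in T (kelvin)
and salinity (g kg⁻¹). N₂O coefficients are the Weiss & Price (1980)
moist-air function, already in mol L⁻¹ atm⁻¹; CH₄ coefficients are the
Wiesenburg & Guinasso (1979) Bunsen-coefficient fit with −ln(22.4136)
folded into A₁ to convert (L gas STP) L⁻¹ atm⁻¹ into mol L⁻¹ atm⁻¹. Both
transcriptions are guarded by an independently typed copy of the
coefficient tables in the test suite and by loose anchors on freshwater
Henry solubilities at 25 °C. Outside the validated window (0–30 °C,
0–40 g kg⁻¹) evaluation extrapolates with a warning rather than failing:
winter samples equilibrated warm sit comfortably inside it.

The headspace inversion is a closed-system mole balance at the
equilibration temperature: original dissolved moles = dissolved moles at
equilibrium (Henry's law) + headspace moles at equilibrium − moles
introduced with the initial headspace gas. Equilibration is assumed
isothermal; degassing during pumping is not modeled. Ionic salinity is
the summed mass of the dominant major ions (sulfate, calcium, magnesium,
sodium, optionally K/Cl/HCO₃) per kg of solution at unit density unless a
density is supplied — adequate for the few-g-kg⁻¹ prairie waters it
corrects for. Default atmospheric mixing ratios (N₂O 0.330 ppm, CH₄
1.9 ppm) are representative mid-2010s values and are configurable.

## Oxygen stoichiometry

2 mol O₂ per mol N gives 4.57 g O₂ per g N; demand is linear in rate and
period, with a 30-day month and a 150-day ice season as period
conventions. The published monthly median oxygen demand of
110 µg O₂ L⁻¹ implies a median rate input of ≈0.80 µg N L⁻¹ d⁻¹ that is
not recoverable from any censoring variant of the packaged survey
(variants yield 15, 178 or 288 µg O₂ L⁻¹ month⁻¹); the acceptance script
therefore reports demand at that implied input, and the discrepancy is
left unresolved rather than forced.

## Survey statistics

**Censoring.** Study rates below 0.11 µg N L⁻¹ d⁻¹ are replaced by 0.11;
literature rates, which carry their own (unreported) method limits, are
kept as printed. The low-rate group after partitioning is therefore
exactly the substituted values.

**Below-detection policy.** Substitution at the MDL, exclusion, and
keep-raw are all exposed per call. The published group summaries are
internally inconsistent — the high-rate-group NH₄⁺ median (516) requires
excluding its one below-MDL value while the low-group median (86.0)
requires substituting — so the package refuses to hard-wire either
policy; the acceptance reconstruction uses exclude-in-high /
substitute-in-low, which reproduces both medians and the reported
significance. The high-group NO₃⁻ median reconstructs as 312 against a
printed 310 under every policy; it is documented here, not asserted.

**Rank-sum tests.** Exact null enumeration when there are no ties and
the smaller group has ≤ 10 observations; otherwise the normal
approximation with average ranks, tie-corrected variance and continuity
correction (the `wilcox.test` defaults). Exact printed p-values from the
original analyses are not reproduction targets; significance at 0.05 is.

**Permutation regression.** OLS of log₁₀(rate + 1) on NH₄⁺ with a
centered predictor, so the intercept equals the mean transformed
response. The +1 transform is applied to *all* fits, including those
whose published equations omit it: it is the only choice that reproduces
the literature-only fit (slope 0.0019, adjusted R² 0.70, intercept 0.68 =
mean response) and it simultaneously reproduces the no-Pasqua fit
(0.0009, adjusted R² 0.07). The pooled 22-record fit reconstructs to
slope ≈0.0015 and adjusted R² ≈0.45 against printed values of 0.0012 and
0.47; no documented censoring variant closes that gap, so the suite
bounds it (slope ∈ [0.0011, 0.0016], R² ∈ [0.45, 0.50]) instead of
asserting equality. Permutation p counts the observed arrangement in
numerator and denominator, so min p = 1/(n_perm + 1); default
n_perm = 5000 with a mandatory seed.

**Summary footers.** Winter rows only. Rates flagged below their sample
LOQ (the negative study values) are excluded from the rate column —
they are unquantifiable, not small — while Wisconsin accumulation-based
estimates are included; NH₄⁺/NO₃⁻ use MDL substitution; other variables
drop missing values. These rules reproduce every reconstructible footer
cell; the published O₂ minimum (2 mg L⁻¹, despite a 0.8 value in the
pool) is not reconstructible and is flagged here rather than forced.

**PCA.** Correlation-matrix PCA (z-score with sample SD, ddof = 1) via
SVD over complete cases, components signed so the largest-magnitude
loading is positive. The published ordination also used chlorophyll and
temperature, which are not available in the packaged tables, so its
variance figure (61 % on PC1+PC2) is not a reproduction target.

## Synthetic data

The incubation simulator is explicit-Euler bookkeeping (default step
1/240 d, i.e. 6 min; halving the step moves a 60 h estimate by < 0.1 %):
each step transfers `rate·dt` µg N L⁻¹ from the ammonium pool at its
current atom % into the nitrate pool, while remineralization returns N
at natural abundance, diluting the label — a zero-order recycling
mechanism, the simplest consistent with re-release of assimilated or
ambient N. With recycling off and no noise, the tracer inversion is
exact (the atom % of the pool is constant), which makes the simulator
the oracle for the whole rate pipeline; with recycling on, 60 h
estimates fall below 24 h estimates, reproducing the qualitative
long-incubation bias. Gaussian noise is applied to the measured atom %
only — the quantity the analytical MDL is defined on — not to masses.
Default scenario conditions (ambient NH₄⁺ 500 µg N L⁻¹, 10 % spike at
98 atom %, 60 h at 0.3 L) mirror a typical mesotrophic study-lake
incubation.

The survey simulator emits tables in the packaged schema: log-normal
NH₄⁺ (median 250 µg N L⁻¹, log-SD 1), log₁₀(rate + 1) linear in NH₄⁺
with slope 0.0019 (the literature-fit magnitude) and residual SD 0.25,
N₂O saturation = 100 + 4·rate plus noise, and below-MDL flags applied at
86/57. It emulates the *statistical structure* the analysis assumes —
monotone rate–substrate coupling, supersaturated N₂O tied to rate,
censored nutrients — not lake physics: there is no seasonality, no
spatial correlation between connected lakes, no oxygen control on rates.
Passing tests therefore demonstrate estimator and inference correctness
under the assumed structure, not field realism.

## Numerical conventions and limitations

* N masses in µg N; atom fractions as percent (0–100); gas
  concentrations in µmol L⁻¹; mixing ratios in dry ppm.
* Medians are midpoints of central pairs; all statistics exclude missing
  values rather than imputing.
* The packaged fixture is checksummed (SHA-256); any edit breaks loading.
* Problem sizes are small throughout — a 31-record survey, 5000
  permutations, 1000 noise replicates, 600-step Euler grids — chosen to
  match the survey's own scale and the precision of its printed values.
* Not modeled: air–water gas flux, whole-lake oxygen budgets, benthic
  nitrification, light/temperature response, recovery-efficiency
  chemistry of the diffusion-disk method, and the diffusion-disk vs
  denitrifier-method comparison (its published means, 534.6 vs
  532.4 µg N L⁻¹ d⁻¹ under a 1 mg N L⁻¹ amendment, are noted here only).
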