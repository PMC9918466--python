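# Methods

## Problem and data model

`bluecarbon` analyses chronosequences of mangrove restoration sites: sites of
different stand ages standing in for one site's trajectory through time
(space-for-time substitution), with unrestored paired control sites providing
the year-0 condition. Each site carries up to three carbon-pool densities in
Mg C ha⁻¹ — aboveground biomass carbon (AGC), belowground biomass carbon
(BGC), and sediment carbon to 1 m depth (SCS) — plus the restoration pathway:
*reforestation* (re-establishing mangroves where they previously grew, e.g.
abandoned aquaculture ponds) or *afforestation* (establishing them on tidal
flats or other sites never occupied by mangroves). Total ecosystem carbon
stock is the exact sum TECS = AGC + BGC + SCS; no pool is ever imputed.

## Carbon-pool accounting

* **Biomass partitioning.** When a study reports only total biomass T and a
  shoot/root ratio r, above = T·r/(r+1) and below = T/(r+1); the parts sum
  back to T exactly.
* **Carbon conversion.** Biomass → carbon with the community-standard
  fractions 0.47 (aboveground) and 0.39 (belowground); a study-specific
  carbon content overrides the default when available.
* **Sediment stock.** A layer of thickness t cm with organic-carbon content
  SOC (%) and bulk density BD (g cm⁻³) holds SOC/100 × BD × t × 100
  Mg C ha⁻¹ (1 ha = 10⁸ cm², 1 Mg = 10⁶ g). Stocks are integrated to exactly
  100 cm: deeper profiles are truncated pro-rata at 1 m; shallower profiles
  are extended by holding the deepest measured layer's volumetric density
  constant down to 1 m — a deliberate, slightly stock-inflating convention
  that makes the integral independent of how the deepest layer is subdivided
  at equal density. Profiles reaching less than 20 cm are surface-only
  measurements and are excluded outright rather than extrapolated 5-fold.
* **CO₂ equivalents.** Mass C × 44/12, exactly.

## Growth models

Three saturating stand-growth families describe density C against age
(years):

| family | C(age) | notes |
|---|---|---|
| Von Bertalanffy | Asym·(1 − e^(−b(age−c))) | no inflection |
| Gompertz | Asym·e^(−b·c^age) | inflection; positive C(0) = Asym·e^(−b) |
| Chapman–Richards | Asym·(1 − e^(−b·age))^c | forces C(0) = 0 |

Asym is the asymptotic density; b and c set the shape and position of the
approach. Admissible ranges for an increasing curve: Asym > 0, b > 0, and
c ∈ (0, 1) for Gompertz, c > 0 for Chapman–Richards.

**Baselines.** Sediment (and hence total ecosystem) carbon is non-zero
before restoration. The pre-restoration stock enters as an *additive* offset,
C(age) = baseline + f(age); additivity is chosen (over rescaling the
asymptote) because it preserves the additivity of increments across pools
when TECS increments are summed. Chapman–Richards, which pins C(0) = 0, is
not offered for baseline pools. The baseline value is the mean density over
paired control sites for the pathway when such sites exist, else a free
fitted parameter bounded below by 0. Control sites are matched to a pathway
by the `prior_land_use` column (`abandoned_pond` → reforestation control,
`mudflat` → afforestation control); the key is a convention, not an
inference, and callers can pass an explicit baseline instead.

**Error model.** Carbon-density scatter in chronosequences is multiplicative:
the spread among 40-year stands (~tens of Mg C ha⁻¹) dwarfs the spread among
2-year stands. The default fit is therefore least squares on log densities —
a lognormal error model with constant coefficient of variation — which
weights young, low-density stands according to their actual precision.
Classical constant-variance least squares on the raw scale is available as
`error_model="gaussian"`. The choice matters for model comparison: under
raw-scale constant-variance fitting the residual sum is dominated by the
noisy old stands where all three families are equally flat, and AIC loses
nearly all power to tell them apart; under the matched lognormal likelihood
the young-stand shape information is retained and the generating family is
recovered reliably (the acceptance script measures both the asymptote bias
and the selection rate). The lognormal fit carries a small known attenuation,
E[log noise] = −σ²/2 ≈ −4% of the curve scale at CV 0.3, well inside the
tolerated asymptote bias.

**Estimation.** `scipy.optimize.curve_fit` (trust-region reflective, bounded)
with multi-start initialisation: Asym₀ = 1.2 × max observed density,
b₀ ∈ {0.1, 0.5, 1, 2}, c₀ ∈ {0.3, 0.6, 0.9} (Gompertz), {−5, 0, 5} (Von
Bertalanffy), {0.5, 1, 2} (Chapman–Richards); the best residual sum wins.
Non-convergence of every start is reported on the fit object
(`converged=False`), never silently. Fewer than p+2 usable (age, density)
pairs, or degenerate (all-equal) ages, raise an error.

**Model comparison.** AIC from the Gaussian log-likelihood on the fitting
scale with the residual variance profiled out: AIC = n·ln(2π·RSS/n) + n + 2k,
k = #curve parameters + 1. AICs are comparable only between fits sharing the
error model (enforced). Ties break toward fewer parameters, then a fixed
family order.

**Uncertainty.** Percentile bootstrap over *sites* (not residuals): resample
sites with replacement, refit from the full-data estimates, take the
2.5th/97.5th percentile of the replicate curves on an age grid. The seed is a
mandatory argument. More than 50% replicate non-convergence aborts with
advice. On noise-free data the band collapses to zero width.

**Pathway contrast.** Whether trajectories differ between pathways is tested
with fixed-effects least squares: density ~ log(age) × pathway + region
indicators, reading the interaction coefficient. A mixed model with region
as a random effect would be the fuller treatment; fixed region indicators
keep the estimate and the direction of the inference while staying in
closed-form OLS, and the package documents this as its chosen simplification.
Age-0 rows are excluded from the log-age model with a notice.

## Scenario projection

Feasible (restorable) area per country/EEZ = total 1996–2016 mangrove loss
minus losses to coastal erosion and settlement (no restoration possibility).
Records with unattributed loss can have that mass redistributed by the mean
driver shares of their geographic zone; totals are conserved exactly.

Restoration rolls out in equal annual cohorts over R ∈ {1, 5, 10} years
(all countries) or country-varying R ∈ {5, 10, 20} within the fixed 40-year
horizon. The cohort planted in rollout-year k accumulates carbon for
40 − k + 1 years, so fixation times run from 40 − R + 1 to 40. Sequestration
per country:

Seq = Σ_cohorts (1/R) · Area_feasible · Σ_pools [C_pool(i) − C_pool(0)] · 44/12

reported in Tg CO₂-eq (1 Tg = 10⁶ Mg). Increments, not stocks, enter the sum
— baselines cancel; the projection credits only carbon accumulated since
restoration. For non-decreasing curves the totals are ordered
one-year ≥ five-year ≥ ten-year ≥ any varying schedule with slower
countries, and the global total is the exact sum of country totals and is
linear in area. Afforestation projections use the same feasible area, making
the pathway gap a pure per-hectare contrast.

**Confidence intervals** evaluate the same cohort sum on each pool's
2.5th/97.5th percentile bootstrap curve and add pools. This treats pools as
co-monotone rather than independent — a conservative, simple default;
negative lower-band increments (possible for the weakly-constrained
afforestation sediment pool) are retained in the CIs, and floored at zero in
point estimates only on explicit request (`floor_negative`).

## Group statistics

Ages bin into 5-year classes with the last class spanning 20–40 years, using
half-open upper-inclusive intervals (0, 5], (5, 10], …, (20, 40]; ages
beyond 40 are excluded with a notice. Densities are skewed and
heteroscedastic, so two-sample comparisons use the two-sided Wilcoxon
rank-sum test (exact for tie-free combined n ≤ 20, tie-corrected normal
approximation otherwise), and ≥3-group comparisons use Kruskal–Wallis plus
Dunn's post hoc z-tests with Bonferroni adjustment (adjusted p = min(1,
p·#pairs)). Dunn's test is implemented in-package (pooled mean ranks with the
standard tie correction) since no installed library provides it. Covariate
relations are ordinary least squares with a t-based slope CI and a pointwise
95% band for the conditional mean; a constant covariate is a degenerate
design and errors.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable offline:

* ages uniform on (0, 40] — mirroring that most restoration sites are
  younger than 40 years;
* density = curve(age) × lognormal site noise (unit mean, CV 0.3 by
  default) × lognormal region multiplier (log-SD 0.1 across five
  ocean-basin region labels with weights favouring the Indo-Pacific);
  multiplicative noise guarantees positive densities;
* default generating curves are Gompertz with 40-year values near 128/39/139
  (reforestation AGC/BGC/SCS increments) and 89/37/65 (afforestation), and
  sediment baselines of 160 and 110 Mg C ha⁻¹ — magnitudes typical of
  restored mangrove stands, so demos are visually comparable to published
  chronosequences without claiming equivalence to any dataset;
* paired control sites (8 per pathway by default) carry baseline-only
  sediment stocks at age 0;
* per-pool missingness rates are configurable; the seed is mandatory and
  fully determines the table.

The country generator splits a total loss area (904,953 ha by default)
across countries by a flat Dirichlet and draws per-country driver shares
from a Dirichlet whose concentrations put ~32% of loss in erosion +
settlement, so about two-thirds of loss is feasible to restore.

What the generator does **not** emulate: spatial autocorrelation, covariate
structure (precipitation, salinity, nutrient couplings beyond optional
linear demos), age–pathway confounding, and measurement error in age.
Passing tests therefore demonstrate correctness of the arithmetic, the
estimators and their calibration under the stated noise model — not that
real-world restoration data satisfy that model.

## Problem sizes and numerical choices

The test suite and acceptance script use: 100 seeded replicates of n = 50
sites at CV 0.3 for parameter recovery and family selection; 20 seeded
datasets of n = 40 for the scenario-ordering property; bootstrap bands of
150–300 replicates in tests and 200 by CLI default; a 20-country synthetic
loss table for projection demos. These sizes give stable medians and
percentile estimates while keeping any single check in tens of seconds.
Other numerical conventions: TECS consistency tolerance max(0.5 Mg C ha⁻¹,
1%); curve parameters bounded away from their open limits by 10⁻⁸; RSS
floored at 10⁻⁸ before the AIC log on noise-free data; presentation rounding
to 1 decimal for Mg C ha⁻¹ and Tg (full precision internally); results CSV
written at 6 decimals and round-tripping exactly at that precision.

## Known limitations

* Fixed region indicators, not random effects; no REML.
* The CI combination across pools is co-monotone percentile summation, not a
  joint resampling of all pools (a Monte-Carlo joint option would require
  refitting all pools per replicate on shared resamples).
* The sediment extension rule can only overestimate; no decay alternative is
  offered.
* Interval-coded ages ("10–25") are rejected, not midpointed.
* Projections credit accumulation since restoration only — no avoided-loss
  accounting, no economics, no pre-1996 loss areas.
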