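# Methods

This note documents the models and procedures `traitsort` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## From biovolume records to annual compositions

Monitoring data arrive as biovolume per taxon per sampling date (roughly
biweekly).  The long-term analysis needs annual quantities that are not
dominated by bloom seasons, so each taxon's record is linearly interpolated
to a continuous multi-year daily series (one series over the whole study
span — interpolation crosses year boundaries; before the first and after
the last sample the series is held constant, which avoids inventing
trends).  Relative biovolumes are computed **per day** and then averaged
over the 365 or 366 days of each calendar year.  An alternative — ratioing
annual-mean biovolumes — is available via
`annual_compositions(..., share_mode="annual_ratio")`; the two differ
whenever a taxon's share covaries with total biovolume within the year, and
the per-day default weights all days of the year equally rather than
favouring bloom periods.

Taxa with cell volume strictly below 30 μm³ are removed before trait
analysis (small cells are unreliably identified in older samples).  The
exclusion report computes the removed taxa's share of community biovolume
on the *pre-filter* composition, so the cost of the filter is measured
against what was actually observed.

## Monod traits and taxonomic imputation

The three traits are parameters of Monod growth curves: maximum growth
rate μ_max (d⁻¹), phosphate affinity γ (L μmol⁻¹ d⁻¹) and light affinity α
(μmol quanta⁻¹ m²), with half-saturation constants k_P = μ_max/γ and
k_I = μ_max/α.  Affinities — initial slopes of the growth–resource curve —
are the competitively decisive parameters at low resource levels, which is
why they, and not the half-saturations, are the analysed traits.

Trait compilations cover only part of any species pool.  A missing value is
imputed as the geometric mean of the measured values of the taxon's closest
relatives: the rank walk proceeds genus → family → order → class → phylum
and stops at the first rank with at least one measured relative.  Three
properties are enforced by construction and verified by tests:

* only originally-measured values act as donors (no chained imputation,
  hence no order dependence and idempotence);
* the three traits are imputed independently of each other;
* the procedure is scale-equivariant (geometric means commute with
  rescaling), consistent with the log-scale treatment of traits throughout.

Inputs carry one row per taxon; if a species has several published
measurements they are expected to be combined (geometrically) upstream.
The leave-one-out routine hides each measured cell in turn and reports the
log10 error distribution per trait (median, MAD, RMSE) — the package's own
measure of how much trust imputed values deserve.

## Community mean traits

Traits are log-distributed over orders of magnitude, so community mean
traits are biovolume-weighted geometric means,
CMT_y = exp(Σ_i ln τ_i · b_iy).  When an inclusion rule removes taxa (e.g.
dropping Dinophyceae, whose frequent mixotrophy makes a purely autotrophic
Monod parameterisation doubtful), the remaining weights are renormalised to
one and the retained pre-renormalisation weight is reported per year as
"coverage" — a rule whose coverage dips low in some years is reshaping the
community there, and the series should be read with that in mind.  Group
(within-class) mean traits renormalise within the class and return NaN for
years in which the class holds no biomass.

## Trend tests, PCA, permutation null

**Prais–Winsten.**  Annual series are short (~40 points) and
autocorrelated.  The regression y_t = a + b·x_t + u_t with AR(1) errors
u_t = ρu_{t−1} + ε_t is estimated iteratively: OLS residuals → lag-1 ρ̂ →
quasi-difference transform retaining the first observation scaled by
√(1−ρ̂²) → re-fit, until |Δρ̂| < 1e−8 (max 50 iterations; non-convergence
raises, carrying the ρ trace — it occurs only for near-unit-root degenerate
series).  R_pw is the signed square root of the transformed fit's
generalised R² (squared correlation of transformed response and fit), and
P_pw a two-sided t test on the transformed slope with n−2 degrees of
freedom.  `fix_rho=0` reproduces OLS exactly, which the tests assert.
CMT series enter trend tests on the log scale, consistent with their
geometric construction.

**PCA.**  Covariance PCA (centred, unscaled) of the year × class share
matrix: all variables share units, and correlation PCA would up-weight
rare classes.  Scaling is available behind a flag.  Component signs follow
a deterministic convention (largest-magnitude loading positive).

**Permutation test.**  The null "species sorting is blind to traits" is
simulated by pairing each taxon's 42-year weight series with the complete
trait triple of a uniformly drawn permutation of taxa (triples are never
split, preserving inter-trait structure), recomputing the CMT series and
the statistic.  Two p estimators are always reported: the literal
strictly-greater fraction p_strict = #{stat* > stat}/k, which can be zero,
and the add-one estimator p_addone = (#{stat* ≥ stat}+1)/(k+1), which is
the default-reported value.  Tie handling is exact because the observed
statistic and the null draws share one bit-identical einsum kernel.  The
default permutation count is 10⁴ (the CLI exposes it; 10⁶ is supported and
simply takes proportionally longer).  Each statistic's stream is seeded
independently from the master seed via a counter, so adding a statistic
never perturbs the others.

## SMA fits, axis scores, weighted percentiles

SMA is used because both variables of a trait–trait relationship carry
error; its slope sign(r)·SD_y/SD_x is equivariant under axis swap and
minimises Σ w_i (y_i − a − b·x_i)²/|b| (the tests check the estimator
against a numeric minimiser of that loss).  Fits are computed at three
integration levels: unique phenotypes unweighted ("community membership"),
phenotypes weighted by summed long-term average shares b̄_i ("average
community composition"; phenotypes are exact-equality groups of trait
triples after imputation), and the across-year CMT series.  Weighted
significance tests use the Kish effective sample size (Σw)²/Σw², a
documented and swappable choice.

Slope confidence intervals: unweighted fits use the analytic interval
b·(√(B+1) ± √B) with B = t²(1−r²)/(n−2); weighted fits use a seeded
percentile bootstrap resampling points with probability proportional to
weight (default 2000 resamples).  Measured coverage of that bootstrap at
nominal 95% is ≈ 91% on Gaussian test data — percentile bootstraps are
known to run mildly liberal for SMA slopes — and the test suite asserts
coverage within an honestly widened band rather than pretending exactness.

Axis scores project points onto the fitted axis in SD-standardised
coordinates (the SMA geometry; raw-space projection is available behind a
flag); weighted percentile p is the smallest score whose cumulative
normalised weight reaches p, so p = 0/1 return the extreme scores carrying
positive weight.  Five-year windows at the nutrient extremes (defaults
1980–1984 and 2002–2006) are compared by the weighted percentiles of their
phenotype scores along the γ–α axis.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes and
provides exact ground truth for every stage:

* **Trait pool.**  ln(γ, α, μ_max) are drawn from a trivariate Gaussian
  truncated at ±2.5 SD per coordinate, with r(lnγ, lnα) = −0.24 (the weak
  physiological trade-off; pool-level R² ≈ 0.06), r(lnα, lnμ_max) = +0.33.
  Scales: γ ≈ 3 L μmol⁻¹ d⁻¹ (SD 0.9 on the log), α ≈ 2·10⁻⁶
  μmol quanta⁻¹ m² in daily-light units (SD 0.9), μ_max ≈ 0.8 d⁻¹ (SD
  0.12).  The truncation exists because an unbounded Gaussian pool
  occasionally contains a several-sigma "good at everything" taxon that
  wins every year — a physiology real pools do not offer; the narrow μ_max
  spread keeps growth-rate luck from swamping affinity-driven sorting under
  the softmax (see limitations).  The taxonomy (balanced genus → phylum
  hierarchy) is carved from the pool ordered along the γ–α trade-off axis,
  giving relatives similar physiology — the phylogenetic signal that makes
  taxonomy-based imputation and class-level composition meaningful.

* **Environment.**  TP at winter mixis follows a piecewise log-linear
  rise-and-fall through (0.9, 2.8, 0.28) μmol L⁻¹ with the peak in 1979: a
  roughly threefold rise and a decline to a tenth of the peak over the
  42-year default period.

* **Species sorting.**  Each year, summer phosphate is a drawdown fraction
  (0.15) of TP, biovolume rises linearly with TP (10⁶ μm³ L⁻¹ per
  μmol L⁻¹), and effective light is I₀/(1 + shading·B) with I₀ = 4·10⁶
  μmol quanta m⁻² d⁻¹ and shading 2.5·10⁻⁶ per μm³ L⁻¹ — numbers chosen so
  phosphate limits growth in nutrient-poor years and self-shaded light in
  nutrient-rich years.  Interannual lognormal noise (σ = 0.25) on realised
  P and I plays the role of weather, moving the yearly fitness optimum
  along the pool's trade-off frontier; the realised values are recorded so
  ground truth stays exactly checkable.  Per-taxon fitness is the Liebig
  minimum of the two Monod rates (a normalised product is available as
  `colimitation="multiplicative"`), and annual weights follow the softmax
  w_iy ∝ exp(λ·μ_iy) with λ = 20 by default; λ = 0 gives a neutral
  community.  The softmax replaces explicit resource-competition dynamics:
  it is the simplest mechanism that concentrates biomass along the realised
  trade-off and its ground truth is analytically checkable.

* **Sampling.**  Biweekly dates, a smooth seasonal modulation of total
  biovolume shared by all taxa (it cancels from daily shares),
  multiplicative lognormal observation noise (σ = 0.3), and 7.5% of taxa
  flagged small-celled (< 30 μm³) carrying 1.8% of community biovolume so
  the cell-volume filter is exercised.

**What passing tests show — and what they do not.**  The generator's
communities are noisy softmax mixtures, not populations with dynamics: no
seasonal succession within years, no grazing, no mixotrophy, no dispersal
limitation, and the softmax's winner-take-all tail means a minority of
random pools still concentrate biomass on one taxon for long stretches
(flattening the community-mean series).  End-to-end recovery on this
generator therefore demonstrates that the *pipeline* measures what it
claims to measure under the assumed structure — it does not by itself
validate the ecological claims on real monitoring data.  Likewise the
permutation-null calibration runs on weights that are exchangeable with
respect to traits by construction (lognormal noise around a uniform
community, the distribution a neutral community with observation noise
induces), which is exactly the null the test is supposed to hold under.

## Problem sizes and numerical choices

Default experiment sizes were chosen desk-scale: generation of a 150-taxon,
42-year dataset takes ~0.2 s and the full pipeline ~1.5 s, so the
calibration experiments (500 permutation tests at k = 999; 200 AR(1)
recoveries at n = 2000) and the acceptance script all complete in seconds
to a few tens of seconds on one CPU.  Normalisation invariants
(Σ_i b_iy = 1, Σ_j g_jy = 1) are asserted to 1e−9 in validation and hold to
1e−12 in the tests; weighted geometric-mean identities (e.g.
CMT(μ_max)/CMT(γ) equals the weighted geometric mean of k_P) are asserted
to 1e−10.  CSVs are written with `%.17g` and read with round-trip float
parsing, so write-then-read is the identity and repeated runs are
byte-identical.  Dates are ISO-8601; missing values are empty fields with
explicit provenance flags in trait tables.
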