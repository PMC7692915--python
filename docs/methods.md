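# Methods

## Scope and data model

The package implements the analysis chain for cotton-strip assays (CSA)
deployed in paired stream surveys around wastewater outfalls: per-strip
assay arithmetic, temperature-standardized mixed models, carbon-evasion
upscaling, and OTU-table diversity analyses. Because raw survey data are
rarely shareable, a first-class synthetic-data module generates datasets
with the statistical structure the analysis assumes; all guarantees quoted
below are verified by the test suite on such data.

Core tables: a per-strip measurement table (DO triplet, chamber volume,
strip dry mass, assay duration, final tensile strength and mass,
incubation days), a daily temperature series per site × location, a
chemistry summary per site × location, and taxa × samples OTU count tables
with sample metadata.

## Assay computations

Respiration is the blank-corrected chamber DO drawdown scaled by chamber
volume and normalized by strip dry mass and time. The stream-start DO
cancels algebraically; it is kept in the computation so each budget term
is auditable. Oxygen converts to carbon by `R/32·RQ·12`; the respiratory
quotient defaults to **RQ = 1.2** (mol CO2 per mol O2), a documented
calibration constant for heterotrophic stream communities, never
hard-coded inside formulas.

Decay coefficients use natural logarithms against the arithmetic mean of
ten non-incubated reference strips. Two time bases are provided: calendar
days (k_D) and temperature-days (k_TD). Temperature-days are the **per-day
sum** of `1/(k_B·T_Kelvin)` (eV⁻¹), mirroring classical degree-days so
longer incubations accumulate more temperature-time; the per-day mean is
not used (the sum is what makes k_TD commensurate across incubation
lengths). Classical degree-days (°C-days) are also available for
cross-checks.

Negative rates — blank drift exceeding the chamber drawdown, or strips
measuring above the reference mean — are **retained and flagged**, never
silently dropped. Flagged records are excluded from ln-scale model fits
(counted in reports) but kept in raw summaries; silently discarding them
would bias low-activity sites.

## Arrhenius mixed models

The linearized Arrhenius model centers inverse temperature at
T̄x = 6.748 °C (279.9 K) so the intercept is the rate at T̄x and the slope
is −E_a. Fits are REML linear mixed models (statsmodels MixedLM) with a
random site intercept; sampling location enters as a fixed factor (U2 is
the reference level, first upstream) and, optionally, interacts with the
temperature covariate to give per-location activation energies
E_a(loc) = −(slope + interaction). Wald 95% CIs use the coefficient
covariance, including the slope–interaction covariance for E_a contrasts.

Degenerate inputs are handled explicitly: a perfect (noiseless) fit puts
the variance components on the boundary, so it is detected (residual sum
of squares below 1e−24 of the response scale) and solved exactly by least
squares; fewer than two sites triggers a fixed-effects OLS fallback with a
warning. Marginal/conditional R² follow the variance-decomposition
convention for mixed models: var(fixed)/total and
(var(fixed)+var(site))/total with total = var(fixed)+var(site)+var(resid).

Location-contrast models reuse the same machinery; all pairwise location
contrasts are Holm-adjusted Wald tests. For count responses (OTU
richness) no pre-installed Python GLMM offers a Poisson family with a
random intercept and clean Wald inference, so the count family is a
Poisson log-link GEE with exchangeable within-site correlation;
exponentiated coefficients are reported as incident rate ratios (IRR), and
the "site % variance" for counts is a between/within ICC on log counts.
Effect sizes are Hedges-corrected standardized mean differences
(J = 1 − 3/(4·df − 1)), computed from site-level means by default (a
per-strip pooled option exists; with within-site correlation its SD is not
a clean unit, which is the documented caveat).

An `mte_consistency` check reports whether an E_a interval intersects the
metabolic-theory prediction band (default 0.6–0.7 eV); intervals are
closed, so touching endpoints count.

## Carbon efflux and upscaling

Strip respiration (mg C hr⁻¹ g⁻¹ DM) converts to areal flux by
`rate × areal_dm_density × 8760 / 10⁶` (kg C m⁻² yr⁻¹). The areal
dry-mass density (default 1000 g DM m⁻²) is an explicit surrogate for a
hydrogeomorphic scaling chain whose constants live in the config; the
headline *relative* downstream change is provably invariant to it (tested),
so this choice affects absolute fluxes only. Site summaries are medians
over per-site medians of strips (a pooled-strip option exists).
Uncertainty is a seeded nonparametric bootstrap resampling **sites** (not
strips), percentile method, 10,000 reps by default. Upscaling approach A
multiplies a national baseline lotic flux by the wastewater-affected
fraction and the median relative change; approach B multiplies the median
absolute areal change by the affected surface area. Configured
self-consistently the two agree up to the median-of-ratios vs
ratio-of-medians discrepancy, which is reported, not hidden. Default
baseline constants (385 Gg C yr⁻¹, 10⁷ m² affected area, fraction 0.2)
are placeholders to be replaced with jurisdiction-specific values.

## Diversity analyses

Counts normalize to relative abundances (columns sum to 1) or
presence/absence. Rarefaction is the exact hypergeometric expectation,
computed in the log-gamma domain; extrapolation beyond the observed depth
uses the Chao1 estimate of undetected richness,
`f̂0 = ((n−1)/n)·f1²/(2·f2)` with the `f1(f1−1)/2` fallback at f2 = 0; the
default target depth is 25,000 reads. A Good–Turing singleton correction
is available for error-inflated amplicon data: equating the ratios
`2f2/f1` and `3f3/f2` gives `f̂1 = 2f2²/(3f3)`, and observed singletons
above that estimate are dropped (falling back to raw counts with a warning
when f3 = 0). "Diversity" is reported as the Hill number of order 1
(exp Shannon) — the effective number of equally abundant taxa — alongside
raw Shannon H; Fisher's alpha solves `S = α·ln(1 + n/α)` by bracketed
root-finding (tolerance 1e−10).

β-diversity uses the Baselga partition: pairwise Sørensen dissimilarity
splits exactly into a Simpson turnover component and a nestedness
remainder; the multi-site family uses the pooled min/max unique-taxon sums
over all pairs. Additivity `β_sor = β_sim + β_nes` is exact and tested to
1e−12.

Ordination is nonmetric MDS (scikit-learn, precomputed Bray–Curtis,
multiple seeded random starts, normalized stress); binary-data analyses
use Bray–Curtis on presence/absence, which equals Sørensen dissimilarity.
PERMANOVA is implemented directly: one-way pseudo-F from total vs
within-group sums of squared distances, with null permutations that
shuffle group labels **only within strata** (sites), respecting the paired
design; p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so ties and the
resolution floor are handled by construction. The statistic matches the
scikit-bio PERMANOVA statistic (cross-checked in tests); scikit-bio's
seedable `permdisp` provides the dispersion test (distances to group
spatial medians in PCoA space), with size-1 groups excluded under a
warning. Note that when every stratum contains the two groups in equal
numbers, the global label swap is a within-strata permutation that
reproduces the observed partition, so the attainable minimum p is slightly
above 1/(n_perm+1); unequal group sizes per stratum restore the floor.

## Synthetic generators

The survey generator emulates the study conditions: 12 sites × three
locations (U2, U1 upstream, D downstream) × 8 strips, 14-day autumn
incubation, site mean temperatures N(8.3, 1.7²) °C with day-to-day SD
0.8 °C, and **+0.44 °C** at D. Strip truth is built on the ln scale:
intercept + location offset − E_a(loc)·x(T) + site intercept + residual,
with x(T) the centered Boltzmann inverse temperature of the strip's
realized incubation-mean temperature. Defaults calibrate respiration to
the fitted coefficients of the survey this package models (intercept
−0.28, E_a 0.79 eV at the reference location, small positive downstream
offset) and tensile-strength decay to its steeper, downstream-flattened
dependence (intercept −3.70; E_a 1.73 eV upstream vs 1.14 eV downstream —
the non-significant U1 slope term is treated as zero); residual SD 0.3 and
site SD 0.35 ln-units reproduce site variance shares near 60%.

Observables are back-computed by inverting the assay equations (chamber
DO from the oxygen equivalent of the true rate; final tensile strength and
mass from the decay coefficients), then perturbed with Gaussian
measurement noise, truncated at zero for DO. The survey reports no
per-strip measurement error magnitudes, so the defaults (DO SD 0.05 mg/L;
reference-strip SDs 4 N and 0.01 g) are implementer-chosen and flagged as
such; setting them to zero makes the generate→assay round trip exact,
which is the tested invariant. Chamber geometry (2 L, 0.5 h assay, 0.5 g
strips) keeps the DO drawdown within the chamber's oxygen budget at the
upper tail of realistic rates. Chemistry uses log-normal draws around the
reported upstream/downstream medians (DIN 3.1→5.0 mg/L, SRP
15.4→49.1 µg/L); toxic-unit medians are invented plumbing with the right
ordering, not calibrated quantities.

OTU tables: each site's upstream community draws S_up taxa (mean 559
ITS-like / 616 16S-like) from a pool with log-series abundance weights
(log-normal optional); the downstream community removes L + R taxa and
adds R novel ones, where L = S_up − S_down comes from the richness ratio
(1.22 ITS-like, 1.12 16S-like) and R = f/(1−f)·L from the turnover
fraction f (at f = 1 and no net loss, R defaults to a quarter of the
upstream set, giving pure replacement with zero nestedness). The default
f = 0.63 was derived by inverting the pairwise Simpson component
(β_sim = additions/S_down) from the turnover/nestedness values this design
emulates; generated communities reproduce those components closely
(≈0.21/0.05 for 16S-like, ≈0.37/0.06 for ITS-like). Counts are multinomial
at 25,000 reads per sample. What the generator does **not** emulate:
sequencing error, chimeras, compositional covariance among taxa,
overdispersion beyond multinomial sampling, and within-site replicate
samples — so passing tests demonstrate correctness of the analysis
arithmetic and calibration of its tests, not robustness to those
real-data features.

Flume generators follow the block design (4 blocks, 4 strips per channel):
treatment mean + block random effect + ln-scale noise. The dilution
defaults are nonmonotone (85% WW below 15% and 50%), the dosing defaults
carry a negative micropollutant effect masked by nutrients, and the
transplant design crosses inoculation source with transfer destination
under a persistence parameter (1 = the inoculation effect is fully
carried). A master seed splits into named substreams (temperatures, rates,
measurement noise, chemistry) so stages regenerate independently and
byte-identically.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical outputs, verified by
  checksum tests on the full pipeline.
- Permutation p-values use the (1 + count)/(1 + n_perm) estimator, so
  p ∈ (0, 1] with resolution 1/(n_perm + 1).
- Problem sizes in the test suite and acceptance script are the study's
  design sizes (12×3×8 surveys; 1,000-replicate calibrations at 199
  permutations; 25-site bootstrap coverage trials at 1,000 reps), chosen
  as the package's own verification conditions.
- Fisher's alpha is undefined for S ≥ n and reported as missing; Pielou's
  J′ is missing for single-taxon samples.
- CSV schemas are strict: mandatory headers, validated location labels,
  malformed cells reported with line numbers; reports embed a
  configuration hash that excludes paths, so identical analyses in
  different directories hash identically.

## Known limitations

- The activation energy of a single 12-site autumn survey is weakly
  identified: the temperature range is narrow and the site random
  intercept absorbs most between-site contrast, so single-survey E_a
  estimates carry wide CIs (the acceptance script therefore averages
  replicate surveys for its headline E_a).
- The Poisson GEE used for count responses is a marginal model, not a
  GLMM; its IRRs are population-averaged.
- The areal-flux chain is a documented surrogate; absolute flux magnitudes
  (and hence approach-B totals) depend linearly on the configured areal
  dry-mass density, and no claim is made that they reproduce any
  particular published table.
- Multi-site β-partitioning is O(n²) in samples; fine at survey scale.
- NMDS stress minima are stochastic; results are reproducible only under
  the documented seed and number of starts.
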