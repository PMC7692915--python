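# streamcsa

Analysis pipeline for **cotton-strip assays (CSA)** in paired
upstream/downstream stream surveys around wastewater treatment plant
(WWTP) discharges: microbial respiration and decomposition rates,
Arrhenius activation energies, carbon-evasion upscaling, and OTU-table
diversity analyses — together with synthetic-data generators that emulate
the field, flume, and laboratory designs, so every stage is testable
without any field data.

It is aimed at stream ecologists and ecotoxicologists who use the CSA as a
standardized functional indicator and want a reproducible, scriptable
version of the full analysis chain.

## The model

Per strip, microbial respiration is the blank-corrected dissolved-oxygen
drawdown in a closed chamber,

```
R_CS = ((DO_S0 − DO_CSt) − (DO_S0 − DO_Ct)) · V_H2O / (m_CS · t)
```

(mg O2 hr⁻¹ g⁻¹ dry mass), converted to carbon with a respiratory quotient
RQ as `R_C = R_CS / 32 · RQ · 12`. Decomposition is the exponential decay
coefficient of tensile strength (or mass) against the mean of
non-incubated reference strips,

```
k_D = −ln(TS_t / TS_0) / t
```

with `t` in days or in temperature-days (the per-day sum of `1/(k_B·T)`,
k_B = 8.6×10⁻⁵ eV/K). Temperature dependence follows the linearized
Arrhenius form of the metabolic theory of ecology (MTE),

```
ln EF(T) = −E_a · (1/(k_B·T) − 1/(k_B·T̄x)) + ln EF(T̄x),    T̄x = 6.748 °C = 279.9 K
```

fitted as a linear mixed model with a random site intercept and
per-location slopes, so each sampling location (U2, U1 upstream; D
downstream) carries its own activation energy E_a (eV). MTE predicts
E_a ≈ 0.6–0.7 eV for respiration.

Respiration scales to areal CO2 evasion (kg C m⁻² yr⁻¹) through a
config-driven areal dry-mass density, and national totals come from two
upscaling routes: baseline flux × affected fraction × median relative
downstream change, or median absolute areal change × affected surface
area. Community structure is analyzed from OTU count tables: α diversity
(rarefied/extrapolated richness, Hill-1, Pielou J′, Berger–Parker,
Fisher's alpha), Baselga partitioning of Sørensen dissimilarity into
turnover and nestedness, Bray–Curtis NMDS, PERMANOVA with permutations
restricted within sites, and a multivariate dispersion test.

## Worked example

```python
import numpy as np
from streamcsa import (SurveyDesign, generate_survey, process_strips,
                       reference_baseline, fit_arrhenius, activation_energy,
                       standardize_temperature, EvasionConfig, evasion_summary)

survey = generate_survey(SurveyDesign(seed=11))   # 12 sites x (U2, U1, D) x 8 strips

strips = process_strips(
    survey.measurements, survey.temperature_series(),
    reference_baseline(survey.reference_ts), reference_baseline(survey.reference_mass),
)
temps = survey.temperatures.groupby(["site", "location"])["temp_c"].mean()
strips["std_temp"] = [
    standardize_temperature(temps.loc[(r.site, r.location)]) for r in strips.itertuples()
]
ok = (strips["k_d_ts"] > 0) & (strips["flags"] == "")
fit_data = strips.loc[ok, ["site", "location", "std_temp"]].copy()
fit_data["ln_ef"] = np.log(strips.loc[ok, "k_d_ts"])
fit = fit_arrhenius(fit_data)
for loc in fit.locations:
    ea = activation_energy(fit, loc)
    print(f"Ea({loc}) = {ea.ea:.2f} eV (95% CI {ea.ci[0]:.2f} to {ea.ci[1]:.2f})")

summary = evasion_summary(strips[strips["flags"] == ""], EvasionConfig(seed=11))
print(f"median downstream efflux change: {100 * summary['median_rel_change']:.1f}%")
```

prints

```
Ea(U2) = 1.69 eV (95% CI 0.98 to 2.40)
Ea(D) = 1.32 eV (95% CI 0.60 to 2.04)
Ea(U1) = 1.61 eV (95% CI 0.94 to 2.29)
median downstream efflux change: 21.2%
```

Decomposition here is strongly temperature dependent (E_a well above the
MTE range) and the downstream location shows a flatter slope — the
generator's default decay process injects exactly this contrast — while
carbon efflux rises below the outfall. The wide CIs reflect the narrow
autumn temperature range typical of such surveys.

The same stages are exposed as a CLI
(`streamcsa simulate|assay|arrhenius|efflux|diversity|flume|report`), each
a thin wrapper over the functions above; `streamcsa report --seed 42 --out
run/` executes the whole chain and writes a config-hashed JSON report.

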