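"""Synthetic field-survey, flume, and transplant data generators.

These generators emulate the statistical structure of a paired
upstream/downstream wastewater survey: 12 sites, each with two upstream
sampling locations (U2, U1) and one downstream location (D) below a
treatment-plant outfall, eight cotton strips per location, a 14-day autumn
incubation with stream temperatures around 4-11 °C, mild downstream warming
(+0.44 °C by default), nutrient enrichment, and toxic-unit increases.

Strip-level truth is built on the natural-log scale:

    ln(rate) = ln EF(Tref) + location offset - Ea(location) * x(T)
               + site intercept + residual

where x(T) is the centered Boltzmann inverse temperature of the strip's
realized incubation-mean temperature. Observable measurements (dissolved
oxygen budgets, tensile strengths, masses) are then back-computed by
inverting the assay equations, plus optional Gaussian measurement noise
(truncated at zero for oxygen). With measurement noise at zero, running the
assay module on the generated observations recovers the true rates exactly.

OTU tables are generated per site for locations U1 and D with a configurable
downstream richness deficit split between species replacement (turnover) and
pure loss (nestedness). Flume generators reproduce the block/treatment
designs of the dilution, dosing, and reciprocal-transplant experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assay import (
    EffluxConfig,
    MOLAR_MASS_C,
    MOLAR_MASS_O2,
    TemperatureSeries,
    ValidationError,
)
from .metabolic import DEFAULT_STANDARD, TemperatureStandard, standardize_temperature

LOCATIONS = ("U2", "U1", "D")


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"invalid design field {fieldname!r}: {msg}")


@dataclass(frozen=True)
class SurveyDesign:
    """Generating parameters of a synthetic paired survey.

    Defaults emulate the 2013 field campaign: 12 sites x 3 locations x 8
    strips, a 14-day incubation, site mean temperatures ~ N(8.3, 1.7) °C
    with +0.44 °C downstream, and a respiration process calibrated to the
    fitted Arrhenius coefficients (intercept -0.28 ln mg C hr^-1 g^-1 at the
    reference temperature; Ea 0.79 eV upstream, slightly lower downstream).
    Tensile-strength decay runs in parallel with its own, steeper
    temperature dependence (Ea 1.73 eV upstream vs 1.14 eV downstream).
    """

    n_sites: int = 12
    locations: tuple[str, ...] = LOCATIONS
    strips_per_location: int = 8
    incubation_days: int = 14
    temp_baseline_mean: float = 8.3  # °C, between-site mean
    temp_baseline_sd: float = 1.7  # °C, between-site SD
    temp_daily_sd: float = 0.8  # °C, day-to-day wobble within a series
    delta_temp_downstream: float = 0.44  # °C added at D
    true_Ea_by_location: dict[str, float] = field(
        default_factory=lambda: {"U2": 0.79, "U1": 0.65, "D": 0.64}
    )
    true_lnEF_at_Tref: float = -0.28  # ln mg C hr^-1 g^-1 DM at Tref
    location_offsets: dict[str, float] = field(
        default_factory=lambda: {"U2": 0.0, "U1": 0.01, "D": 0.14}
    )
    residual_sd: float = 0.3  # ln-scale strip residual
    site_sd: float = 0.35  # ln-scale site random-intercept SD
    # tensile-strength decay process (per day at Tref)
    decay_lnk_at_Tref: float = -3.70
    decay_Ea_by_location: dict[str, float] = field(
        default_factory=lambda: {"U2": 1.73, "U1": 1.73, "D": 1.14}
    )
    decay_offsets: dict[str, float] = field(
        default_factory=lambda: {"U2": 0.0, "U1": 0.14, "D": 0.37}
    )
    mass_lnk_at_Tref: float = -4.96  # ln day^-1; mass loss runs slower than TS loss
    # chemistry medians (upstream, downstream)
    nutrient_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"DIN": (3.1, 5.0), "SRP": (15.4, 49.1)}
    )
    tu_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TU_fungicide": (0.005, 0.012),
            "TU_nonfungicide": (0.010, 0.030),
        }
    )
    # assay geometry and measurement noise (implementer-chosen; the survey
    # reports no per-strip measurement error magnitudes)
    chamber_volume_l: float = 2.0
    strip_mass_g: float = 0.5
    assay_duration_hr: float = 0.5
    do_stream_start: float = 10.0
    blank_drift: float = 0.2  # mg/L DO drop in blank chambers
    do_noise_sd: float = 0.05  # mg/L, truncated at 0
    ts_initial_mean: float = 100.0  # N
    ts_reference_sd: float = 4.0  # spread of non-incubated reference strips
    mass_initial_g: float = 0.5
    mass_reference_sd: float = 0.01
    respiratory_quotient: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_sites >= 2, "n_sites", "need >= 2")
        _check(self.strips_per_location >= 1, "strips_per_location", "need >= 1")
        _check(len(self.locations) == 3, "locations", "exactly three locations")
        _check(self.incubation_days >= 1, "incubation_days", "need >= 1 day")
        for name in (
            "temp_baseline_sd", "temp_daily_sd", "residual_sd", "site_sd",
            "do_noise_sd", "ts_reference_sd", "mass_reference_sd",
        ):
            _check(getattr(self, name) >= 0, name, "SD must be >= 0")
        for name in ("true_Ea_by_location", "location_offsets",
                     "decay_Ea_by_location", "decay_offsets"):
            missing = set(self.locations) - set(getattr(self, name))
            _check(not missing, name, f"missing locations {sorted(missing)}")
        _check(self.seed >= 0, "seed", "must be a non-negative integer")

    def null(self) -> "SurveyDesign":
        """Copy with every injected effect and noise source zeroed."""
        flat_ea = {l: 0.0 for l in self.locations}
        return replace(
            self,
            delta_temp_downstream=0.0,
            true_Ea_by_location=flat_ea,
            location_offsets={l: 0.0 for l in self.locations},
            decay_Ea_by_location=flat_ea,
            decay_offsets={l: 0.0 for l in self.locations},
            residual_sd=0.0,
            site_sd=0.0,
            do_noise_sd=0.0,
            ts_reference_sd=0.0,
            mass_reference_sd=0.0,
        )


@dataclass
class SurveyDataset:
    measurements: pd.DataFrame
    temperatures: pd.DataFrame
    chemistry: pd.DataFrame
    reference_ts: np.ndarray
    reference_mass: np.ndarray
    truth: pd.DataFrame
    design: SurveyDesign

    def temperature_series(self) -> dict[tuple[str, str], TemperatureSeries]:
        out: dict[tuple[str, str], TemperatureSeries] = {}
        for (site, loc), grp in self.temperatures.groupby(["site", "location"]):
            out[(site, loc)] = TemperatureSeries(
                site=site, location=loc,
                temperatures_c=tuple(grp.sort_values("day")["temp_c"]),
            )
        return out


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_survey(
    design: SurveyDesign, std: TemperatureStandard = DEFAULT_STANDARD
) -> SurveyDataset:
    """Generate one synthetic paired survey (see module docstring)."""
    rng_temp, rng_rate, rng_meas, rng_chem = _substreams(design.seed, 4)

    sites = [f"S{i + 1:02d}" for i in range(design.n_sites)]
    site_means = rng_temp.normal(design.temp_baseline_mean, design.temp_baseline_sd,
                                 size=design.n_sites)
    site_b = rng_rate.normal(0.0, design.site_sd, size=design.n_sites)

    temp_rows, meas_rows, truth_rows = [], [], []
    rq = design.respiratory_quotient
    for i, site in enumerate(sites):
        for loc in design.locations:
            loc_mean = site_means[i] + (
                design.delta_temp_downstream if loc == "D" else 0.0
            )
            daily = loc_mean + rng_temp.normal(0.0, design.temp_daily_sd,
                                               size=design.incubation_days)
            for day, t in enumerate(daily, start=1):
                temp_rows.append({"site": site, "location": loc, "day": day,
                                  "temp_c": float(t)})
            x = standardize_temperature(float(daily.mean()), std)

            for s in range(design.strips_per_location):
                eps = rng_rate.normal(0.0, design.residual_sd)
                ln_resp = (
                    design.true_lnEF_at_Tref
                    + design.location_offsets[loc]
                    - design.true_Ea_by_location[loc] * x
                    + site_b[i]
                    + eps
                )
                eps_k = rng_rate.normal(0.0, design.residual_sd)
                ln_k = (
                    design.decay_lnk_at_Tref
                    + design.decay_offsets[loc]
                    - design.decay_Ea_by_location[loc] * x
                    + site_b[i]
                    + eps_k
                )
                ln_k_mass = ln_k + (design.mass_lnk_at_Tref - design.decay_lnk_at_Tref)

                resp_c = math.exp(ln_resp)  # mg C hr^-1 g^-1
                resp_o2 = resp_c * MOLAR_MASS_O2 / (MOLAR_MASS_C * rq)
                # invert the respiration equation for the chamber-end DO
                do_ct = design.do_stream_start - design.blank_drift
                drop = (resp_o2 * design.strip_mass_g * design.assay_duration_hr
                        / design.chamber_volume_l)
                do_cst = do_ct - drop
                if do_cst < 0:
                    raise ValidationError(
                        "generated chamber DO would be negative; reduce rates or "
                        "increase chamber_volume_l"
                    )
                noise = rng_meas.normal(0.0, design.do_noise_sd, size=3) \
                    if design.do_noise_sd > 0 else np.zeros(3)
                do_obs = np.maximum(
                    [design.do_stream_start + noise[0], do_cst + noise[1],
                     do_ct + noise[2]],
                    0.0,
                )
                # invert the decay equation for final tensile strength / mass
                k_d = math.exp(ln_k)
                ts_final = design.ts_initial_mean * math.exp(-k_d * design.incubation_days)
                k_mass = math.exp(ln_k_mass)
                mass_final = design.mass_initial_g * math.exp(
                    -k_mass * design.incubation_days
                )
                meas_rows.append({
                    "site": site, "location": loc, "strip_id": f"{site}-{loc}-{s + 1}",
                    "do_stream_start": float(do_obs[0]),
                    "do_chamber_end": float(do_obs[1]),
                    "do_blank_end": float(do_obs[2]),
                    "chamber_volume_L": design.chamber_volume_l,
                    "strip_mass_g": design.strip_mass_g,
                    "assay_duration_hr": design.assay_duration_hr,
                    "ts_final_N": float(ts_final),
                    "mass_final_g": float(mass_final),
                    "incubation_days": design.incubation_days,
                })
                truth_rows.append({
                    "site": site, "location": loc, "strip_id": f"{site}-{loc}-{s + 1}",
                    "mean_temp_c": float(daily.mean()), "std_temp": float(x),
                    "ln_resp_c": ln_resp, "ln_k_d": ln_k, "ln_k_mass": ln_k_mass,
                    "site_intercept": float(site_b[i]),
                })

    chem_rows = []
    for site in sites:
        for loc in design.locations:
            downstream = loc == "D"
            row = {"site": site, "location": loc}
            for name, (up, down) in {**design.nutrient_effects, **design.tu_effects}.items():
                med = down if downstream else up
                row[name] = float(med * math.exp(rng_chem.normal(0.0, 0.3)))
            row["pct_ww"] = float(rng_chem.uniform(15, 55)) if downstream else 0.0
            chem_rows.append(row)

    ref_ts = design.ts_initial_mean + (
        rng_meas.normal(0.0, design.ts_reference_sd, size=10)
        if design.ts_reference_sd > 0 else np.zeros(10)
    )
    ref_mass = design.mass_initial_g + (
        rng_meas.normal(0.0, design.mass_reference_sd, size=10)
        if design.mass_reference_sd > 0 else np.zeros(10)
    )
    return SurveyDataset(
        measurements=pd.DataFrame(meas_rows),
        temperatures=pd.DataFrame(temp_rows),
        chemistry=pd.DataFrame(chem_rows),
        reference_ts=ref_ts,
        reference_mass=ref_mass,
        truth=pd.DataFrame(truth_rows),
        design=design,
    )


@dataclass(frozen=True)
class OTUDesign:
    """Generating parameters for one marker's OTU tables.

    ``downstream_richness_ratio`` is upstream:downstream expected richness
    (an incident-rate-ratio sense: 1.22 means ~22% more taxa upstream).
    ``turnover_fraction`` splits the downstream deviation between species
    replacement and pure loss. Abundance weights follow a log-series
    (compatible with Fisher's alpha); a log-normal option is provided.
    """

    n_taxa_pool: int = 2000
    reads_per_sample: int = 25_000
    upstream_richness_mean: int = 559
    upstream_richness_sd: float = 50.0
    downstream_richness_ratio: float = 1.22
    turnover_fraction: float = 0.63
    replacement_rate_when_no_loss: float = 0.25
    abundance_distribution: str = "log_series"  # or "log_normal"
    log_series_p: float = 0.95
    log_normal_sigma: float = 1.0
    marker: str = "ITS-like"
    seed: int = 1

    def __post_init__(self) -> None:
        _check(self.downstream_richness_ratio > 0, "downstream_richness_ratio", "> 0")
        _check(0.0 <= self.turnover_fraction <= 1.0, "turnover_fraction", "in [0, 1]")
        _check(self.upstream_richness_mean <= self.n_taxa_pool,
               "upstream_richness_mean", "cannot exceed n_taxa_pool")
        _check(self.abundance_distribution in ("log_series", "log_normal"),
               "abundance_distribution", "log_series or log_normal")


BACTERIA_OTU_DEFAULTS = OTUDesign(
    upstream_richness_mean=616,
    downstream_richness_ratio=1.12,
    turnover_fraction=0.63,
    marker="16S-like",
    seed=2,
)


def _abundance_weights(design: OTUDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    if design.abundance_distribution == "log_series":
        from scipy.stats import logser

        return logser.rvs(design.log_series_p, size=n, random_state=rng).astype(float)
    return np.exp(rng.normal(0.0, design.log_normal_sigma, size=n))


def _one_marker_tables(
    design: OTUDesign, sites: list[str], locations: tuple[str, str] = ("U1", "D")
):
    from .diversity import OTUTable

    rng = np.random.default_rng(design.seed)
    pool = np.arange(design.n_taxa_pool)
    weights = _abundance_weights(design, design.n_taxa_pool, rng)

    samples: dict[str, np.ndarray] = {}
    meta_rows = []
    for site in sites:
        s_up = int(np.clip(
            round(rng.normal(design.upstream_richness_mean, design.upstream_richness_sd)),
            2, design.n_taxa_pool,
        ))
        s_down = int(np.clip(round(s_up / design.downstream_richness_ratio), 1, s_up))
        up_set = rng.choice(pool, size=s_up, replace=False)
        loss = s_up - s_down
        f = design.turnover_fraction
        if f >= 1.0:
            repl = int(round(design.replacement_rate_when_no_loss * s_up))
        else:
            repl = int(round(f / (1.0 - f) * loss))
        repl = min(repl, s_up - loss)
        removed = rng.choice(up_set, size=loss + repl, replace=False)
        outside = np.setdiff1d(pool, up_set, assume_unique=False)
        added = rng.choice(outside, size=min(repl, outside.size), replace=False)
        down_set = np.concatenate([np.setdiff1d(up_set, removed), added])

        for loc, taxa in zip(locations, (up_set, down_set)):
            w = weights[taxa]
            counts = rng.multinomial(design.reads_per_sample, w / w.sum())
            vec = np.zeros(design.n_taxa_pool, dtype=int)
            vec[taxa] = counts
            sample_id = f"{site}-{loc}"
            samples[sample_id] = vec
            meta_rows.append({"sample_id": sample_id, "site": site, "location": loc,
                              "marker": design.marker})

    counts_df = pd.DataFrame(
        samples, index=[f"OTU{i + 1:05d}" for i in range(design.n_taxa_pool)]
    )
    counts_df = counts_df.loc[counts_df.sum(axis=1) > 0]
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return OTUTable(counts=counts_df, metadata=meta)


def generate_otu_tables(
    design: OTUDesign,
    dataset: SurveyDataset,
    bacteria_design: OTUDesign | None = None,
    locations: tuple[str, str] = ("U1", "D"),
):
    """Generate (bacteria-like, fungi-like) OTU tables, one sample per
    site x location of the survey dataset.

    ``design`` parameterizes the fungal-like (ITS) marker; the bacterial
    (16S) marker uses ``bacteria_design`` or calibrated defaults.
    """
    sites = sorted(dataset.measurements["site"].unique())
    for loc in locations:
        if loc not in set(dataset.measurements["location"]):
            raise ValidationError(f"dataset has no samples at location {loc!r}")
    b_design = bacteria_design if bacteria_design is not None else BACTERIA_OTU_DEFAULTS
    bacteria = _one_marker_tables(b_design, sites, locations)
    fungi = _one_marker_tables(design, sites, locations)
    return bacteria, fungi


FLUME_EXPERIMENTS = ("dilution", "dosing", "transplant")

_DEFAULT_TREATMENTS: dict[str, dict[str, float]] = {
    # ln-scale effects relative to river water; the 85% WW response sits
    # below the 15% and 50% fractions (a subsidy-stress hump).
    "dilution": {"0% WW": 0.0, "15% WW": 0.25, "50% WW": 0.30, "85% WW": 0.12},
    "dosing": {"River": 0.0, "Control": -0.05, "MPs": -0.30, "MPs+Nutrients": -0.02},
    "transplant": {"river": 0.0, "ww": 0.35},
}

_DEFAULT_DURATION = {"dilution": 13, "dosing": 35, "transplant": 14}


@dataclass(frozen=True)
class FlumeSpec:
    """One flume experiment: treatments with ln-scale mean effects, blocks.

    For ``transplant``, ``treatments`` are inoculation-source effects and
    ``persistence`` controls how much of the inoculation effect is carried
    after strips are transferred to the opposite water (1 = fully carried).
    """

    experiment: str = "dilution"
    treatments: dict[str, float] | None = None
    n_blocks: int = 4
    strips_per_channel: int = 4
    duration_days: int | None = None
    baseline_ln_rate: float = -3.5
    block_sd: float = 0.10
    residual_sd: float = 0.15
    persistence: float = 1.0
    seed: int = 3

    def __post_init__(self) -> None:
        if self.experiment not in FLUME_EXPERIMENTS:
            raise ValidationError(
                f"unknown experiment id {self.experiment!r}; "
                f"expected one of {FLUME_EXPERIMENTS}"
            )
        _check(self.n_blocks >= 2, "n_blocks", "need >= 2 blocks")
        _check(self.strips_per_channel >= 1, "strips_per_channel", ">= 1")
        _check(0.0 <= self.persistence <= 1.0, "persistence", "in [0, 1]")
        if self.experiment == "dilution":
            for label in (self.treatments or _DEFAULT_TREATMENTS["dilution"]):
                try:
                    frac = float(label.rstrip("% WW").strip() or 0) / 100.0
                except ValueError:
                    raise ValidationError(
                        f"dilution label {label!r} must encode a WW percentage"
                    ) from None
                _check(0.0 <= frac <= 1.0, "treatments",
                       f"dilution label {label!r} must encode a WW fraction in [0,1]")

    def effects(self) -> dict[str, float]:
        return dict(self.treatments or _DEFAULT_TREATMENTS[self.experiment])

    @property
    def days(self) -> int:
        return self.duration_days or _DEFAULT_DURATION[self.experiment]


def generate_flume(spec: FlumeSpec) -> pd.DataFrame:
    """Generate one flume dataset: treatment + block effect + noise on ln scale.

    The transplant design crosses inoculation source with transfer
    destination; the realized mean is
    baseline + persistence * inoc_effect + (1 - persistence) * dest_effect.
    """
    rng = np.random.default_rng(spec.seed)
    effects = spec.effects()
    block_b = rng.normal(0.0, spec.block_sd, size=spec.n_blocks)
    rows = []
    if spec.experiment == "transplant":
        sources = list(effects)
        for b in range(spec.n_blocks):
            for src in sources:
                for dest in sources:
                    mean = (spec.baseline_ln_rate
                            + spec.persistence * effects[src]
                            + (1.0 - spec.persistence) * effects[dest])
                    for s in range(spec.strips_per_channel):
                        ln_y = mean + block_b[b] + rng.normal(0.0, spec.residual_sd)
                        rows.append({
                            "experiment": spec.experiment, "block": f"B{b + 1}",
                            "inoculation": src, "transfer": dest,
                            "treatment": f"{src}->{dest}",
                            "strip_id": f"B{b + 1}-{src}-{dest}-{s + 1}",
                            "ln_response": ln_y, "response": math.exp(ln_y),
                            "duration_days": spec.days,
                        })
    else:
        for b in range(spec.n_blocks):
            for trt, eff in effects.items():
                for s in range(spec.strips_per_channel):
                    ln_y = (spec.baseline_ln_rate + eff + block_b[b]
                            + rng.normal(0.0, spec.residual_sd))
                    rows.append({
                        "experiment": spec.experiment, "block": f"B{b + 1}",
                        "treatment": trt,
                        "strip_id": f"B{b + 1}-{trt}-{s + 1}",
                        "ln_response": ln_y, "response": math.exp(ln_y),
                        "duration_days": spec.days,
                    })
    return pd.DataFrame(rows)
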