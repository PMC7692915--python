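"""Arrhenius / metabolic-scaling models for cotton-strip process rates.

The temperature dependence of a rate EF is modelled with the linearized
Arrhenius form

    ln EF(T) = -Ea * (1/(kB*T) - 1/(kB*Tref)) + ln EF(Tref)

where kB is the Boltzmann constant in eV/K and Tref a fixed centering
temperature (the survey-wide mean). Centering the inverse temperature makes
the intercept the rate at Tref and the slope the negative activation energy
Ea (eV). Metabolic theory predicts Ea around 0.6-0.7 eV for respiration.

Fits are linear mixed models (REML) with a random intercept per site;
sampling location enters as a fixed factor interacting with the temperature
covariate, so each location carries its own activation energy. Degenerate
noiseless inputs (a perfect linear fit) are detected and solved exactly by
least squares, because the mixed-model variance components are then on the
boundary and iterative REML adds nothing but numerical noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assay import BOLTZMANN_EV, CELSIUS_TO_KELVIN, ValidationError


@dataclass(frozen=True)
class TemperatureStandard:
    """Centering convention for the inverse-temperature covariate."""

    t_ref_celsius: float = 6.748
    k_b: float = BOLTZMANN_EV

    @property
    def t_ref_kelvin(self) -> float:
        return self.t_ref_celsius + CELSIUS_TO_KELVIN


DEFAULT_STANDARD = TemperatureStandard()


def standardize_temperature(
    t_celsius: float | np.ndarray, std: TemperatureStandard = DEFAULT_STANDARD
) -> float | np.ndarray:
    """Centered inverse temperature 1/(kB*T) - 1/(kB*Tref), in eV^-1.

    Zero at the reference temperature; strictly decreasing in temperature,
    so a slope of -Ea on this covariate corresponds to rates rising with
    warmth when Ea > 0.
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -CELSIUS_TO_KELVIN):
        raise ValidationError("temperature at or below absolute zero")
    kelvin = t + CELSIUS_TO_KELVIN
    out = 1.0 / (std.k_b * kelvin) - 1.0 / (std.k_b * std.t_ref_kelvin)
    return float(out) if np.isscalar(t_celsius) else out


@dataclass
class ArrheniusFit:
    """Fitted linearized Arrhenius mixed model.

    ``slope_reference`` is the coefficient on the standardized inverse
    temperature for the reference location (= -Ea there);
    ``slope_interactions`` hold per-location slope shifts. Ea(loc) =
    -(slope_reference + interaction). ``params``/``cov`` keep the full
    coefficient vector and covariance for CI propagation.
    """

    reference_location: str
    locations: list[str]
    intercept: float
    slope_reference: float
    location_offsets: dict[str, float]
    slope_interactions: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    params: pd.Series
    cov: pd.DataFrame
    site_variance: float
    residual_variance: float
    marginal_r2: float
    conditional_r2: float
    n_obs: int
    n_excluded: int = 0
    method: str = "mixedlm-reml"


@dataclass
class EffectSize:
    g: float
    contrast: str
    n_a: int
    n_b: int
    ci: tuple[float, float] | None = None


def _slope_name(loc: str) -> str:
    return f"slope:{loc}"


def _offset_name(loc: str) -> str:
    return f"loc:{loc}"


def _build_design(
    df: pd.DataFrame, locations: list[str], reference: str, interactions: bool
) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", "slope"]
    cols = [np.ones(len(df)), df["std_temp"].to_numpy(float)]
    others = [l for l in locations if l != reference]
    for loc in others:
        ind = (df["location"] == loc).to_numpy(float)
        cols.append(ind)
        names.append(_offset_name(loc))
    if interactions:
        for loc in others:
            ind = (df["location"] == loc).to_numpy(float)
            cols.append(ind * df["std_temp"].to_numpy(float))
            names.append(_slope_name(loc))
    return np.column_stack(cols), names


def fit_arrhenius(
    data: pd.DataFrame,
    reference_location: str = "U2",
    interactions: bool = True,
    std: TemperatureStandard = DEFAULT_STANDARD,
) -> ArrheniusFit:
    """Fit ln EF ~ std_temp * location + (1 | site) by REML.

    ``data`` needs columns ``ln_ef`` (or ``ef`` > 0, logged here),
    ``std_temp`` (or ``temperature_c``, standardized here), ``location``,
    ``site``. Rows with non-positive ``ef`` are excluded and counted.
    Falls back to an exact least-squares solution when the fit is perfect
    (noiseless inputs) and to a fixed-effects fit when fewer than two sites
    are present.
    """
    df = data.copy()
    if "ln_ef" not in df.columns:
        if "ef" not in df.columns:
            raise ValidationError("data must contain 'ln_ef' or 'ef'")
        n_bad = int((df["ef"] <= 0).sum())
        if n_bad == len(df):
            bad = df.index[df["ef"] <= 0].tolist()
            raise ValidationError(f"all responses non-positive; offending records: {bad}")
        df = df[df["ef"] > 0].copy()
        df["ln_ef"] = np.log(df["ef"])
    else:
        n_bad = 0
    if "std_temp" not in df.columns:
        df["std_temp"] = standardize_temperature(df["temperature_c"].to_numpy(float), std)
    if df["std_temp"].nunique() < 2:
        raise ValidationError("need at least two distinct temperatures")

    locations = sorted(df["location"].unique(), key=lambda l: (l != reference_location, l))
    if reference_location not in locations:
        raise ValidationError(f"reference location {reference_location!r} absent from data")
    X, names = _build_design(df, locations, reference_location, interactions)
    y = df["ln_ef"].to_numpy(float)
    n_sites = df["site"].nunique()

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    ssr = float(resid @ resid)
    y_scale = max(float(y @ y), 1.0)

    if ssr / y_scale < 1e-24:
        # perfect fit: exact solution, zero variance components
        params = pd.Series(beta_ols, index=names)
        cov = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
        site_var, resid_var, method = 0.0, 0.0, "exact-lstsq"
    elif n_sites < 2:
        warnings.warn(
            "fewer than two sites: falling back to fixed-effects OLS", stacklevel=2
        )
        ols = sm.OLS(y, X).fit()
        params = pd.Series(ols.params, index=names)
        cov = pd.DataFrame(np.asarray(ols.cov_params()), index=names, columns=names)
        site_var, resid_var, method = 0.0, float(ols.scale), "ols"
    else:
        X_df = pd.DataFrame(X, columns=names)
        model = sm.MixedLM(y, X_df, groups=df["site"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        params = pd.Series(np.asarray(res.fe_params), index=names)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[: len(names), : len(names)],
            index=names,
            columns=names,
        )
        site_var = float(np.asarray(res.cov_re).squeeze())
        resid_var = float(res.scale)
        method = "mixedlm-reml"

    fitted_fixed = X @ params.to_numpy()
    var_f = float(np.var(fitted_fixed))
    denom = var_f + site_var + resid_var
    r2m = var_f / denom if denom > 0 else 1.0
    r2c = (var_f + site_var) / denom if denom > 0 else 1.0

    z = stats.norm.ppf(0.975)
    conf = {
        name: (params[name] - z * math.sqrt(max(cov.loc[name, name], 0.0)),
               params[name] + z * math.sqrt(max(cov.loc[name, name], 0.0)))
        for name in names
    }
    offsets = {l: float(params.get(_offset_name(l), 0.0)) for l in locations}
    inter = {l: float(params.get(_slope_name(l), 0.0)) for l in locations}
    return ArrheniusFit(
        reference_location=reference_location,
        locations=list(locations),
        intercept=float(params["intercept"]),
        slope_reference=float(params["slope"]),
        location_offsets=offsets,
        slope_interactions=inter,
        conf_int=conf,
        params=params,
        cov=cov,
        site_variance=site_var,
        residual_variance=resid_var,
        marginal_r2=r2m,
        conditional_r2=r2c,
        n_obs=len(df),
        n_excluded=n_bad,
        method=method,
    )


@dataclass
class ActivationEnergy:
    location: str
    ea: float
    se: float
    ci: tuple[float, float]


def activation_energy(fit: ArrheniusFit, location: str) -> ActivationEnergy:
    """Ea for a location: -(reference slope + interaction), Wald 95% CI.

    The variance combines the slope and interaction variances with their
    covariance from the fitted coefficient covariance matrix.
    """
    if location not in fit.locations:
        raise ValidationError(f"unknown location {location!r}; have {fit.locations}")
    slope = fit.slope_reference
    inter = fit.slope_interactions.get(location, 0.0)
    ea = -(slope + inter)
    var = fit.cov.loc["slope", "slope"]
    name = _slope_name(location)
    if name in fit.cov.index:
        var = var + fit.cov.loc[name, name] + 2.0 * fit.cov.loc["slope", name]
    se = math.sqrt(max(float(var), 0.0))
    z = stats.norm.ppf(0.975)
    return ActivationEnergy(location=location, ea=ea, se=se, ci=(ea - z * se, ea + z * se))


def mte_consistency(
    ea_ci: tuple[float, float], mte_range: tuple[float, float] = (0.6, 0.7)
) -> bool:
    """True iff the Ea confidence interval intersects the predicted range.

    Closed intervals: touching endpoints count as overlap.
    """
    low, high = mte_range
    if low > high:
        raise ValidationError("range low must be <= high")
    ci_low, ci_high = ea_ci
    return ci_low <= high and low <= ci_high


def hedges_g(group_a, group_b, contrast: str = "D - U1") -> EffectSize:
    """Hedges-corrected standardized mean difference (mean_a - mean_b) / s_pooled.

    Applies the small-sample correction J = 1 - 3/(4*df - 1) with
    df = n_a + n_b - 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    df = a.size + b.size - 2
    pooled = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    if pooled == 0:
        raise ValidationError("pooled SD is zero")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (a.mean() - b.mean()) / pooled
    return EffectSize(g=float(g), contrast=contrast, n_a=int(a.size), n_b=int(b.size))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="holm")[1]


@dataclass
class Contrast:
    pair: tuple[str, str]
    estimate: float
    se: float
    p_raw: float
    p_holm: float = float("nan")


@dataclass
class LMEResult:
    response: str
    family: str
    fixed_effects: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p, irr (count)
    site_variance_share: float  # percent
    contrasts: list[Contrast]
    converged: bool
    diagnostics: str = ""
    cov: pd.DataFrame | None = None


def _pairwise_contrasts(
    levels: list[str], reference: str, params: pd.Series, cov: pd.DataFrame
) -> list[Contrast]:
    def coef_vec(loc: str) -> np.ndarray:
        v = np.zeros(len(params))
        if loc != reference:
            v[params.index.get_loc(_offset_name(loc))] = 1.0
        return v

    out = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            c = coef_vec(lb) - coef_vec(la)
            est = float(c @ params.to_numpy())
            se = math.sqrt(max(float(c @ cov.to_numpy() @ c), 0.0))
            zstat = est / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(zstat)) if se > 0 else 1.0
            out.append(Contrast(pair=(la, lb), estimate=est, se=se, p_raw=p))
    if out:
        adj = holm_adjust([c.p_raw for c in out])
        for c, pa in zip(out, adj):
            c.p_holm = float(pa)
    return out


def fit_location_lme(
    data: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    reference_location: str = "U2",
    covariates: list[str] | None = None,
) -> LMEResult:
    """Sampling-location mixed model with a random site intercept.

    Gaussian: REML linear mixed model; reports the percent of remaining
    variance attributed to the site intercept. Count: Poisson log-link GEE
    with exchangeable within-site correlation; exponentiated coefficients
    are reported as incident rate ratios (IRR). All pairwise location
    contrasts are Holm-adjusted.
    """
    df = data.dropna(subset=[response]).copy()
    levels = sorted(df["location"].unique(), key=lambda l: (l != reference_location, l))
    if len(levels) < 2:
        raise ValidationError("need >= 2 locations")
    if df["site"].nunique() < 2:
        raise ValidationError("need >= 2 sites for the random effect")
    covariates = covariates or []

    names = ["intercept"] + [_offset_name(l) for l in levels if l != reference_location]
    cols = [np.ones(len(df))] + [
        (df["location"] == l).to_numpy(float) for l in levels if l != reference_location
    ]
    for c in covariates:
        names.append(c)
        cols.append(df[c].to_numpy(float))
    X = np.column_stack(cols)
    y = df[response].to_numpy(float)

    diagnostics = ""
    if family == "gaussian":
        X_df = pd.DataFrame(X, columns=names)
        model = sm.MixedLM(y, X_df, groups=df["site"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        params = pd.Series(np.asarray(res.fe_params), index=names)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[: len(names), : len(names)],
            index=names,
            columns=names,
        )
        site_var = float(np.asarray(res.cov_re).squeeze())
        resid_var = float(res.scale)
        share = 100.0 * site_var / (site_var + resid_var) if site_var + resid_var > 0 else 0.0
        converged = bool(res.converged)
        if not converged:
            diagnostics = "REML did not converge; estimates may sit on a variance boundary"
        irr = None
    elif family == "count":
        fam = sm.families.Poisson()
        model = sm.GEE(
            y, X, groups=df["site"].to_numpy(), family=fam,
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        params = pd.Series(np.asarray(res.params), index=names)
        cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
        # variance share proxy: ICC of log counts across sites
        ln_y = np.log(np.clip(y, 1e-9, None))
        grp = pd.DataFrame({"y": ln_y, "site": df["site"].to_numpy()})
        between = grp.groupby("site")["y"].mean().var(ddof=1)
        within = grp.groupby("site")["y"].var(ddof=1).mean()
        tot = (between or 0.0) + (within or 0.0)
        share = 100.0 * float(between) / tot if tot and tot > 0 else 0.0
        converged = True
        irr = np.exp(params)
    else:
        raise ValidationError(f"unknown family {family!r}")

    z = stats.norm.ppf(0.975)
    se = np.sqrt(np.clip(np.diag(cov.to_numpy()), 0.0, None))
    pvals = 2.0 * stats.norm.sf(np.abs(params.to_numpy()) / np.where(se > 0, se, np.inf))
    fe = pd.DataFrame(
        {
            "term": names,
            "estimate": params.to_numpy(),
            "se": se,
            "ci_low": params.to_numpy() - z * se,
            "ci_high": params.to_numpy() + z * se,
            "p": pvals,
        }
    )
    if irr is not None:
        fe["irr"] = np.exp(fe["estimate"])
        fe["irr_ci_low"] = np.exp(fe["ci_low"])
        fe["irr_ci_high"] = np.exp(fe["ci_high"])

    contrasts = _pairwise_contrasts(levels, reference_location, params, cov)
    return LMEResult(
        response=response,
        family=family,
        fixed_effects=fe,
        site_variance_share=float(share),
        contrasts=contrasts,
        converged=converged,
        diagnostics=diagnostics,
        cov=cov,
    )


def location_term_pvalue(result: LMEResult) -> float:
    """Wald chi-square p-value for the joint location effect."""
    loc_terms = [t for t in result.fixed_effects["term"] if t.startswith("loc:")]
    if not loc_terms:
        raise ValidationError("no location terms in fit")
    fe = result.fixed_effects.set_index("term")
    est = fe.loc[loc_terms, "estimate"].to_numpy()
    if result.cov is not None:
        block = result.cov.loc[loc_terms, loc_terms].to_numpy()
        chi2 = float(est @ np.linalg.solve(block, est))
    else:
        se = fe.loc[loc_terms, "se"].to_numpy()
        chi2 = float(np.sum((est / se) ** 2))
    return float(stats.chi2.sf(chi2, df=len(loc_terms)))
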