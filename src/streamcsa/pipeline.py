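"""End-to-end orchestration, file schemas, and reproducibility controls.

File schemas (CSV, comma-separated, UTF-8, mandatory header; empty cell =
missing):

* measurements: site, location (U2|U1|D), strip_id, do_stream_start,
  do_chamber_end, do_blank_end, chamber_volume_L, strip_mass_g,
  assay_duration_hr, ts_final_N, mass_final_g, incubation_days
* temperatures: site, location, day, temp_c
* chemistry: site, location, DIN, SRP, TU_fungicide, TU_nonfungicide, pct_ww
* OTU tables: TSV, first column the OTU id, remaining columns samples;
  sample metadata CSV: sample_id, site, location, marker

A run executes simulate -> assay -> Arrhenius models -> efflux ->
diversity, records per-stage outputs and warnings, and stamps every report
with a config hash so reruns under an altered configuration are
distinguishable. Stage failures are recorded; later independent stages
still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import (
    EffluxConfig,
    ReferenceBaseline,
    ValidationError,
    process_strips,
    reference_baseline,
)
from .diversity import (
    OTUTable,
    alpha_profile,
    beta_pairwise,
    bray_curtis,
    dispersion_test,
    normalize_table,
    permanova_strata,
)
from .efflux import EvasionConfig, evasion_summary
from .metabolic import (
    DEFAULT_STANDARD,
    activation_energy,
    fit_arrhenius,
    fit_location_lme,
    hedges_g,
    standardize_temperature,
)
from .synthetic import OTUDesign, SurveyDataset, SurveyDesign, generate_otu_tables, generate_survey

MEASUREMENT_COLUMNS = [
    "site", "location", "strip_id",
    "do_stream_start", "do_chamber_end", "do_blank_end",
    "chamber_volume_L", "strip_mass_g", "assay_duration_hr",
    "ts_final_N", "mass_final_g", "incubation_days",
]
NUMERIC_MEASUREMENT_COLUMNS = MEASUREMENT_COLUMNS[3:]
VALID_LOCATIONS = {"U2", "U1", "D"}


@dataclass
class RunConfig:
    output_dir: str = "streamcsa_out"
    input_dir: str | None = None  # None -> simulate
    seed: int = 0
    survey: SurveyDesign | None = None
    otu: OTUDesign | None = None
    evasion: EvasionConfig | None = None
    n_boot: int = 2000
    n_permutations: int = 999
    target_depth: int = 25_000
    simulate: bool = True
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")

    def resolved(self) -> "RunConfig":
        cfg = dataclasses.replace(self)
        if cfg.survey is None:
            cfg.survey = SurveyDesign(seed=self.seed)
        if cfg.otu is None:
            cfg.otu = OTUDesign(seed=self.seed + 1)
        if cfg.evasion is None:
            cfg.evasion = EvasionConfig(seed=self.seed, bootstrap_reps=self.n_boot)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded, so
        the same analysis in a different directory hashes identically)."""
        payload = _to_jsonable(self.resolved())
        payload.pop("output_dir", None)
        payload.pop("input_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    kwargs = dict(raw or {})
    if "survey" in kwargs and kwargs["survey"] is not None:
        sv = dict(kwargs["survey"])
        for key in ("locations",):
            if key in sv:
                sv[key] = tuple(sv[key])
        for key in ("nutrient_effects", "tu_effects"):
            if key in sv:
                sv[key] = {k: tuple(v) for k, v in sv[key].items()}
        kwargs["survey"] = SurveyDesign(**sv)
    if "otu" in kwargs and kwargs["otu"] is not None:
        kwargs["otu"] = OTUDesign(**kwargs["otu"])
    if "evasion" in kwargs and kwargs["evasion"] is not None:
        kwargs["evasion"] = EvasionConfig(**kwargs["evasion"])
    return RunConfig(**kwargs)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement CSV; malformed rows are reported with
    1-based line numbers (header = line 1)."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"measurement file missing required column(s): {missing}")
    bad_loc = df.index[~df["location"].isin(VALID_LOCATIONS)].tolist()
    if bad_loc:
        lines = [i + 2 for i in bad_loc]
        raise ValidationError(f"invalid location label(s) at line(s) {lines}")
    for col in NUMERIC_MEASUREMENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            lines = [i + 2 for i in bad]
            raise ValidationError(f"non-numeric value in column {col!r} at line(s) {lines}")
        df[col] = coerced
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def write_otu_table(table: OTUTable, counts_path: str | Path, meta_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="otu_id")
    table.metadata.to_csv(meta_path, index_label="sample_id")


def read_otu_table(counts_path: str | Path, meta_path: str | Path) -> OTUTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    return OTUTable(counts=counts, metadata=meta)


def write_survey(dataset: SurveyDataset, out_dir: str | Path) -> dict[str, str]:
    """Write survey CSVs; returns file names relative to ``out_dir`` so
    reports stay byte-identical across working directories."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {
        "measurements": "measurements.csv",
        "temperatures": "temperatures.csv",
        "chemistry": "chemistry.csv",
        "reference_strips": "reference_strips.csv",
    }
    write_measurements(dataset.measurements, out / names["measurements"])
    dataset.temperatures.to_csv(out / names["temperatures"], index=False)
    dataset.chemistry.to_csv(out / names["chemistry"], index=False)
    pd.DataFrame(
        {"ts_N": dataset.reference_ts, "mass_g": dataset.reference_mass}
    ).to_csv(out / names["reference_strips"], index=False)
    return names


@dataclass
class StageReport:
    name: str
    status: str  # "ok" | "failed" | "skipped"
    outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    reason: str = ""


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: list[StageReport] = field(default_factory=list)

    def stage(self, name: str) -> StageReport:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(_to_jsonable_report(self), indent=2, sort_keys=True)


def _to_jsonable_report(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable_report(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable_report(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable_report(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    return obj


def run_field_pipeline(cfg: RunConfig) -> RunReport:
    """Simulate (or load) a survey and run every analysis stage.

    Each stage records outputs or a failure reason; an early failure does
    not stop later stages that do not depend on it.
    """
    cfg = cfg.resolved()
    report = RunReport(version=__version__, config_hash=cfg.config_hash(), seed=cfg.seed)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- simulate / load ------------------------------------------------
    stage = StageReport(name="simulate", status="ok")
    dataset = None
    try:
        if cfg.simulate or cfg.input_dir is None:
            dataset = generate_survey(cfg.survey)
        else:
            meas = read_measurements(Path(cfg.input_dir) / "measurements.csv")
            temps = pd.read_csv(Path(cfg.input_dir) / "temperatures.csv")
            chem = pd.read_csv(Path(cfg.input_dir) / "chemistry.csv")
            refs = pd.read_csv(Path(cfg.input_dir) / "reference_strips.csv")
            dataset = SurveyDataset(
                measurements=meas, temperatures=temps, chemistry=chem,
                reference_ts=refs["ts_N"].to_numpy(),
                reference_mass=refs["mass_g"].to_numpy(),
                truth=pd.DataFrame(), design=cfg.survey,
            )
        stage.outputs = write_survey(dataset, out_dir / "survey")
    except Exception as exc:  # noqa: BLE001 - reported, not silenced
        stage.status = "failed"
        stage.reason = str(exc)
    report.stages.append(stage)

    strip_results = None
    if dataset is not None:
        # --- assay ------------------------------------------------------
        stage = StageReport(name="assay", status="ok")
        try:
            ts_base = reference_baseline(dataset.reference_ts)
            mass_base = reference_baseline(dataset.reference_mass)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                strip_results = process_strips(
                    dataset.measurements, dataset.temperature_series(),
                    ts_base, mass_base,
                )
            stage.warnings = [str(w.message) for w in caught]
            n_flagged = int((strip_results["flags"] != "").sum())
            stage.outputs["n_strips"] = len(strip_results)
            stage.outputs["n_flagged"] = n_flagged
            strip_results.to_csv(out_dir / "strip_results.csv", index=False)
            stage.outputs["strip_results"] = "strip_results.csv"
        except Exception as exc:  # noqa: BLE001
            stage.status = "failed"
            stage.reason = str(exc)
        report.stages.append(stage)

    if strip_results is not None:
        # --- Arrhenius / location models ---------------------------------
        stage = StageReport(name="models", status="ok")
        try:
            temps = dataset.temperatures.groupby(["site", "location"])["temp_c"].mean()
            df = strip_results.copy()
            df["mean_temp_c"] = [
                temps.loc[(r.site, r.location)] for r in df.itertuples()
            ]
            df["std_temp"] = standardize_temperature(
                df["mean_temp_c"].to_numpy(float), DEFAULT_STANDARD
            )
            keep = (df["resp_c"] > 0) & (df["flags"] == "")
            fit_df = df.loc[keep, ["site", "location", "std_temp"]].copy()
            fit_df["ln_ef"] = np.log(df.loc[keep, "resp_c"])
            fit = fit_arrhenius(fit_df)
            eas = {loc: activation_energy(fit, loc) for loc in fit.locations}
            stage.outputs["n_excluded_ln_fit"] = int((~keep).sum())
            stage.outputs["ea_ev"] = {
                loc: {"estimate": ea.ea, "ci": list(ea.ci)} for loc, ea in eas.items()
            }
            stage.outputs["marginal_r2"] = fit.marginal_r2
            stage.outputs["conditional_r2"] = fit.conditional_r2

            lme = fit_location_lme(df.assign(resp=df["resp_c"]), "resp")
            stage.outputs["location_model"] = {
                "site_pct_var": lme.site_variance_share,
                "contrasts": {
                    f"{a}-{b}": {"estimate": c.estimate, "p_holm": c.p_holm}
                    for c, (a, b) in ((c, c.pair) for c in lme.contrasts)
                },
            }
            d = df[df["location"] == "D"].groupby("site")["resp_c"].mean()
            u1 = df[df["location"] == "U1"].groupby("site")["resp_c"].mean()
            common = d.index.intersection(u1.index)
            es = hedges_g(d.loc[common], u1.loc[common])
            stage.outputs["hedges_g_resp_D_vs_U1"] = es.g
            (out_dir / "models.json").write_text(
                json.dumps(_to_jsonable_report(stage.outputs), indent=2)
            )
        except Exception as exc:  # noqa: BLE001
            stage.status = "failed"
            stage.reason = str(exc)
        report.stages.append(stage)

        # --- efflux -------------------------------------------------------
        stage = StageReport(name="efflux", status="ok")
        try:
            summary = evasion_summary(strip_results, cfg.evasion)
            med = summary.pop("per_site_medians")
            med.to_csv(out_dir / "efflux_site_medians.csv")
            stage.outputs = summary
            (out_dir / "efflux.json").write_text(
                json.dumps(_to_jsonable_report(summary), indent=2)
            )
        except Exception as exc:  # noqa: BLE001
            stage.status = "failed"
            stage.reason = str(exc)
        report.stages.append(stage)

    if dataset is not None:
        # --- diversity ----------------------------------------------------
        stage = StageReport(name="diversity", status="ok")
        try:
            bacteria, fungi = generate_otu_tables(cfg.otu, dataset)
            write_otu_table(bacteria, out_dir / "otu_16s.tsv", out_dir / "otu_16s_meta.csv")
            write_otu_table(fungi, out_dir / "otu_its.tsv", out_dir / "otu_its_meta.csv")
            div = {}
            for name, table in (("bacteria", bacteria), ("fungi", fungi)):
                rel = normalize_table(table, "relative")
                pa = normalize_table(table, "presence_absence")
                alphas = {
                    sid: alpha_profile(table.counts[sid].to_numpy(), cfg.target_depth)
                    for sid in table.sample_ids
                }
                groups = table.metadata.loc[table.counts.columns, "location"].to_numpy()
                strata = table.metadata.loc[table.counts.columns, "site"].to_numpy()
                dist = bray_curtis(pa.counts)
                perm = permanova_strata(
                    dist, groups, strata, n_perm=cfg.n_permutations, seed=cfg.seed
                )
                disp = dispersion_test(dist, groups, n_perm=cfg.n_permutations, seed=cfg.seed)
                betas = []
                for site, grp in table.metadata.groupby("site"):
                    ids = grp.index
                    if len(ids) == 2:
                        a = set(table.counts.index[table.counts[ids[0]] > 0])
                        b = set(table.counts.index[table.counts[ids[1]] > 0])
                        part = beta_pairwise(a, b)
                        betas.append((part.beta_sim, part.beta_nes))
                sims = [b[0] for b in betas]
                ness = [b[1] for b in betas]
                div[name] = {
                    "mean_richness": {
                        loc: float(np.mean([
                            alphas[s].observed_richness
                            for s in table.sample_ids
                            if table.metadata.loc[s, "location"] == loc
                        ]))
                        for loc in ("U1", "D")
                    },
                    "permanova": {"F": perm.statistic, "p": perm.p_value},
                    "dispersion": {"F": disp.statistic, "p": disp.p_value},
                    "turnover_mean": float(np.mean(sims)) if sims else None,
                    "nestedness_mean": float(np.mean(ness)) if ness else None,
                }
            stage.outputs = div
            (out_dir / "diversity.json").write_text(
                json.dumps(_to_jsonable_report(div), indent=2)
            )
        except Exception as exc:  # noqa: BLE001
            stage.status = "failed"
            stage.reason = str(exc)
        report.stages.append(stage)

    (out_dir / "report.json").write_text(report.to_json())
    return report
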