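"""End-to-end orchestration, file formats and report generation.

The pipeline composes the module operations in protocol order —
simulate (or read) → clamp QC → Steele kinetics → indices →
sex-stratified bootstrap contrasts — and emits tables shaped like a
genotype-association study report: per-sex contrast tables with 99%
bootstrap CIs, a cohort descriptive table (median, 25th, 75th
percentile by sex×genotype), a QC summary, and provenance.

Interchange formats are plain CSV (units encoded in column names) and
JSON for nested summaries; every run writes its resolved configuration
and seed beside the outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DesignError, SchemaError
from .indices import auc_trapezoid, hir, matsuda_index
from .synthetic_data import (
    ClampSimParams,
    MealSimParams,
    sample_cohort,
    simulate_clamp,
    simulate_meal,
)
from .stats import (
    bootstrap_lmm_percentile,
    bootstrap_rlm_bca,
    fit_lmm_reml,
    fit_rlm,
    genotype_contrasts,
    genotype_design,
    lmm_contrasts,
)
from .tracer_kinetics import analyze_clamp
from .types import (
    ClampProtocol,
    ClampSeries,
    KineticsConfig,
    KineticsResult,
    MealSeries,
    SubjectRecord,
)

log = logging.getLogger(__name__)

SUBJECT_COLUMNS = ["subject_id", "sex", "genotype", "weight_kg", "height_m",
                   "ffm_kg", "fat_kg", "visceral_fat_g",
                   "android_gynoid_ratio"]
CLAMP_TS_COLUMNS = ["subject_id", "time_min", "glucose_mmol_l", "ttr",
                    "insulin_pmol_l", "ginf_ml_h"]
SCHEDULE_COLUMNS = ["subject_id", "prime_mg", "tracer_mg_min", "ginf_mg_ml",
                    "spike_mg_per_g"]
MEAL_TS_COLUMNS = ["subject_id", "time_min", "glucose_mmol_l",
                   "insulin_pmol_l"]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run."""

    mode: str = "full"                 # simulate | analyze | full
    seed: int = 0
    n_phase1: int = 50
    n_phase2: int = 47
    minor_allele_freq: float = 0.44
    sex_ratio_female: float = 0.69
    clamp_completion: float = 79.0 / 97.0   # meal n=97 vs clamp n=79
    n_boot: int = 50000
    level: float = 0.99
    unit_mode: str = "si"
    auc_window: tuple[float, float] = (0.0, 150.0)
    retain_qc_failures: bool = False
    min_per_cell: int = 2              # subjects per sex×genotype cell to fit
    out_dir: Optional[str] = None

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["auc_window"] = list(d["auc_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "auc_window" in d:
            d["auc_window"] = tuple(d["auc_window"])
        return cls(**d)


# --------------------------------------------------------------------------
# table IO
# --------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str],
                     what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) "
                          f"{', '.join(missing)}")


def subjects_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in SUBJECT_COLUMNS}
                         for r in records], columns=SUBJECT_COLUMNS)


def subjects_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    _require_columns(df, SUBJECT_COLUMNS, "subject table")
    return [SubjectRecord(**{c: row[c] for c in SUBJECT_COLUMNS})
            for _, row in df.iterrows()]


def write_subject_table(records, path) -> None:
    df = records if isinstance(records, pd.DataFrame) \
        else subjects_to_frame(records)
    df.to_csv(path, index=False)


def read_subject_table(path) -> pd.DataFrame:
    """Read and validate a subject CSV; unknown columns are preserved."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SUBJECT_COLUMNS, "subject table")
    return df


def _sorted_timeseries(df: pd.DataFrame, what: str) -> pd.DataFrame:
    order = df.sort_values(["subject_id", "time_min"], kind="stable")
    if not order.index.equals(df.index):
        log.warning("%s rows were not sorted by (subject, time); sorting",
                    what)
    return order.reset_index(drop=True)


def write_clamp_timeseries(series_list: Sequence[ClampSeries],
                           ts_path, schedule_path) -> None:
    """Write clamp series as a long sample CSV plus an infusion-schedule
    CSV. Pump-update rows carry the step rate with empty measurement
    cells."""
    rows, sched = [], []
    for s in series_list:
        for i, t in enumerate(s.times_min):
            rows.append([s.subject_id, t, s.glucose_mmol_l[i], s.ttr[i],
                         s.insulin_pmol_l[i],
                         float(s.ginf_rate_at(t)[0])])
        for t, r in zip(s.ginf_times_min, s.ginf_ml_h):
            if t not in s.times_min:
                rows.append([s.subject_id, t, np.nan, np.nan, np.nan, r])
        sched.append([s.subject_id, s.prime_mg, s.tracer_rate_mg_min,
                      s.ginf_concentration_mg_ml, s.ginf_spike_mg_per_g])
    pd.DataFrame(rows, columns=CLAMP_TS_COLUMNS).sort_values(
        ["subject_id", "time_min"]).to_csv(ts_path, index=False)
    pd.DataFrame(sched, columns=SCHEDULE_COLUMNS).to_csv(schedule_path,
                                                         index=False)


def read_clamp_timeseries(ts_path, schedule_path) -> list[ClampSeries]:
    ts = pd.read_csv(ts_path, float_precision="round_trip")
    _require_columns(ts, CLAMP_TS_COLUMNS, "clamp time-series")
    sched = pd.read_csv(schedule_path,
                        float_precision="round_trip").set_index("subject_id")
    _require_columns(sched.reset_index(), SCHEDULE_COLUMNS,
                     "infusion schedule")
    ts = _sorted_timeseries(ts, "clamp time-series")
    out = []
    for sid, grp in ts.groupby("subject_id", sort=True):
        samples = grp.dropna(subset=["glucose_mmol_l"])
        pump = grp.dropna(subset=["ginf_ml_h"])
        sc = sched.loc[sid]
        out.append(ClampSeries(
            subject_id=str(sid),
            times_min=samples["time_min"].to_numpy(),
            glucose_mmol_l=samples["glucose_mmol_l"].to_numpy(),
            ttr=samples["ttr"].to_numpy(),
            insulin_pmol_l=samples["insulin_pmol_l"].to_numpy(),
            ginf_times_min=pump["time_min"].to_numpy(),
            ginf_ml_h=pump["ginf_ml_h"].to_numpy(),
            prime_mg=float(sc["prime_mg"]),
            tracer_rate_mg_min=float(sc["tracer_mg_min"]),
            ginf_concentration_mg_ml=float(sc["ginf_mg_ml"]),
            ginf_spike_mg_per_g=float(sc["spike_mg_per_g"])))
    return out


def write_meal_timeseries(series_list: Sequence[MealSeries], path) -> None:
    rows = [[s.subject_id, t, g, i]
            for s in series_list
            for t, g, i in zip(s.times_min, s.glucose_mmol_l,
                               s.insulin_pmol_l)]
    pd.DataFrame(rows, columns=MEAL_TS_COLUMNS).to_csv(path, index=False)


def read_meal_timeseries(path) -> list[MealSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MEAL_TS_COLUMNS, "meal time-series")
    df = _sorted_timeseries(df, "meal time-series")
    return [MealSeries(subject_id=str(sid),
                       times_min=g["time_min"].to_numpy(),
                       glucose_mmol_l=g["glucose_mmol_l"].to_numpy(),
                       insulin_pmol_l=g["insulin_pmol_l"].to_numpy())
            for sid, g in df.groupby("subject_id", sort=True)]


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class RunReport:
    """All tables produced by one pipeline run."""

    contrasts: pd.DataFrame            # rows: stratum × endpoint × contrast
    descriptives: pd.DataFrame         # median (Q1, Q3) by sex × genotype
    endpoints: pd.DataFrame            # per-subject endpoint values
    qc: pd.DataFrame                   # clamp-quality per subject
    provenance: dict = field(default_factory=dict)


_DESC_COLUMNS = ["sex", "genotype", "variable", "n", "median", "q25", "q75"]


def _describe(df: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=_DESC_COLUMNS)
    recs = []
    for (sex, geno), grp in df.groupby(["sex", "genotype"], sort=True):
        for col in value_cols:
            v = grp[col].dropna()
            if v.empty:
                continue
            recs.append(dict(sex=sex, genotype=geno, variable=col,
                             n=int(v.size), median=float(v.median()),
                             q25=float(v.quantile(0.25)),
                             q75=float(v.quantile(0.75))))
    return pd.DataFrame(recs, columns=_DESC_COLUMNS)


def _contrast_rows(stratum, endpoint, estimates):
    return [dict(stratum=stratum, endpoint=endpoint, contrast=ce.label,
                 estimate=ce.estimate, ci_low=ce.ci_low, ci_high=ce.ci_high,
                 level=ce.level, method=ce.method, n_boot=ce.n_boot,
                 significant=ce.significant) for ce in estimates]


def _fit_one_time(sub: pd.DataFrame, col: str, B: int, level: float,
                  seed: int):
    """RLM + residual-bootstrap BCa for a one-time endpoint."""
    data = sub.dropna(subset=[col])
    if data["genotype"].nunique() < 3:
        raise DesignError(f"{col}: not all genotype groups present")
    X, names = genotype_design(data["genotype"])
    f = fit_rlm(X, data[col].to_numpy(float))
    cons = genotype_contrasts(f.coef, names)
    return bootstrap_rlm_bca(f, cons, B=B, level=level, seed=seed)


def _fit_repeated(long_df: pd.DataFrame, B: int, level: float, seed: int,
                  time_levels=None):
    """Random-intercept LMM + parametric percentile bootstrap."""
    fit = fit_lmm_reml(long_df, "value", time_levels=time_levels)
    if len(fit.genotype_levels) < 3:
        raise DesignError("not all genotype groups present")
    cons = lmm_contrasts(fit)
    return bootstrap_lmm_percentile(fit, cons, B=B, level=level, seed=seed), \
        fit


def run_pipeline(config: PipelineConfig,
                 subjects: Optional[Sequence[SubjectRecord]] = None,
                 clamp_series: Optional[Sequence[ClampSeries]] = None,
                 meal_series: Optional[Sequence[MealSeries]] = None,
                 clamp_params: Optional[ClampSimParams] = None,
                 meal_params: Optional[MealSimParams] = None,
                 protocol: Optional[ClampProtocol] = None,
                 kinetics_config: Optional[KineticsConfig] = None,
                 ) -> RunReport:
    """Run the pipeline end-to-end.

    In ``simulate``/``full`` mode the cohort and time-series are
    forward-simulated (a fraction ``clamp_completion`` of subjects
    completes the clamp, emulating dropout); in ``analyze`` mode they
    must be supplied. Subjects failing clamp QC are excluded from clamp
    endpoints (set ``retain_qc_failures`` to keep them) and always
    reported. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    kcfg = kinetics_config or KineticsConfig()
    protocol = protocol or ClampProtocol()

    if config.mode in ("simulate", "full"):
        if subjects is None:
            subjects = sample_cohort(
                config.n_phase1, config.n_phase2, config.minor_allele_freq,
                config.sex_ratio_female,
                seed=int(rng.integers(2**31)))
        meal_series = [simulate_meal(s, meal_params,
                                     seed=int(rng.integers(2**31)))
                       for s in subjects]
        does_clamp = rng.random(len(subjects)) < config.clamp_completion

        def _cp(s):
            # clamp_params may be one setting or a per-genotype dict
            if isinstance(clamp_params, dict):
                return clamp_params[s.genotype]
            return clamp_params

        clamp_series = [simulate_clamp(s, _cp(s), protocol,
                                       seed=int(rng.integers(2**31)))[0]
                        if dc else None
                        for s, dc in zip(subjects, does_clamp)]
    elif config.mode == "analyze":
        if subjects is None or meal_series is None:
            raise SchemaError("analyze mode needs subjects and meal series")
        clamp_series = clamp_series or []
    else:
        raise SchemaError(f"unknown mode {config.mode!r}")

    by_id = {s.subject_id: s for s in subjects}
    meal_by_id = {m.subject_id: m for m in meal_series}

    # --- kinetics + QC -----------------------------------------------------
    kin: dict[str, KineticsResult] = {}
    qc_rows = []
    for cs in clamp_series:
        if cs is None:
            continue
        subj = by_id[cs.subject_id]
        res = analyze_clamp(cs, subj, kcfg)
        qc_rows.append(dict(subject_id=cs.subject_id,
                            qc_basal_ratio=res.qc_basal_ratio,
                            qc_clamped_ratio=res.qc_clamped_ratio,
                            qc_pass=res.qc_pass))
        if res.qc_pass or config.retain_qc_failures:
            kin[cs.subject_id] = res
        else:
            log.info("excluding %s from clamp endpoints (QC fail: "
                     "basal %.3f clamped %.3f)", cs.subject_id,
                     res.qc_basal_ratio, res.qc_clamped_ratio)
    qc = pd.DataFrame(qc_rows,
                      columns=["subject_id", "qc_basal_ratio",
                               "qc_clamped_ratio", "qc_pass"])

    # --- per-subject endpoints --------------------------------------------
    rows = []
    for s in subjects:
        r: dict = dict(subject_id=s.subject_id, sex=s.sex,
                       genotype=s.genotype, weight_kg=s.weight_kg,
                       ffm_kg=s.ffm_kg, fat_kg=s.fat_kg,
                       visceral_fat_g=s.visceral_fat_g,
                       android_gynoid_ratio=s.android_gynoid_ratio,
                       completed_clamp=s.subject_id in kin)
        m = meal_by_id.get(s.subject_id)
        if m is not None:
            lo, hi = config.auc_window
            w = (m.times_min >= lo) & (m.times_min <= hi)
            r.update(
                matsuda=matsuda_index(m, config.unit_mode),
                auc_glucose=auc_trapezoid(m.times_min[w],
                                          m.glucose_mmol_l[w]),
                auc_insulin=auc_trapezoid(m.times_min[w],
                                          m.insulin_pmol_l[w]),
                glucose_30=float(m.glucose_mmol_l[m.times_min == 30.0][0]),
                glucose_150=float(m.glucose_mmol_l[m.times_min == 150.0][0]),
                insulin_30=float(m.insulin_pmol_l[m.times_min == 30.0][0]),
                insulin_150=float(m.insulin_pmol_l[m.times_min == 150.0][0]),
            )
        k = kin.get(s.subject_id)
        if k is not None:
            r.update(hir=hir(k.basal_egp, k.basal_insulin),
                     gir_ffm=k.gir_ffm,
                     egp_basal_ffm=k.basal_egp * s.weight_kg / s.ffm_kg,
                     egp_clamped_ffm=k.clamped_egp * s.weight_kg / s.ffm_kg,
                     rd_basal_ffm=k.basal_rd * s.weight_kg / s.ffm_kg,
                     rd_clamped_ffm=k.clamped_rd * s.weight_kg / s.ffm_kg,
                     mcr_basal_ffm=k.basal_mcr * s.weight_kg / s.ffm_kg,
                     mcr_clamped_ffm=k.clamped_mcr * s.weight_kg / s.ffm_kg)
        rows.append(r)
    base_cols = ["subject_id", "sex", "genotype", "weight_kg", "ffm_kg",
                 "fat_kg", "visceral_fat_g", "android_gynoid_ratio",
                 "completed_clamp"]
    endpoints = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=base_cols)

    # --- sex-stratified contrasts -----------------------------------------
    one_time = ["matsuda", "hir", "gir_ffm", "auc_glucose", "auc_insulin"]
    repeated_meal = [("meal_glucose", "glucose_30", "glucose_150"),
                     ("meal_insulin", "insulin_30", "insulin_150")]
    repeated_clamp = [("egp_ffm", "egp_basal_ffm", "egp_clamped_ffm"),
                      ("rd_ffm", "rd_basal_ffm", "rd_clamped_ffm"),
                      ("mcr_ffm", "mcr_basal_ffm", "mcr_clamped_ffm")]
    contrast_rows = []
    for sex, sub in endpoints.groupby("sex", sort=True):
        cell_ok = (sub.groupby("genotype")["subject_id"].count()
                   .reindex(["TT", "AT", "AA"]).fillna(0)
                   >= config.min_per_cell).all()
        if not cell_ok:
            log.warning("stratum %s: a genotype cell has fewer than %d "
                        "subjects; skipping contrasts", sex,
                        config.min_per_cell)
            continue
        for col in one_time:
            if col not in sub.columns or sub[col].dropna().empty:
                continue
            try:
                ces = _fit_one_time(sub, col, config.n_boot, config.level,
                                    seed=int(rng.integers(2**31)))
                contrast_rows += _contrast_rows(sex, col, ces)
            except DesignError as exc:
                log.warning("stratum %s endpoint %s skipped: %s",
                            sex, col, exc)
        for name, c1, c2 in repeated_meal + repeated_clamp:
            if c1 not in sub.columns or c2 not in sub.columns:
                continue
            base = sub.dropna(subset=[c1, c2])
            if base.empty:
                continue
            t1 = float(c1.rsplit("_", 1)[-1]) if c1[-1].isdigit() else "basal"
            t2 = float(c2.rsplit("_", 1)[-1]) if c2[-1].isdigit() \
                else "clamped"
            long_df = pd.concat([
                base[["subject_id", "genotype"]].assign(time=t1,
                                                        value=base[c1]),
                base[["subject_id", "genotype"]].assign(time=t2,
                                                        value=base[c2])],
                ignore_index=True)
            try:
                ces, _ = _fit_repeated(long_df, config.n_boot, config.level,
                                       seed=int(rng.integers(2**31)))
                contrast_rows += _contrast_rows(sex, name, ces)
            except DesignError as exc:
                log.warning("stratum %s endpoint %s skipped: %s",
                            sex, name, exc)

    contrasts = pd.DataFrame(
        contrast_rows, columns=["stratum", "endpoint", "contrast",
                                "estimate", "ci_low", "ci_high", "level",
                                "method", "n_boot", "significant"])
    desc_cols = ["weight_kg", "ffm_kg", "fat_kg", "visceral_fat_g",
                 "android_gynoid_ratio"] + \
        [c for c in endpoints.columns
         if c in one_time or c.startswith(("glucose_", "insulin_", "egp_",
                                           "rd_", "mcr_"))]
    descriptives = _describe(endpoints, desc_cols)

    provenance = dict(version=__version__, seed=config.seed,
                      config=dataclasses.asdict(config),
                      n_subjects=len(subjects),
                      n_clamp=int(qc.shape[0]),
                      n_qc_excluded=int((~qc["qc_pass"]).sum())
                      if not qc.empty else 0,
                      windows=dict(basal=list(kcfg.basal_window),
                                   clamped=list(kcfg.clamped_window)),
                      unit_mode=config.unit_mode,
                      auc_window=list(config.auc_window))
    return RunReport(contrasts=contrasts, descriptives=descriptives,
                     endpoints=endpoints, qc=qc, provenance=provenance)


def write_report(report: RunReport, out_dir,
                 config: Optional[PipelineConfig] = None) -> Path:
    """Write all report tables, the JSON summary and the resolved
    configuration to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.contrasts.to_csv(out / "contrasts.csv", index=False)
    report.descriptives.to_csv(out / "descriptives.csv", index=False)
    report.endpoints.to_csv(out / "endpoints.csv", index=False)
    report.qc.to_csv(out / "qc.csv", index=False)
    summary = dict(schema_version=1, provenance=report.provenance,
                   contrasts=report.contrasts.to_dict(orient="records"))
    (out / "report.json").write_text(json.dumps(summary, indent=2,
                                                default=float))
    if config is not None:
        config.to_yaml(out / "config.yaml")
    return out
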