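"""Record schema, validation filters and the end-to-end pipeline driver.

CSV interchange schema (one row per admission, ISO-8601 date-times):

========== =========================================================
column      meaning
========== =========================================================
admission   admission date-time (required, valid)
discharge   discharge date-time (required, ≥ admission)
age         years, non-negative number
gender      ``F`` or ``M``
icd10_codes semicolon-joined ICD-10 diagnosis codes; the first is the
            principal diagnosis and must be present
drg         diagnosis related group label, non-empty
route       ``ED`` or ``non-ED``
death_date  date-time of death, empty if alive (invalid values exclude
            the record)
========== =========================================================

Validation mirrors administrative-data cleaning: records failing any
rule are excluded, with each exclusion attributed to the *first*
failing rule in the fixed order admission_date, discharge_date,
date_order, death_date, diagnosis, drg, age, gender.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import evaluation as eval_mod
from . import models as models_mod
from .forecast import trajectory_table

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "admission",
    "discharge",
    "age",
    "gender",
    "icd10_codes",
    "drg",
    "route",
)

#: exclusion rules in attribution order
RULE_ORDER = (
    "admission_date",
    "discharge_date",
    "date_order",
    "death_date",
    "diagnosis",
    "drg",
    "age",
    "gender",
)


@dataclass
class ValidationReport:
    n_input: int
    n_retained: int
    exclusions: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "exclusions": dict(self.exclusions),
        }


def validate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Apply the exclusion rules to an admissions table.

    Returns the retained records with typed columns plus a report whose
    per-rule counts attribute each excluded row to its first failing
    rule; ``n_retained + sum(exclusions) == n_input``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    n_input = len(records)
    df = records.copy()

    adm = pd.to_datetime(df["admission"], errors="coerce")
    dis = pd.to_datetime(df["discharge"], errors="coerce")
    age = pd.to_numeric(df["age"], errors="coerce")
    death_raw = df["death_date"] if "death_date" in df.columns else pd.Series("", index=df.index)
    death_str = death_raw.astype(str).str.strip()
    absent = death_raw.isna() | death_str.str.lower().isin(["", "nat", "nan", "none"])
    death = pd.to_datetime(death_str.where(~absent), errors="coerce")
    codes = df["icd10_codes"].fillna("").astype(str).str.strip().str.strip(";")

    fails = {
        "admission_date": adm.isna(),
        "discharge_date": dis.isna(),
        "date_order": adm.notna() & dis.notna() & (dis < adm),
        "death_date": ~absent & death.isna(),
        "diagnosis": codes == "",
        "drg": df["drg"].fillna("").astype(str).str.strip() == "",
        "age": age.isna() | (age < 0),
        "gender": ~df["gender"].fillna("").astype(str).isin(["F", "M"]),
    }
    attributed = pd.Series(index=df.index, dtype=object)
    for rule in RULE_ORDER:
        mask = fails[rule] & attributed.isna()
        attributed[mask] = rule
    keep = attributed.isna()

    exclusions = {rule: int((attributed == rule).sum()) for rule in RULE_ORDER}
    report = ValidationReport(n_input, int(keep.sum()), exclusions)
    logger.info(
        "validated %d records: retained %d, excluded %s",
        n_input,
        report.n_retained,
        {k: v for k, v in exclusions.items() if v},
    )

    out = df[keep].copy()
    out["admission"] = adm[keep]
    out["discharge"] = dis[keep]
    out["age"] = age[keep]
    out["death_date"] = death[keep]
    return out, report


def load_and_validate(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read an admissions CSV and apply the exclusion rules."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"admissions file not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    return validate_records(raw)


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the interchange schema (ISO-8601 date-times)."""
    cols = [c for c in (*REQUIRED_COLUMNS, "death_date") if c in records.columns]
    out = records[cols].copy()
    for c in ("admission", "discharge", "death_date"):
        if c in out.columns:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """End-to-end run: simulate (or load), split, fit, evaluate, forecast."""

    out_dir: str | Path
    input_csv: str | Path | None = None  # load this file instead of simulating
    n_admissions: int = 20000
    seed: int = 0
    mode: str = "logit-exact"
    test_year: int = 2007
    model_presets: tuple[str, ...] = ("model1", "model2a", "model2b", "model2c",
                                      "model3", "model4a", "model4b", "model4c",
                                      "model5a", "model5b", "model5c")
    full_model: str = "model5c"
    by_los_max_day: int = 14
    forecast_horizon: int = 14

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "model_presets" in data:
            data["model_presets"] = tuple(data["model_presets"])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis and write its artifacts.

    Writes (under ``out_dir``): the cohort CSV and ground-truth sidecar
    (when simulating), the validation report, a model-family summary
    table (one row per preset: variables, AUC + CI, AIC, BIC, cutoff
    and threshold metrics), the by-LOS performance table and per-block
    odds ratios for the full model, and example risk trajectories.
    Deterministic given the seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        records, report = load_and_validate(config.input_csv)
        logger.info("loaded %d admissions from %s", len(records), config.input_csv)
    else:
        cc = cohort_mod.CohortConfig(
            n_admissions=config.n_admissions, seed=config.seed, mode=config.mode
        )
        records = cohort_mod.simulate_cohort(cc)
        write_cohort_csv(records, out_dir / "cohort.csv")
        (out_dir / "ground_truth.json").write_text(
            json.dumps(cc.ground_truth(), indent=2)
        )
        # round-trip through the validation filters (should exclude nothing)
        records, report = validate_records(records)
    (out_dir / "validation_report.json").write_text(
        json.dumps(report.as_dict(), indent=2)
    )

    records = models_mod.prepare_features(records)
    train, test = models_mod.split_by_year(records, config.test_year)
    logger.info("split: %d training / %d test admissions", len(train), len(test))

    rows = []
    fitted: dict[str, models_mod.FittedModel] = {}
    for name in config.model_presets:
        spec = models_mod.preset(name)
        model = models_mod.fit_preset(train, name)
        fitted[name] = model
        rep = eval_mod.evaluate(model, test)
        row = {"model": name, "n_variables": spec.n_covariates}
        row.update(rep.as_row())
        rows.append(row)
        logger.info("%s: %d variables, test AUC %.3f", name, spec.n_covariates, rep.auc.auc)
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "model_summary.csv", index=False)

    full = fitted.get(config.full_model) or models_mod.fit_preset(train, config.full_model)
    full.to_json(out_dir / f"{config.full_model}.json")
    by_los = eval_mod.evaluate_by_los(full, test, max_day=config.by_los_max_day)
    by_los.to_csv(out_dir / "by_los.csv", index=False)
    or_table = models_mod.odds_ratios(full)
    or_table.to_csv(out_dir / "odds_ratios.csv")

    monday = _first_monday_of(config.test_year)
    admissions = [monday + pd.Timedelta(days=d, hours=10) for d in (0, 5, 6)]
    covs = [
        {"age": 76.0, "gender": "F", "charlson": 3},
        {"age": 45.0, "gender": "M", "charlson": 0},
    ]
    traj = trajectory_table(full, covs, admissions, horizon=config.forecast_horizon)
    traj.to_csv(out_dir / "trajectories.csv", index=False)

    return {
        "validation": report.as_dict(),
        "summary": summary,
        "by_los": by_los,
        "odds_ratios": or_table,
        "trajectories": traj,
        "models": fitted,
    }


def _first_monday_of(year: int) -> pd.Timestamp:
    d = pd.Timestamp(year=year, month=1, day=1)
    return d + pd.Timedelta(days=(7 - d.weekday()) % 7)
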