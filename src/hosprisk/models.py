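"""The logistic model family: design matrices, presets and ML fitting.

Every model predicts death up to seven days post-discharge from some
combination of three covariate blocks:

* background risk — age (years, linear) and gender (M = 1);
* time-exposure risk — variant ``a`` (raw LOS), ``b`` (weekday/weekend
  LOS split + admission hour) or ``c`` (the 21 weekly period counters +
  admission hour);
* disease risk — the Charlson comorbidity score (raw integer).

The named presets reproduce the published model family: model1
(background), model2a/b/c (exposure alone), model3 (disease),
model4a/b/c (background + exposure), model5a/b/c (full), and subgroup
refits of the full model on a single DRG (``model6:<drg>``) or admission
route (``model7:<route>``).  The intercept is always estimated and never
counted among the covariates, matching the published variable counts
(2, 1/3/22, 1, 3/5/24, 4/6/25).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .comorbidity import charlson_index
from .exposure import (
    DAYS,
    PERIOD_LABELS,
    PERIOD_NAMES,
    encode_exposure_batch,
    exposure_feature_names,
    weekday_weekend_exposure_batch,
)

logger = logging.getLogger(__name__)

DEATH_WINDOW_DAYS = 7


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate blocks a model uses, plus an optional subgroup."""

    include_background: bool = False
    exposure_variant: str = "none"  # none | a | b | c
    include_disease: bool = False
    subgroup: tuple[str, str] | None = None  # ("drg", "R61") | ("route", "ED")

    def __post_init__(self) -> None:
        if self.exposure_variant not in ("none", "a", "b", "c"):
            raise ValueError(f"unknown exposure variant {self.exposure_variant!r}")
        if not (self.include_background or self.include_disease or self.exposure_variant != "none"):
            raise ValueError("model spec selects no covariate block")
        if self.subgroup is not None and self.subgroup[0] not in ("drg", "route"):
            raise ValueError(f"subgroup filter must key on 'drg' or 'route': {self.subgroup}")

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        if self.include_background:
            names += ["age", "gender_M"]
        if self.exposure_variant != "none":
            names += exposure_feature_names(self.exposure_variant)
        if self.include_disease:
            names += ["charlson"]
        return names

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names())


_PRESETS: dict[str, ModelSpec] = {
    "model1": ModelSpec(include_background=True),
    "model2a": ModelSpec(exposure_variant="a"),
    "model2b": ModelSpec(exposure_variant="b"),
    "model2c": ModelSpec(exposure_variant="c"),
    "model3": ModelSpec(include_disease=True),
    "model4a": ModelSpec(include_background=True, exposure_variant="a"),
    "model4b": ModelSpec(include_background=True, exposure_variant="b"),
    "model4c": ModelSpec(include_background=True, exposure_variant="c"),
    "model5a": ModelSpec(include_background=True, exposure_variant="a", include_disease=True),
    "model5b": ModelSpec(include_background=True, exposure_variant="b", include_disease=True),
    "model5c": ModelSpec(include_background=True, exposure_variant="c", include_disease=True),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ModelSpec:
    """Look up a named preset.

    ``model6:<DRG>`` refits the full model within one DRG;
    ``model7:ED`` / ``model7:non-ED`` within one admission route.
    """
    if name in _PRESETS:
        return _PRESETS[name]
    if name.startswith("model6:"):
        return ModelSpec(
            include_background=True,
            exposure_variant="c",
            include_disease=True,
            subgroup=("drg", name.split(":", 1)[1]),
        )
    if name.startswith("model7:"):
        route = name.split(":", 1)[1]
        if route not in ("ED", "non-ED"):
            raise KeyError(f"model7 route must be 'ED' or 'non-ED', got {route!r}")
        return ModelSpec(
            include_background=True,
            exposure_variant="c",
            include_disease=True,
            subgroup=("route", route),
        )
    raise KeyError(f"unknown model preset {name!r}")


def prepare_features(records: pd.DataFrame) -> pd.DataFrame:
    """Attach derived covariate columns (exposure counters, LOS splits,
    Charlson score, gender indicator, outcome) to a record table.

    Idempotent: columns already present are kept as-is, so generator
    output with a ``charlson`` column is not recomputed.
    """
    out = records.copy()
    adm = pd.to_datetime(out["admission"])
    dis = pd.to_datetime(out["discharge"])
    if PERIOD_NAMES[0] not in out.columns:
        enc = encode_exposure_batch(adm, dis)
        enc.index = out.index
        out = pd.concat([out, enc], axis=1)
    if "los_weekday" not in out.columns:
        ww = weekday_weekend_exposure_batch(adm, dis)
        ww.index = out.index
        out = pd.concat([out, ww], axis=1)
    if "gender_M" not in out.columns:
        out["gender_M"] = (out["gender"].astype(str) == "M").astype(np.int64)
    if "charlson" not in out.columns:
        out["charlson"] = [
            charlson_index(_split_codes(c)).score for c in out["icd10_codes"]
        ]
    if "y" not in out.columns and "death_date" in out.columns:
        death = pd.to_datetime(out["death_date"], errors="coerce")
        limit = dis + pd.Timedelta(days=DEATH_WINDOW_DAYS)
        out["y"] = (death.notna() & (death <= limit)).astype(np.int64)
    return out


def _split_codes(value) -> list[str]:
    if isinstance(value, (list, tuple)):
        return list(value)
    return [c for c in str(value).split(";") if c.strip()]


def build_design_matrix(
    records: pd.DataFrame, spec: ModelSpec, require_outcome: bool = True
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Assemble (X, y, names) for a model spec.

    Column order is fixed: intercept, background (age, gender_M),
    exposure block, Charlson.  Raises an informative error when a
    subgroup filter empties the table.
    """
    if records.empty:
        raise ValueError("record table is empty")
    data = prepare_features(records)
    if spec.subgroup is not None:
        col, val = spec.subgroup
        data = data[data[col] == val]
        if data.empty:
            raise ValueError(
                f"no records left after subgroup filter {col} == {val!r}"
            )
    names = ["intercept"] + spec.covariate_names()
    X = np.column_stack(
        [np.ones(len(data))]
        + [data[c].to_numpy(dtype=float) for c in spec.covariate_names()]
    )
    if require_outcome:
        if "y" not in data.columns:
            raise ValueError("records carry no outcome: need a 'y' or 'death_date' column")
        y = data["y"].to_numpy(dtype=float)
    else:
        y = None
    return X, y, names


@dataclass
class FittedModel:
    """A fitted logistic model: coefficients plus fit diagnostics."""

    spec: ModelSpec
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    n: int
    k: int
    n_iter: int
    grad_norm: float

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params

    def predict(self, X: np.ndarray) -> np.ndarray:
        # clamp so predictions stay in the open interval (0, 1)
        return expit(np.clip(X @ self.params, -35.0, 35.0))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spec": {
                "include_background": self.spec.include_background,
                "exposure_variant": self.spec.exposure_variant,
                "include_disease": self.spec.include_disease,
                "subgroup": list(self.spec.subgroup) if self.spec.subgroup else None,
            },
            "names": self.names,
            "params": [float(v) for v in self.params],
            "bse": [float(v) for v in self.bse],
            "llf": self.llf,
            "n": self.n,
            "k": self.k,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        spec = ModelSpec(
            include_background=d["spec"]["include_background"],
            exposure_variant=d["spec"]["exposure_variant"],
            include_disease=d["spec"]["include_disease"],
            subgroup=tuple(d["spec"]["subgroup"]) if d["spec"]["subgroup"] else None,
        )
        return cls(
            spec=spec,
            names=list(d["names"]),
            params=np.asarray(d["params"], dtype=float),
            bse=np.asarray(d["bse"], dtype=float),
            llf=float(d["llf"]),
            n=int(d["n"]),
            k=int(d["k"]),
            n_iter=int(d["n_iter"]),
            grad_norm=float(d["grad_norm"]),
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns from the small diagonal entries of R
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        scale = diag.max() if diag.max() > 0 else 1.0
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * scale)]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear columns: {bad or 'undetermined'}"
        )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    spec: ModelSpec | None = None,
    maxiter: int = 200,
) -> FittedModel:
    """Maximum-likelihood logistic fit (Newton iterations).

    Requires both outcome classes and a full-rank design; perfect
    separation is reported as an error rather than silently penalized,
    so information criteria stay comparable across the model family.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(
            f"outcome must contain both classes 0 and 1, got values {classes}"
        )
    _check_rank(X, names)
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
        big = [names[i] for i in np.flatnonzero(np.abs(params) > 1e3)]
        raise SeparationError(
            f"perfect or quasi-perfect separation suspected; runaway coefficients: {big}"
        )
    grad = model.score(params)
    return FittedModel(
        spec=spec if spec is not None else ModelSpec(include_background=True),
        names=names,
        params=params,
        bse=np.asarray(res.bse, dtype=float),
        llf=float(res.llf),
        n=int(X.shape[0]),
        k=int(X.shape[1]),
        n_iter=int(res.mle_retvals.get("iterations", 0)) if hasattr(res, "mle_retvals") else 0,
        grad_norm=float(np.abs(grad).max()),
    )


def fit_preset(records: pd.DataFrame, name: str) -> FittedModel:
    """Build the design matrix for a named preset and fit it."""
    spec = preset(name)
    X, y, names = build_design_matrix(records, spec)
    return fit_logistic(X, y, names, spec=spec)


def predict_risk(model: FittedModel, records: pd.DataFrame) -> np.ndarray:
    """Per-record predicted probability of death up to 7 days
    post-discharge, in the open interval (0, 1)."""
    X, _, names = build_design_matrix(records, model.spec, require_outcome=False)
    if names != model.names:
        missing = [n for n in model.names if n not in names]
        raise ValueError(f"records lack covariates required by the model: {missing}")
    return model.predict(X)


def split_by_year(
    records: pd.DataFrame, test_year: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prospective split: training = admissions before ``test_year``,
    test = admissions in ``test_year``; later records are dropped."""
    years = pd.to_datetime(records["admission"]).dt.year
    train = records[years < test_year]
    test = records[years == test_year]
    n_later = int((years > test_year).sum())
    if n_later:
        logger.info("excluded %d records admitted after test year %d", n_later, test_year)
    if train.empty:
        raise ValueError(f"no training records before test year {test_year}")
    if test.empty:
        raise ValueError(f"no test records in test year {test_year}")
    return train, test


def odds_ratios(
    model: FittedModel, reference_block: tuple[str, str] = ("Mon", "daytime")
) -> pd.DataFrame:
    """Per-block odds ratios relative to a reference block.

    OR_b = exp(β_b − β_ref) for each of the 21 period counters; the
    reference block's OR is 1 by construction.  Requires an exposure
    variant ``c`` model.
    """
    if model.spec.exposure_variant != "c":
        raise ValueError("odds ratios per block require exposure variant 'c'")
    ref_name = f"count_{reference_block[0]}_{reference_block[1]}"
    if ref_name not in model.names:
        raise ValueError(f"unknown reference block {reference_block}")
    b_ref = model.coef(ref_name)
    rows = []
    for d, b in PERIOD_LABELS:
        name = f"count_{d}_{b}"
        beta = model.coef(name)
        rows.append(
            {
                "day": d,
                "block": b,
                "coefficient": beta,
                "odds_ratio": float(np.exp(beta - b_ref)),
            }
        )
    return pd.DataFrame(rows, index=list(PERIOD_NAMES))
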