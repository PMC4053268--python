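"""Dynamic cumulative-risk trajectories.

For a patient with fixed covariates admitted at a given instant, the
trajectory evaluates the fitted full model at hypothetical discharges
1, 2, …, *horizon* days after admission: each additional day of stay
accumulates further period-counter doses, so predicted risk traces the
model's view of the cumulative cost of continued hospitalization.  The
curve is a profile of the static model over hypothetical lengths of
stay — it does not condition on having survived to the current day.

Because the period grid repeats weekly, shifting the admission instant
by exactly seven days leaves the whole trajectory unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import _coerce_datetime
from .models import FittedModel, predict_risk


@dataclass(frozen=True)
class RiskTrajectory:
    """Per-day predicted cumulative death risk for one patient."""

    covariates: dict
    admission: datetime
    horizon: int
    points: tuple[tuple[int, float], ...]  # (day, probability)

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.points])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["day", "probability"])
        for k, v in self.covariates.items():
            df[k] = v
        df["admission"] = self.admission
        return df


def _records_for_horizon(
    covariates: Mapping, admission: datetime, horizon: int
) -> pd.DataFrame:
    rows = []
    for d in range(1, horizon + 1):
        rows.append(
            {
                "admission": admission,
                "discharge": admission + timedelta(days=d),
                "age": covariates["age"],
                "gender": covariates["gender"],
                "charlson": covariates["charlson"],
                "icd10_codes": covariates.get("icd10_codes", ""),
                "drg": covariates.get("drg", "OTH"),
                "route": covariates.get("route", "non-ED"),
            }
        )
    return pd.DataFrame(rows)


def forecast_trajectory(
    model: FittedModel,
    covariates: Mapping,
    admission: datetime,
    horizon: int,
) -> RiskTrajectory:
    """Risk trajectory over hypothetical continued stay.

    ``covariates`` must provide ``age``, ``gender`` and ``charlson``.
    Requires a fine-grained exposure model (variant ``c``): coarser
    variants have no time-of-week structure to project.
    """
    if model.spec.exposure_variant != "c":
        raise ValueError("trajectories require an exposure variant 'c' model")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    for key in ("age", "gender", "charlson"):
        if key not in covariates:
            raise ValueError(f"missing covariate {key!r}")
    admission = _coerce_datetime(admission)
    records = _records_for_horizon(covariates, admission, horizon)
    # one prediction per literal record, so each trajectory point is
    # bit-identical to predict_risk on that record
    points = tuple(
        (d, float(predict_risk(model, records.iloc[[d - 1]])[0]))
        for d in range(1, horizon + 1)
    )
    return RiskTrajectory(dict(covariates), admission, horizon, points)


def trajectory_table(
    model: FittedModel,
    covariate_grid: Sequence[Mapping],
    admission_grid: Sequence[datetime],
    horizon: int,
) -> pd.DataFrame:
    """Batch driver: one trajectory per (covariates, admission) pair,
    long format, in stable grid order."""
    covariate_grid = list(covariate_grid)
    admission_grid = list(admission_grid)
    if not covariate_grid or not admission_grid:
        raise ValueError("covariate and admission grids must be non-empty")
    frames = []
    for ci, cov in enumerate(covariate_grid):
        for ai, adm in enumerate(admission_grid):
            traj = forecast_trajectory(model, cov, adm, horizon)
            df = traj.to_frame()
            df.insert(0, "patient", ci)
            df.insert(1, "admission_index", ai)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
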