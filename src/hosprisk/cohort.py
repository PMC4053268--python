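"""Synthetic admission cohorts with diurnal and weekly mortality structure.

The administrative collection the method was designed for is not public,
so this module generates cohorts that reproduce its statistical shape:
the demographic mix (eight age bands, gender split, Charlson severity
categories), a heavily right-skewed length-of-stay distribution (median
1 day, mean ≈ 3), an overall death rate in the 1–2% band with a share of
deaths falling 1–7 days after discharge, and — the key feature — death
risk that varies sinusoidally within the day (peaking in the evening)
and is elevated on weekends.

Two generation modes:

``logit-exact``
    The death indicator is Bernoulli with p = inverse-logit(β·x) where x
    is exactly the covariate vector the full risk-exposure model later
    reconstructs (age, gender, Charlson score, admission hour, 21 period
    counters).  The model is well specified, so fitted coefficients must
    recover the configured truth — the module's main purpose.

``block-hazard``
    Risk accrues as a hazard: a per-occupied-block dose with a
    sinusoidal within-day modulation (evening peak, mid-morning trough,
    nights elevated) and a weekend multiplier, plus an admission-acuity
    term weighting the hazard of the block the patient presents in —
    the admission-indexed component of the weekly mortality pattern.
    The logistic period-counter model is then only an approximation:
    this is the misspecification testbed for the claim that three
    samples per day (above the Nyquist rate for a daily cycle) capture
    the rhythm while a weekday/weekend split with a linear
    admission-hour term cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .comorbidity import HIERARCHY, charlson_index, default_mapping
from .exposure import (
    ADMISSION_TIME_NAME,
    BLOCK_ENDS,
    BLOCK_STARTS,
    DAYS,
    N_PERIODS,
    PERIOD_LABELS,
    PERIOD_NAMES,
    encode_exposure_batch,
)


class ConfigError(ValueError):
    """Invalid cohort configuration."""


#: age bands as printed in the source demographics, [low, high] years
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (0, 5), (6, 15), (16, 35), (36, 55), (56, 65), (66, 75), (76, 85), (86, 105),
)
_AGE_BAND_RAW = np.array([0.102, 0.044, 0.219, 0.252, 0.135, 0.128, 0.099, 0.022])
AGE_BAND_PROBS: tuple[float, ...] = tuple(_AGE_BAND_RAW / _AGE_BAND_RAW.sum())

_CHARLSON_RAW = np.array([0.686, 0.200, 0.068, 0.045])
CHARLSON_CATEGORY_PROBS: dict[str, float] = dict(
    zip(("zero", "mild", "moderate", "severe"), _CHARLSON_RAW / _CHARLSON_RAW.sum())
)

GENDER_PROBS: dict[str, float] = {"F": 0.547, "M": 0.453}

#: five condition groups known for day-to-day risk variation, plus a pooled rest
DRG_PROBS: dict[str, float] = {
    "OTH": 0.95, "R61": 0.01, "E02": 0.01, "F70": 0.01, "E64": 0.01, "J62": 0.01,
}

#: share of deaths dated 1–7 days post-discharge (23,819 of 201,647)
POST_DISCHARGE_DEATH_FRACTION = 23819 / 201647

#: Sunday-daytime vs Monday-daytime odds ratio used as the default
#: weekend contrast (the headline per-block-count contrast)
SUNDAY_MONDAY_OR = 1.7

#: intercept frozen from a one-off marginal calibration of the default
#: configuration to a ~1.5% overall death rate (see docs/methods.md)
DEFAULT_INTERCEPT = -9.932

#: per-block coefficients relative to the weekday-daytime level:
#: daytime care adds no extra risk, evenings and nights are elevated,
#: weekends more so, with Sunday daytime ln(1.7) above Monday daytime
_RELATIVE_PROFILE_WEEKDAY = {"night": 0.10, "daytime": 0.0, "evening": 0.20}
_RELATIVE_PROFILE_WEEKEND = {"night": 0.40, "daytime": math.log(SUNDAY_MONDAY_OR), "evening": 0.48}

#: weekday-daytime baseline level; slightly negative so the net weekly
#: dose stays a modest +0.17 logit per day of stay
_PERIOD_BASELINE = -0.15

#: non-comorbid principal-diagnosis pool (match no Charlson group)
_PRINCIPAL_CODES = ("R07.4", "A09", "S72.0", "O80", "J18.9", "K52.9", "I10", "Z38.0")


def default_true_coefficients(
    sunday_monday_or: float = SUNDAY_MONDAY_OR,
    intercept: float = DEFAULT_INTERCEPT,
) -> dict[str, float]:
    """Ground-truth full-model coefficients.

    Magnitudes are anchored to the demographic death-rate gradients the
    generator emulates: +0.055/yr of age, +0.34 for male gender, +0.40
    per Charlson point.  Period-counter coefficients follow the weekly
    risk profile the analysis is built around: daytime hospital care on
    weekdays adds no extra risk (slightly negative baseline), evenings
    and nights are elevated, weekends more so, with the weekend daytime
    blocks ``ln(sunday_monday_or)`` above Monday daytime — so the
    Sunday-daytime vs Monday-daytime per-block odds ratio equals the
    configured contrast (1.7 by default).
    """
    beta: dict[str, float] = {
        "intercept": intercept,
        "age": 0.055,
        "gender_M": 0.34,
        "charlson": 0.40,
        ADMISSION_TIME_NAME: 0.01,
    }
    for d, b in PERIOD_LABELS:
        if d in ("Sat", "Sun"):
            rel = dict(_RELATIVE_PROFILE_WEEKEND, daytime=math.log(sunday_monday_or))[b]
        else:
            rel = _RELATIVE_PROFILE_WEEKDAY[b]
        beta[f"count_{d}_{b}"] = _PERIOD_BASELINE + rel
    return beta


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions.

    LOS is log-normal with the configured median/mean (median 1 day,
    mean ≈ 3), truncated at ``los_max`` days.  ``admission_block_weights``
    are 21 probabilities over the weekly grid (uniform by default).
    """

    n_admissions: int
    seed: int = 0
    start: date = date(2005, 1, 1)
    end: date = date(2007, 12, 31)
    age_band_probs: Sequence[float] = AGE_BAND_PROBS
    gender_probs: Mapping[str, float] = field(default_factory=lambda: dict(GENDER_PROBS))
    charlson_category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(CHARLSON_CATEGORY_PROBS)
    )
    drg_probs: Mapping[str, float] = field(default_factory=lambda: dict(DRG_PROBS))
    ed_prob: float = 0.4
    los_median: float = 1.0
    los_mean: float = 3.0
    los_max: float = 180.0
    admission_block_weights: Sequence[float] | None = None
    true_coefficients: Mapping[str, float] = field(
        default_factory=default_true_coefficients
    )
    post_discharge_death_fraction: float = POST_DISCHARGE_DEATH_FRACTION
    mode: str = "logit-exact"
    # block-hazard mode parameters: a per-occupied-block hazard with a
    # first-harmonic within-day modulation (peak ~21:00 puts the trough
    # mid-morning and leaves both evenings and nights elevated), a
    # weekend multiplier, and an admission-acuity term that weights the
    # admission block's hazard — the admission-indexed component of the
    # weekly risk pattern
    base_hazard: float = 0.0003
    sinusoid_amplitude: float = 0.8
    peak_hour: float = 21.0
    weekend_multiplier: float = 1.7
    admission_acuity_weight: float = 30.0
    hazard_age_slope: float = 0.01

    def validate(self) -> None:
        if not isinstance(self.n_admissions, (int, np.integer)) or self.n_admissions < 1:
            raise ConfigError(f"n_admissions must be a positive integer, got {self.n_admissions}")
        if self.mode not in ("logit-exact", "block-hazard"):
            raise ConfigError(f"unknown generation mode {self.mode!r}")
        if self.end < self.start:
            raise ConfigError("date range end precedes start")
        for name, vec in (
            ("age_band_probs", list(self.age_band_probs)),
            ("gender_probs", list(self.gender_probs.values())),
            ("charlson_category_probs", list(self.charlson_category_probs.values())),
            ("drg_probs", list(self.drg_probs.values())),
        ):
            v = np.asarray(vec, dtype=float)
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1 (±1e-9)")
        if self.admission_block_weights is not None:
            w = np.asarray(self.admission_block_weights, dtype=float)
            if w.shape != (N_PERIODS,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    "admission_block_weights must be 21 non-negative values summing to 1"
                )
        if not (0 <= self.ed_prob <= 1) or not (
            0 <= self.post_discharge_death_fraction <= 1
        ):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.los_median <= 0 or self.los_mean < self.los_median or self.los_max <= 0:
            raise ConfigError("LOS distribution requires 0 < median <= mean and los_max > 0")
        missing = [
            k
            for k in ["intercept", "age", "gender_M", "charlson", ADMISSION_TIME_NAME]
            + list(PERIOD_NAMES)
            if k not in self.true_coefficients
        ]
        if missing:
            raise ConfigError(f"true_coefficients missing {missing}")

    def ground_truth(self) -> dict:
        """Sidecar record of the generator's truth (for recovery tests)."""
        return {
            "mode": self.mode,
            "seed": int(self.seed),
            "true_coefficients": dict(self.true_coefficients),
        }


def block_hazards(config: CohortConfig) -> np.ndarray:
    """Per-block hazards of block-hazard mode, in grid order: a cosine
    with the configured peak hour (evaluated at block midpoints) times
    the weekend multiplier on Sat/Sun."""
    mids = np.array(
        [(s + e) / 2.0 for s, e in zip(BLOCK_STARTS, BLOCK_ENDS)] * 7
    ).reshape(7, 3)
    lam = config.base_hazard * (
        1.0
        + config.sinusoid_amplitude
        * np.cos(2 * np.pi * (mids - config.peak_hour) / 24.0)
    )
    weekend = np.array([d in ("Sat", "Sun") for d in DAYS])[:, None]
    return np.where(weekend, lam * config.weekend_multiplier, lam).ravel()


# --- sampling helpers -------------------------------------------------------

_CHARLSON_SCORE_CHOICES = {
    "zero": (0,),
    "mild": (1, 2),
    "moderate": (3, 4),
    "severe": (5, 6, 7, 8),
}


def _group_tiers() -> dict[int, list[str]]:
    tiers: dict[int, list[str]] = {}
    for group, (weight, _) in default_mapping().items():
        tiers.setdefault(weight, []).append(group)
    return tiers


def _codes_for_score(target: int, rng: np.random.Generator) -> list[str]:
    """Pick comorbidity groups whose weights sum exactly to ``target``,
    respecting the hierarchy pairs, and return one code per group."""
    mapping = default_mapping()
    tiers = _group_tiers()
    excluded: set[str] = set()
    chosen: list[str] = []
    remaining = target
    for w in sorted(tiers, reverse=True):
        pool = [g for g in tiers[w] if g not in excluded]
        rng.shuffle(pool)
        for g in pool:
            if remaining >= w and g not in excluded:
                chosen.append(g)
                remaining -= w
                for mild, severe in HIERARCHY:
                    if g == severe:
                        excluded.add(mild)
                    elif g == mild:
                        excluded.add(severe)
    if remaining:  # unreachable for targets ≤ 8
        raise ConfigError(f"cannot realize Charlson score {target}")
    return [mapping[g][1][0] for g in chosen]


def _sample_admissions(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Admission instants: a uniform full week in range, a block drawn
    from the 21-block weight profile, a uniform instant in the block."""
    start_ord = config.start.toordinal()
    end_ord = config.end.toordinal()
    first_monday = start_ord + (-start_ord + 1) % 7  # toordinal(Mon) % 7 == 1
    n_weeks = (end_ord - first_monday + 1) // 7
    if n_weeks < 1:
        raise ConfigError("date range must contain at least one full Mon–Sun week")
    n = config.n_admissions
    weeks = rng.integers(0, n_weeks, size=n)
    if config.admission_block_weights is None:
        w = np.full(N_PERIODS, 1.0 / N_PERIODS)
    else:
        w = np.asarray(config.admission_block_weights, dtype=float)
    labels = rng.choice(N_PERIODS, size=n, p=w)
    weekday, block = np.divmod(labels, 3)
    starts = np.asarray(BLOCK_STARTS, dtype=float)[block]
    ends = np.asarray(BLOCK_ENDS, dtype=float)[block]
    hour = starts + rng.random(n) * (ends - starts)
    epoch = date(1970, 1, 1).toordinal()
    day_number = first_monday - epoch + 7 * weeks + weekday
    return (
        day_number.astype("datetime64[D]").astype("datetime64[s]")
        + np.round(hour * 3600).astype("timedelta64[s]")
    )


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort of admission records.

    Returns one row per admission with columns ``admission``,
    ``discharge``, ``age``, ``gender``, ``icd10_codes`` (semicolon
    joined), ``drg``, ``route``, ``death_date`` (NaT if alive),
    ``charlson`` (the generator's score), the derived outcome ``y``
    (death up to 7 days post-discharge) and the generator's own death
    probability ``true_p``.  Byte-identical for equal config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions

    admission = _sample_admissions(config, rng)

    sigma = math.sqrt(2.0 * math.log(config.los_mean / config.los_median))
    mu = math.log(config.los_median)
    los = np.minimum(rng.lognormal(mu, sigma, size=n), config.los_max)
    discharge = admission + np.round(los * 86400).astype("timedelta64[s]")

    bands = rng.choice(len(AGE_BANDS), size=n, p=np.asarray(list(config.age_band_probs)))
    lo = np.array([b[0] for b in AGE_BANDS], dtype=float)[bands]
    hi = np.array([b[1] for b in AGE_BANDS], dtype=float)[bands]
    age = np.round(lo + rng.random(n) * (hi - lo), 1)

    genders = list(config.gender_probs)
    gender = np.asarray(genders)[
        rng.choice(len(genders), size=n, p=list(config.gender_probs.values()))
    ]

    cats = list(config.charlson_category_probs)
    cat_idx = rng.choice(len(cats), size=n, p=list(config.charlson_category_probs.values()))
    scores = np.empty(n, dtype=np.int64)
    codes: list[str] = []
    principal = rng.choice(len(_PRINCIPAL_CODES), size=n)
    for i in range(n):
        target = int(rng.choice(_CHARLSON_SCORE_CHOICES[cats[cat_idx[i]]]))
        scores[i] = target
        comorbid = _codes_for_score(target, rng) if target else []
        codes.append(";".join([_PRINCIPAL_CODES[principal[i]]] + comorbid))

    drgs = list(config.drg_probs)
    drg = np.asarray(drgs)[rng.choice(len(drgs), size=n, p=list(config.drg_probs.values()))]
    route = np.where(rng.random(n) < config.ed_prob, "ED", "non-ED")

    exposure = encode_exposure_batch(admission, discharge)

    if config.mode == "logit-exact":
        beta = config.true_coefficients
        eta = (
            beta["intercept"]
            + beta["age"] * age
            + beta["gender_M"] * (gender == "M")
            + beta["charlson"] * scores
            + beta[ADMISSION_TIME_NAME] * exposure[ADMISSION_TIME_NAME].to_numpy()
            + exposure[list(PERIOD_NAMES)].to_numpy()
            @ np.array([beta[k] for k in PERIOD_NAMES])
        )
        p = expit(np.clip(eta, -35.0, 35.0))
    else:  # block-hazard
        lam = block_hazards(config)
        adm_hour = exposure[ADMISSION_TIME_NAME].to_numpy()
        adm_block = np.select([adm_hour < 8, adm_hour < 17], [0, 1], default=2)
        adm_weekday = (
            admission.astype("datetime64[D]").astype("int64") + 3
        ) % 7  # epoch day 0 = Thu
        adm_label = adm_weekday * 3 + adm_block
        cumhaz = (
            exposure[list(PERIOD_NAMES)].to_numpy() @ lam
            + config.admission_acuity_weight * lam[adm_label]
        )
        cumhaz = cumhaz * np.exp(config.hazard_age_slope * (age - 45.0))
        p = 1.0 - np.exp(-cumhaz)

    y = (rng.random(n) < p).astype(np.int64)

    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[s]")
    dead = np.flatnonzero(y == 1)
    if dead.size:
        post = rng.random(dead.size) < config.post_discharge_death_fraction
        lag_days = rng.integers(1, 8, size=dead.size)
        frac = rng.random(dead.size)
        dis_d = discharge[dead]
        adm_d = admission[dead]
        in_hosp = adm_d + (np.round(frac * ((dis_d - adm_d) / np.timedelta64(1, "s")))).astype(
            "timedelta64[s]"
        )
        post_dates = dis_d + (lag_days * 86400).astype("timedelta64[s]")
        death_date[dead] = np.where(post, post_dates, in_hosp)

    return pd.DataFrame(
        {
            "admission": admission.astype("datetime64[ns]"),
            "discharge": discharge.astype("datetime64[ns]"),
            "age": age,
            "gender": gender,
            "icd10_codes": codes,
            "drg": drg,
            "route": route,
            "death_date": death_date.astype("datetime64[ns]"),
            "charlson": scores,
            "y": y,
            "true_p": p,
        }
    )


def empirical_period_risk(records: pd.DataFrame) -> pd.DataFrame:
    """Death rate by admission block: the 21-row table behind a
    diurnal/weekly risk plot.  Blocks with no admissions get rate NaN."""
    if records.empty:
        raise ValueError("records table is empty")
    adm = pd.to_datetime(records["admission"])
    hour = adm.dt.hour + adm.dt.minute / 60.0
    block = np.select([hour < 8, hour < 17], [0, 1], default=2)
    label_idx = adm.dt.weekday.to_numpy() * 3 + block
    y = records["y"].to_numpy()
    rows = []
    for i, (d, b) in enumerate(PERIOD_LABELS):
        mask = label_idx == i
        n_i = int(mask.sum())
        deaths = int(y[mask].sum())
        rows.append(
            {
                "day": d,
                "block": b,
                "n": n_i,
                "deaths": deaths,
                "rate": deaths / n_i if n_i else np.nan,
            }
        )
    return pd.DataFrame(rows, index=list(PERIOD_NAMES))


def cohort_summary(records: pd.DataFrame) -> dict:
    """Demographic summary in the style of an admissions table: share of
    cohort and death rate by age band, gender and Charlson category,
    plus LOS statistics and the overall death rate."""
    if records.empty:
        raise ValueError("records table is empty")
    n = len(records)
    y = records["y"].to_numpy()
    age = records["age"].to_numpy()
    out: dict = {"n_admissions": n, "overall_death_rate": float(y.mean())}

    rows = []
    for lo, hi in AGE_BANDS:
        m = (age >= lo) & (age <= hi)
        rows.append(
            {
                "band": f"[{lo}-{hi}]",
                "n": int(m.sum()),
                "pct": float(m.mean()),
                "death_rate": float(y[m].mean()) if m.any() else np.nan,
            }
        )
    out["age_bands"] = pd.DataFrame(rows)

    rows = []
    for g in ("F", "M"):
        m = records["gender"].to_numpy() == g
        rows.append(
            {
                "gender": g,
                "n": int(m.sum()),
                "pct": float(m.mean()),
                "death_rate": float(y[m].mean()) if m.any() else np.nan,
            }
        )
    out["gender"] = pd.DataFrame(rows)

    if "charlson" in records:
        scores = records["charlson"].to_numpy()
    else:
        scores = np.array(
            [charlson_index(str(c).split(";")).score for c in records["icd10_codes"]]
        )
    bounds = {"zero": (0, 0), "mild": (1, 2), "moderate": (3, 4), "severe": (5, 10**9)}
    rows = []
    for cat, (lo, hi) in bounds.items():
        m = (scores >= lo) & (scores <= hi)
        rows.append(
            {
                "category": cat,
                "n": int(m.sum()),
                "pct": float(m.mean()),
                "death_rate": float(y[m].mean()) if m.any() else np.nan,
            }
        )
    out["charlson"] = pd.DataFrame(rows)

    los = (
        pd.to_datetime(records["discharge"]) - pd.to_datetime(records["admission"])
    ).dt.total_seconds() / 86400.0
    q1, q3 = np.percentile(los, [25, 75])
    out["los"] = {
        "mean": float(los.mean()),
        "std": float(los.std()),
        "median": float(los.median()),
        "iqr": float(q3 - q1),
        "max": float(los.max()),
    }
    return out
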