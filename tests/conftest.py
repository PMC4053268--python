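"""Shared fixtures and independent oracles.

The oracles deliberately avoid the implementation's code paths: the
exposure oracle scans stays minute by minute, the AUC oracle enumerates
all positive–negative pairs, the cutoff oracle searches thresholds
exhaustively, and the Charlson oracle re-reads the mapping fixture with
the csv module.
"""

from __future__ import annotations

import csv
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from hosprisk.cohort import CohortConfig, simulate_cohort
from hosprisk.exposure import DAYS, PERIOD_NAMES

FIXTURE_TSV = (
    Path(__file__).resolve().parents[1]
    / "src" / "hosprisk" / "data" / "charlson_icd10.tsv"
)


# --- exposure oracle --------------------------------------------------------

def minute_scan_exposure(admission: datetime, discharge: datetime) -> dict[str, int]:
    """Count distinct calendar block-instances per label by walking the
    closed stay interval minute by minute."""
    seen: set[tuple[int, int]] = set()  # (ordinal day, block index)
    t = admission
    one_min = timedelta(minutes=1)
    while t <= discharge:
        h = t.hour
        block = 0 if h < 8 else (1 if h < 17 else 2)
        seen.add((t.toordinal(), block))
        t += one_min
    counts = dict.fromkeys(PERIOD_NAMES, 0)
    for ordinal, block in seen:
        day = DAYS[datetime.fromordinal(ordinal).weekday()]
        blk = ("night", "daytime", "evening")[block]
        counts[f"count_{day}_{blk}"] += 1
    return counts


def hourly_scan_weekend(admission: datetime, discharge: datetime) -> tuple[float, float]:
    """Weekday/weekend LOS split by scanning whole hours (endpoints must
    be hour-aligned for exactness)."""
    weekday = weekend = 0.0
    t = admission
    one_h = timedelta(hours=1)
    while t < discharge:
        if t.weekday() >= 5:
            weekend += 1 / 24
        else:
            weekday += 1 / 24
        t += one_h
    return weekday, weekend


# --- evaluation oracles -----------------------------------------------------

def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive mean over all positive–negative pairs of
    1[s+ > s−] + ½·1[s+ = s−]."""
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


def exhaustive_cutoff(scores: np.ndarray, labels: np.ndarray):
    """Best threshold by brute force over all distinct scores; among
    ties in sens+spec prefer the higher (more specific) threshold."""
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (sens + spec, spec)
        if best is None or key > best[0]:
            best = (key, float(t), 100 * sens, 100 * spec)
    return best[1], best[2], best[3]


# --- Charlson oracle --------------------------------------------------------

def fixture_charlson_score(codes: list[str]) -> int:
    """Re-read the mapping TSV independently and score by brute force."""
    with open(FIXTURE_TSV) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    matched: dict[str, int] = {}
    for row in rows:
        prefixes = [p.strip().upper().replace(".", "") for p in row["prefixes"].split(",")]
        for code in codes:
            c = str(code).strip().upper().replace(".", "")
            if any(c.startswith(p) for p in prefixes):
                matched[row["group"]] = int(row["weight"])
                break
    if "diabetes_complicated" in matched:
        matched.pop("diabetes_uncomplicated", None)
    if "metastatic_solid_tumour" in matched:
        matched.pop("malignancy", None)
    return sum(matched.values())


# --- logistic oracle --------------------------------------------------------

def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Plain Newton–Raphson MLE for logistic regression (test oracle)."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - p)
        W = p * (1 - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """20k logit-exact admissions over 2005–2007 (default conditions)."""
    return simulate_cohort(CohortConfig(n_admissions=20_000, seed=42))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140521)


def random_stays(n: int, seed: int, max_days: float = 20.0):
    """Minute-aligned random (admission, discharge) pairs."""
    gen = np.random.default_rng(seed)
    base = datetime(2006, 1, 1)
    out = []
    for _ in range(n):
        start = base + timedelta(minutes=int(gen.integers(0, 2 * 365 * 24 * 60)))
        los_min = int(gen.integers(0, int(max_days * 24 * 60)))
        out.append((start, start + timedelta(minutes=los_min)))
    return out
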