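"""Weekly period grid and exposure encoding of hospital stays.

The risk-exposure model treats time spent in hospital as cumulative doses
of risk that vary with the time of week.  Each 24-hour day is segmented
into three clinically motivated blocks —

* ``night``   [00:00, 08:00)
* ``daytime`` [08:00, 17:00)
* ``evening`` [17:00, 24:00)

— which, crossed with the seven days of the week, yield 21 weekly sample
periods.  Three samples per day strictly exceeds the Nyquist rate (2/day)
for the one-cycle-per-day mortality rhythm seen in admission data, so the
grid can represent a daily sinusoid without aliasing; a weekday/weekend
split cannot.

A stay is encoded as 21 non-negative integer counters: counter *(day,
block)* is the number of distinct calendar block-instances with that label
whose interval intersects the closed stay interval ``[admission,
discharge]``.  Any non-empty intersection counts as one full dose; a stay
spanning the same label in two different weeks increments that counter
twice.  Timestamps are naive local clock times (no DST handling): the
grid repeats identically every calendar week.

Counter ordering is fixed and public: Mon-night, Mon-daytime,
Mon-evening, ..., Sun-evening.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

DAYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
BLOCKS: tuple[str, ...] = ("night", "daytime", "evening")

#: block start hours within a day; the implied intervals are half-open
BLOCK_STARTS: tuple[int, ...] = (0, 8, 17)
BLOCK_ENDS: tuple[int, ...] = (8, 17, 24)

#: ordered (day, block) labels of the 21 weekly sample periods
PERIOD_LABELS: tuple[tuple[str, str], ...] = tuple(
    (d, b) for d in DAYS for b in BLOCKS
)
#: feature names for the 21 period counters, in grid order
PERIOD_NAMES: tuple[str, ...] = tuple(f"count_{d}_{b}" for d, b in PERIOD_LABELS)

N_PERIODS = len(PERIOD_LABELS)
SAMPLES_PER_DAY = len(BLOCKS)
DAILY_SIGNAL_CYCLES_PER_DAY = 1

_SECONDS_PER_DAY = 86400.0
# 1970-01-01 (numpy datetime64 epoch) was a Thursday
_EPOCH_WEEKDAY = 3

ADMISSION_TIME_NAME = "admission_hour"


class PeriodGrid:
    """The fixed 21-block weekly grid.

    Exposed as a class for introspection (labels, boundaries); the grid
    itself is not configurable — alternative grids are out of scope.
    """

    days = DAYS
    blocks = BLOCKS
    labels = PERIOD_LABELS
    names = PERIOD_NAMES

    @staticmethod
    def block_bounds(block: str) -> tuple[int, int]:
        """Return the [start, end) hours of a within-day block."""
        try:
            i = BLOCKS.index(block)
        except ValueError:
            raise ValueError(f"unknown block {block!r}") from None
        return BLOCK_STARTS[i], BLOCK_ENDS[i]

    @staticmethod
    def exceeds_nyquist() -> bool:
        """Whether the within-day sampling rate exceeds the Nyquist rate
        for a one-cycle-per-day signal."""
        return SAMPLES_PER_DAY > 2 * DAILY_SIGNAL_CYCLES_PER_DAY


@dataclass(frozen=True)
class ExposureVector:
    """Encoded exposure of a single stay.

    Attributes
    ----------
    period_counts:
        21 non-negative integers in grid order (``PERIOD_NAMES``).
    admission_time:
        hour of day of admission, real in [0, 24).
    los_days:
        length of stay in days (discharge − admission).
    """

    period_counts: tuple[int, ...]
    admission_time: float
    los_days: float

    def as_dict(self) -> dict[str, float]:
        d: dict[str, float] = dict(zip(PERIOD_NAMES, self.period_counts))
        d[ADMISSION_TIME_NAME] = self.admission_time
        d["los_days"] = self.los_days
        return d

    @property
    def total_blocks(self) -> int:
        return int(sum(self.period_counts))


def _block_of_hour(hour: float) -> int:
    if hour < 8:
        return 0
    if hour < 17:
        return 1
    return 2


def assign_block(timestamp: datetime) -> tuple[str, str]:
    """Map an instant to its (day-of-week, block) label.

    Boundaries are half-open: 08:00 belongs to daytime, 17:00 to evening.
    """
    if not isinstance(timestamp, datetime):
        timestamp = _coerce_datetime(timestamp)
    day = DAYS[timestamp.weekday()]
    block = BLOCKS[_block_of_hour(timestamp.hour + timestamp.minute / 60.0)]
    return day, block


def _coerce_datetime(value) -> datetime:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid date-time: {value!r}") from exc
    if ts is pd.NaT:
        raise ValueError(f"invalid date-time: {value!r}")
    return ts.to_pydatetime()


def _global_block_index(ts: datetime) -> int:
    """Index of the block-instance containing ``ts`` in the global
    sequence of blocks since the epoch (3 per day)."""
    day_number = ts.toordinal() - datetime(1970, 1, 1).toordinal()
    return 3 * day_number + _block_of_hour(ts.hour + ts.minute / 60.0 + ts.second / 3600.0)


def _label_index_of_global(i: int) -> int:
    """Grid-order label index (Mon-night = 0) of a global block index."""
    day_number, b = divmod(i, 3)
    weekday = (day_number + _EPOCH_WEEKDAY) % 7
    return weekday * 3 + b


def encode_exposure(admission: datetime, discharge: datetime) -> ExposureVector:
    """Encode one stay into its 21 period counters.

    A zero-length stay counts its single containing block; counters are
    per calendar occurrence, so long stays accumulate doses week after
    week.
    """
    admission = _coerce_datetime(admission)
    discharge = _coerce_datetime(discharge)
    if discharge < admission:
        raise ValueError(
            f"discharge {discharge} precedes admission {admission}"
        )
    counts = [0] * N_PERIODS
    i0 = _global_block_index(admission)
    i1 = _global_block_index(discharge)
    for i in range(i0, i1 + 1):
        counts[_label_index_of_global(i)] += 1
    los = (discharge - admission).total_seconds() / _SECONDS_PER_DAY
    adm_hour = (
        admission.hour
        + admission.minute / 60.0
        + admission.second / 3600.0
        + admission.microsecond / 3.6e9
    )
    return ExposureVector(tuple(counts), adm_hour, los)


def encode_exposure_batch(
    admissions: Sequence | np.ndarray | pd.Series,
    discharges: Sequence | np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Vectorized exposure encoding for whole cohorts.

    Returns a DataFrame with the 21 counter columns (``PERIOD_NAMES``),
    ``admission_hour`` and ``los_days``.  Counting uses the closed-form
    residue arithmetic: block-instances form a global integer sequence in
    which labels repeat with period 21, so the count for label *c* over
    instances ``[i0, i1]`` is ``(i1 - c)//21 - (i0 - 1 - c)//21``.
    Equivalent to :func:`encode_exposure` row by row (tested property).
    """
    adm = pd.to_datetime(pd.Series(admissions)).to_numpy()
    dis = pd.to_datetime(pd.Series(discharges)).to_numpy()
    if np.any(pd.isna(adm)) or np.any(pd.isna(dis)):
        raise ValueError("invalid date-time in admissions/discharges")
    if np.any(dis < adm):
        bad = int(np.argmax(dis < adm))
        raise ValueError(f"discharge precedes admission at row {bad}")

    def gindex(ts: np.ndarray) -> np.ndarray:
        days = ts.astype("datetime64[D]")
        day_number = days.astype("int64")
        secs = (ts - days) / np.timedelta64(1, "s")
        hour = secs / 3600.0
        b = np.select([hour < 8, hour < 17], [0, 1], default=2)
        return 3 * day_number + b, day_number, hour

    i0, _, adm_hour = gindex(adm)
    i1, _, _ = gindex(dis)

    counts = np.empty((len(adm), N_PERIODS), dtype=np.int64)
    for label_idx in range(N_PERIODS):
        weekday, b = divmod(label_idx, 3)
        # residue of this label in the global 21-periodic block sequence
        c = ((weekday - _EPOCH_WEEKDAY) % 7) * 3 + b
        counts[:, label_idx] = (i1 - c) // 21 - (i0 - 1 - c) // 21

    out = pd.DataFrame(counts, columns=list(PERIOD_NAMES))
    out[ADMISSION_TIME_NAME] = adm_hour
    out["los_days"] = (dis - adm) / np.timedelta64(1, "s") / _SECONDS_PER_DAY
    return out


def weekday_weekend_exposure(
    admission: datetime, discharge: datetime
) -> tuple[float, float]:
    """Partition a stay's length into weekday (Mon–Fri) and weekend
    (Sat–Sun) days.  The two parts sum to ``los_days`` exactly."""
    admission = _coerce_datetime(admission)
    discharge = _coerce_datetime(discharge)
    if discharge < admission:
        raise ValueError(
            f"discharge {discharge} precedes admission {admission}"
        )
    los = (discharge - admission).total_seconds() / _SECONDS_PER_DAY
    weekend = _cumulative_weekend_days(discharge) - _cumulative_weekend_days(
        admission
    )
    return los - weekend, weekend


def _cumulative_weekend_days(ts: datetime) -> float:
    """Weekend time (in days) elapsed between the epoch and ``ts``."""
    epoch = datetime(1970, 1, 1)
    k = ts.toordinal() - epoch.toordinal()
    frac = (ts - datetime(ts.year, ts.month, ts.day)).total_seconds() / _SECONDS_PER_DAY
    # day numbers congruent to 2 or 3 mod 7 are Sat/Sun (epoch day 0 = Thu)
    full = 0
    for r in (2, 3):
        full += (k - 1 - r) // 7 - (-1 - r) // 7
    partial = frac if (k + _EPOCH_WEEKDAY) % 7 >= 5 else 0.0
    return full + partial


def weekday_weekend_exposure_batch(
    admissions, discharges
) -> pd.DataFrame:
    """Vectorized :func:`weekday_weekend_exposure`; columns
    ``los_weekday``, ``los_weekend``."""
    adm = pd.to_datetime(pd.Series(admissions)).to_numpy()
    dis = pd.to_datetime(pd.Series(discharges)).to_numpy()
    if np.any(dis < adm):
        raise ValueError("discharge precedes admission")

    def cum_weekend(ts: np.ndarray) -> np.ndarray:
        days = ts.astype("datetime64[D]")
        k = days.astype("int64")
        frac = (ts - days) / np.timedelta64(1, "s") / _SECONDS_PER_DAY
        full = np.zeros_like(k)
        for r in (2, 3):
            full = full + (k - 1 - r) // 7 - (-1 - r) // 7
        is_weekend = (k + _EPOCH_WEEKDAY) % 7 >= 5
        return full + np.where(is_weekend, frac, 0.0)

    los = (dis - adm) / np.timedelta64(1, "s") / _SECONDS_PER_DAY
    weekend = cum_weekend(dis) - cum_weekend(adm)
    return pd.DataFrame({"los_weekday": los - weekend, "los_weekend": weekend})


def exposure_feature_names(variant: str) -> list[str]:
    """Covariate names for the three time-exposure model variants.

    * ``a``: raw length of stay — 1 covariate;
    * ``b``: weekday/weekend split plus admission time — 3 covariates;
    * ``c``: the 21 period counters plus admission time — 22 covariates.
    """
    if variant == "a":
        return ["los_days"]
    if variant == "b":
        return ["los_weekday", "los_weekend", ADMISSION_TIME_NAME]
    if variant == "c":
        return list(PERIOD_NAMES) + [ADMISSION_TIME_NAME]
    raise ValueError(f"unknown exposure variant {variant!r}; expected a, b or c")
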