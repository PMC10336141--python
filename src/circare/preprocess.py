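"""Quality control for raw actigraphy: nonwear detection, day scoring, imputation.

The pipeline turns a raw epoch series (possibly with device gaps and off-wrist
periods) into a gap-free concatenation of valid days:

1. :func:`detect_nonwear` — runs of consecutive zero counts are flagged as
   off-wrist time. Because genuine stillness is common at night, the threshold
   is clock-time dependent: a zero run of >= 15 min whose span lies entirely
   inside 08:00-23:00 is nonwear, while a run touching the 23:00-08:00 window
   must last >= 3 h to count. Diary-reported off-wrist intervals are always
   nonwear.
2. :func:`score_days` — each complete calendar day is valid when it has at
   least 20 h of wear and no missing run longer than 3 consecutive hours.
3. :func:`impute` — missing epochs (nonwear or device gaps, treated alike) are
   filled first with the mean of the same clock time on the other complete
   days, then any remainder with the mean of the ~6 nearest observed epochs.
4. :func:`select_valid` — keep valid days only; a subject needs >= 3 of them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    ImputationError,
    InsufficientDataError,
    InvalidInputError,
)
from .series import EpochSeries

__all__ = [
    "WearMask",
    "DayQuality",
    "detect_nonwear",
    "score_days",
    "impute",
    "select_valid",
    "preprocess",
    "DAYTIME_START_MINUTE",
    "DAYTIME_END_MINUTE",
    "DAY_ZERO_RUN_MIN",
    "NIGHT_ZERO_RUN_MIN",
    "MIN_WEAR_HOURS",
    "MAX_MISSING_RUN_HOURS",
    "MIN_VALID_DAYS",
]

# Clock window in which short zero runs are already suspicious (08:00-23:00).
DAYTIME_START_MINUTE = 8 * 60
DAYTIME_END_MINUTE = 23 * 60
DAY_ZERO_RUN_MIN = 15          # minutes of zeros -> nonwear inside the window
NIGHT_ZERO_RUN_MIN = 180       # minutes of zeros -> nonwear elsewhere
MIN_WEAR_HOURS = 20.0
MAX_MISSING_RUN_HOURS = 3.0
MIN_VALID_DAYS = 3


@dataclass
class WearMask:
    """Per-epoch wear flag aligned to an :class:`EpochSeries`.

    ``wear[i]`` is True when epoch *i* carries usable on-wrist data; nonwear
    and device-gap (NaN) epochs are False.
    """

    wear: np.ndarray

    def __post_init__(self) -> None:
        self.wear = np.asarray(self.wear, dtype=bool)

    def __len__(self) -> int:
        return len(self.wear)


@dataclass
class DayQuality:
    date: dt.date
    wear_hours: float
    longest_missing_run: float  # hours
    valid: bool
    start: int = 0   # slice of the parent series covering this day
    stop: int = 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_nonwear(series: EpochSeries, diary=None) -> WearMask:
    """Flag off-wrist epochs by zero-run rules and an optional diary.

    Parameters
    ----------
    series : EpochSeries
        Raw counts; NaN epochs are device gaps and are marked not-worn.
    diary : list of (start, end) pairs, optional
        Reported off-wrist intervals (half-open, local time); must lie within
        the recording span.
    """
    counts = series.counts
    observed = ~np.isnan(counts)
    if observed.any() and np.nanmin(counts) < 0:
        raise InvalidInputError("negative activity counts")

    wear = observed.copy()
    mod = series.minute_of_day()
    per_min = series.epoch_minutes

    zero = observed & (counts == 0)
    for start, stop in _runs(zero):
        length_min = (stop - start) * per_min
        span_mod = mod[start:stop]
        inside_daytime = (
            np.all(span_mod >= DAYTIME_START_MINUTE)
            and np.all(span_mod + per_min <= DAYTIME_END_MINUTE)
            and length_min <= (DAYTIME_END_MINUTE - DAYTIME_START_MINUTE)
        )
        threshold = DAY_ZERO_RUN_MIN if inside_daytime else NIGHT_ZERO_RUN_MIN
        if length_min >= threshold:
            wear[start:stop] = False

    if diary:
        t0, t1 = series.timestamps[0], series.timestamps[-1]
        for interval in diary:
            a, b = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
            if b <= a:
                raise InvalidInputError(f"diary interval {interval} is empty")
            if a < t0 or b > t1 + pd.Timedelta(seconds=series.epoch_seconds):
                raise InvalidInputError(
                    f"diary interval {interval} falls outside the recording span"
                )
            sel = (series.timestamps >= a) & (series.timestamps < b)
            wear[np.asarray(sel)] = False

    return WearMask(wear)


def score_days(series: EpochSeries, mask: WearMask) -> list[DayQuality]:
    """Score every complete calendar day; partial first/last days are dropped."""
    if len(mask) != len(series):
        raise InvalidInputError("mask is not aligned to the series")
    epd = series.epochs_per_day
    mod = series.minute_of_day()
    missing = ~mask.wear

    # complete days start at a local midnight and cover epd epochs
    midnights = np.flatnonzero(mod == 0)
    out: list[DayQuality] = []
    for start in midnights:
        stop = start + epd
        if stop > len(series):
            continue
        day_missing = missing[start:stop]
        wear_hours = (epd - int(day_missing.sum())) * series.epoch_seconds / 3600.0
        longest = max((b - a for a, b in _runs(day_missing)), default=0)
        longest_hours = longest * series.epoch_seconds / 3600.0
        valid = wear_hours >= MIN_WEAR_HOURS and longest_hours <= MAX_MISSING_RUN_HOURS
        out.append(
            DayQuality(
                date=series.timestamps[start].date(),
                wear_hours=wear_hours,
                longest_missing_run=longest_hours,
                valid=valid,
                start=int(start),
                stop=int(stop),
            )
        )
    return out


def impute(series: EpochSeries, mask: WearMask, days: list[DayQuality]) -> EpochSeries:
    """Fill missing epochs in two stages.

    Stage 1 replaces a missing epoch with the mean of observed counts at the
    same clock time on the other complete days. Stage 2 fills whatever remains
    (typically gaps recurring at a fixed clock time every day) with the mean of
    the nearest ~6 observed epochs, three on each side, shrinking at the record
    edges. Observed epochs pass through bit-exactly.
    """
    if len(mask) != len(series):
        raise InvalidInputError("mask is not aligned to the series")
    counts = series.counts.copy()
    missing = ~mask.wear
    if not missing.any():
        out = series.copy()
        out.metadata["n_imputed"] = 0
        return out

    observed_vals = np.where(missing, np.nan, counts)

    # stage 1: same clock time on the other complete days
    day_slices = [(d.start, d.stop) for d in days]
    if day_slices:
        epd = series.epochs_per_day
        stack = np.full((len(day_slices), epd), np.nan)
        for r, (a, b) in enumerate(day_slices):
            stack[r] = observed_vals[a:b]
        n_obs = np.sum(~np.isnan(stack), axis=0)
        col_sum = np.nansum(stack, axis=0)
        for r, (a, b) in enumerate(day_slices):
            row = stack[r]
            fill = np.isnan(row)
            others_n = n_obs - (~np.isnan(row)).astype(int)
            others_sum = col_sum - np.where(np.isnan(row), 0.0, row)
            ok = fill & (others_n > 0)
            counts[a:b][ok] = (others_sum[ok] / others_n[ok])
            missing[a:b] &= ~ok

    # stage 2: nearest observed neighbours (3 each side)
    still = np.flatnonzero(missing)
    if still.size:
        obs_idx = np.flatnonzero(~np.isnan(observed_vals))
        if obs_idx.size == 0:
            raise DegenerateInputError("no observed wear epochs anywhere in the record")
        for i in still:
            pos = np.searchsorted(obs_idx, i)
            before = obs_idx[max(0, pos - 3):pos]
            after = obs_idx[pos:pos + 3]
            neigh = np.concatenate([before, after])
            if neigh.size == 0:
                raise ImputationError(f"epoch {i} has no observed neighbour")
            counts[i] = observed_vals[neigh].mean()

    out = EpochSeries(series.timestamps, counts, series.epoch_seconds, dict(series.metadata))
    out.metadata["n_imputed"] = int((~mask.wear).sum())
    return out


def select_valid(series: EpochSeries, days: list[DayQuality]) -> EpochSeries:
    """Concatenate the valid days of an imputed series.

    Raises :class:`InsufficientDataError` when fewer than three days are valid.
    Non-contiguous retained days are re-indexed onto a contiguous midnight-
    aligned grid (clock phase is preserved since every day is complete); the
    original dates and a contiguity flag are recorded in ``metadata``.
    """
    valid = [d for d in days if d.valid]
    if len(valid) < MIN_VALID_DAYS:
        raise InsufficientDataError(
            f"only {len(valid)} valid day(s); at least {MIN_VALID_DAYS} required",
            n_valid=len(valid),
        )
    parts = [series.counts[d.start:d.stop] for d in valid]
    counts = np.concatenate(parts)
    if np.isnan(counts).any():
        raise InvalidInputError("select_valid expects an imputed (gap-free) series")
    first = pd.Timestamp(valid[0].date)
    ts = pd.date_range(first, periods=len(counts), freq=pd.Timedelta(seconds=series.epoch_seconds))
    dates = [d.date for d in valid]
    contiguous = all(
        (dates[i + 1] - dates[i]).days == 1 for i in range(len(dates) - 1)
    )
    meta = dict(series.metadata)
    meta.update(
        {
            "retained_dates": [d.isoformat() for d in dates],
            "contiguous_days": contiguous,
            "n_valid_days": len(valid),
        }
    )
    return EpochSeries(ts, counts, series.epoch_seconds, meta)


def preprocess(series: EpochSeries, diary=None) -> tuple[EpochSeries, dict]:
    """Full QC pipeline: nonwear -> day scoring -> imputation -> valid-day cut.

    Returns the gap-free valid-day series and a QC report dict (per-day wear
    hours, valid flags, imputed-epoch count).
    """
    mask = detect_nonwear(series, diary=diary)
    days = score_days(series, mask)
    qc = {
        "days": [
            {
                "date": d.date.isoformat(),
                "wear_hours": round(d.wear_hours, 3),
                "longest_missing_run_hours": round(d.longest_missing_run, 3),
                "valid": d.valid,
            }
            for d in days
        ],
        "n_days_scored": len(days),
        "n_valid_days": sum(d.valid for d in days),
        "n_nonwear_epochs": int((~mask.wear).sum()),
    }
    filled = impute(series, mask, days)
    qc["n_imputed_epochs"] = filled.metadata.get("n_imputed", 0)
    clean = select_valid(filled, days)
    qc["contiguous_days"] = clean.metadata["contiguous_days"]
    return clean, qc
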