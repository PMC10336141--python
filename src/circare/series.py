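"""Epoch-level activity-count time series.

The container used throughout the pipeline is :class:`EpochSeries`: a uniformly
sampled, timestamped vector of non-negative activity counts at a fixed epoch
length (60 s by default, matching wrist actigraphs that log counts per minute).
Missing epochs are stored as NaN; timestamps are naive local clock time, so the
series is aligned to the wearer's day rather than to UTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["EpochSeries", "read_activity_csv", "write_activity_csv"]


@dataclass
class EpochSeries:
    """Uniformly sampled activity counts with local timestamps.

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Naive local clock times, strictly increasing with constant spacing
        equal to ``epoch_seconds``.
    counts : numpy.ndarray
        Non-negative counts per epoch; NaN marks a missing epoch.
    epoch_seconds : int
        Epoch length in seconds (default 60).
    metadata : dict
        Free-form provenance (subject id, QC flags, retained days, ...).
    """

    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    epoch_seconds: int = 60
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.timestamps) != len(self.counts):
            raise InvalidInputError("timestamps and counts differ in length")
        if len(self.counts) < 2:
            raise InvalidInputError("an EpochSeries needs at least 2 epochs")
        if self.epoch_seconds <= 0:
            raise InvalidInputError("epoch_seconds must be a positive integer")
        step = np.diff(self.timestamps.asi8)
        if not np.all(step == self.epoch_seconds * 1_000_000_000):
            raise InvalidInputError(
                "timestamps must be strictly increasing with constant spacing "
                f"of {self.epoch_seconds} s"
            )
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and observed.min() < 0:
            raise InvalidInputError("activity counts must be non-negative")

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return len(self.counts)

    @property
    def epochs_per_day(self) -> int:
        return 86_400 // self.epoch_seconds

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_seconds / 60.0

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing (NaN) epochs."""
        return np.isnan(self.counts)

    def minute_of_day(self) -> np.ndarray:
        """Clock offset of each epoch in minutes since local midnight."""
        t = self.timestamps
        return (t.hour * 60 + t.minute + t.second / 60.0).to_numpy()

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            self.timestamps.copy(),
            self.counts.copy(),
            self.epoch_seconds,
            dict(self.metadata),
        )


def read_activity_csv(path, epoch_seconds: int = 60) -> EpochSeries:
    """Read an activity CSV with columns ``timestamp`` and ``counts``.

    Empty count cells are treated as missing epochs. Counts sampled faster than
    ``epoch_seconds`` are summed into ``epoch_seconds`` bins provided the target
    epoch is an integer multiple of the source spacing.
    """
    df = pd.read_csv(path)
    if "counts" not in df.columns or "timestamp" not in df.columns:
        raise InvalidInputError(f"{path}: need columns 'timestamp' and 'counts'")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    counts = pd.to_numeric(df["counts"], errors="coerce").to_numpy(dtype=float)
    step = np.diff(ts.asi8)
    if step.size == 0:
        raise InvalidInputError(f"{path}: need at least 2 rows")
    meta: dict = {"source": str(path)}
    if len(np.unique(step)) > 1:
        # Naive local clocks can repeat or skip an hour at daylight-saving
        # transitions; we flag the anomaly and re-grid from the first stamp
        # rather than guessing a correction.
        meta["clock_anomaly"] = True
        ts = pd.date_range(ts[0], periods=len(ts), freq=pd.Timedelta(seconds=int(step[0]) // 1_000_000_000))
        step = np.diff(ts.asi8)
    src = int(step[0]) // 1_000_000_000
    if src != epoch_seconds:
        if src <= 0 or epoch_seconds % src != 0:
            raise InvalidInputError(
                f"{path}: source epoch {src}s is not a divisor of {epoch_seconds}s"
            )
        frame = pd.Series(counts, index=ts)
        binned = frame.resample(f"{epoch_seconds}s").sum(min_count=1)
        ts, counts = binned.index, binned.to_numpy(dtype=float)
    return EpochSeries(ts, counts, epoch_seconds, metadata=meta)


def write_activity_csv(series: EpochSeries, path) -> None:
    """Write a series in the same CSV dialect that :func:`read_activity_csv` reads."""
    df = pd.DataFrame({"timestamp": series.timestamps, "counts": series.counts})
    df.to_csv(path, index=False)
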