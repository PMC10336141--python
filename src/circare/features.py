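"""Scalar circadian features of an activity record.

The headline metric is CARE (circadian activity rhythm energy): the fraction
of total signal energy carried by the ~24-h SSA sub-signal,

    CARE = sum_{i in I} ||X_i||_F^2 / ||X||_F^2,

where ``I`` indexes the eigentriples grouped as circadian. With the (default)
singular-value energy basis the Frobenius norms are the squared singular
values of the trajectory matrix, so the base / circadian / noise / other
fractions are an exact partition of unity and CARE is unitless in [0, 1].
The companion metric is the relative energy of behavioural noise — the same
ratio over sub-signals with period < 24 h plus the truncation residual.

Also provided: the classical nonparametric relative amplitude
RA = (M10 - L5) / (M10 + L5) from the most/least active consecutive 10/5 h of
the average day, and an FFT band-energy baseline for comparison with SSA.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import preprocess as pp
from . import ssa
from .exceptions import DegenerateInputError, InvalidParameterError
from .series import EpochSeries

__all__ = [
    "FeatureSet",
    "signal_energy",
    "care",
    "noise_fraction",
    "base_fraction",
    "other_fraction",
    "relative_amplitude",
    "band_energy_fft",
    "extract_features",
]


@dataclass
class FeatureSet:
    """Per-subject circadian features; the four energy fractions sum to 1."""

    care: float
    noise_fraction: float
    base_fraction: float
    other_fraction: float
    relative_amplitude: float
    m10: float              # counts/min, most active consecutive 10 h
    l5: float               # counts/min, least active consecutive 5 h
    n_valid_days: int

    def to_dict(self) -> dict:
        return asdict(self)


def signal_energy(series, t0: int = 0, span: int | None = None) -> float:
    """Energy of a discrete signal: the sum of squared values over a window.

    ``t0``/``span`` are epoch offsets into the record; units are
    (activity counts)^2 / min^2 for count-per-minute input.
    """
    x = series.counts if isinstance(series, EpochSeries) else np.asarray(series, float)
    stop = x.size if span is None else t0 + span
    if t0 < 0 or stop > x.size:
        raise InvalidParameterError("energy window outside the record")
    return float(np.sum(x[t0:stop] ** 2))


def _fraction(decomp: ssa.Decomposition, label: str) -> float:
    if not decomp.groups:
        raise InvalidParameterError("decomposition has not been grouped")
    if decomp.total_energy <= 0:
        raise DegenerateInputError("total signal energy is zero")
    return decomp.group_energy(label) / decomp.total_energy


def care(decomp: ssa.Decomposition) -> float:
    """Circadian activity rhythm energy: circadian-group energy over total."""
    return _fraction(decomp, "circadian")


def noise_fraction(decomp: ssa.Decomposition) -> float:
    """Relative energy of behavioural noise (periods < 24 h, plus residual)."""
    return _fraction(decomp, "noise")


def base_fraction(decomp: ssa.Decomposition) -> float:
    return _fraction(decomp, "base")


def other_fraction(decomp: ssa.Decomposition) -> float:
    return _fraction(decomp, "other")


def _daily_profile(series: EpochSeries) -> np.ndarray:
    """Mean count at each clock epoch across the record (the 'average day')."""
    epd = series.epochs_per_day
    mod = np.round(series.minute_of_day() / series.epoch_minutes).astype(int) % epd
    sums = np.bincount(mod, weights=series.counts, minlength=epd)
    n = np.bincount(mod, minlength=epd)
    if (n == 0).any():
        raise InvalidParameterError("average day undefined: some clock epochs unseen")
    return sums / n


def _circular_window_means(profile: np.ndarray, w: int) -> np.ndarray:
    wrapped = np.concatenate([profile, profile[: w - 1]])
    c = np.concatenate([[0.0], np.cumsum(wrapped)])
    return (c[w:] - c[:-w]) / w


def relative_amplitude(series: EpochSeries) -> tuple[float, float, float]:
    """RA = (M10 - L5)/(M10 + L5) on the average 24-h profile.

    M10/L5 are the max/min means over all circular 600-/300-min windows of the
    profile. Returns ``(ra, m10, l5)``; RA is 0 by convention when both are 0.
    """
    profile = _daily_profile(series)
    per_hour = int(round(60 / series.epoch_minutes))
    m10 = float(np.max(_circular_window_means(profile, 10 * per_hour)))
    l5 = float(np.min(_circular_window_means(profile, 5 * per_hour)))
    ra = 0.0 if m10 + l5 == 0 else (m10 - l5) / (m10 + l5)
    return ra, m10, l5


def band_energy_fft(
    series, circadian_band: tuple[float, float] = ssa.DEFAULT_CIRCADIAN_BAND,
    epoch_seconds: int = 60,
) -> float:
    """Fraction of mean-removed periodogram power inside the circadian band.

    The Fourier analogue of CARE, used as a fixed-basis comparison baseline.
    """
    if isinstance(series, EpochSeries):
        x, epoch_seconds = series.counts, series.epoch_seconds
    else:
        x = np.asarray(series, float)
    if np.isnan(x).any():
        raise InvalidParameterError("band_energy_fft requires a gap-free series")
    lo, hi = circadian_band
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    total = float(power[1:].sum())
    if total == 0:
        return 0.0
    n = x.size
    k = np.arange(1, power.size)
    period_min = (n * epoch_seconds / 60.0) / k
    in_band = (period_min >= lo) & (period_min <= hi)
    return float(power[1:][in_band].sum() / total)


def extract_features(
    raw: EpochSeries,
    diary=None,
    window_epochs: int | None = None,
    circadian_band: tuple[float, float] = ssa.DEFAULT_CIRCADIAN_BAND,
    rank: int = 50,
    energy_basis: str = "singular_values",
    seed: int = 0,
) -> tuple[FeatureSet, dict]:
    """Preprocess a raw record, run SSA, and assemble the full feature set.

    Deterministic given the configuration. Returns ``(features, qc)`` where
    ``qc`` is the preprocessing report extended with decomposition metadata.

    ``energy_basis`` selects the numerator/denominator convention for the
    energy fractions: ``"singular_values"`` (exact partition via sigma^2, the
    default) or ``"series"`` (energies of the diagonal-averaged group series
    over the preprocessed-series energy, for sensitivity analysis).
    """
    clean, qc = pp.preprocess(raw, diary=diary)
    if not np.any(clean.counts > 0):
        raise DegenerateInputError("record is all zero after preprocessing")
    L = window_epochs or ssa.default_window(len(clean), clean.epoch_seconds)
    T = ssa.embed(clean, L)
    rank = min(rank, min(T.shape))
    decomp = ssa.group_components(ssa.decompose(T, rank=rank, v0_seed=seed), circadian_band)

    if energy_basis == "singular_values":
        c = care(decomp)
        nf = noise_fraction(decomp)
        bf = base_fraction(decomp)
        of = other_fraction(decomp)
    elif energy_basis == "series":
        denom = signal_energy(clean)
        if denom <= 0:
            raise DegenerateInputError("total signal energy is zero")
        c = signal_energy(ssa.reconstruct(decomp, "circadian")) / denom
        nf = signal_energy(ssa.reconstruct(decomp, "noise")) / denom
        bf = signal_energy(ssa.reconstruct(decomp, "base")) / denom
        of = signal_energy(ssa.reconstruct(decomp, "other")) / denom
    else:
        raise InvalidParameterError(f"unknown energy_basis {energy_basis!r}")

    ra, m10, l5 = relative_amplitude(clean)
    fs = FeatureSet(
        care=c,
        noise_fraction=nf,
        base_fraction=bf,
        other_fraction=of,
        relative_amplitude=ra,
        m10=m10,
        l5=l5,
        n_valid_days=clean.metadata["n_valid_days"],
    )
    qc = dict(qc)
    qc.update(
        {
            "window_epochs": L,
            "rank": rank,
            "circadian_band_minutes": list(decomp.circadian_band),
            "energy_basis": energy_basis,
            "eigentriple_periods_min": [t.dominant_period for t in decomp.eigentriples],
            "groups": list(decomp.groups),
        }
    )
    return fs, qc
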