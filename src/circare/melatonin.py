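"""Sparse saliva-melatonin profiles: cleaning, curve fitting, validation.

Saliva melatonin is sampled only a handful of times per 24 h, so the nightly
secretion profile is recovered by fitting a parametric curve. We use a
baseline plus skewed cosine pulse ("SBCF-like"): concentration sits at a flat
daytime baseline ``H`` and rises in a single unimodal nocturnal pulse of
height ``A`` peaking at the acrophase ``phi``, with asymmetric half-widths
``w(1 - s)`` before and ``w(1 + s)`` after the peak (skew ``s``); the pulse is
clipped at zero outside its support. Melatonin amplitude is the max - min of
the fitted 24-h curve, in pg/ml.

The functional form is isolated in :func:`sbcf_curve` so an alternative
parameterisation can be swapped in without touching the fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .exceptions import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "MelatoninFit",
    "sbcf_curve",
    "clean_samples",
    "interpolate_profile",
    "fit_sbcf",
    "melatonin_amplitude",
    "validate",
]

ASSAY_RANGE = (1.0, 1000.0)  # pg/ml quantifiable by the LC-MS/MS assay
_LOW_VALUE_CUTOFF = 2.0      # pg/ml
_NIGHT_WINDOW = (120.0, 240.0)  # 03:00 +/- 1 h, minutes after midnight


def sbcf_curve(
    t_min: np.ndarray,
    baseline: float,
    amplitude: float,
    acrophase: float,
    width: float,
    skew: float,
) -> np.ndarray:
    """Evaluate the skewed baseline cosine pulse at clock minutes ``t_min``.

    ``width`` is the mean half-width (minutes); ``skew`` in (-1, 1) shifts it
    to ``width*(1-skew)`` on the rising side and ``width*(1+skew)`` on the
    falling side. The curve is 24-h periodic and never below ``baseline``.
    """
    t = np.asarray(t_min, dtype=float)
    delta = (t - acrophase + 720.0) % 1440.0 - 720.0
    w_side = np.where(delta >= 0, width * (1.0 + skew), width * (1.0 - skew))
    with np.errstate(divide="ignore", invalid="ignore"):
        phase = np.where(w_side > 0, delta / w_side, np.inf)
    pulse = np.where(np.abs(phase) <= 1.0, np.cos(0.5 * np.pi * phase), 0.0)
    return baseline + amplitude * np.clip(pulse, 0.0, None)


@dataclass
class MelatoninFit:
    baseline: float          # pg/ml
    amplitude_param: float   # pg/ml, pulse height A
    acrophase: float         # clock minutes of the peak
    width: float             # minutes, mean half-width
    skew: float              # unitless, in (-1, 1)
    fitted_curve: np.ndarray  # 24-h curve on a 1-min grid (1440 points)
    amplitude: float         # pg/ml, max - min of fitted_curve
    rss: float               # (pg/ml)^2
    n_samples: int

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.baseline, self.amplitude_param, self.acrophase, self.width, self.skew]
        )


def _as_frame(samples) -> pd.DataFrame:
    df = pd.DataFrame(samples).copy()
    required = {"timestamp", "melatonin_pg_ml"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"melatonin table needs columns {sorted(required)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if (df["melatonin_pg_ml"] < 0).any():
        raise InvalidInputError("negative melatonin concentration")
    return df.sort_values("timestamp").reset_index(drop=True)


def clean_samples(samples) -> pd.DataFrame:
    """Drop implausible night samples: < 2 pg/ml collected at 03:00 +/- 1 h.

    A low value at the nocturnal peak indicates a collection or assay problem,
    while low daytime values are physiological and are kept. Also annotates
    values outside the assay's quantifiable range in an ``assay_qc`` column.
    """
    df = _as_frame(samples)
    mod = df["timestamp"].dt.hour * 60 + df["timestamp"].dt.minute
    low_night = (df["melatonin_pg_ml"] < _LOW_VALUE_CUTOFF) & (
        (mod >= _NIGHT_WINDOW[0]) & (mod <= _NIGHT_WINDOW[1])
    )
    df = df.loc[~low_night].reset_index(drop=True)
    df["assay_qc"] = (df["melatonin_pg_ml"] >= ASSAY_RANGE[0]) & (
        df["melatonin_pg_ml"] <= ASSAY_RANGE[1]
    )
    return df


def interpolate_profile(samples, grid_minutes: float = 1.0):
    """Piecewise-linear melatonin profile over the sampled span on a 1-min grid.

    Returns ``(t_grid, values)`` where ``t_grid`` is minutes since the first
    sample; the profile is exact at the sample times.
    """
    df = _as_frame(samples)
    t0 = df["timestamp"].iloc[0]
    t = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 60.0
    y = df["melatonin_pg_ml"].to_numpy(dtype=float)
    grid = np.arange(0.0, t[-1] + 0.5 * grid_minutes, grid_minutes)
    return grid, np.interp(grid, t, y)


def fit_sbcf(samples, n_starts: int = 8, seed: int = 0) -> MelatoninFit:
    """Fit the skewed baseline cosine pulse by nonlinear least squares.

    Sparse 5-point fits are multimodal in the acrophase, so the optimiser is
    restarted from ``n_starts`` acrophases spread over 24 h and the best RSS is
    kept; a baseline-only (flat) fit acts as a floor so the returned RSS never
    exceeds the flat model's. Deterministic for a given seed and start grid.
    """
    df = _as_frame(samples)
    if len(df) < 5:
        raise InsufficientDataError(f"need >= 5 samples, got {len(df)}", n_valid=len(df))
    t0 = df["timestamp"].iloc[0]
    span_h = (df["timestamp"].iloc[-1] - t0).total_seconds() / 3600.0
    if span_h < 18:
        raise InsufficientDataError(f"samples span {span_h:.1f} h < 18 h")
    # the model is 24-h periodic: use actual clock time of each sample
    t = (df["timestamp"].dt.hour * 60 + df["timestamp"].dt.minute
         + df["timestamp"].dt.second / 60.0).to_numpy(dtype=float)
    y = df["melatonin_pg_ml"].to_numpy(dtype=float)

    ymin, ymax = float(y.min()), float(y.max())
    spread = max(ymax - ymin, 1e-6)
    flat_rss = float(np.sum((y - y.mean()) ** 2))

    def resid(p):
        return sbcf_curve(t, *p) - y

    lower = [0.0, 0.0, -720.0, 30.0, -0.8]
    upper = [max(ymax, 1e-6), max(4 * spread, 1e-3), 2160.0, 600.0, 0.8]
    best = None
    trace = []
    starts = [
        (phi0, w0)
        for phi0 in np.linspace(0.0, 1440.0, n_starts, endpoint=False)
        for w0 in (120.0, 240.0, 420.0)
    ]
    for phi0, w0 in starts:
        p0 = np.array([ymin, spread, phi0, w0, 0.0])
        p0 = np.clip(p0, lower, upper)
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        trace.append(rss)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitFailureError("SBCF fit failed from every start", rss_trace=trace)

    rss, p = best
    if rss > flat_rss + 1e-12:
        # amplitude 0 is inside the feasible set, so flat is always attainable
        p = np.array([float(np.clip(y.mean(), lower[0], upper[0])), 0.0, 0.0, 240.0, 0.0])
        rss = float(np.sum(resid(p) ** 2))
    baseline, amp, phi, width, skew = p
    grid = np.arange(1440.0)
    curve = sbcf_curve(grid, baseline, amp, phi % 1440.0, width, skew)
    return MelatoninFit(
        baseline=float(baseline),
        amplitude_param=float(amp),
        acrophase=float(phi % 1440.0),
        width=float(width),
        skew=float(skew),
        fitted_curve=curve,
        amplitude=float(curve.max() - curve.min()),
        rss=rss,
        n_samples=len(df),
    )


def melatonin_amplitude(fit: MelatoninFit) -> float:
    """Max - min of the fitted 24-h secretion curve on the 1-min grid (pg/ml)."""
    return float(fit.fitted_curve.max() - fit.fitted_curve.min())


def validate(
    features: pd.DataFrame,
    amplitudes: pd.DataFrame,
    feature_cols: tuple[str, ...] = ("care", "relative_amplitude", "noise_fraction"),
    covariates: pd.DataFrame | None = None,
    on: str = "subject",
) -> dict:
    """Pearson correlation of wearable features with melatonin amplitude.

    ``features`` and ``amplitudes`` are joined on ``subject``; the amplitude
    column is ``amplitude_pg_ml``. Returns a report dict with r, two-sided p,
    and n per feature, plus (when ``covariates`` with age/sex are supplied) the
    share of melatonin-amplitude variance explained by each predictor, from the
    R-squared drop when that predictor is removed from the joint OLS model.
    """
    merged = features.merge(amplitudes, on=on, how="inner")
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} paired subjects; need >= 3", n_valid=len(merged)
        )
    amp = merged["amplitude_pg_ml"].to_numpy(dtype=float)
    report: dict = {"n": int(len(merged)), "correlations": {}}
    for col in feature_cols:
        r, p = stats.pearsonr(merged[col].to_numpy(dtype=float), amp)
        report["correlations"][col] = {"r": float(r), "p": float(p), "n": int(len(merged))}

    if covariates is not None:
        import statsmodels.api as sm

        cov = merged.merge(covariates, on=on, how="inner")
        predictors = [feature_cols[0]] + [
            c for c in ("age", "sex") if c in cov.columns
        ]
        X_full = sm.add_constant(cov[predictors].astype(float))
        yv = cov["amplitude_pg_ml"].astype(float)
        r2_full = sm.OLS(yv, X_full).fit().rsquared
        shares = {}
        for pcol in predictors:
            rest = [c for c in predictors if c != pcol]
            X_r = sm.add_constant(cov[rest].astype(float)) if rest else np.ones((len(cov), 1))
            r2_r = sm.OLS(yv, X_r).fit().rsquared
            shares[pcol] = float(r2_full - r2_r)
        report["variance_shares"] = shares
        report["r2_full"] = float(r2_full)
    return report
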