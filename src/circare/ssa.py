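"""Singular spectrum analysis (SSA) of activity-count series.

SSA decomposes a length-``N`` series into additive sub-signals without assuming
a fixed basis: the series is embedded as an ``L x K`` Hankel trajectory matrix
(``K = N - L + 1``), the matrix is factored by SVD into eigentriples
``(sigma_i, u_i, v_i)``, and each rank-one term ``sigma_i u_i v_i^T`` is mapped
back to a series by averaging along anti-diagonals. Grouping eigentriples by
the dominant period of their component series separates the slow trend (the
*base* signal), the ~24-h circadian oscillation, and faster behavioural
fluctuations.

Because the squared singular values partition the trajectory-matrix energy
exactly (``sum_i sigma_i^2 = ||T||_F^2``), group energies are well-defined
fractions of the total; the truncated remainder is tracked as
``residual_energy`` so the partition stays exact at any rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hankel
from scipy.signal import fftconvolve
from scipy.sparse.linalg import LinearOperator, svds

from .exceptions import InvalidParameterError
from .series import EpochSeries

__all__ = [
    "TrajectoryMatrix",
    "Eigentriple",
    "Decomposition",
    "embed",
    "decompose",
    "reconstruct",
    "dominant_period",
    "group_components",
    "default_window",
    "DEFAULT_CIRCADIAN_BAND",
]

DEFAULT_CIRCADIAN_BAND = (1320.0, 1560.0)  # minutes: 24 h +/- 2 h
_DENSE_LIMIT = 512  # below this min(L, K) a dense SVD is cheaper than ARPACK


@dataclass
class TrajectoryMatrix:
    """Hankel embedding of a series: entry ``(i, j) = x[i + j]`` (0-based).

    The dense matrix is materialised lazily; energy and matrix-vector products
    are computed from the series itself, which keeps long records cheap.
    """

    series: np.ndarray
    L: int
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        N = self.series.size
        if not np.all(np.isfinite(self.series)):
            raise InvalidParameterError("trajectory matrix requires finite values")
        # L and K play symmetric roles; anything with both >= 2 embeds cleanly,
        # though L <= N/2 (see default_window) is the recommended regime.
        if not (2 <= self.L <= N - 1):
            raise InvalidParameterError(
                f"window length L={self.L} outside 2 <= L <= N-1 (N={N})"
            )

    @property
    def N(self) -> int:
        return self.series.size

    @property
    def K(self) -> int:
        return self.N - self.L + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.L, self.K)

    @property
    def values(self) -> np.ndarray:
        """The dense L x K Hankel matrix."""
        return hankel(self.series[: self.L], self.series[self.L - 1:])

    def frobenius_sq(self) -> float:
        """``||T||_F^2`` via anti-diagonal multiplicities, without densifying."""
        return float(np.sum(self.series**2 * _antidiag_counts(self.L, self.K)))

    def matvec(self, v: np.ndarray) -> np.ndarray:
        # (T v)_i = sum_j x[i+j] v_j : a correlation, done in O(N log N)
        full = fftconvolve(self.series, np.ravel(v)[::-1])
        return full[self.K - 1 : self.K - 1 + self.L]

    def rmatvec(self, u: np.ndarray) -> np.ndarray:
        full = fftconvolve(self.series, np.ravel(u)[::-1])
        return full[self.L - 1 : self.L - 1 + self.K]

    def as_operator(self) -> LinearOperator:
        return LinearOperator(
            self.shape, matvec=self.matvec, rmatvec=self.rmatvec, dtype=float
        )


def _antidiag_counts(L: int, K: int) -> np.ndarray:
    """Number of (i, j) pairs with i + j = t for an L x K matrix."""
    t = np.arange(L + K - 1)
    return np.minimum(np.minimum(t + 1, L), np.minimum(K, L + K - 1 - t)).astype(float)


@dataclass
class Eigentriple:
    """One SVD component of the trajectory matrix plus its series form."""

    index: int                    # 1-based rank order by singular value
    sigma: float
    left_vector: np.ndarray       # length L, unit norm
    right_vector: np.ndarray      # length K, unit norm
    component_series: np.ndarray  # length N, anti-diagonal averaged
    dominant_period: float | None = None  # minutes; None for trend-like


@dataclass
class Decomposition:
    eigentriples: list[Eigentriple]
    residual_energy: float
    total_energy: float
    epoch_seconds: int = 60
    groups: list[str] = field(default_factory=list)  # base/circadian/noise/other
    circadian_band: tuple[float, float] = DEFAULT_CIRCADIAN_BAND

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([e.sigma for e in self.eigentriples])

    def group_energy(self, label: str) -> float:
        """Summed ``sigma^2`` of a group; the residual is credited to noise."""
        e = sum(
            t.sigma**2 for t, g in zip(self.eigentriples, self.groups) if g == label
        )
        if label == "noise":
            e += self.residual_energy
        return float(e)

    def indices(self, label: str) -> list[int]:
        return [i for i, g in enumerate(self.groups) if g == label]


def default_window(n_epochs: int, epoch_seconds: int = 60) -> int:
    """Default SSA window: 2 days of epochs, else the largest whole number of
    days fitting in N/2. A window divisible by the 24-h period maximises
    separability of the circadian pair."""
    per_day = 86_400 // epoch_seconds
    if n_epochs >= 4 * per_day:
        return 2 * per_day
    L = (n_epochs // 2) // per_day * per_day
    if L < 2:
        raise InvalidParameterError(
            f"series of {n_epochs} epochs is too short for a day-aligned window"
        )
    return L


def embed(series: EpochSeries | np.ndarray, L: int, epoch_seconds: int | None = None) -> TrajectoryMatrix:
    """Embed a series as an L x K Hankel trajectory matrix, K = N - L + 1."""
    if isinstance(series, EpochSeries):
        return TrajectoryMatrix(series.counts, L, series.epoch_seconds)
    return TrajectoryMatrix(np.asarray(series, dtype=float), L, epoch_seconds or 60)


def _diagonal_average(sigma: float, u: np.ndarray, v: np.ndarray, counts: np.ndarray) -> np.ndarray:
    # anti-diagonal means of sigma * u v^T, via full linear convolution
    return sigma * fftconvolve(u, v) / counts


def decompose(T: TrajectoryMatrix, rank: int | None = None, v0_seed: int = 0) -> Decomposition:
    """SVD of the trajectory matrix into eigentriples sorted by descending sigma.

    For small problems (or full rank) a dense SVD is used; otherwise a truncated
    SVD runs on the Hankel matrix as a fast FFT-based linear operator with a
    deterministic start vector, so repeated runs are bit-identical.
    """
    L, K = T.shape
    m = min(L, K)
    if rank is None:
        rank = min(50, m)
    if not (1 <= rank <= m):
        raise InvalidParameterError(f"rank={rank} outside 1..min(L,K)={m}")

    total = T.frobenius_sq()
    if rank >= m or m <= _DENSE_LIMIT:
        U, s, Vt = np.linalg.svd(T.values, full_matrices=False)
        U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
        V = Vt.T
    else:
        rng = np.random.default_rng(v0_seed)
        v0 = rng.standard_normal(m)
        U, s, Vt = svds(T.as_operator(), k=rank, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, V = U[:, order], s[order], Vt[order].T

    counts = _antidiag_counts(L, K)
    triples = []
    for i in range(rank):
        u, v = U[:, i].copy(), V[:, i].copy()
        # fix the SVD sign ambiguity deterministically
        j = int(np.argmax(np.abs(u)))
        if u[j] < 0:
            u, v = -u, -v
        comp = _diagonal_average(float(s[i]), u, v, counts)
        triples.append(
            Eigentriple(
                index=i + 1,
                sigma=float(s[i]),
                left_vector=u,
                right_vector=v,
                component_series=comp,
            )
        )
    for t in triples:
        t.dominant_period = dominant_period(t, T.epoch_seconds)
    residual = max(total - float(np.sum(s**2)), 0.0)
    return Decomposition(
        eigentriples=triples,
        residual_energy=residual,
        total_energy=total,
        epoch_seconds=T.epoch_seconds,
    )


def reconstruct(decomp: Decomposition, which=None) -> np.ndarray:
    """Sum of component series for a group label, index list, or everything.

    ``which`` may be a group label ("circadian", ...), an iterable of 0-based
    eigentriple positions, or None for all retained eigentriples. Linear in its
    inputs: the reconstruction of a group equals the sum of its members'.
    """
    n = decomp.eigentriples[0].component_series.size if decomp.eigentriples else 0
    if which is None:
        idx = range(len(decomp.eigentriples))
    elif isinstance(which, str):
        idx = decomp.indices(which)
    else:
        idx = list(which)
    out = np.zeros(n)
    for i in idx:
        out += decomp.eigentriples[i].component_series
    return out


def dominant_period(triple: Eigentriple | np.ndarray, epoch_seconds: int = 60) -> float | None:
    """Dominant period of a component in minutes, or None for trend-like ones.

    A component is trend-like when more than half of its energy sits in the
    zero-frequency (DC) band; otherwise the period is the inverse of the
    arg-max frequency of the mean-removed periodogram, with ties broken toward
    the lower frequency.
    """
    x = triple.component_series if isinstance(triple, Eigentriple) else np.asarray(triple, float)
    n = x.size
    total = float(np.sum(x**2))
    if total == 0:
        return None
    dc = n * float(np.mean(x)) ** 2
    if dc / total > 0.5:
        return None
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    if spec[1:].size == 0 or not spec[1:].any():
        return None
    k = 1 + int(np.argmax(spec[1:]))  # first max = lowest frequency on ties
    return (n * epoch_seconds / 60.0) / k


def group_components(
    decomp: Decomposition, circadian_band: tuple[float, float] = DEFAULT_CIRCADIAN_BAND
) -> Decomposition:
    """Label each eigentriple base / circadian / noise / other.

    The rank-1 eigentriple is always the base signal (the non-periodic trend
    carrying the largest energy). Among the rest, a dominant period inside the
    circadian band is circadian; shorter periods are behavioural noise; longer
    or undefined periods are "other". The truncation residual is credited to
    the noise group, which keeps the four-way energy partition exact.
    """
    lo, hi = circadian_band
    if not (0 < lo < hi):
        raise InvalidParameterError(f"bad circadian band {circadian_band}")
    labels = []
    for t in decomp.eigentriples:
        if t.index == 1:
            labels.append("base")
        elif t.dominant_period is None:
            labels.append("other")
        elif lo <= t.dominant_period <= hi:
            labels.append("circadian")
        elif t.dominant_period < lo:
            labels.append("noise")
        else:
            labels.append("other")
    decomp.groups = labels
    decomp.circadian_band = (float(lo), float(hi))
    return decomp
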