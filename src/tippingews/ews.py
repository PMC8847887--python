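"""Generic early-warning-signal (EWS) indicators.

Critical slowing down inflates the variance and short-lag memory of
fluctuations around a drifting equilibrium.  The classical pipeline is:
detrend the series with a Gaussian kernel smoother, slide a window over the
residuals, compute an indicator per window position, and summarise the
resulting track by its Kendall rank correlation with time (a positive tau
means a rising indicator, i.e. an approaching transition).

Indicators follow the standard EWS-toolbox definitions:

======  ==============================================================
SD      sample standard deviation of the window residuals
CV      SD divided by |mean| of the *original* (un-detrended) window
AR1     lag-1 autocorrelation (Pearson) of the window residuals
ACF1    conditional-least-squares AR(1) coefficient (x[t+1] ~ x[t])
RR      return rate, 1 / |AR1|
DR      density ratio: periodogram power in the lowest 5% of
        frequencies over power in the top 50%
======  ==============================================================

Feature vectors concatenate the tau summaries over a grid of bandwidths and
window sizes, ordered indicator-major, then bandwidth, then window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "EWSConfig",
    "IndicatorTrack",
    "INDICATORS",
    "detrend",
    "rolling_indicator",
    "kendall_tau",
    "ews_feature_vector",
    "feature_names",
]

INDICATORS = ("ACF1", "SD", "CV", "RR", "DR", "AR1")

#: density-ratio band edges as fractions of the positive frequency axis
DR_LOW_FRACTION = 0.05
DR_HIGH_FRACTION = 0.50


@dataclass(frozen=True)
class EWSConfig:
    """Grid of smoothing bandwidths and rolling-window sizes.

    ``units_mode`` controls whether bandwidths/windows are percentages of
    the series length ("percent", the toolbox convention) or absolute
    numbers of points ("points").
    """

    bandwidths: tuple[float, ...] = (20.0, 30.0, 40.0)
    window_sizes: tuple[float, ...] = (40.0, 50.0, 60.0)
    indicators: tuple[str, ...] = INDICATORS
    units_mode: str = "percent"

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bandwidths) or any(w <= 0 for w in self.window_sizes):
            raise ValueError("bandwidths and window sizes must be positive")
        unknown = set(self.indicators) - set(INDICATORS)
        if unknown:
            raise ValueError(f"unknown indicators {sorted(unknown)}; valid: {INDICATORS}")
        if self.units_mode not in ("percent", "points"):
            raise ValueError("units_mode must be 'percent' or 'points'")

    def bandwidth_points(self, bw: float, length: int) -> float:
        return bw * length / 100.0 if self.units_mode == "percent" else bw

    def window_points(self, w: float, length: int) -> int:
        pts = w * length / 100.0 if self.units_mode == "percent" else w
        return max(2, int(round(pts)))


@dataclass
class IndicatorTrack:
    """One indicator's rolling-window values and their trend statistic."""

    indicator: str
    window: int
    bandwidth: float
    values: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        if np.isfinite(self.tau) and not (-1.0 - 1e-12 <= self.tau <= 1.0 + 1e-12):
            raise ValueError("tau must lie in [-1, 1]")


def detrend(series: np.ndarray, bandwidth: float) -> np.ndarray:
    """Subtract a Gaussian-kernel smoothed trend.

    ``bandwidth`` is the kernel standard deviation in points.  Weights are
    renormalised at the edges, so a constant series yields exactly zero
    residuals and output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("series must have length >= 3")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    idx = np.arange(x.size)
    d = idx[:, None] - idx[None, :]
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    norm = w.sum(axis=1)
    if np.any(norm < np.finfo(float).tiny) or not np.all(np.isfinite(w)):
        raise ValueError(f"bandwidth {bandwidth} degenerates the kernel weights")
    trend = (w @ x) / norm
    return x - trend


def _sliding_sums(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling sum and sum of squares via cumulative sums."""
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    return s1, s2


def _rolling_sd(x: np.ndarray, window: int) -> np.ndarray:
    s1, s2 = _sliding_sums(x, window)
    var = (s2 - s1 * s1 / window) / (window - 1)
    return np.sqrt(np.maximum(var, 0.0))


def _rolling_lag1_sums(x: np.ndarray, window: int):
    """Per-window sums over the (x[t], x[t+1]) pairs, m = window - 1 pairs."""
    a, b = x[:-1], x[1:]
    m = window - 1
    ca = np.concatenate(([0.0], np.cumsum(a)))
    cb = np.concatenate(([0.0], np.cumsum(b)))
    caa = np.concatenate(([0.0], np.cumsum(a * a)))
    cbb = np.concatenate(([0.0], np.cumsum(b * b)))
    cab = np.concatenate(([0.0], np.cumsum(a * b)))
    sl = slice(m, None)
    sa = ca[sl] - ca[:-m]
    sb = cb[sl] - cb[:-m]
    saa = caa[sl] - caa[:-m]
    sbb = cbb[sl] - cbb[:-m]
    sab = cab[sl] - cab[:-m]
    return sa, sb, saa, sbb, sab, m


def _rolling_ar1(x: np.ndarray, window: int) -> np.ndarray:
    """Lag-1 Pearson autocorrelation per window."""
    sa, sb, saa, sbb, sab, m = _rolling_lag1_sums(x, window)
    cov = sab - sa * sb / m
    va = saa - sa * sa / m
    vb = sbb - sb * sb / m
    denom = np.sqrt(np.maximum(va, 0.0) * np.maximum(vb, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    return r


def _rolling_acf1(x: np.ndarray, window: int) -> np.ndarray:
    """Conditional-least-squares AR(1) slope (x[t+1] on x[t], intercept)."""
    sa, sb, saa, sbb, sab, m = _rolling_lag1_sums(x, window)
    cov = sab - sa * sb / m
    va = saa - sa * sa / m
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(va > 0, cov / np.where(va > 0, va, 1.0), np.nan)
    return slope


def _rolling_dr(x: np.ndarray, window: int) -> np.ndarray:
    """Spectral density ratio per window: low-band over high-band power."""
    from numpy.lib.stride_tricks import sliding_window_view

    wins = sliding_window_view(x, window)
    spec = np.abs(np.fft.rfft(wins, axis=-1)) ** 2
    spec = spec[:, 1:]  # drop DC
    nf = spec.shape[1]
    n_low = max(1, int(np.floor(DR_LOW_FRACTION * nf)))
    n_high = max(1, int(np.floor(DR_HIGH_FRACTION * nf)))
    low = spec[:, :n_low].sum(axis=1)
    high = spec[:, nf - n_high :].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(high > 0, low / np.where(high > 0, high, 1.0), np.nan)


def rolling_indicator(
    residuals: np.ndarray,
    window: int,
    indicator: str,
    original: np.ndarray | None = None,
) -> np.ndarray:
    """One indicator evaluated at every rolling-window position.

    ``original`` (the un-detrended series) is required for CV, whose
    denominator is the raw window mean.  Degenerate windows (zero variance
    for the autocorrelation family, |AR1| = 0 for RR) yield NaN.
    """
    x = np.asarray(residuals, dtype=float)
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    if not 2 <= window <= x.size:
        raise ValueError(f"window {window} invalid for series of length {x.size}")
    if indicator == "SD":
        return _rolling_sd(x, window)
    if indicator == "CV":
        if original is None:
            raise ValueError("CV needs the original (un-detrended) series")
        orig = np.asarray(original, dtype=float)
        s1, _ = _sliding_sums(orig, window)
        mean = s1 / window
        sd = _rolling_sd(x, window)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(np.abs(mean) > 0, sd / np.abs(np.where(mean != 0, mean, 1.0)), np.nan)
        n_bad = int(np.sum(~np.isfinite(out)))
        if n_bad:
            log.debug("CV: %d windows with zero mean -> NaN", n_bad)
        return out
    if indicator == "AR1":
        out = _rolling_ar1(x, window)
    elif indicator == "ACF1":
        out = _rolling_acf1(x, window)
    elif indicator == "RR":
        ar1 = _rolling_ar1(x, window)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(np.abs(ar1) > 0, 1.0 / np.abs(np.where(ar1 != 0, ar1, 1.0)), np.nan)
    else:  # DR
        out = _rolling_dr(x, window)
    n_bad = int(np.sum(~np.isfinite(out)))
    if n_bad:
        log.debug("%s: %d degenerate windows -> NaN", indicator, n_bad)
    return out


def kendall_tau(values: np.ndarray) -> float:
    """Tie-corrected Kendall tau-b of a track against its time index.

    Non-finite entries are dropped (pairwise with their index); fewer than
    two finite values, or an all-tied track, give NaN.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    v = v[finite]
    if v.size < 2:
        warnings.warn("kendall_tau: fewer than 2 finite values", stacklevel=2)
        return float("nan")
    t = np.flatnonzero(finite)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau, _ = stats.kendalltau(t, v)
    return float(tau)


def indicator_track(
    series: np.ndarray,
    indicator: str,
    bandwidth: float,
    window: float,
    config: EWSConfig | None = None,
) -> IndicatorTrack:
    """Detrend, roll one indicator, and attach its Kendall tau."""
    config = config or EWSConfig()
    x = np.asarray(series, dtype=float)
    bw_pts = config.bandwidth_points(bandwidth, x.size)
    win_pts = config.window_points(window, x.size)
    if win_pts > x.size:
        raise ValueError(
            f"series of length {x.size} is shorter than window {window} "
            f"({win_pts} points)"
        )
    resid = detrend(x, bw_pts)
    vals = rolling_indicator(resid, win_pts, indicator, original=x)
    return IndicatorTrack(
        indicator=indicator,
        window=win_pts,
        bandwidth=bw_pts,
        values=vals,
        tau=kendall_tau(vals),
    )


def feature_names(config: EWSConfig | None = None) -> list[str]:
    """Names of the concatenated features, in emission order."""
    config = config or EWSConfig()
    return [
        f"{ind}_bw{bw:g}_w{w:g}"
        for ind in config.indicators
        for bw in config.bandwidths
        for w in config.window_sizes
    ]


def ews_feature_vector(series: np.ndarray, config: EWSConfig | None = None) -> np.ndarray:
    """Kendall-tau trend of every (indicator, bandwidth, window) combination.

    Fixed ordering: indicators in config order, then bandwidths ascendingly
    as given, then windows.  Tracks whose tau is undefined (e.g. constant
    input) contribute 0, with a logged warning.
    """
    config = config or EWSConfig()
    x = np.asarray(series, dtype=float)
    largest = max(config.window_points(w, x.size) for w in config.window_sizes)
    if largest > x.size:
        raise ValueError(
            f"series of length {x.size} too short for the largest window "
            f"({largest} points)"
        )
    resid_by_bw = {
        bw: detrend(x, config.bandwidth_points(bw, x.size)) for bw in set(config.bandwidths)
    }
    feats = []
    for ind in config.indicators:
        for bw in config.bandwidths:
            resid = resid_by_bw[bw]
            for w in config.window_sizes:
                win_pts = config.window_points(w, x.size)
                vals = rolling_indicator(resid, win_pts, ind, original=x)
                finite = vals[np.isfinite(vals)]
                degenerate = finite.size < 2 or (
                    # all-tied track up to float rounding (e.g. constant input)
                    np.ptp(finite) <= 1e-10 * max(1.0, float(np.abs(finite).max()))
                )
                tau = float("nan") if degenerate else kendall_tau(vals)
                if not np.isfinite(tau):
                    log.warning(
                        "feature %s_bw%g_w%g: undefined tau mapped to 0", ind, bw, w
                    )
                    tau = 0.0
                feats.append(tau)
    return np.asarray(feats)
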