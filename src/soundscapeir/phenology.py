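"""Acoustic phenology: intensity series, lagged correlations, cycle models.

Each separated channel is reduced to a relative intensity series (per-frame
frequency-integrated energy, min-max normalized to [0, 1]).  Recurring
patterns are quantified with time-lagged Pearson correlations — the
autocorrelation of one source, or the cross-correlation between two — whose
moving-maximum envelope exposes diurnal, lunar, and seasonal recurrence as
peaks at the corresponding lags.  Diurnal, lunar, and seasonal activity
profiles are modeled by pooling intensities into cycle bins (10-minute bins
by time of day; daily bins folded on the 29.53-day synodic month or the
calendar year) and fitting a periodic cubic spline through the per-bin 95th
percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks

__all__ = [
    "IntensitySeries",
    "LagCorrelation",
    "CycleModel",
    "intensity_series",
    "lag_correlation",
    "cycle_model",
    "SYNODIC_DAYS",
    "LUNAR_EPOCH",
]

#: synodic month length used to fold the lunar cycle
SYNODIC_DAYS = 29.530588
#: reference new moon for lunar-phase folding (configurable per call)
LUNAR_EPOCH = np.datetime64("2000-01-06T18:14:00", "s")


@dataclass
class IntensitySeries:
    """Relative intensity of one separated source over absolute time."""

    time_axis: np.ndarray  # datetime64[s], uniform spacing
    values: np.ndarray  # in [0, 1]
    label: str = ""

    @property
    def dt_seconds(self) -> float:
        if len(self.time_axis) < 2:
            return float("nan")
        return float(
            (self.time_axis[1] - self.time_axis[0]) / np.timedelta64(1, "s")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time_axis, "value": self.values})

    def pooled(self, bin_seconds: float) -> "IntensitySeries":
        """Pool the series into fixed time bins (mean per bin).

        Mirrors the study convention of pooling intensities (e.g. 10-minute
        bins for diurnal analysis) before correlation or cycle fitting;
        pooling also averages down frame-level amplitude jitter so lag peaks
        resolve at the pooled-frame scale.
        """
        t = self.time_axis.astype("datetime64[s]")
        step = np.timedelta64(int(round(bin_seconds)), "s")
        idx = ((t - t[0]) / np.timedelta64(1, "s") // bin_seconds).astype(int)
        n_bins = idx[-1] + 1
        sums = np.bincount(idx, weights=self.values, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return IntensitySeries(
            time_axis=t[0] + np.arange(n_bins) * step, values=vals, label=self.label
        )


@dataclass
class LagCorrelation:
    """Correlation scores per time lag with a moving-maximum envelope."""

    lags_seconds: np.ndarray
    scores: np.ndarray  # NaN where overlap insufficient
    envelope: np.ndarray
    peaks: list[tuple[float, float]]  # envelope (lag_seconds, score) local maxima
    score_peaks: list[tuple[float, float]]  # raw-score local maxima

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_days": self.lags_seconds / 86400.0,
                "score": self.scores,
                "envelope": self.envelope,
            }
        )


@dataclass
class CycleModel:
    """Binned cycle statistics with a periodic cubic spline through the q95."""

    kind: str  # diurnal | lunar | seasonal
    period_days: float
    bin_centers: np.ndarray  # cycle position in days, within [0, period)
    q95: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    spline: CubicSpline

    def __call__(self, position_days: np.ndarray) -> np.ndarray:
        # map into the spline's knot span [c0, c0 + period) before evaluating
        c0 = float(self.bin_centers[0])
        pos = np.mod(np.asarray(position_days, dtype=np.float64) - c0, self.period_days)
        return self.spline(pos + c0)


def intensity_series(
    source_grid,
    mask_ranges: Sequence[tuple] = (),
    label: str = "",
    time_axis: np.ndarray | None = None,
) -> IntensitySeries:
    """Integrate a separated grid over frequency and min-max normalize.

    ``mask_ranges`` are (start, end) absolute-time intervals whose frames are
    forced to 0 before normalization (e.g. periods corrupted by broadband
    interference).  A constant series degenerates to all zeros with a
    warning.
    """
    if hasattr(source_grid, "Pw"):
        grid = source_grid.Pw
        time_axis = source_grid.time_axis
    else:
        grid = np.asarray(source_grid)
        if time_axis is None:
            raise ValueError("time_axis required when passing a bare array")
    if (grid < 0).any():
        raise ValueError("source grid must be nonnegative")
    values = grid.sum(axis=0).astype(np.float64)
    t = np.asarray(time_axis).astype("datetime64[s]")
    for start, end in mask_ranges:
        s = np.datetime64(start, "s")
        e = np.datetime64(end, "s")
        values[(t >= s) & (t < e)] = 0.0
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        warnings.warn("constant intensity series; returning all zeros", stacklevel=2)
        return IntensitySeries(time_axis=t, values=np.zeros_like(values), label=label)
    return IntensitySeries(time_axis=t, values=(values - lo) / (hi - lo), label=label)


def _lagged_pearson(a: np.ndarray, b: np.ndarray, lag: int, min_frac: float) -> float:
    """Pearson correlation of a[t] with b[t+lag] on pairwise-complete samples."""
    n = len(a)
    if lag >= 0:
        x, y = a[: n - lag] if lag else a, b[lag:]
    else:
        x, y = a[-lag:], b[: n + lag]
    ok = np.isfinite(x) & np.isfinite(y)
    nominal = n - abs(lag)
    if nominal < 3 or ok.sum() < max(3, min_frac * nominal):
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _plateau_peaks(
    curve: np.ndarray, lags: np.ndarray, prominence: float
) -> list[tuple[float, float]]:
    filled = np.where(np.isfinite(curve), curve, -np.inf)
    idx, props = find_peaks(filled, prominence=prominence, plateau_size=1)
    out = []
    for k, left, right in zip(idx, props["left_edges"], props["right_edges"]):
        mid = (left + right) // 2
        out.append((float(lags[mid]), float(curve[mid])))
    return out


def lag_correlation(
    a: IntensitySeries,
    b: IntensitySeries | None = None,
    max_lag: float = 2.0 * 86400.0,
    envelope_window: float = 86400.0,
    min_overlap: float = 0.5,
    peak_prominence: float = 0.01,
) -> LagCorrelation:
    """Time-lagged Pearson correlation with a moving-maximum envelope.

    ``b is None`` (or ``b is a``) gives the autocorrelation, computed for
    nonnegative lags and mirrored; otherwise the cross-correlation over
    lags in [-max_lag, +max_lag], where a positive lag means ``b`` trails
    ``a``.  Lags whose pairwise-complete overlap falls below ``min_overlap``
    of the nominal overlap are reported as NaN.  The envelope is a centered
    moving maximum over ``envelope_window`` seconds; peaks are plateau
    midpoints of envelope local maxima with the given prominence (plateau
    midpoints recover the true recurrence lag when peaks are well separated).
    """
    auto = b is None or b is a
    bb = a if auto else b
    if not auto:
        if len(a.values) != len(bb.values) or not np.array_equal(
            a.time_axis, bb.time_axis
        ):
            raise ValueError("series must share a common time grid")
    dt = a.dt_seconds
    L = int(round(max_lag / dt))
    x = np.asarray(a.values, dtype=np.float64)
    y = np.asarray(bb.values, dtype=np.float64)
    pos = np.array([_lagged_pearson(x, y, k, min_overlap) for k in range(L + 1)])
    if auto:
        scores = np.concatenate([pos[:0:-1], pos])
    else:
        neg = np.array([_lagged_pearson(x, y, -k, min_overlap) for k in range(1, L + 1)])
        scores = np.concatenate([neg[::-1], pos])
    lags = np.arange(-L, L + 1) * dt
    w = max(1, int(round(envelope_window / dt)) | 1)  # odd-sized centered window
    envelope = maximum_filter1d(
        np.where(np.isfinite(scores), scores, -np.inf), size=w, mode="nearest"
    )
    envelope = np.where(np.isfinite(envelope), envelope, np.nan)
    peaks = _plateau_peaks(envelope, lags, peak_prominence)
    score_peaks = _plateau_peaks(scores, lags, peak_prominence)
    return LagCorrelation(
        lags_seconds=lags,
        scores=scores,
        envelope=envelope,
        peaks=peaks,
        score_peaks=score_peaks,
    )


_CYCLES = {"diurnal": 1.0, "lunar": SYNODIC_DAYS, "seasonal": 365.25}


def cycle_model(
    series: IntensitySeries,
    kind: str,
    lunar_epoch: np.datetime64 = LUNAR_EPOCH,
    percentile: float = 95.0,
) -> CycleModel:
    """Fit a periodic cycle profile to a relative-intensity series.

    Diurnal: 144 ten-minute bins by time of day.  Lunar: daily pools folded
    on the synodic month from the reference new moon (30 bins of one lunar
    day).  Seasonal: daily pools folded on the calendar year into 52 weekly
    bins.  Each bin carries the 95th percentile (the spline target), mean,
    and standard deviation of its pooled values.
    """
    if kind not in _CYCLES:
        raise ValueError(f"kind must be one of {sorted(_CYCLES)}")
    period = _CYCLES[kind]
    t = series.time_axis.astype("datetime64[s]")
    dt_days = series.dt_seconds / 86400.0
    span_days = float((t[-1] - t[0]) / np.timedelta64(1, "D")) + dt_days
    if span_days < 2 * period:
        raise ValueError(
            f"{kind} model needs >= 2 full cycles ({2 * period:.1f} d), "
            f"series spans {span_days:.1f} d"
        )
    days = (t - np.datetime64("2000-01-01T00:00:00", "s")) / np.timedelta64(1, "D")
    if kind == "diurnal":
        n_bins = 144
        pos = np.mod(days, 1.0)
    elif kind == "lunar":
        n_bins = 30
        epoch_days = float(
            (np.datetime64(lunar_epoch, "s") - np.datetime64("2000-01-01T00:00:00", "s"))
            / np.timedelta64(1, "D")
        )
        pos = np.mod(np.floor(days) - epoch_days, SYNODIC_DAYS)
    else:
        n_bins = 52
        # day-of-year via pandas for calendar correctness
        doy = pd.DatetimeIndex(t).dayofyear.to_numpy() - 1
        pos = np.minimum(doy // 7, 51) * (period / 52.0)
    # epsilon guards against samples landing exactly on a bin edge in floats
    which = np.clip(
        np.floor(pos * n_bins / period + 1e-9).astype(int), 0, n_bins - 1
    )
    edges = np.linspace(0.0, period, n_bins + 1)
    q95 = np.full(n_bins, np.nan)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    v = np.asarray(series.values, dtype=np.float64)
    for i in range(n_bins):
        sel = v[which == i]
        sel = sel[np.isfinite(sel)]
        if sel.size:
            q95[i] = np.percentile(sel, percentile)
            mean[i] = sel.mean()
            sd[i] = sel.std()
    centers = 0.5 * (edges[:-1] + edges[1:])
    filled = q95.copy()
    missing = ~np.isfinite(filled)
    if missing.all():
        raise ValueError("no finite intensity values to bin")
    if missing.any():
        # circular linear interpolation across empty bins
        good = np.nonzero(~missing)[0]
        filled[missing] = np.interp(
            centers[missing],
            np.concatenate([centers[good] - period, centers[good], centers[good] + period]),
            np.tile(filled[good], 3),
        )
    x = np.concatenate([centers, [centers[0] + period]])
    ycl = np.concatenate([filled, [filled[0]]])
    spline = CubicSpline(x, ycl, bc_type="periodic")
    return CycleModel(
        kind=kind,
        period_days=period,
        bin_centers=centers,
        q95=q95,
        mean=mean,
        sd=sd,
        spline=spline,
    )
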