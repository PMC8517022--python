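"""Flowering seasonality from monthly detection series.

Per pixel, the detection states are aggregated into 12 month-of-year values
(detections / cloud-free observations, pooled across years), cleaned and
weighted, and modelled by a constrained three-harmonic series

    bloom(t) = bloom0 + pow0 * ( p4  * sin(2*pi*t/4  + rho4)
                               + p6  * sin(2*pi*t/6  + rho6)
                               + p12 * sin(2*pi*t/12 + rho12) )

with ``p4 + p6 + p12 = 1`` and t the time in months (t = 1 ... 12*n over the
n = 3 replicated yearly cycles).  The 4-, 6- and 12-month periods are the
tris-annual, bis-annual and annual frequencies of the flowering signal;
``bloom0`` is the mean level, ``pow0`` the signal power, the ``p``'s the
relative proportions of each period and the ``rho``'s their phase delays.

Because ``pow0 * p_k * sin(w t + rho_k) = a_k sin(w t) + b_k cos(w t)``, the
model is linear in disguise: the weighted least-squares fit is solved exactly
in the harmonic basis and the amplitude/phase parameterization is recovered
from the linear coefficients.  The fit is therefore deterministic and global,
with no initialization sensitivity.

The fitted model is evaluated on a 365-day year; circular local maxima of the
daily series are blooming peaks and each peak's start/end days are the
nearest surrounding pits or zero days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from . import mapping

__all__ = [
    "MonthlySeries", "CleanedSeries", "BloomFit", "BloomEvent",
    "PERIODS", "SCALE", "SHOULDER_FACTOR", "N_REPLICATES", "DAYS_PER_YEAR",
    "monthly_series", "clean_series", "fit_bloom_model",
    "reconstruct_daily", "extract_bloom_events", "analyze_pixel",
    "day_to_month_time", "month_of_day",
]

#: harmonic periods in months (tris-annual, bis-annual, annual)
PERIODS = (4, 6, 12)
#: cleaned series are multiplied by 10 before fitting
SCALE = 10.0
#: shoulder months are set to -0.15 x the maximum of the scaled series
SHOULDER_FACTOR = -0.15
#: the 12-month cycle is replicated 3 times before fitting
N_REPLICATES = 3
DAYS_PER_YEAR = 365


@dataclass
class MonthlySeries:
    """Month-of-year normalized detection values for one pixel.

    ``values[m]`` is detections / cloud-free observations in calendar month
    ``m+1`` pooled across years (NaN when the month was never observed
    cloud-free).
    """

    values: np.ndarray
    obs_counts: np.ndarray
    detection_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.obs_counts = np.asarray(self.obs_counts, int)
        self.detection_counts = np.asarray(self.detection_counts, int)
        for arr in (self.values, self.obs_counts, self.detection_counts):
            if arr.shape != (12,):
                raise ValueError("monthly series must have 12 entries")

    @property
    def total_detections(self) -> int:
        return int(self.detection_counts.sum())


@dataclass
class CleanedSeries:
    """Cleaned, scaled, weighted series replicated over 3 yearly cycles."""

    values: np.ndarray   # 36 reals
    weights: np.ndarray  # 36 non-negative reals
    shoulder_value: float
    scale: float = SCALE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.weights = np.asarray(self.weights, float)
        n = 12 * N_REPLICATES
        if self.values.shape != (n,) or self.weights.shape != (n,):
            raise ValueError(f"cleaned series must have {n} entries")

    @property
    def zero_weight_months(self) -> np.ndarray:
        """Boolean mask (12,) of calendar months with weight 0."""
        return self.weights[:12] == 0


@dataclass
class BloomFit:
    """Parameters of the three-harmonic blooming model plus weighted R^2."""

    bloom0: float
    pow0: float
    p4: float
    p6: float
    p12: float
    rho4: float
    rho6: float
    rho12: float
    weighted_r2: float

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p4, self.p6, self.p12])

    @property
    def phases(self) -> np.ndarray:
        return np.array([self.rho4, self.rho6, self.rho12])

    def predict(self, t) -> np.ndarray:
        """Evaluate the fitted model at month-time ``t``."""
        t = np.asarray(t, float)
        out = np.full(t.shape, self.bloom0)
        for period, p, rho in zip(PERIODS, self.proportions, self.phases):
            out = out + self.pow0 * p * np.sin(2 * np.pi * t / period + rho)
        return out


@dataclass
class BloomEvent:
    """One flowering episode: start, peak and end day-of-year (1-365)."""

    start_day: int
    peak_day: int
    end_day: int
    peak_value: float
    start_value: float = 0.0
    end_value: float = 0.0

    @property
    def duration_days(self) -> int:
        """Circular span from start to end."""
        d = (self.end_day - self.start_day) % DAYS_PER_YEAR
        return d if d else DAYS_PER_YEAR


def monthly_series(dates, states) -> MonthlySeries:
    """Aggregate one pixel's daily observation states by calendar month.

    ``states`` uses the :mod:`bloomsat.mapping` codes; only cloud-free
    observations (detected or clear) enter the counts.
    """
    states = np.asarray(states)
    if len(dates) == 0 or states.size == 0:
        raise ValueError("empty observation series")
    months = np.array([d.month for d in dates])
    det = np.zeros(12, int)
    obs = np.zeros(12, int)
    for m in range(1, 13):
        sel = months == m
        det[m - 1] = int((states[sel] == mapping.DETECTED).sum())
        obs[m - 1] = det[m - 1] + int((states[sel] == mapping.CLEAR).sum())
    if obs.sum() == 0:
        values = np.full(12, np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(obs > 0, det / np.maximum(obs, 1), np.nan)
    return MonthlySeries(values, obs, det)


def clean_series(
    series: MonthlySeries, min_total_detections: int = 4
) -> CleanedSeries | None:
    """Apply the cleaning and weighting rules; None when the pixel is dropped.

    Rules, in order: pixels with fewer than ``min_total_detections``
    detections over the whole span are excluded; isolated peaks backed by at
    most 2 detections and flanked by zero-detection months are set to 0;
    values are multiplied by 10; the months immediately before and after each
    contiguous blooming run are set to -0.15 x the maximum of the scaled
    series (the blossom onset/offset is assumed to fall inside them); weights
    are 0 for zero months, 1 for the negative shoulder months and the value
    itself for positive months; values and weights are replicated over 3
    yearly cycles.
    """
    if series.total_detections < min_total_detections:
        return None
    vals = np.where(np.isfinite(series.values), series.values, 0.0).copy()
    det = series.detection_counts
    # isolated single-month peaks with <= 2 detections between
    # zero-detection months
    isolated = np.zeros(12, bool)
    for m in range(12):
        if vals[m] > 0 and det[m] <= 2 \
                and det[(m - 1) % 12] == 0 and det[(m + 1) % 12] == 0:
            isolated[m] = True
    vals[isolated] = 0.0
    vals *= SCALE
    positive = vals > 0
    shoulder = np.zeros(12, bool)
    if positive.any() and not positive.all():
        for m in range(12):
            if positive[m]:
                if not positive[(m - 1) % 12]:
                    shoulder[(m - 1) % 12] = True
                if not positive[(m + 1) % 12]:
                    shoulder[(m + 1) % 12] = True
    shoulder_value = SHOULDER_FACTOR * float(vals.max()) if shoulder.any() \
        else 0.0
    vals[shoulder] = shoulder_value
    weights = np.zeros(12)
    weights[positive] = vals[positive]
    weights[shoulder] = 1.0
    return CleanedSeries(
        np.tile(vals, N_REPLICATES), np.tile(weights, N_REPLICATES),
        shoulder_value,
    )


def _harmonic_design(t: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)]
    for period in PERIODS:
        w = 2 * np.pi / period
        cols.append(np.sin(w * t))
        cols.append(np.cos(w * t))
    return np.column_stack(cols)


def fit_bloom_model(cleaned: CleanedSeries) -> BloomFit:
    """Exact weighted least-squares fit of the three-harmonic model.

    Solved in the linear harmonic basis {1, sin, cos at each period}; the
    amplitude/phase form is recovered as ``A_k = hypot(a_k, b_k)``,
    ``rho_k = atan2(b_k, a_k)``, ``pow0 = sum A_k``, ``p_k = A_k / pow0``.
    The simplex constraint ``p4 + p6 + p12 = 1`` holds by construction.
    """
    w = cleaned.weights
    y = cleaned.values
    if not (w > 0).any():
        raise ValueError("all weights are zero; nothing to fit")
    if int((w > 0).sum()) < 8:
        raise ValueError("need at least 8 positively weighted points")
    t = np.arange(1, y.size + 1, dtype=float)
    X = _harmonic_design(t)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    bloom0 = float(beta[0])
    amps, phases = [], []
    for k in range(len(PERIODS)):
        a, b = beta[1 + 2 * k], beta[2 + 2 * k]
        amp = float(np.hypot(a, b))
        amps.append(amp)
        phases.append(float(np.arctan2(b, a)) if amp > 0 else 0.0)
    pow0 = float(sum(amps))
    if pow0 > 0:
        props = [a / pow0 for a in amps]
    else:
        props = [0.0, 0.0, 1.0]  # degenerate constant fit; convention
        phases = [0.0, 0.0, 0.0]
    mask = w > 0
    resid = y - X @ beta
    sse = float(np.sum(w[mask] * resid[mask] ** 2))
    ybar = float(np.sum(w[mask] * y[mask]) / np.sum(w[mask]))
    sst = float(np.sum(w[mask] * (y[mask] - ybar) ** 2))
    r2 = 1.0 if sst <= 1e-12 else 1.0 - sse / sst
    return BloomFit(bloom0, pow0, *props, *phases, weighted_r2=r2)


def day_to_month_time(day) -> np.ndarray:
    """Map day-of-year 1-365 to month-time t (month m's center maps to t=m)."""
    return 12.0 * (np.asarray(day, float) - 0.5) / DAYS_PER_YEAR + 0.5


def month_of_day(day) -> np.ndarray:
    """Calendar month index 1-12 of a day under the uniform 365-day year."""
    d = np.asarray(day)
    return (12 * (d - 0.5) / DAYS_PER_YEAR).astype(int) + 1


def reconstruct_daily(
    fit: BloomFit, zero_weight_months: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate the fitted model on all 365 days of the (circular) year.

    Predicted negative values are clamped to 0 and all days falling in
    zero-weight months (boolean mask of the 12 calendar months) are zeroed.
    """
    days = np.arange(1, DAYS_PER_YEAR + 1)
    daily = fit.predict(day_to_month_time(days))
    daily = np.maximum(daily, 0.0)
    if zero_weight_months is not None:
        zero_weight_months = np.asarray(zero_weight_months, bool)
        daily[zero_weight_months[month_of_day(days) - 1]] = 0.0
    return daily


def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Circular runs of equal values as (start_index, length, value)."""
    n = values.size
    starts = [0]
    for i in range(1, n):
        if values[i] != values[i - 1]:
            starts.append(i)
    if len(starts) > 1 and values[0] == values[-1]:
        # merge wrap-around run into the first
        starts[0] = starts.pop()
    return [(s, (starts[(j + 1) % len(starts)] - s) % n or n, values[s])
            for j, s in enumerate(starts)]


def extract_bloom_events(
    daily: np.ndarray, fit: BloomFit | None = None
) -> list[BloomEvent]:
    """Find flowering episodes in a 365-day reconstructed series.

    A peak is a circular local maximum with positive value (plateaus report
    their first day); its start/end are the nearest preceding/following day
    that is a pit (circular local minimum) or has value zero.  Events are
    sorted by peak day.

    When the ``fit`` is supplied, peak candidates are the circular local
    maxima of the fitted harmonic curve itself (at most three per year),
    kept only where the processed series is positive.  Clamping negatives
    and zeroing empty months can clip a curve lobe into spurious extra
    maxima of the processed series; anchoring the candidates on the smooth
    curve suppresses those artifacts while boundaries (pits and zero days)
    still come from the processed series.
    """
    daily = np.asarray(daily, float)
    n = daily.size
    if not (daily > 0).any():
        return []
    runs = _runs(daily)
    if len(runs) == 1:  # constant positive series: no local structure
        return []
    k = len(runs)
    peaks, boundary = [], np.zeros(n, bool)
    boundary[daily == 0] = True
    for j, (s, length, v) in enumerate(runs):
        prev_v = runs[(j - 1) % k][2]
        next_v = runs[(j + 1) % k][2]
        if fit is None and v > prev_v and v > next_v and v > 0:
            peaks.append(s)
        elif v < prev_v and v < next_v:
            boundary[s] = True  # pit run: first day marks the boundary
    if fit is not None:
        raw = fit.predict(day_to_month_time(np.arange(1, n + 1)))
        rruns = _runs(raw)
        rk = len(rruns)
        if rk > 1:
            for j, (s, length, v) in enumerate(rruns):
                if v > rruns[(j - 1) % rk][2] and v > rruns[(j + 1) % rk][2] \
                        and daily[s] > 0:
                    peaks.append(s)
    events = []
    for s in peaks:
        v = daily[s]
        start = s
        for step in range(1, n):
            d = (s - step) % n
            if boundary[d]:
                start = d
                break
        end = s
        for step in range(1, n):
            d = (s + step) % n
            if boundary[d]:
                end = d
                break
        events.append(BloomEvent(
            start_day=start + 1, peak_day=s + 1, end_day=end + 1,
            peak_value=float(v),
            start_value=float(daily[start]), end_value=float(daily[end]),
        ))
    events.sort(key=lambda e: e.peak_day)
    return events


def analyze_pixel(
    series: MonthlySeries, min_total_detections: int = 4
) -> tuple[BloomFit, np.ndarray, list[BloomEvent]] | None:
    """Clean, fit, reconstruct and extract events for one pixel.

    Returns ``(fit, daily, events)`` or ``None`` when the pixel is excluded
    by the minimum-detections rule.
    """
    cleaned = clean_series(series, min_total_detections)
    if cleaned is None or not (cleaned.weights > 0).any():
        return None
    fit = fit_bloom_model(cleaned)
    daily = reconstruct_daily(fit, cleaned.zero_weight_months)
    return fit, daily, extract_bloom_events(daily, fit)
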