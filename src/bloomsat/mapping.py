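"""Spatialize patch predictions and maintain daily observation states.

Each 1280 m grid cell gets, for every day of the study span, exactly one of
four observation states: ``detected`` (observed with a flowering stand),
``clear`` (observed, no flowering), ``cloud`` (observed but cloud covered) or
``missing`` (no scene / nodata).  Detection frequencies are expressed as a
percentage of the cloud-free observations.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING", "CLEAR", "DETECTED", "CLOUD", "STATE_NAMES",
    "ObservationSeries", "DetectionSummary",
    "spatialize_predictions", "cell_cloud_mask",
    "accumulate_daily_states", "frequency_map",
]

MISSING, CLEAR, DETECTED, CLOUD = 0, 1, 2, 3
STATE_NAMES = {MISSING: "missing", CLEAR: "clear",
               DETECTED: "detected", CLOUD: "cloud"}


@dataclass
class ObservationSeries:
    """Per-pixel, per-date observation states on the analysis grid.

    ``states`` has shape ``(n_dates, rows, cols)`` with the integer codes
    above; ``dates`` is sorted and unique.
    """

    dates: list[_dt.date]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, np.uint8)
        if self.states.ndim != 3:
            raise ValueError("states must be (n_dates, rows, cols)")
        if len(self.dates) != self.states.shape[0]:
            raise ValueError("dates length must match states")
        order = np.argsort([d.toordinal() for d in self.dates])
        self.dates = [self.dates[i] for i in order]
        self.states = self.states[order]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.states.shape[1:]

    @property
    def n_dates(self) -> int:
        return self.states.shape[0]

    def counts(self) -> dict[str, np.ndarray]:
        """Per-pixel counts of each state; they sum to ``n_dates``."""
        return {name: (self.states == code).sum(axis=0)
                for code, name in STATE_NAMES.items()}

    def pixel(self, row: int, col: int) -> np.ndarray:
        return self.states[:, row, col]

    def to_frame(self):
        """Long-format table (pixel_id, date, state)."""
        import pandas as pd

        t, r, c = np.nonzero(np.ones_like(self.states, bool))
        return pd.DataFrame({
            "pixel_id": r * self.grid_shape[1] + c,
            "date": [self.dates[i] for i in t],
            "state": [STATE_NAMES[s] for s in self.states[t, r, c]],
        })


@dataclass
class DetectionSummary:
    """Per-pixel observation-state counts and detection frequency (%)."""

    n_detected: np.ndarray
    n_clear: np.ndarray
    n_cloud: np.ndarray
    n_missing: np.ndarray
    frequency_pct: np.ndarray  # NaN where no cloud-free observation
    min_detections: int
    #: fraction of pixels with >= 1 detection in every 12-month window
    frac_detected_every_year: float = float("nan")
    median_frequency_nonzero: float = float("nan")
    frequency_interval: tuple[float, float] = (float("nan"), float("nan"))


def spatialize_predictions(
    predictions: np.ndarray, grid_shape: tuple[int, int]
) -> np.ndarray:
    """Arrange per-patch 0/1 predictions on the (rows, cols) presence grid.

    Predictions are ordered row-major (row 0 left-to-right, then row 1, ...),
    matching the tiling order of :func:`bloomsat.radiometry.tile_scene`.
    """
    predictions = np.asarray(predictions)
    rows, cols = grid_shape
    if predictions.size != rows * cols:
        raise ValueError(
            f"{predictions.size} predictions for a {rows}x{cols} grid"
        )
    return predictions.reshape(rows, cols).astype(np.uint8)


def cell_cloud_mask(
    cloud_mask: np.ndarray, cell_pixels: int, threshold: float = 0.5
) -> np.ndarray:
    """Collapse a scene-resolution cloud mask to the analysis grid.

    A cell is cloud when more than ``threshold`` of its source pixels are
    cloud-masked.  The mask is padded with clear pixels up to a multiple of
    ``cell_pixels``.
    """
    mask = np.asarray(cloud_mask, bool)
    rows, cols = mask.shape
    n_r, n_c = -(-rows // cell_pixels), -(-cols // cell_pixels)
    padded = np.zeros((n_r * cell_pixels, n_c * cell_pixels), bool)
    padded[:rows, :cols] = mask
    frac = padded.reshape(n_r, cell_pixels, n_c, cell_pixels).mean(axis=(1, 3))
    return frac > threshold


def accumulate_daily_states(
    presence_rasters: list[np.ndarray],
    cloud_cell_masks: list[np.ndarray],
    scene_dates: list[_dt.date],
    all_dates: list[_dt.date] | None = None,
) -> ObservationSeries:
    """Combine dated presence rasters and cell cloud masks into daily states.

    Cloud overrides a detection (a positive under cloud is treated as a cloud
    artifact).  Same-day duplicate scenes (overlapping orbits) merge by OR on
    detection and AND on cloud.  Days in ``all_dates`` without any scene are
    ``missing`` everywhere.
    """
    if not (len(presence_rasters) == len(cloud_cell_masks)
            == len(scene_dates)):
        raise ValueError("presence, cloud and date lists must align")
    if not scene_dates and not all_dates:
        raise ValueError("no scenes and no date span given")
    shape = np.asarray(
        presence_rasters[0] if presence_rasters else cloud_cell_masks[0]
    ).shape
    by_date: dict[_dt.date, list[int]] = {}
    for i, d in enumerate(scene_dates):
        by_date.setdefault(d, []).append(i)
    dates = sorted(set(all_dates or []) | set(scene_dates))
    states = np.full((len(dates), *shape), MISSING, np.uint8)
    for t, d in enumerate(dates):
        idx = by_date.get(d)
        if not idx:
            continue
        det = np.zeros(shape, bool)
        cloud = np.ones(shape, bool)
        for i in idx:
            det |= np.asarray(presence_rasters[i], bool)
            cloud &= np.asarray(cloud_cell_masks[i], bool)
        day = np.full(shape, CLEAR, np.uint8)
        day[det] = DETECTED
        day[cloud] = CLOUD  # cloud precedence
        states[t] = day
    return ObservationSeries(dates, states)


def _detected_every_year(series: ObservationSeries) -> float:
    """Fraction of pixels with >= 1 detection in each 12-month window."""
    start = series.dates[0].toordinal()
    offsets = np.array([d.toordinal() - start for d in series.dates])
    n_years = max(1, int(np.ceil((offsets[-1] + 1) / 365)))
    ok = np.ones(series.grid_shape, bool)
    for y in range(n_years):
        sel = (offsets >= 365 * y) & (offsets < 365 * (y + 1))
        if not sel.any():
            continue
        ok &= (series.states[sel] == DETECTED).any(axis=0)
    return float(ok.mean())


def frequency_map(
    series: ObservationSeries,
    min_detections: int = 4,
    interval_percentiles: tuple[float, float] = (2.75, 97.5),
) -> DetectionSummary:
    """Detection frequency in percent of cloud-free observations per pixel.

    Pixels with fewer than ``min_detections`` detections over the whole span
    are forced to 0%.  Pixels never observed cloud-free are NaN and excluded
    from the summary statistics.
    """
    counts = series.counts()
    n_det = counts["detected"]
    n_clear = counts["clear"]
    cloud_free = n_det + n_clear
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cloud_free > 0, 100.0 * n_det / cloud_free, np.nan)
    freq = np.where((n_det < min_detections) & (cloud_free > 0), 0.0, freq)
    nonzero = freq[np.isfinite(freq) & (freq > 0)]
    if nonzero.size:
        median = float(np.median(nonzero))
        lo, hi = np.percentile(nonzero, interval_percentiles)
        interval = (float(lo), float(hi))
    else:
        median, interval = float("nan"), (float("nan"), float("nan"))
    return DetectionSummary(
        n_detected=n_det, n_clear=n_clear, n_cloud=counts["cloud"],
        n_missing=counts["missing"], frequency_pct=freq,
        min_detections=min_detections,
        frac_detected_every_year=_detected_every_year(series),
        median_frequency_nonzero=median,
        frequency_interval=interval,
    )
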