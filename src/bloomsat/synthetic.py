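"""Seeded synthetic worlds: presence grids, phenology truth, covariates,
rendered 4-band scenes and shortcut observation series.

The generator emulates the statistical structure of the study system: a
green-forest background; spatially clumped stands of magenta-blossoming
pioneer trees whose bloom intensity follows a smooth, year-periodic seasonal
curve; pink-soil confounders; cloud occlusion; and environmental covariates
(elevation, slope, tree cover, precipitation, min/max temperature) that can
be linked to presence probability.  Every stage of the analysis pipeline can
be exercised against the recorded ground truth without any downloads.

The truth bloom-intensity curve of a pixel is a scaled Gaussian bump in
day-of-year centered on its peak day with SD = duration/4, truncated at two
SDs (so the support is exactly [start, end] = peak -/+ duration/2) and
wrapped circularly across the year boundary.  Blooming pixels are rendered
with additive offsets on the red and blue bands that grow with intensity and
always exceed the configured magenta contrast over green, so a color-rule
detector recovers currently blooming cells exactly on noiseless scenes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import mapping
from .radiometry import SceneStack

__all__ = [
    "PopulationConfig", "WorldConfig", "SyntheticWorld",
    "generate_world", "render_scene", "simulate_observations",
    "make_patch_dataset", "day_of_year", "save_world", "load_world",
    "FOREST_BASE", "CLOUD_LEVEL", "SOIL_BASE",
]

#: 12-bit base reflectance of the forest background (red, green, blue, NIR)
FOREST_BASE = (500, 1200, 400, 3800)
#: bright cloud level in all bands
CLOUD_LEVEL = 9000
#: pink-soil confounder color: red above green but blue below it
SOIL_BASE = (1800, 1200, 900, 2600)

COVARIATE_NAMES = ("elevation", "slope", "tree_cover",
                   "precipitation", "tmin", "tmax")

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class PopulationConfig:
    """Phenology and spatial footprint of one flowering population."""

    peak_day: int          # day-of-year 1-365 of the population bloom peak
    duration_days: float   # start-to-end span of the bloom episode
    amplitude: float       # peak bloom intensity, fraction in (0, 1]
    center_row: float      # spatial center, in grid-cell units
    center_col: float
    spread_cells: float    # SD of the spatial membership kernel

    def __post_init__(self) -> None:
        if not 1 <= self.peak_day <= DAYS_PER_YEAR:
            raise ValueError("peak_day must be in [1, 365]")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be a fraction in (0, 1]")


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a synthetic world; identical seed and config give a
    bit-identical world."""

    grid_rows: int = 20
    grid_cols: int = 20
    patch_pixels: int = 16            # scene pixels per grid-cell side
    populations: tuple[PopulationConfig, ...] = ()
    background_fraction: float = 0.1  # presence probability at zero link
    two_peak_fraction: float = 0.0    # presence pixels joining 2 populations
    peak_jitter_days: float = 4.0     # per-pixel SD around population peak
    cloud_prob: float = 0.0           # per scene, per grid cell
    covariate_link: dict = field(default_factory=dict)
    visibility_threshold: float = 0.05
    magenta_contrast: int = 600       # 12-bit red/blue excess over green
    noise_sd: float = 50.0            # radiometric noise SD (12-bit units)
    n_soil_patches: int = 0
    cell_size_m: float = 1280.0
    x_origin_m: float = 300_000.0
    y_origin_m: float = 7_500_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        for name in ("background_fraction", "two_peak_fraction",
                     "cloud_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.covariate_link) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariates in link: {sorted(unknown)}")

    @property
    def n_populations(self) -> int:
        return len(self.populations)


@dataclass
class SyntheticWorld:
    """A generated world: presence, phenology truth and covariates."""

    config: WorldConfig
    presence: np.ndarray                  # (rows, cols) bool
    phenology: pd.DataFrame               # one row per (pixel, population)
    covariates: dict[str, np.ndarray]
    blobs: pd.DataFrame                   # per-pixel stand geometry

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.presence.shape

    def pixel_ids(self) -> np.ndarray:
        r, c = np.nonzero(self.presence)
        return r * self.config.grid_cols + c

    def coordinates(self) -> pd.DataFrame:
        """Metric center coordinates of every grid cell."""
        rows, cols = self.grid_shape
        r, c = np.mgrid[0:rows, 0:cols]
        cfg = self.config
        return pd.DataFrame({
            "pixel_id": (r * cols + c).ravel(),
            "row": r.ravel(), "col": c.ravel(),
            "x_m": cfg.x_origin_m + (c.ravel() + 0.5) * cfg.cell_size_m,
            "y_m": cfg.y_origin_m - (r.ravel() + 0.5) * cfg.cell_size_m,
        })

    def intensity(self, date: _dt.date | int) -> np.ndarray:
        """True bloom intensity per grid cell on ``date`` (0 outside bloom).

        A two-peak pixel takes the maximum over its two truth rows.
        """
        doy = day_of_year(date)
        out = np.zeros(self.grid_shape)
        if self.phenology.empty:
            return out
        ph = self.phenology
        delta = _circular_diff(doy, ph["peak_day"].to_numpy(float))
        sigma = ph["duration_days"].to_numpy(float) / 4.0
        inside = np.abs(delta) <= 2.0 * sigma
        inten = np.where(
            inside,
            ph["amplitude"].to_numpy(float)
            * np.exp(-0.5 * (delta / sigma) ** 2),
            0.0,
        )
        np.maximum.at(out, (ph["row"].to_numpy(int), ph["col"].to_numpy(int)),
                      inten)
        return out

    def bloom_mask(self, date: _dt.date | int) -> np.ndarray:
        """Cells currently blooming (truth intensity > 0)."""
        return self.intensity(date) > 0


def day_of_year(date: _dt.date | int) -> int:
    """Day-of-year 1-365 (31 December of leap years folds onto day 365)."""
    if isinstance(date, (int, np.integer)):
        doy = int(date)
        if not 1 <= doy <= DAYS_PER_YEAR:
            raise ValueError("day-of-year must be in [1, 365]")
        return doy
    return min(date.timetuple().tm_yday, DAYS_PER_YEAR)


def _circular_diff(doy: float, peak: np.ndarray) -> np.ndarray:
    d = (doy - peak) % DAYS_PER_YEAR
    return np.where(d > DAYS_PER_YEAR / 2, d - DAYS_PER_YEAR, d)


def _smooth_field(rng: np.random.Generator, shape, sigma: float
                  ) -> np.ndarray:
    """Standardized smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma,
                                mode="wrap")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f * 0.0


def _make_covariates(rng: np.random.Generator, shape,
                     cell_size_m: float) -> dict[str, np.ndarray]:
    elev_f = _smooth_field(rng, shape, sigma=max(2, min(shape) / 8))
    elevation = 600.0 + 450.0 * elev_f
    if min(shape) >= 2:
        gy, gx = np.gradient(elevation, cell_size_m)
        slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    else:
        slope = np.zeros(shape)
    # local relief contributes sub-cell slope the coarse gradient misses
    slope = slope + 2.0 + 1.5 * np.abs(_smooth_field(rng, shape, 2))
    tree_cover = np.clip(55 + 25 * _smooth_field(rng, shape, 3)
                         + 10 * elev_f, 0, 100)
    precipitation = 1400.0 + 300.0 * _smooth_field(rng, shape, 4) \
        + 150.0 * elev_f
    tmin = 16.0 - 4.0 * elev_f + 1.0 * _smooth_field(rng, shape, 3)
    tmax = 28.0 - 4.5 * elev_f + 1.0 * _smooth_field(rng, shape, 3)
    return {
        "elevation": elevation, "slope": slope, "tree_cover": tree_cover,
        "precipitation": precipitation, "tmin": tmin, "tmax": tmax,
    }


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a seeded synthetic world.

    Presence pixels are Bernoulli draws whose probability is
    ``background_fraction`` warped through a logistic covariate link
    (coefficients on standardized covariates; all-zero coefficients leave
    the probability exactly at ``background_fraction``).  Presence pixels are
    assigned to populations through spatial Gaussian membership kernels, so
    phenology is spatially clumped; a ``two_peak_fraction`` share of pixels
    joins a second population and carries two truth rows.  With no
    populations configured there is nothing to bloom and presence is empty.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    covariates = _make_covariates(rng, shape, config.cell_size_m)

    if config.n_populations == 0:
        presence = np.zeros(shape, bool)
        phen = _empty_phenology()
        blobs = _empty_blobs()
        return SyntheticWorld(config, presence, phen, covariates, blobs)

    eta = np.log(config.background_fraction
                 / (1 - config.background_fraction)) \
        if 0 < config.background_fraction < 1 else \
        (np.inf if config.background_fraction == 1 else -np.inf)
    eta = np.full(shape, eta)
    for name, coef in config.covariate_link.items():
        cov = covariates[name]
        sd = cov.std()
        z = (cov - cov.mean()) / sd if sd > 0 else np.zeros_like(cov)
        eta = eta + coef * z
    prob = 1.0 / (1.0 + np.exp(-eta))
    presence = rng.random(shape) < prob

    rows, cols = np.nonzero(presence)
    n_pix = rows.size
    # spatial membership weights of each population at each presence pixel
    weights = np.empty((n_pix, config.n_populations))
    for j, pop in enumerate(config.populations):
        d2 = (rows - pop.center_row) ** 2 + (cols - pop.center_col) ** 2
        weights[:, j] = np.exp(-0.5 * d2 / pop.spread_cells ** 2) + 1e-12
    weights /= weights.sum(axis=1, keepdims=True)

    records = []
    blob_records = []
    for i in range(n_pix):
        first = rng.choice(config.n_populations, p=weights[i])
        members = [int(first)]
        if config.n_populations > 1 and \
                rng.random() < config.two_peak_fraction:
            w2 = weights[i].copy()
            w2[first] = 0
            if w2.sum() > 0:
                members.append(int(rng.choice(config.n_populations,
                                              p=w2 / w2.sum())))
        pid = int(rows[i] * config.grid_cols + cols[i])
        for pop_idx in members:
            pop = config.populations[pop_idx]
            peak = int(np.round(pop.peak_day
                                + rng.normal(0, config.peak_jitter_days)))
            peak = (peak - 1) % DAYS_PER_YEAR + 1
            half = pop.duration_days / 2.0
            start = (peak - 1 - half) % DAYS_PER_YEAR + 1
            end = (peak - 1 + half) % DAYS_PER_YEAR + 1
            records.append({
                "pixel_id": pid, "row": int(rows[i]), "col": int(cols[i]),
                "population": pop_idx, "peak_day": peak,
                "duration_days": float(pop.duration_days),
                "amplitude": float(pop.amplitude),
                "start_day": float(start), "end_day": float(end),
            })
        # stand geometry: a clumped disc inside the cell, fixed per pixel
        blob_records.append({
            "pixel_id": pid, "row": int(rows[i]), "col": int(cols[i]),
            "center_u": float(rng.uniform(0.3, 0.7)),
            "center_v": float(rng.uniform(0.3, 0.7)),
            "radius_frac": float(rng.uniform(0.18, 0.35)),
        })
    phen = pd.DataFrame(records) if records else _empty_phenology()
    blobs = pd.DataFrame(blob_records) if blob_records else _empty_blobs()
    return SyntheticWorld(config, presence, phen, covariates, blobs)


def _empty_phenology() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "pixel_id", "row", "col", "population", "peak_day",
        "duration_days", "amplitude", "start_day", "end_day"])


def _empty_blobs() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "pixel_id", "row", "col", "center_u", "center_v", "radius_frac"])


def render_scene(
    world: SyntheticWorld,
    date: _dt.date | int,
    seed: int = 0,
    noise_sd: float | None = None,
    cloud_prob: float | None = None,
) -> SceneStack:
    """Render the world on ``date`` as a 12-bit 4-band scene.

    Blooming stands get additive red and blue offsets of
    ``(green_excess + contrast * (1 + intensity))`` inside their stand disc,
    so red and blue exceed green by at least the configured contrast whenever
    the truth intensity is positive.  Cloudy cells are bright in all bands
    and flagged in the cloud mask.  Values are integers in [0, 10000].
    """
    cfg = world.config
    rng = np.random.default_rng(seed)
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    cp = cfg.cloud_prob if cloud_prob is None else cloud_prob
    rows, cols = world.grid_shape
    px = cfg.patch_pixels
    h, w = rows * px, cols * px
    scene = np.empty((h, w, 4), float)
    for b, base in enumerate(FOREST_BASE):
        scene[..., b] = base
    if sd > 0:
        scene += rng.normal(0, sd, scene.shape)

    intensity = world.intensity(date)
    ge_red = FOREST_BASE[1] - FOREST_BASE[0]
    ge_blue = FOREST_BASE[1] - FOREST_BASE[2]
    if not world.blobs.empty:
        uu, vv = np.mgrid[0:px, 0:px]
        for rec in world.blobs.itertuples():
            inten = intensity[rec.row, rec.col]
            if inten <= 0:
                continue
            cy, cx = rec.center_u * px, rec.center_v * px
            disc = (uu - cy) ** 2 + (vv - cx) ** 2 \
                <= (rec.radius_frac * px) ** 2
            r0, c0 = rec.row * px, rec.col * px
            cell = scene[r0:r0 + px, c0:c0 + px]
            boost = cfg.magenta_contrast * (1.0 + inten)
            cell[..., 0][disc] += ge_red + boost
            cell[..., 2][disc] += ge_blue + boost
            cell[..., 3][disc] -= 600 * inten  # blossoms mute the NIR bounce

    for _ in range(cfg.n_soil_patches):
        sr = int(rng.integers(0, max(1, h - px)))
        sc = int(rng.integers(0, max(1, w - px)))
        sh = int(rng.integers(px // 2, px + 1))
        for b, base in enumerate(SOIL_BASE):
            scene[sr:sr + sh, sc:sc + sh, b] = \
                base + (rng.normal(0, sd, (min(sh, h - sr), min(sh, w - sc)))
                        if sd > 0 else 0)

    cloud_cells = rng.random((rows, cols)) < cp
    cloud_mask = np.kron(cloud_cells, np.ones((px, px), bool))
    if cloud_mask.any():
        n_cloud = int(cloud_mask.sum())
        cloudy = CLOUD_LEVEL + (rng.normal(0, sd, (n_cloud, 4))
                                if sd > 0 else 0)
        scene[cloud_mask] = cloudy

    scene = np.clip(np.rint(scene), 0, 10000).astype(np.uint16)
    return SceneStack(scene, _as_date(date), cloud_mask=cloud_mask)


def _as_date(date: _dt.date | int) -> _dt.date:
    if isinstance(date, (int, np.integer)):
        return _dt.date(2019, 1, 1) + _dt.timedelta(days=int(date) - 1)
    return date


def simulate_observations(
    world: SyntheticWorld,
    dates: list[_dt.date | int],
    p_detect: float = 0.95,
    cloud_prob: float | None = None,
    seed: int = 0,
) -> mapping.ObservationSeries:
    """Draw per-pixel observation states directly, bypassing imagery.

    On each date a grid cell is cloud with probability ``cloud_prob``;
    otherwise a visible bloom (truth intensity above the visibility
    threshold) is detected with probability ``p_detect * intensity`` —
    ``p_detect`` is the detection probability of a stand at full bloom and
    detectability ramps up and down with the bloom, as the detection
    frequencies of real stands do — else the cell is clear.
    """
    if len(dates) == 0:
        raise ValueError("empty date list")
    if not 0 <= p_detect <= 1:
        raise ValueError("p_detect must be in [0, 1]")
    cp = world.config.cloud_prob if cloud_prob is None else cloud_prob
    rng = np.random.default_rng(seed)
    shape = world.grid_shape
    states = np.empty((len(dates), *shape), np.uint8)
    for t, d in enumerate(dates):
        cloud = rng.random(shape) < cp
        intensity = world.intensity(d)
        p = np.where(intensity > world.config.visibility_threshold,
                     p_detect * intensity, 0.0)
        detected = rng.random(shape) < p
        day = np.full(shape, mapping.CLEAR, np.uint8)
        day[detected] = mapping.DETECTED
        day[cloud] = mapping.CLOUD
        states[t] = day
    return mapping.ObservationSeries([_as_date(d) for d in dates], states)


def make_patch_dataset(
    n: int,
    side: int = 32,
    seed: int = 0,
    bloom_fraction: float = 0.5,
    confounder_fraction: float = 0.25,
    min_clump_radius: float = 0.12,
    noise_sd: float = 4.0,
    border: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 8-bit patches for detector training and oracle tests.

    Positive patches carry a magenta stand disc inside the core; a share of
    the negatives carries a pink-soil square (red above green, blue below)
    that a color rule must reject.  Returns ``(patches, labels)`` with
    patches of shape ``(n, side, side, 4)`` uint8.
    """
    rng = np.random.default_rng(seed)
    base = np.array([50, 120, 40, 96], float)  # 8-bit forest background
    X = np.empty((n, side, side, 4), np.uint8)
    y = np.zeros(n, int)
    uu, vv = np.mgrid[0:side, 0:side]
    core_lo, core_hi = border, side - border
    for i in range(n):
        patch = base + rng.normal(0, noise_sd, (side, side, 4))
        if rng.random() < bloom_fraction:
            y[i] = 1
            rad = rng.uniform(min_clump_radius, 0.3) * side
            cy = rng.uniform(core_lo + rad, core_hi - rad)
            cx = rng.uniform(core_lo + rad, core_hi - rad)
            disc = (uu - cy) ** 2 + (vv - cx) ** 2 <= rad ** 2
            patch[..., 0][disc] = 180 + rng.normal(0, noise_sd,
                                                   int(disc.sum()))
            patch[..., 2][disc] = 170 + rng.normal(0, noise_sd,
                                                   int(disc.sum()))
            patch[..., 3][disc] -= 30
        elif rng.random() < confounder_fraction:
            s = int(rng.integers(side // 4, side // 2))
            r0 = int(rng.integers(0, side - s))
            c0 = int(rng.integers(0, side - s))
            patch[r0:r0 + s, c0:c0 + s, 0] = 180
            patch[r0:r0 + s, c0:c0 + s, 1] = 120
            patch[r0:r0 + s, c0:c0 + s, 2] = 90
        X[i] = np.clip(np.rint(patch), 0, 254).astype(np.uint8)
    return X, y


# ---------------------------------------------------------------------------
# serialization

def save_world(world: SyntheticWorld, directory: str | Path) -> None:
    """Write presence, truth, blob and covariate tables as CSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows, cols = world.grid_shape
    r, c = np.mgrid[0:rows, 0:cols]
    pd.DataFrame({
        "row": r.ravel(), "col": c.ravel(),
        "presence": world.presence.ravel().astype(int),
    }).to_csv(d / "presence.csv", index=False)
    world.phenology.to_csv(d / "phenology_truth.csv", index=False)
    world.blobs.to_csv(d / "blobs.csv", index=False)
    for name, grid in world.covariates.items():
        np.savetxt(d / f"covariate_{name}.csv", grid, delimiter=",")


def load_world(directory: str | Path, config: WorldConfig) -> SyntheticWorld:
    """Read a world saved by :func:`save_world` (config supplied by caller)."""
    d = Path(directory)
    pres = pd.read_csv(d / "presence.csv")
    presence = np.zeros((config.grid_rows, config.grid_cols), bool)
    presence[pres["row"], pres["col"]] = pres["presence"].astype(bool)
    phen = pd.read_csv(d / "phenology_truth.csv")
    blobs = pd.read_csv(d / "blobs.csv")
    covariates = {
        name: np.loadtxt(d / f"covariate_{name}.csv", delimiter=",",
                         ndmin=2)
        for name in COVARIATE_NAMES
    }
    return SyntheticWorld(config, presence, phen, covariates, blobs)
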