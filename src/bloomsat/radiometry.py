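"""Scene selection, 12-bit to 8-bit conversion and overlap tiling.

The preprocessing reproduces the conventions of Sentinel-2 L1C style input:
4-band (red, green, blue, NIR) top-of-atmosphere reflectance coded as
integers 0-10000, converted to 8-bit (0-254), padded with a nodata border to
a multiple of the 128-pixel analysis cell, and cut into 136 x 136 patches
(128-pixel core plus a 4-pixel context margin on each side).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SceneStack",
    "Patch",
    "DEFAULT_FLOWERING_MONTHS",
    "RGB_CLIP",
    "NIR_SCALE",
    "CORE_PIXELS",
    "BORDER_PIXELS",
    "select_scenes",
    "convert_to_8bit",
    "convert_scene",
    "tile_scene",
    "reassemble_patches",
    "grid_shape",
]

#: reflectance ceiling kept before the /10 rescale to 8 bits
RGB_CLIP = 2540
#: constant dividing the NIR band so its full 0-10000 range maps into 0-2540
NIR_SCALE = 3.937
#: side of the core analysis cell in scene pixels (1280 m at 10 m/px)
CORE_PIXELS = 128
#: context margin added on each side of a patch core
BORDER_PIXELS = 4

#: months treated as the flowering season (December through June); scenes in
#: the complementary months face the stricter cloud-cover threshold
DEFAULT_FLOWERING_MONTHS = frozenset({12, 1, 2, 3, 4, 5, 6})

BAND_NAMES = ("red", "green", "blue", "nir")


@dataclass
class SceneStack:
    """One dated 4-band scene with cloud and nodata masks.

    ``bands`` has shape ``(rows, cols, 4)`` in red/green/blue/NIR order.
    Values are 0-10000 integers (``uint16``) before conversion or 0-254
    (``uint8``) after.
    """

    bands: np.ndarray
    date: _dt.date
    cloud_mask: np.ndarray = None
    nodata_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3 or self.bands.shape[2] != 4:
            raise ValueError(
                f"bands must be (rows, cols, 4), got {self.bands.shape}"
            )
        shape = self.bands.shape[:2]
        if self.cloud_mask is None:
            self.cloud_mask = np.zeros(shape, bool)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(shape, bool)
        self.cloud_mask = np.asarray(self.cloud_mask, bool)
        self.nodata_mask = np.asarray(self.nodata_mask, bool)
        if self.cloud_mask.shape != shape or self.nodata_mask.shape != shape:
            raise ValueError("masks must share the band grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    @property
    def cloud_fraction(self) -> float:
        """Mean of the cloud mask over valid (non-nodata) pixels."""
        valid = ~self.nodata_mask
        if not valid.any():
            return 0.0
        return float(self.cloud_mask[valid].mean())

    def band(self, name: str) -> np.ndarray:
        return self.bands[..., BAND_NAMES.index(name)]


@dataclass
class Patch:
    """A 136 x 136 x 4 patch; the central 128 x 128 core carries the label."""

    pixels: np.ndarray
    grid_row: int
    grid_col: int
    core_pixels: int = CORE_PIXELS
    border: int = BORDER_PIXELS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        side = self.core_pixels + 2 * self.border
        if self.pixels.shape[:2] != (side, side):
            raise ValueError(
                f"patch side must be {side}, got {self.pixels.shape[:2]}"
            )

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def core(self) -> np.ndarray:
        b = self.border
        return self.pixels[b:-b, b:-b]


def select_scenes(
    scenes: list[SceneStack],
    flowering_months: frozenset[int] | set[int] = DEFAULT_FLOWERING_MONTHS,
    max_cloud: float = 0.80,
    max_cloud_off_season: float = 0.25,
) -> list[SceneStack]:
    """Keep scenes below the cloud-cover thresholds.

    A scene is retained when its cloud fraction is below ``max_cloud``
    (default 80%); outside the flowering months the stricter
    ``max_cloud_off_season`` threshold (default 25%) applies.
    """
    kept = []
    for scene in scenes:
        limit = max_cloud if scene.date.month in flowering_months \
            else max_cloud_off_season
        if scene.cloud_fraction < limit:
            kept.append(scene)
    return kept


def convert_to_8bit(values, band_kind: str = "rgb") -> np.ndarray:
    """Convert 0-10000 reflectance integers to 8-bit 0-254.

    rgb bands: ``floor(min(2540, v) / 10)``.  The NIR band is first divided
    by 3.937 so that its full range compresses into 0-2540:
    ``floor(min(2540, v / 3.937) / 10)``.
    """
    arr = np.asarray(values)
    if np.any(arr < 0):
        raise ValueError("reflectance values must be non-negative")
    if band_kind == "rgb":
        scaled = np.minimum(RGB_CLIP, arr)
    elif band_kind == "nir":
        scaled = np.minimum(RGB_CLIP, arr / NIR_SCALE)
    else:
        raise ValueError(f"band_kind must be 'rgb' or 'nir', got {band_kind!r}")
    out = np.floor(scaled / 10).astype(np.uint8)
    return out if out.shape else out[()]


def convert_scene(scene: SceneStack) -> SceneStack:
    """Return the scene with all four bands converted to 8 bits."""
    out = np.empty(scene.bands.shape, np.uint8)
    for i, name in enumerate(BAND_NAMES):
        kind = "nir" if name == "nir" else "rgb"
        out[..., i] = convert_to_8bit(scene.bands[..., i], kind)
    return SceneStack(out, scene.date, scene.cloud_mask.copy(),
                      scene.nodata_mask.copy())


def grid_shape(
    rows: int, cols: int, core: int = CORE_PIXELS
) -> tuple[int, int]:
    """Patch-grid shape after padding a scene up to a multiple of ``core``."""
    if rows <= 0 or cols <= 0:
        raise ValueError("scene must be non-empty")
    return (-(-rows // core), -(-cols // core))


def tile_scene(
    scene: SceneStack,
    core: int = CORE_PIXELS,
    border: int = BORDER_PIXELS,
) -> list[Patch]:
    """Cut a converted scene into overlapping patches.

    The scene is padded with nodata zeros up to the next multiple of ``core``;
    patch ``(r, c)`` covers padded rows/cols ``[core*r, core*(r+1))`` extended
    by ``border`` pixels on each side (out-of-image extension filled with 0).
    Patch cores tile the padded scene exactly once.
    """
    rows, cols = scene.shape
    n_r, n_c = grid_shape(rows, cols, core)
    pr, pc = n_r * core, n_c * core
    padded = np.zeros((pr + 2 * border, pc + 2 * border, 4),
                      scene.bands.dtype)
    padded[border:border + rows, border:border + cols] = scene.bands
    patches = []
    for r in range(n_r):
        for c in range(n_c):
            sub = padded[core * r:core * (r + 1) + 2 * border,
                         core * c:core * (c + 1) + 2 * border]
            patches.append(Patch(sub.copy(), r, c, core, border))
    return patches


def reassemble_patches(
    patches: list[Patch], dtype=None
) -> np.ndarray:
    """Stitch patch cores back into the padded scene (round-trip check)."""
    if not patches:
        raise ValueError("no patches to reassemble")
    core = patches[0].core_pixels
    n_r = max(p.grid_row for p in patches) + 1
    n_c = max(p.grid_col for p in patches) + 1
    out = np.zeros((n_r * core, n_c * core, 4),
                   dtype or patches[0].pixels.dtype)
    for p in patches:
        out[core * p.grid_row:core * (p.grid_row + 1),
            core * p.grid_col:core * (p.grid_col + 1)] = p.core
    return out
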