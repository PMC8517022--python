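"""Minimal GeoTIFF I/O.

Rasters are plain numpy grids, ``(rows, cols)`` single band or
``(rows, cols, bands)``, with the raster origin at the top-left corner
(x = column, y = row).  Georeferencing is the simple north-up affine used by
the analysis grid: an ``(x_origin, y_origin, pixel_size)`` triple.  Files are
written with the standard GeoTIFF ModelPixelScale / ModelTiepoint tags plus a
JSON ImageDescription carrying nodata and band names, so integer grids
round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_raster", "read_raster", "RasterMeta"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


class RasterMeta(dict):
    """Sidecar metadata of a raster file (georeference, nodata, bands)."""

    @property
    def transform(self) -> tuple[float, float, float]:
        return (self["x_origin"], self["y_origin"], self["pixel_size"])


def write_raster(
    path: str | Path,
    grid: np.ndarray,
    *,
    transform: tuple[float, float, float] = (0.0, 0.0, 1280.0),
    nodata: float | int | None = None,
    band_names: list[str] | None = None,
) -> None:
    """Write ``grid`` to ``path`` as a (Geo)TIFF.

    ``transform`` is ``(x_origin, y_origin, pixel_size)`` with square pixels
    and a north-up orientation.
    """
    grid = np.asarray(grid)
    if grid.ndim not in (2, 3):
        raise ValueError(f"grid must be 2-D or 3-D, got shape {grid.shape}")
    if band_names is not None:
        nbands = 1 if grid.ndim == 2 else grid.shape[2]
        if len(band_names) != nbands:
            raise ValueError(
                f"{len(band_names)} band names for {nbands} band(s)"
            )
    x0, y0, px = transform
    meta = {
        "x_origin": float(x0),
        "y_origin": float(y0),
        "pixel_size": float(px),
        "nodata": None if nodata is None else float(nodata),
        "band_names": band_names,
    }
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(px), float(px), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    tifffile.imwrite(
        str(path),
        grid,
        photometric="minisblack",
        planarconfig="contig" if grid.ndim == 3 else None,
        description=json.dumps(meta),
        extratags=extratags,
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterMeta]:
    """Read a raster written by :func:`write_raster` (or any simple TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        meta = RasterMeta(
            x_origin=0.0, y_origin=0.0, pixel_size=1.0, nodata=None,
            band_names=None,
        )
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta.update(json.loads(desc.value))
            except (json.JSONDecodeError, TypeError):
                pass
    return grid, meta
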