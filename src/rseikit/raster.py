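"""Raster container and GeoTIFF I/O.

A :class:`RasterGrid` is the universal per-pixel currency of the toolkit: a
2-D value array plus a north-up affine georeference (top-left origin, pixel
size in metres) and an optional nodata sentinel. Internally all indexing is
0-based (row, col); row 0 is the northernmost row.

GeoTIFF files are written with :mod:`tifffile` carrying the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) and a JSON
ImageDescription holding the CRS identifier and band names, so that a
write -> read round trip preserves values, transform, CRS and nodata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "CoregistrationError",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
    "assert_coregistered",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class CoregistrationError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """2-D georeferenced value grid.

    Parameters
    ----------
    values : ndarray
        2-D array of pixel values. Float arrays may contain NaN, which is
        always treated as nodata in addition to the ``nodata`` sentinel.
    origin : (float, float)
        (x, y) map coordinates of the outer corner of pixel (0, 0)
        (top-left, north-up convention).
    pixel_size : (float, float)
        (width, height) of a pixel in map units; both positive, height is
        applied southward.
    crs : str
        Opaque CRS identifier (e.g. "EPSG:32650"); carried through, never
        interpreted.
    nodata : float or None
        Sentinel marking invalid pixels.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: tuple[float, float] = (1.0, 1.0)
    crs: str = ""
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.pixel_size[0] == 0 or self.pixel_size[1] == 0:
            raise ValueError("pixel sizes must be nonzero")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_area_km2(self) -> float:
        """Area of one pixel in km^2 (pixel sizes are metres)."""
        return abs(self.pixel_size[0] * self.pixel_size[1]) / 1e6

    def valid_mask(self) -> np.ndarray:
        """Boolean mask, True where the pixel carries a valid value."""
        mask = np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= np.isfinite(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def like(self, values: np.ndarray, nodata: float | None = np.nan) -> "RasterGrid":
        """New grid sharing this one's georeference."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise CoregistrationError(
                f"replacement values shape {values.shape} != {self.shape}"
            )
        return replace(self, values=values, nodata=nodata)

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())

    def georef(self) -> tuple:
        return (self.shape, self.origin, self.pixel_size, self.crs)


def assert_coregistered(*grids: RasterGrid) -> None:
    """Raise :class:`CoregistrationError` unless all grids share shape,
    origin, pixel size and CRS."""
    if not grids:
        return
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise CoregistrationError(f"shape mismatch: {g.shape} vs {ref.shape}")
        if not np.allclose(g.origin, ref.origin) or not np.allclose(
            g.pixel_size, ref.pixel_size
        ):
            raise CoregistrationError("transform mismatch between rasters")
        if g.crs != ref.crs and g.crs and ref.crs:
            raise CoregistrationError(f"CRS mismatch: {g.crs!r} vs {ref.crs!r}")


# -- GeoTIFF I/O --------------------------------------------------------

def _geo_tags(grid: RasterGrid) -> list:
    px, py = grid.pixel_size
    x0, y0 = grid.origin
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(px), float(py), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    if grid.nodata is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))))
    return tags


def _description(grid: RasterGrid, bands: Sequence[str] | None) -> str:
    return json.dumps({"crs": grid.crs, "bands": list(bands) if bands else None})


def _parse_tags(page) -> tuple[tuple, tuple, str, float | None, list | None]:
    tags = page.tags
    px, py = 1.0, 1.0
    x0, y0 = 0.0, 0.0
    if _TAG_PIXEL_SCALE in tags:
        scale = tags[_TAG_PIXEL_SCALE].value
        px, py = float(scale[0]), float(scale[1])
    if _TAG_TIEPOINT in tags:
        tie = tags[_TAG_TIEPOINT].value
        x0, y0 = float(tie[3]), float(tie[4])
    crs, bands = "", None
    if 270 in tags:
        try:
            meta = json.loads(tags[270].value)
            crs = meta.get("crs", "") or ""
            bands = meta.get("bands")
        except (json.JSONDecodeError, AttributeError, TypeError):
            pass
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        except ValueError:
            pass
    return (x0, y0), (px, py), crs, nodata, bands


def write_raster(grid: RasterGrid, path) -> None:
    """Write a single-band GeoTIFF."""
    tifffile.imwrite(
        path,
        grid.values,
        extratags=_geo_tags(grid),
        description=_description(grid, None),
        photometric="minisblack",
    )


def read_raster(path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = tif.asarray()
        origin, pixel_size, crs, nodata, _ = _parse_tags(page)
    if values.ndim == 3:
        values = values[0]
    return RasterGrid(values, origin=origin, pixel_size=pixel_size, crs=crs, nodata=nodata)


def write_stack(grids: Mapping[str, RasterGrid], path) -> None:
    """Write co-registered single-band grids as one multiband GeoTIFF.

    Band order follows the mapping order; band names are stored in the file
    header for :func:`read_stack` to recover.
    """
    grids = dict(grids)
    assert_coregistered(*grids.values())
    names = list(grids)
    ref = grids[names[0]]
    cube = np.stack([grids[n].values for n in names])
    tifffile.imwrite(
        path,
        cube,
        extratags=_geo_tags(ref),
        description=_description(ref, names),
        photometric="minisblack",
    )


def read_stack(path) -> dict[str, RasterGrid]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        cube = tif.asarray()
        origin, pixel_size, crs, nodata, bands = _parse_tags(page)
    if cube.ndim == 2:
        cube = cube[None]
    if bands is None or len(bands) != cube.shape[0]:
        bands = [f"band{i + 1}" for i in range(cube.shape[0])]
    return {
        name: RasterGrid(
            cube[i], origin=origin, pixel_size=pixel_size, crs=crs, nodata=nodata
        )
        for i, name in enumerate(bands)
    }
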