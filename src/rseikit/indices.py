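"""Indicator rasters: greenness (NDVI), wetness (tasseled cap third
component), dryness (bare soil index) and heat (single-channel land surface
temperature), plus grid resampling.

Wetness uses the fixed tasseled-cap weights for the six reflective roles
(blue, green, red, NIR, SWIR1, SWIR2); the same weights are published for
Sentinel-2A surface reflectance and for Landsat apparent reflectance, so one
coefficient set serves both with the input convention recorded by the
caller. LST follows the single-channel radiative-transfer correction: sensor
radiance is stripped of up/down-welling path terms and emissivity, then the
Planck function is inverted with the sensor's calibration constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.ndimage import map_coordinates

from .raster import RasterGrid, assert_coregistered

__all__ = [
    "TasseledCapCoefficients",
    "SENTINEL2_WETNESS",
    "LANDSAT_WETNESS",
    "LSTParams",
    "ndvi",
    "wetness",
    "bare_soil_index",
    "planck_radiance",
    "lst",
    "resample",
]


@dataclass(frozen=True)
class TasseledCapCoefficients:
    """Per-role weights of the wetness component."""

    blue: float
    green: float
    red: float
    nir: float
    swir1: float
    swir2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "blue": self.blue,
            "green": self.green,
            "red": self.red,
            "nir": self.nir,
            "swir1": self.swir1,
            "swir2": self.swir2,
        }


#: Wetness weights for Sentinel-2A bands (B2, B3, B4, B8, B11, B12).
SENTINEL2_WETNESS = TasseledCapCoefficients(
    blue=0.1509, green=0.1973, red=0.3279, nir=0.3406, swir1=-0.7112, swir2=-0.4572
)
#: The same component for Landsat visible/NIR/SWIR roles.
LANDSAT_WETNESS = SENTINEL2_WETNESS


@dataclass
class LSTParams:
    """Single-channel LST parameters; all from scene metadata/atmospheric
    profile, with radiance calibration L = gain * DN + offset.

    epsilon : surface emissivity (0, 1].
    tau_atm : atmospheric transmissivity in the thermal band (0, 1].
    l_up, l_down : up/down-welling path radiance, W m^-2 sr^-1 um^-1.
    k1, k2 : Planck calibration constants (W m^-2 sr^-1 um^-1, K).
    """

    epsilon: float
    tau_atm: float
    l_up: float
    l_down: float
    k1: float
    k2: float
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if not 0 < self.tau_atm <= 1:
            raise ValueError("tau_atm must be in (0, 1]")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("Planck constants must be positive")


def ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """(NIR - Red) / (NIR + Red); NaN where the sum is zero or either
    input is nodata."""
    assert_coregistered(red, nir)
    r = red.values.astype(float)
    n = nir.values.astype(float)
    s = n + r
    valid = red.valid_mask() & nir.valid_mask() & (s != 0)
    out = np.full(red.shape, np.nan)
    out[valid] = (n[valid] - r[valid]) / s[valid]
    return red.like(out)


def wetness(
    stack: Mapping[str, RasterGrid],
    coeffs: TasseledCapCoefficients = SENTINEL2_WETNESS,
) -> RasterGrid:
    """Per-pixel dot product of the six reflective roles with the wetness
    weights. ``stack`` must contain keys blue, green, red, nir, swir1, swir2."""
    weights = coeffs.as_dict()
    missing = [k for k in weights if k not in stack]
    if missing:
        raise KeyError(f"missing band roles for wetness: {missing}")
    grids = [stack[k] for k in weights]
    assert_coregistered(*grids)
    out = np.zeros(grids[0].shape, dtype=float)
    valid = np.ones(grids[0].shape, dtype=bool)
    for role, w in weights.items():
        g = stack[role]
        out += w * g.values.astype(float)
        valid &= g.valid_mask()
    out[~valid] = np.nan
    return grids[0].like(out)


def bare_soil_index(stack: Mapping[str, RasterGrid]) -> RasterGrid:
    """Bare soil index SI = [(SWIR1 + Red) - (NIR + Blue)] /
    [(SWIR1 + Red) + (NIR + Blue)], in [-1, 1]; rises with surface
    bareness and runs inverse to wetness."""
    for k in ("blue", "red", "nir", "swir1"):
        if k not in stack:
            raise KeyError(f"missing band role for bare soil index: {k}")
    b, r, n, s1 = (stack[k] for k in ("blue", "red", "nir", "swir1"))
    assert_coregistered(b, r, n, s1)
    a = s1.values.astype(float) + r.values.astype(float)
    c = n.values.astype(float) + b.values.astype(float)
    denom = a + c
    valid = (
        b.valid_mask() & r.valid_mask() & n.valid_mask() & s1.valid_mask()
        & (denom != 0)
    )
    out = np.full(b.shape, np.nan)
    out[valid] = (a[valid] - c[valid]) / denom[valid]
    return b.like(out)


def planck_radiance(temp_k, k1: float, k2: float):
    """Blackbody radiance at temperature ``temp_k`` (K) under the two-constant
    Planck parameterisation: B = K1 / (exp(K2 / T) - 1)."""
    temp_k = np.asarray(temp_k, dtype=float)
    out = k1 / (np.exp(k2 / temp_k) - 1.0)
    return float(out) if out.ndim == 0 else out


def lst(thermal: RasterGrid, p: LSTParams) -> RasterGrid:
    """Land surface temperature (degrees C) from a thermal DN/radiance grid.

    L = gain*DN + offset; blackbody radiance
    B = (L - L_up - tau*(1-eps)*L_down) / (tau*eps);
    T = K2 / ln(K1/B + 1) - 273.15. Pixels with B <= 0 become nodata.
    """
    L = p.gain * thermal.values.astype(float) + p.offset
    B = (L - p.l_up - p.tau_atm * (1.0 - p.epsilon) * p.l_down) / (
        p.tau_atm * p.epsilon
    )
    valid = thermal.valid_mask() & (B > 0)
    out = np.full(thermal.shape, np.nan)
    out[valid] = p.k2 / np.log(p.k1 / B[valid] + 1.0) - 273.15
    return thermal.like(out)


def resample(
    raster: RasterGrid, target_pixel_size: float, method: str = "nearest"
) -> RasterGrid:
    """Resample to a new square pixel size over the same extent.

    ``nearest`` preserves the source value set (e.g. 30 m -> 10 m expands
    each pixel into a 3x3 block); ``bilinear`` interpolates between source
    pixel centres, reproducing linear ramps exactly.
    """
    if target_pixel_size <= 0:
        raise ValueError("target pixel size must be positive")
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown method {method!r}")
    rows, cols = raster.shape
    px, py = raster.pixel_size
    new_rows = max(1, int(round(rows * py / target_pixel_size)))
    new_cols = max(1, int(round(cols * px / target_pixel_size)))
    # source fractional index of each target pixel centre
    rr = (np.arange(new_rows) + 0.5) * rows / new_rows - 0.5
    cc = (np.arange(new_cols) + 0.5) * cols / new_cols - 0.5
    RR, CC = np.meshgrid(rr, cc, indexing="ij")
    if method == "nearest":
        ri = np.clip(np.round(RR).astype(int), 0, rows - 1)
        ci = np.clip(np.round(CC).astype(int), 0, cols - 1)
        out = raster.values[ri, ci]
    else:
        out = map_coordinates(
            raster.values.astype(float), [RR, CC], order=1, mode="nearest"
        )
    return RasterGrid(
        out,
        origin=raster.origin,
        pixel_size=(target_pixel_size, target_pixel_size),
        crs=raster.crs,
        nodata=raster.nodata,
    )
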