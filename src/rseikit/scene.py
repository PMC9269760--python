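"""Synthetic coastal scenes with known truth fields.

The generator emulates the spatial structure a coastal saline-alkali
tamarisk reserve presents to a multispectral sensor: a land-to-sea soil
salinity gradient, patchy shrub cover with a configurable densely-vegetated
(dark-pixel) fraction, a water body along the sea edge, a smooth aerosol
optical depth field, and surface temperature contrast between dense and
sparse vegetation. Band reflectance is a linear mixture of three endmembers
(vegetation, bare saline soil, water) plus Gaussian noise; the thermal
radiance is the exact Planck forward model of the truth temperature, and the
aerosol-sensor top-of-atmosphere bands are the exact lookup-table forward
model of the truth AOD — so every retrieval stage has an invertible oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .aod import AODLookupTable, make_synthetic_lut
from .indices import LSTParams, planck_radiance
from .raster import RasterGrid

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "SoilSampleSet",
    "SceneConfigError",
    "SamplingError",
    "forward_toa",
    "make_scene",
    "sample_soil",
    "BANDS",
    "VEG_ENDMEMBER",
    "SOIL_ENDMEMBER",
    "WATER_ENDMEMBER",
]

BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

# Endmember surface reflectance per band. Values are implementation
# defaults shaped to give realistic NDVI / bare-soil-index / wetness
# contrast between dense shrub, bright saline soil and water.
VEG_ENDMEMBER = {
    "B2": 0.03, "B3": 0.05, "B4": 0.04, "B5": 0.10, "B6": 0.25,
    "B7": 0.32, "B8": 0.38, "B8A": 0.40, "B11": 0.18, "B12": 0.09,
}
SOIL_ENDMEMBER = {
    "B2": 0.12, "B3": 0.16, "B4": 0.20, "B5": 0.22, "B6": 0.24,
    "B7": 0.26, "B8": 0.28, "B8A": 0.29, "B11": 0.40, "B12": 0.35,
}
WATER_ENDMEMBER = {
    "B2": 0.06, "B3": 0.05, "B4": 0.03, "B5": 0.02, "B6": 0.01,
    "B7": 0.008, "B8": 0.006, "B8A": 0.005, "B11": 0.002, "B12": 0.001,
}

_AXES = ("north", "south", "east", "west")


class SceneConfigError(ValueError):
    """Invalid synthetic-scene configuration."""


class SamplingError(ValueError):
    """Soil sampling request cannot be satisfied."""


@dataclass
class SceneConfig:
    """Synthetic scene parameters.

    veg_fraction is the target share of pixels whose NDVI exceeds the
    dark-pixel threshold (0.3); salinity_range (g/kg) spans the land->sea
    gradient; aod_field = (base tau, spatial amplitude) bounds the smooth
    truth AOD in [base - amp, base + amp]; lst_range bounds the truth
    surface temperature (degrees C). Defaults portray a ~1.3 km coastal
    reserve strip at 10 m pixels with the AOD and temperature spans
    reported for such sites (AOD 0.50-1.40, LST 24.5-30.2 degC).
    """

    rows: int = 128
    cols: int = 128
    pixel_size: float = 10.0
    seed: int = 0
    veg_fraction: float = 0.45
    salinity_range: tuple[float, float] = (0.5, 30.0)
    aod_field: tuple[float, float] = (0.95, 0.45)
    lst_range: tuple[float, float] = (24.5, 30.2)
    noise_sd: float = 0.005
    water_mask_fraction: float = 0.10
    sea_axis: str = "north"
    ndvi_threshold: float = 0.3
    k_ratio: float = 1.60
    geometry: tuple[float, float, float] = (24.0, 30.0, 96.0)
    snap_aod_to_grid: bool = False
    lst_params: LSTParams = field(
        default_factory=lambda: LSTParams(
            epsilon=0.986, tau_atm=0.85, l_up=1.2, l_down=2.0,
            k1=774.8853, k2=1321.0789,
        )
    )

    def __post_init__(self) -> None:
        if self.rows < 8 or self.cols < 8:
            raise SceneConfigError("rows and cols must be >= 8")
        if not 0 <= self.veg_fraction <= 1:
            raise SceneConfigError("veg_fraction must be in [0, 1]")
        if not 0 <= self.water_mask_fraction <= 1:
            raise SceneConfigError("water_mask_fraction must be in [0, 1]")
        if self.veg_fraction + self.water_mask_fraction > 1:
            raise SceneConfigError("veg_fraction + water_mask_fraction exceeds 1")
        for name in ("salinity_range", "lst_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SceneConfigError(f"{name} must be ordered (min, max)")
        if self.aod_field[1] < 0:
            raise SceneConfigError("aod_field amplitude must be >= 0")
        if self.sea_axis not in _AXES:
            raise SceneConfigError(f"sea_axis must be one of {_AXES}")
        if self.noise_sd < 0:
            raise SceneConfigError("noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    """Generated scene: per-band surface reflectance, aerosol-sensor TOA
    bands, thermal radiance, and the truth fields each stage should
    recover."""

    reflectance: dict[str, RasterGrid]
    toa: dict[str, RasterGrid]
    thermal_radiance: RasterGrid
    truth_aod: RasterGrid
    truth_salinity: RasterGrid
    truth_lst: RasterGrid
    water_mask: np.ndarray
    veg_mask: np.ndarray
    lut: AODLookupTable
    geometry: tuple[float, float, float]
    lst_params: LSTParams
    config: SceneConfig

    def band_roles(self) -> dict[str, RasterGrid]:
        """Reflective roles used by the index suite."""
        return {
            "blue": self.reflectance["B2"],
            "green": self.reflectance["B3"],
            "red": self.reflectance["B4"],
            "nir": self.reflectance["B8"],
            "swir1": self.reflectance["B11"],
            "swir2": self.reflectance["B12"],
        }


@dataclass
class SoilSampleSet:
    """Point soil samples: measured soluble salt (g/kg) and the per-band
    reflectance at the sampled pixels."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        if (t["salt_gkg"] < 0).any():
            raise ValueError("measured salt must be >= 0")
        band_cols = [c for c in t.columns if c in BANDS]
        refl = t[band_cols].to_numpy()
        if ((refl < 0) | (refl > 1)).any():
            raise ValueError("reflectance must lie in [0, 1]")

    @property
    def bands(self) -> list[str]:
        return [c for c in self.table.columns if c in BANDS]

    @property
    def salt(self) -> np.ndarray:
        return self.table["salt_gkg"].to_numpy(dtype=float)

    def reflectance_matrix(self, bands=None) -> np.ndarray:
        return self.table[list(bands or self.bands)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SoilSampleSet":
        return cls(pd.read_csv(path))


def forward_toa(rho, rho_a, T, S):
    """Apparent (TOA) reflectance of a Lambertian surface under a single
    atmospheric layer: rho* = rho_a + T * rho / (1 - S * rho).

    The exact forward model whose inverse the AOD retrieval applies.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.asarray(S) * rho >= 1):
        raise ValueError("S * rho must be < 1")
    out = rho_a + T * rho / (1.0 - S * rho)
    return float(out) if out.ndim == 0 else out


# -- construction helpers -----------------------------------------------

def _axis_coord(cfg: SceneConfig) -> np.ndarray:
    """Per-pixel distance toward the sea, normalised to [0, 1]
    (1 = sea edge)."""
    r = np.linspace(0.0, 1.0, cfg.rows)[:, None] * np.ones((1, cfg.cols))
    c = np.ones((cfg.rows, 1)) * np.linspace(0.0, 1.0, cfg.cols)[None, :]
    return {"north": 1 - r, "south": r, "west": 1 - c, "east": c}[cfg.sea_axis]


def _smooth_field(rng, shape, sigma_frac=0.08) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    sigma = max(1.0, sigma_frac * min(shape))
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def _ndvi_of_mix(v: float, soil_scale: float = 1.0) -> float:
    n = (1 - v) * SOIL_ENDMEMBER["B8"] * soil_scale + v * VEG_ENDMEMBER["B8"]
    r = (1 - v) * SOIL_ENDMEMBER["B4"] * soil_scale + v * VEG_ENDMEMBER["B4"]
    return (n - r) / (n + r)


def _veg_abundance(rank: np.ndarray, land_veg_fraction: float,
                   threshold: float, margin: float = 0.05) -> np.ndarray:
    """Map land-pixel ranks (uniform in [0,1]) to vegetation abundance so
    that exactly the top ``land_veg_fraction`` share clears the dark-pixel
    NDVI threshold with a safety margin against band noise."""
    v_star = brentq(lambda v: _ndvi_of_mix(v) - threshold, 0.0, 1.0)
    lo_cap = max(v_star - margin, 1e-3)
    hi_base = min(v_star + margin, 1.0 - 1e-3)
    q = 1.0 - land_veg_fraction
    v = np.empty_like(rank)
    below = rank < q
    if q > 0:
        v[below] = lo_cap * rank[below] / q
    if q < 1:
        v[~below] = hi_base + (1.0 - hi_base) * (rank[~below] - q) / (1.0 - q)
    return v


def make_scene(config: SceneConfig | None = None,
               lut: AODLookupTable | None = None) -> SyntheticScene:
    """Generate a synthetic scene; deterministic for a fixed seed."""
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.rows, cfg.cols)
    lut = lut or make_synthetic_lut()

    seaward = _axis_coord(cfg)

    # water body along the sea edge, fraction exact by quantile threshold
    coast_noise = _smooth_field(rng, shape)
    elevation = (1.0 - seaward) + 0.15 * (coast_noise - 0.5)
    if cfg.water_mask_fraction > 0:
        thr = np.quantile(elevation, cfg.water_mask_fraction)
        water = elevation <= thr
    else:
        water = np.zeros(shape, dtype=bool)

    # vegetation abundance on land, calibrated to the target dark fraction
    patch = _smooth_field(rng, shape)
    land = ~water
    n_land = int(land.sum())
    v = np.zeros(shape)
    if n_land:
        order = np.argsort(patch[land], kind="stable")
        rank = np.empty(n_land)
        rank[order] = np.arange(n_land) / max(n_land - 1, 1)
        land_veg = min(cfg.veg_fraction * cfg.rows * cfg.cols / n_land, 1.0)
        v[land] = _veg_abundance(rank, land_veg, cfg.ndvi_threshold)

    # truth fields
    smin, smax = cfg.salinity_range
    truth_sal = smin + (smax - smin) * seaward
    sal_norm = seaward

    base, amp = cfg.aod_field
    aod_noise = _smooth_field(rng, shape)
    truth_aod = base + amp * (2.0 * aod_noise - 1.0)
    tau_axis = lut.tau_axis
    truth_aod = np.clip(truth_aod, tau_axis[0], tau_axis[-1])
    if cfg.snap_aod_to_grid:
        idx = np.abs(truth_aod[..., None] - tau_axis[None, None, :]).argmin(axis=-1)
        truth_aod = tau_axis[idx]

    lmin, lmax = cfg.lst_range
    coolness = np.clip(v + water.astype(float), 0.0, 1.0)
    truth_lst = lmax - (lmax - lmin) * coolness

    # surface reflectance: linear endmember mixing; bare saline soil
    # brightens with salinity
    soil_scale = 0.85 + 0.30 * sal_norm
    reflectance: dict[str, np.ndarray] = {}
    for b in BANDS:
        land_val = (1 - v) * SOIL_ENDMEMBER[b] * soil_scale + v * VEG_ENDMEMBER[b]
        val = np.where(water, WATER_ENDMEMBER[b], land_val)
        if cfg.noise_sd > 0:
            val = val + rng.normal(0.0, cfg.noise_sd, shape)
        reflectance[b] = np.clip(val, 0.0, 1.0)

    # aerosol-sensor surface bands: dense vegetation satisfies the DDV
    # red/blue ratio k exactly; elsewhere blue is the scene blue band
    veg_mask_truth = v > brentq(
        lambda x: _ndvi_of_mix(x) - cfg.ndvi_threshold, 0.0, 1.0
    )
    red_surf = reflectance["B4"]
    blue_surf = np.where(veg_mask_truth, red_surf / cfg.k_ratio, reflectance["B2"])
    nir_surf = reflectance["B8"]

    # LUT-consistent TOA forward model at fixed geometry, per-pixel tau
    ts, tv, phi = cfg.geometry
    toa: dict[str, np.ndarray] = {}
    for band, surf in (("red", red_surf), ("blue", blue_surf), ("nir", nir_surf)):
        coeff_nodes = lut.interpolate(
            band,
            np.full(tau_axis.shape, ts),
            np.full(tau_axis.shape, tv),
            np.full(tau_axis.shape, phi),
            tau_axis,
        )
        per_pix = [np.interp(truth_aod, tau_axis, c) for c in coeff_nodes]
        toa[band] = forward_toa(surf, *per_pix)

    # thermal radiance: exact Planck forward model of the truth LST
    p = cfg.lst_params
    B = planck_radiance(truth_lst + 273.15, p.k1, p.k2)
    thermal = p.tau_atm * p.epsilon * B + p.l_up + p.tau_atm * (1 - p.epsilon) * p.l_down
    thermal = (thermal - p.offset) / p.gain

    def grid(a):
        return RasterGrid(
            np.asarray(a, dtype=float),
            origin=(0.0, 0.0),
            pixel_size=(cfg.pixel_size, cfg.pixel_size),
            crs="local",
            nodata=None,
        )

    return SyntheticScene(
        reflectance={b: grid(a) for b, a in reflectance.items()},
        toa={b: grid(a) for b, a in toa.items()},
        thermal_radiance=grid(thermal),
        truth_aod=grid(truth_aod),
        truth_salinity=grid(truth_sal),
        truth_lst=grid(truth_lst),
        water_mask=water,
        veg_mask=veg_mask_truth,
        lut=lut,
        geometry=cfg.geometry,
        lst_params=p,
        config=cfg,
    )


def sample_soil(
    scene: SyntheticScene, n: int, seed: int = 0, noise_sd: float = 0.0
) -> SoilSampleSet:
    """Draw ``n`` distinct land pixels as soil samples.

    The measured soluble salt is the truth salinity at the pixel plus
    Gaussian noise of ``noise_sd`` g/kg (clipped at zero); the per-band
    reflectance is the scene's surface reflectance there.
    """
    land = np.argwhere(~scene.water_mask)
    if n > len(land):
        raise SamplingError(f"requested {n} samples but only {len(land)} land pixels")
    rng = np.random.default_rng(seed)
    pick = land[rng.choice(len(land), size=n, replace=False)]
    rows, cols = pick[:, 0], pick[:, 1]
    salt = scene.truth_salinity.values[rows, cols]
    if noise_sd > 0:
        salt = salt + rng.normal(0.0, noise_sd, n)
    salt = np.clip(salt, 0.0, None)
    table = pd.DataFrame({"id": np.arange(n), "row": rows, "col": cols,
                          "salt_gkg": salt})
    for b in BANDS:
        table[b] = scene.reflectance[b].values[rows, cols]
    return SoilSampleSet(table)
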