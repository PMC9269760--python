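"""Aerosol optical depth retrieval by the dense-dark-vegetation (DDV) method.

Over densely vegetated ("dark") pixels the surface red/blue reflectance
ratio is stable (k, default 1.60 for the HJ1-CCD sensor), so the atmospheric
contribution can be separated from the top-of-atmosphere signal: for each
candidate AOD tau, the single-layer TOA equation

    rho* = rho_a + T * rho / (1 - S * rho)

is inverted in the red and blue bands using (rho_a, T, S) taken from a
radiative-transfer lookup table, and the tau whose inverted surface
reflectances come closest to the ratio k is the retrieval. Non-dark pixels
are then filled by inverse-distance-weighted interpolation of the dark-pixel
retrievals followed by mean-filter smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import uniform_filter
from scipy.spatial import cKDTree

from .raster import RasterGrid

__all__ = [
    "AODLookupTable",
    "DDVConfig",
    "AODMap",
    "LUTDomainError",
    "RetrievalError",
    "make_synthetic_lut",
    "invert_surface_reflectance",
    "detect_dark",
    "retrieve_aod_pixel",
    "retrieve_aod",
    "fill_aod",
]

_COEFFS = ("rho_a", "T", "S")


class LUTDomainError(ValueError):
    """Query outside the lookup-table axis hull."""


class RetrievalError(RuntimeError):
    """No valid AOD retrieval is possible."""


@dataclass
class DDVConfig:
    """Parameters of the DDV retrieval.

    ndvi_threshold : pixels with NDVI strictly above this are dark.
    k_ratio : assumed surface red/blue reflectance ratio on dark pixels.
    tau_candidates : AOD grid scanned during inversion (defaults to the
        lookup table's tau axis, which guarantees interpolation validity).
    idw_power, idw_max_neighbors : inverse-distance weighting for the fill.
    smooth_kernel : width (pixels) of the final mean filter.
    """

    ndvi_threshold: float = 0.3
    k_ratio: float = 1.60
    tau_candidates: np.ndarray | None = None
    idw_power: float = 2.0
    idw_max_neighbors: int = 12
    smooth_kernel: int = 3

    def __post_init__(self) -> None:
        if not -1 < self.ndvi_threshold < 1:
            raise ValueError("ndvi_threshold must lie in (-1, 1)")
        if self.k_ratio <= 0:
            raise ValueError("k_ratio must be positive")
        if self.tau_candidates is not None:
            taus = np.asarray(self.tau_candidates, dtype=float)
            if taus.size == 0 or np.any(np.diff(taus) <= 0):
                raise ValueError("tau_candidates must be non-empty and increasing")
            self.tau_candidates = taus


class AODLookupTable:
    """(theta_s, theta_v, phi, tau) -> (rho_a, T, S) on a complete 4-D grid,
    one value cube per spectral band; multilinear interpolation between
    nodes, exact at nodes."""

    def __init__(
        self,
        theta_s: np.ndarray,
        theta_v: np.ndarray,
        phi: np.ndarray,
        tau: np.ndarray,
        values: dict[str, dict[str, np.ndarray]],
    ) -> None:
        self.axes = tuple(
            np.asarray(a, dtype=float) for a in (theta_s, theta_v, phi, tau)
        )
        for name, ax in zip(("theta_s", "theta_v", "phi", "tau"), self.axes):
            if ax.ndim != 1 or (ax.size > 1 and np.any(np.diff(ax) <= 0)):
                raise ValueError(f"axis {name} must be strictly increasing")
        shape = tuple(ax.size for ax in self.axes)
        self.values = {}
        for band, cubes in values.items():
            self.values[band] = {}
            for c in _COEFFS:
                arr = np.asarray(cubes[c], dtype=float)
                if arr.shape != shape:
                    raise ValueError(
                        f"value cube {band}/{c} shape {arr.shape} != grid {shape}"
                    )
                self.values[band][c] = arr
        self._interp: dict[tuple[str, str], RegularGridInterpolator] = {}

    @property
    def bands(self) -> list[str]:
        return list(self.values)

    @property
    def tau_axis(self) -> np.ndarray:
        return self.axes[3]

    def _interpolator(self, band: str, coeff: str) -> RegularGridInterpolator:
        key = (band, coeff)
        if key not in self._interp:
            self._interp[key] = RegularGridInterpolator(
                self.axes, self.values[band][coeff], method="linear",
                bounds_error=True,
            )
        return self._interp[key]

    def interpolate(self, band, theta_s, theta_v, phi, tau):
        """Multilinear interpolation; returns (rho_a, T, S) arrays broadcast
        over the query points. Raises :class:`LUTDomainError` outside the
        axis hull."""
        pts = np.stack(
            np.broadcast_arrays(
                np.asarray(theta_s, float),
                np.asarray(theta_v, float),
                np.asarray(phi, float),
                np.asarray(tau, float),
            ),
            axis=-1,
        )
        try:
            out = tuple(self._interpolator(band, c)(pts) for c in _COEFFS)
        except ValueError as exc:
            raise LUTDomainError(str(exc)) from exc
        if pts.ndim == 1:
            return tuple(float(np.asarray(o).reshape(-1)[0]) for o in out)
        return out

    # -- tabular round trip ---------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flatten to the tidy layout (rho_a,T,S,theta_s,theta_v,phi,tau,band)."""
        grids = np.meshgrid(*self.axes, indexing="ij")
        rows = []
        for band in self.bands:
            df = pd.DataFrame(
                {
                    "rho_a": self.values[band]["rho_a"].ravel(),
                    "T": self.values[band]["T"].ravel(),
                    "S": self.values[band]["S"].ravel(),
                    "theta_s": grids[0].ravel(),
                    "theta_v": grids[1].ravel(),
                    "phi": grids[2].ravel(),
                    "tau": grids[3].ravel(),
                }
            )
            df["band"] = band
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AODLookupTable":
        """Build from a tidy frame with a complete grid per band."""
        axes = [np.sort(df[c].unique()) for c in ("theta_s", "theta_v", "phi", "tau")]
        shape = tuple(a.size for a in axes)
        index = {
            c: {v: i for i, v in enumerate(ax)}
            for c, ax in zip(("theta_s", "theta_v", "phi", "tau"), axes)
        }
        values: dict[str, dict[str, np.ndarray]] = {}
        for band, sub in df.groupby("band"):
            if len(sub) != np.prod(shape):
                raise ValueError(f"band {band!r}: grid has gaps")
            cubes = {c: np.full(shape, np.nan) for c in _COEFFS}
            ii = sub["theta_s"].map(index["theta_s"]).to_numpy()
            jj = sub["theta_v"].map(index["theta_v"]).to_numpy()
            kk = sub["phi"].map(index["phi"]).to_numpy()
            ll = sub["tau"].map(index["tau"]).to_numpy()
            for c in _COEFFS:
                cubes[c][ii, jj, kk, ll] = sub[c].to_numpy()
            values[band] = cubes
        return cls(*axes, values=values)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AODLookupTable":
        return cls.from_frame(pd.read_csv(path))


def make_synthetic_lut(
    theta_s=(0, 6, 12, 24, 40, 60),
    theta_v=(0, 3, 15, 30, 45, 60),
    phi=(0, 12, 48, 96, 132, 180),
    tau=(0.0001, 0.25, 0.5, 0.75, 1.0, 1.5, 1.95),
    bands=("red", "blue", "nir"),
    overrides: pd.DataFrame | None = None,
) -> AODLookupTable:
    """A smooth physically-shaped lookup table for testing and synthesis.

    Path reflectance grows and transmissivity decays with tau and air mass;
    the blue band scatters more than red, red more than NIR, so red/blue
    inversion discrepancies vary monotonically enough with tau for the DDV
    argmin to be well posed. ``overrides`` may supply exact published rows
    (columns rho_a,T,S,theta_s,theta_v,phi,tau,band) to be stamped onto the
    grid nodes after synthesis.
    """
    ts, tv, ph, ta = (np.asarray(a, dtype=float) for a in (theta_s, theta_v, phi, tau))
    TS, TV, PH, TA = np.meshgrid(ts, tv, ph, ta, indexing="ij")
    # relative air mass from the two zenith angles (capped below 70 deg axes)
    mu_s = np.cos(np.radians(TS))
    mu_v = np.cos(np.radians(TV))
    m = 1.0 / mu_s + 1.0 / mu_v
    scatter = {"blue": 1.35, "red": 1.0, "nir": 0.72}
    values: dict[str, dict[str, np.ndarray]] = {}
    for band in bands:
        b = scatter[band]
        rho_a = (0.04 * b + 0.16 * b * TA / (1.0 + TA)) * (
            1.0 + 0.05 * (m / 2.0 - 1.0) + 0.01 * np.cos(np.radians(PH))
        )
        T = np.exp(-0.5 * (0.08 * b + 0.55 * b * TA) * m / 2.0)
        S = (0.05 * b + 0.14 * b * TA / (1.0 + TA)) * (
            1.0 + 0.002 * PH / 180.0
        )
        values[band] = {"rho_a": rho_a, "T": T, "S": np.clip(S, 0.0, 0.95)}
    lut = AODLookupTable(ts, tv, ph, ta, values)
    if overrides is not None:
        for _, row in overrides.iterrows():
            band = row["band"]
            if band not in lut.values:
                continue
            idx = tuple(
                int(np.argmin(np.abs(ax - row[c])))
                for ax, c in zip(lut.axes, ("theta_s", "theta_v", "phi", "tau"))
            )
            for ax, c, i in zip(lut.axes, ("theta_s", "theta_v", "phi", "tau"),
                                idx):
                if abs(ax[i] - row[c]) > 1e-9:
                    raise ValueError(f"override row not on grid: {c}={row[c]}")
            for c in _COEFFS:
                lut.values[band][c][idx] = row[c]
        lut._interp.clear()
    return lut


# -- core arithmetic ----------------------------------------------------

def invert_surface_reflectance(rho_star, rho_a, T, S):
    """Invert the TOA equation for surface reflectance.

    rho = (rho* - rho_a) / (T + S * (rho* - rho_a)); pixels where the
    denominator is <= 0 or inputs are non-finite come back NaN (retrieval
    flagged invalid there).
    """
    rho_star = np.asarray(rho_star, dtype=float)
    d = rho_star - rho_a
    denom = T + S * d
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, d / denom, np.nan)
    if rho.ndim == 0:
        return float(rho)
    return rho


def detect_dark(ndvi: RasterGrid, threshold: float = 0.3) -> np.ndarray:
    """Dark (densely vegetated) pixel mask: NDVI strictly above threshold;
    nodata pixels are never dark."""
    with np.errstate(invalid="ignore"):
        mask = ndvi.values > threshold
    return mask & ndvi.valid_mask()


def _candidate_coeffs(lut, band, geometry, taus):
    theta_s, theta_v, phi = geometry
    return lut.interpolate(
        band,
        np.full(taus.shape, theta_s),
        np.full(taus.shape, theta_v),
        np.full(taus.shape, phi),
        taus,
    )


def retrieve_aod_pixel(
    rho_star_red: float,
    rho_star_blue: float,
    geometry: tuple[float, float, float],
    lut: AODLookupTable,
    cfg: DDVConfig | None = None,
) -> tuple[float, float]:
    """Retrieve AOD for one dark pixel.

    Scans the candidate tau grid, inverts surface reflectance in red and
    blue, and returns the tau minimising |rho_red/rho_blue - k| together
    with the achieved discrepancy. Ties break toward smaller tau; if no
    candidate yields valid reflectances both come back NaN.
    """
    cfg = cfg or DDVConfig()
    taus = cfg.tau_candidates if cfg.tau_candidates is not None else lut.tau_axis
    taus = np.asarray(taus, dtype=float)
    ra_r, T_r, S_r = _candidate_coeffs(lut, "red", geometry, taus)
    ra_b, T_b, S_b = _candidate_coeffs(lut, "blue", geometry, taus)
    rho_r = invert_surface_reflectance(rho_star_red, ra_r, T_r, S_r)
    rho_b = invert_surface_reflectance(rho_star_blue, ra_b, T_b, S_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.abs(rho_r / rho_b - cfg.k_ratio)
    disc = np.where(np.isfinite(disc) & (rho_b > 0), disc, np.inf)
    i = int(np.argmin(disc))  # argmin returns the first (smallest tau) on ties
    if not np.isfinite(disc[i]):
        return float("nan"), float("nan")
    return float(taus[i]), float(disc[i])


def retrieve_aod(
    red_toa: RasterGrid,
    blue_toa: RasterGrid,
    dark_mask: np.ndarray,
    geometry: tuple[float, float, float],
    lut: AODLookupTable,
    cfg: DDVConfig | None = None,
) -> tuple[RasterGrid, np.ndarray]:
    """Vectorised dark-pixel retrieval over a scene with fixed geometry.

    Returns (sparse tau grid with NaN off the dark mask, discrepancy array).
    """
    cfg = cfg or DDVConfig()
    taus = cfg.tau_candidates if cfg.tau_candidates is not None else lut.tau_axis
    taus = np.asarray(taus, dtype=float)
    ra_r, T_r, S_r = _candidate_coeffs(lut, "red", geometry, taus)
    ra_b, T_b, S_b = _candidate_coeffs(lut, "blue", geometry, taus)
    red = red_toa.values[dark_mask][:, None]
    blue = blue_toa.values[dark_mask][:, None]
    rho_r = invert_surface_reflectance(red, ra_r[None, :], T_r[None, :], S_r[None, :])
    rho_b = invert_surface_reflectance(blue, ra_b[None, :], T_b[None, :], S_b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.abs(rho_r / rho_b - cfg.k_ratio)
    disc = np.where(np.isfinite(disc) & (rho_b > 0), disc, np.inf)
    best = np.argmin(disc, axis=1)
    best_disc = disc[np.arange(disc.shape[0]), best]
    tau_pix = np.where(np.isfinite(best_disc), taus[best], np.nan)
    tau_grid = np.full(red_toa.shape, np.nan)
    tau_grid[dark_mask] = tau_pix
    disc_grid = np.full(red_toa.shape, np.nan)
    disc_grid[dark_mask] = np.where(np.isfinite(best_disc), best_disc, np.nan)
    return red_toa.like(tau_grid), disc_grid


@dataclass
class AODMap:
    """Retrieved + filled AOD field."""

    tau: RasterGrid
    dark_mask: np.ndarray
    discrepancy: np.ndarray | None = None


def fill_aod(
    sparse_tau: RasterGrid,
    cfg: DDVConfig | None = None,
    discrepancy: np.ndarray | None = None,
) -> AODMap:
    """Fill non-retrieved pixels by inverse-distance weighting of the
    nearest retrievals, then smooth with a mean filter.

    Retrieved values are kept as-is before smoothing; the result is
    independent of pixel ordering and, being a convex combination at every
    step, stays within [min, max] of the retrievals.
    """
    cfg = cfg or DDVConfig()
    vals = sparse_tau.values
    retrieved = np.isfinite(vals)
    if not retrieved.any():
        raise RetrievalError("no retrieved dark pixels to interpolate from")
    filled = vals.copy().astype(float)
    missing = ~retrieved
    if missing.any():
        src = np.argwhere(retrieved).astype(float)
        dst = np.argwhere(missing).astype(float)
        tree = cKDTree(src)
        k = min(cfg.idw_max_neighbors, len(src))
        dist, idx = tree.query(dst, k=k)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        with np.errstate(divide="ignore"):
            w = 1.0 / dist**cfg.idw_power
        w = np.where(np.isinf(w), np.finfo(float).max, w)
        src_vals = vals[retrieved][idx]
        filled[missing] = (w * src_vals).sum(axis=1) / w.sum(axis=1)
    if cfg.smooth_kernel and cfg.smooth_kernel > 1:
        filled = uniform_filter(filled, size=cfg.smooth_kernel, mode="nearest")
    return AODMap(sparse_tau.like(filled), dark_mask=retrieved, discrepancy=discrepancy)
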