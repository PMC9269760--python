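"""Soil soluble-salt inversion from multispectral reflectance.

Band screening uses the diagnosis index D_i = 100 * sigma_i * R_i, the
product of a band's reflectance dispersion (population standard deviation
across samples) and its Pearson correlation with the measured salt content:
bands that both vary and co-vary with salinity carry the inversion signal.
Two predictive models are provided — ordinary least squares on the selected
bands, and a single-hidden-layer backpropagation network with min-max
normalised inputs/outputs and a step-up search over hidden-node counts —
plus the hold-out validation arithmetic (error and relative error per
sample, the relative error taken against the inverted value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .raster import RasterGrid, assert_coregistered
from .scene import SoilSampleSet

__all__ = [
    "BandDiagnostics",
    "LinearSalinityModel",
    "BPNetConfig",
    "BPSalinityModel",
    "band_diagnostics",
    "select_bands",
    "fit_linear",
    "predict_linear",
    "predict_linear_map",
    "fit_bpnn",
    "validate",
    "changyi_linear_model",
]


@dataclass
class BandDiagnostics:
    """Per-band screening statistics: sigma (dispersion), R (correlation
    with salt), Di = 100 * sigma * R; constant bands are flagged."""

    table: pd.DataFrame  # columns: band, sigma, R, Di, flagged

    def __getitem__(self, band: str) -> pd.Series:
        return self.table.set_index("band").loc[band]


def band_diagnostics(samples: SoilSampleSet) -> BandDiagnostics:
    """Compute the diagnosis index for every band in the sample set."""
    salt = samples.salt
    if len(salt) < 3:
        raise ValueError("need at least 3 samples for diagnostics")
    rows = []
    for band in samples.bands:
        x = samples.table[band].to_numpy(dtype=float)
        sigma = float(np.std(x))  # population (ddof=0) dispersion
        if sigma == 0 or np.std(salt) == 0:
            rows.append({"band": band, "sigma": sigma, "R": np.nan,
                         "Di": np.nan, "flagged": True})
            continue
        r = float(np.corrcoef(x, salt)[0, 1])
        rows.append({"band": band, "sigma": sigma, "R": r,
                     "Di": 100.0 * sigma * r, "flagged": False})
    return BandDiagnostics(pd.DataFrame(rows))


def select_bands(diag: BandDiagnostics, top_n: int) -> list[str]:
    """Bands ranked by |Di| descending; ties keep the input band order.
    Flagged (constant) bands are excluded."""
    t = diag.table[~diag.table["flagged"]].reset_index(drop=True)
    if top_n > len(t):
        raise ValueError(f"top_n={top_n} exceeds {len(t)} usable bands")
    order = sorted(range(len(t)), key=lambda i: (-abs(t["Di"][i]), i))
    return [t["band"][i] for i in order[:top_n]]


@dataclass
class LinearSalinityModel:
    """Multiple linear regression: salt = X @ coefficients + intercept."""

    bands: list[str]
    coefficients: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.bands):
            raise ValueError("coefficient count must equal band count")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"bands": self.bands,
                 "coefficients": self.coefficients.tolist(),
                 "intercept": self.intercept},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "LinearSalinityModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["bands"], np.asarray(d["coefficients"]), d["intercept"])


def changyi_linear_model() -> LinearSalinityModel:
    """The regression fitted for the Changyi reserve campaign
    (five diagnostic bands B2, B6, B7, B8, B8A)."""
    from .data import CHANGYI_LINEAR_MODEL_COEFFS, CHANGYI_LINEAR_MODEL_INTERCEPT

    return LinearSalinityModel(
        list(CHANGYI_LINEAR_MODEL_COEFFS),
        np.array(list(CHANGYI_LINEAR_MODEL_COEFFS.values())),
        CHANGYI_LINEAR_MODEL_INTERCEPT,
    )


def fit_linear(samples: SoilSampleSet, bands: Sequence[str]) -> LinearSalinityModel:
    """Ordinary least squares of measured salt on the selected bands."""
    bands = list(bands)
    X = samples.reflectance_matrix(bands)
    y = samples.salt
    if len(y) < len(bands) + 1:
        raise ValueError("need at least bands + 1 samples")
    A = np.column_stack([X, np.ones(len(y))])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearSalinityModel(bands, beta[:-1], float(beta[-1]))


def predict_linear(model: LinearSalinityModel, reflectance: Mapping[str, float]
                   ) -> float:
    """Predict salt (g/kg) for one observation given per-band reflectance."""
    missing = [b for b in model.bands if b not in reflectance]
    if missing:
        raise KeyError(f"missing bands for prediction: {missing}")
    x = np.array([reflectance[b] for b in model.bands], dtype=float)
    return float(x @ model.coefficients + model.intercept)


def predict_linear_map(model: LinearSalinityModel,
                       bands: Mapping[str, RasterGrid]) -> RasterGrid:
    """Apply the regression per pixel to map salinity."""
    missing = [b for b in model.bands if b not in bands]
    if missing:
        raise KeyError(f"missing bands for prediction: {missing}")
    grids = [bands[b] for b in model.bands]
    assert_coregistered(*grids)
    out = np.full(grids[0].shape, model.intercept, dtype=float)
    valid = np.ones(grids[0].shape, dtype=bool)
    for g, c in zip(grids, model.coefficients):
        out += c * g.values.astype(float)
        valid &= g.valid_mask()
    out[~valid] = np.nan
    return grids[0].like(out)


@dataclass
class BPNetConfig:
    """Single-hidden-layer backpropagation network settings.

    The hidden-node count is searched step-by-step from 2 upward until the
    training error (MSE on min-max normalised targets) reaches
    ``target_error`` or ``max_hidden_nodes`` is hit.
    """

    bands: tuple[str, ...] = ("B2", "B6", "B7", "B8", "B8A")
    max_hidden_nodes: int = 20
    target_error: float = 0.001
    seed: int = 0
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.max_hidden_nodes < 2:
            raise ValueError("hidden node search starts at 2")
        if self.target_error <= 0:
            raise ValueError("target_error must be positive")


@dataclass
class BPSalinityModel:
    """Trained network plus the normalisation ranges needed to apply it."""

    bands: list[str]
    net: MLPRegressor
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: float
    y_range: float
    hidden_nodes: int
    training_error: float
    converged: bool

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / self.x_range

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict salt (g/kg) from a (n, bands) reflectance matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = self.net.predict(self._normalize(X))
        return z * self.y_range + self.y_min

    def predict_samples(self, samples: SoilSampleSet) -> np.ndarray:
        return self.predict(samples.reflectance_matrix(self.bands))


def fit_bpnn(samples: SoilSampleSet, cfg: BPNetConfig | None = None
             ) -> BPSalinityModel:
    """Train the BP network with the step-up hidden-node search.

    Deterministic for a fixed config seed. If no node count reaches the
    target error the best network found is returned with
    ``converged=False``.
    """
    cfg = cfg or BPNetConfig()
    bands = [b for b in cfg.bands if b in samples.bands]
    if len(bands) != len(cfg.bands):
        raise ValueError("sample set lacks configured input bands")
    X = samples.reflectance_matrix(bands)
    y = samples.salt
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    x_min = X.min(axis=0)
    ptp = np.ptp(X, axis=0)
    x_range = np.where(ptp > 0, ptp, 1.0)
    y_min = float(y.min())
    y_range = float(np.ptp(y)) or 1.0
    Xn = (X - x_min) / x_range
    yn = (y - y_min) / y_range

    best: BPSalinityModel | None = None
    for h in range(2, cfg.max_hidden_nodes + 1):
        net = MLPRegressor(
            hidden_layer_sizes=(h,),
            activation="logistic",
            solver="lbfgs",
            alpha=1e-6,
            max_iter=cfg.max_iter,
            random_state=cfg.seed,
            tol=1e-10,
        )
        net.fit(Xn, yn)
        err = float(np.mean((net.predict(Xn) - yn) ** 2))
        model = BPSalinityModel(
            bands, net, x_min, x_range, y_min, y_range,
            hidden_nodes=h, training_error=err, converged=err <= cfg.target_error,
        )
        if best is None or err < best.training_error:
            best = model
        if model.converged:
            return model
    assert best is not None
    return best


def validate(measured: Sequence[float], inverted: Sequence[float]) -> pd.DataFrame:
    """Hold-out validation table.

    error = inverted - measured (g/kg); relative_error = 100 * error /
    inverted (%), taken against the inverted value; rows with inverted == 0
    get NaN relative error and a flag.
    """
    measured = np.asarray(measured, dtype=float)
    inverted = np.asarray(inverted, dtype=float)
    if measured.shape != inverted.shape:
        raise ValueError("measured and inverted must have equal length")
    error = inverted - measured
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(inverted != 0, 100.0 * error / inverted, np.nan)
    return pd.DataFrame(
        {
            "measured_gkg": measured,
            "inverted_gkg": inverted,
            "error_gkg": error,
            "relative_error_pct": rel,
            "flagged": inverted == 0,
        }
    )
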