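"""RSEI composition: normalization, spatial PCA, grading, change detection.

Indicator rasters are first clipped to robust percentiles (default 2nd/98th
— noise-tolerant histogram bounds) and min-max scaled to [0, 1]. Treating
each valid pixel as an observation vector over the indicator layers, PCA of
the covariance matrix yields the loadings and contribution rates; RSEI is
the first principal component, oriented so that greenness loads positively
(dense vegetation scores high), rescaled to [0, 1]. The score is graded into
five classes at 0.2 intervals (worst .. excellent) with per-class area
statistics, and two dates are compared by differencing with a +/-0.1
threshold into Worse / Unchanged / Better classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import RasterGrid, assert_coregistered

__all__ = [
    "NormalizedIndexStack",
    "PCAResult",
    "GRADE_NAMES",
    "percentile_normalize",
    "run_spca",
    "compose_rsei",
    "grade",
    "combined_rate",
    "change_detect",
    "class_ratios",
    "cumulative_rates",
    "correlation_report",
    "summary",
]

GRADE_NAMES = ("Worst", "Worse", "Medium", "Good", "Excellent")
CHANGE_NAMES = ("Worse", "Unchanged", "Better")


def percentile_normalize(
    raster: RasterGrid, lower: float = 2.0, upper: float = 98.0
) -> RasterGrid:
    """Clip to the [lower, upper] percentiles of the valid pixels, then
    min-max scale to [0, 1]. A constant raster maps to 0.5 everywhere."""
    valid = raster.valid_mask()
    if not valid.any():
        raise ValueError("raster has no valid pixels")
    vals = raster.values.astype(float)
    lo, hi = np.percentile(vals[valid], [lower, upper])
    out = np.full(raster.shape, np.nan)
    if hi == lo:
        out[valid] = 0.5
    else:
        out[valid] = (np.clip(vals[valid], lo, hi) - lo) / (hi - lo)
    return raster.like(out)


class NormalizedIndexStack:
    """Co-registered named indicator layers in [0, 1] sharing a union
    nodata mask."""

    def __init__(self, layers: Mapping[str, RasterGrid]) -> None:
        if len(layers) < 2:
            raise ValueError("need at least 2 layers")
        self.layers = dict(layers)
        assert_coregistered(*self.layers.values())
        mask = np.ones(next(iter(self.layers.values())).shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask()
        self.valid_mask = mask
        for name, g in self.layers.items():
            v = g.values[mask]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError(f"layer {name!r} not normalized to [0, 1]")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def matrix(self) -> np.ndarray:
        """(n_valid_pixels, n_layers) observation matrix."""
        return np.column_stack(
            [self.layers[n].values[self.valid_mask] for n in self.names]
        )


@dataclass
class PCAResult:
    """Loadings (layers x components), eigenvalues and contribution rates
    of the spatial PCA."""

    layer_names: list[str]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    means: np.ndarray

    @property
    def contribution_rate(self) -> np.ndarray:
        """% of total variance per component."""
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / total

    @property
    def cumulative_rate(self) -> np.ndarray:
        return np.cumsum(self.contribution_rate)

    def loading(self, layer: str, component: int = 0) -> float:
        return float(self.loadings[self.layer_names.index(layer), component])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        df = pd.DataFrame(self.loadings, index=self.layer_names, columns=cols)
        df.loc["Eigenvalue"] = self.eigenvalues
        df.loc["Contribution rate/%"] = self.contribution_rate
        df.loc["Cumulative rate/%"] = self.cumulative_rate
        return df


def cumulative_rates(rates: Sequence[float]) -> np.ndarray:
    """Cumulative contribution (%) from per-component rates."""
    return np.cumsum(np.asarray(rates, dtype=float))


def run_spca(stack: NormalizedIndexStack) -> PCAResult:
    """PCA of the covariance matrix of the valid-pixel observations.

    Eigenvalues come back descending; each loading column's first nonzero
    entry is made positive so the decomposition is deterministic.
    Degenerate (zero-variance) directions are reported with zero
    eigenvalues.
    """
    X = stack.matrix()
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer valid pixels than layers")
    means = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        col = evecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            evecs[:, j] = -col
    return PCAResult(stack.names, evecs, evals, means)


def compose_rsei(
    stack: NormalizedIndexStack,
    pca: PCAResult,
    greenness_layer: str = "greenness",
) -> RasterGrid:
    """Project pixels onto PC1, orient so greenness contributes positively,
    and min-max rescale to [0, 1] (a monotone transform: pixel ranking of
    PC1 scores is preserved)."""
    pc1 = pca.loadings[:, 0].copy()
    if greenness_layer in pca.layer_names and pca.loading(greenness_layer, 0) < 0:
        pc1 = -pc1
    X = stack.matrix()
    scores = (X - pca.means) @ pc1
    lo, hi = scores.min(), scores.max()
    scaled = np.full(scores.shape, 0.5) if hi == lo else (scores - lo) / (hi - lo)
    out = np.full(stack.reference.shape, np.nan)
    out[stack.valid_mask] = scaled
    return stack.reference.like(out)


def grade(
    rsei: RasterGrid,
    pixel_area_km2: float | None = None,
    breaks: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> tuple[pd.DataFrame, RasterGrid]:
    """Five-grade classification of RSEI at 0.2 intervals.

    Bins are left-closed/right-open except the top bin which includes 1.0.
    Returns the grade table (grade, area_km2, ratio_pct) and the class
    raster (0..4, NaN at nodata).
    """
    valid = rsei.valid_mask()
    vals = rsei.values[valid]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("RSEI values must lie in [0, 1]")
    if pixel_area_km2 is None:
        pixel_area_km2 = rsei.pixel_area_km2
    edges = np.asarray(breaks, dtype=float)
    idx = np.clip(np.digitize(vals, edges[1:-1], right=False), 0, len(GRADE_NAMES) - 1)
    counts = np.bincount(idx, minlength=len(GRADE_NAMES))
    total = counts.sum()
    areas = counts * pixel_area_km2
    ratios = 100.0 * counts / total if total else np.zeros(len(GRADE_NAMES))
    table = pd.DataFrame(
        {"grade": list(GRADE_NAMES), "area_km2": areas, "ratio_pct": ratios}
    )
    classes = np.full(rsei.shape, np.nan)
    classes[valid] = idx
    return table, rsei.like(classes)


def combined_rate(table: pd.DataFrame, grades: Sequence[str]) -> float:
    """Sum of the ratio entries for a subset of grades (e.g. the
    excellent-and-good rate)."""
    known = set(table["grade"])
    unknown = [g for g in grades if g not in known]
    if unknown:
        raise KeyError(f"unknown grades: {unknown}")
    sel = table.set_index("grade").loc[list(grades), "ratio_pct"]
    return float(sel.sum())


def class_ratios(areas: Mapping[str, float], total: float | None = None
                 ) -> dict[str, float]:
    """Per-class ratio (%) from per-class areas."""
    tot = total if total is not None else sum(areas.values())
    return {k: 100.0 * a / tot for k, a in areas.items()}


def change_detect(
    rsei_a: RasterGrid,
    rsei_b: RasterGrid,
    threshold: float = 0.1,
    pixel_area_km2: float | None = None,
) -> tuple[pd.DataFrame, RasterGrid]:
    """Difference two RSEI dates into Worse / Unchanged / Better.

    delta = b - a; Better where delta > threshold, Worse where
    delta < -threshold, Unchanged on the closed interval between.
    """
    assert_coregistered(rsei_a, rsei_b)
    if pixel_area_km2 is None:
        pixel_area_km2 = rsei_a.pixel_area_km2
    valid = rsei_a.valid_mask() & rsei_b.valid_mask()
    delta = rsei_b.values - rsei_a.values
    cls = np.full(rsei_a.shape, np.nan)
    cls[valid & (delta < -threshold)] = 0
    cls[valid & (np.abs(delta) <= threshold)] = 1
    cls[valid & (delta > threshold)] = 2
    counts = np.array([(cls == i).sum() for i in range(3)])
    total = counts.sum()
    areas = counts * pixel_area_km2
    ratios = 100.0 * counts / total if total else np.zeros(3)
    table = pd.DataFrame(
        {"class": list(CHANGE_NAMES), "area_km2": areas, "ratio_pct": ratios}
    )
    return table, rsei_a.like(cls)


def correlation_report(
    stack: NormalizedIndexStack, rsei: RasterGrid | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation matrix over valid pixels, plus each variable's
    mean absolute off-diagonal correlation (self excluded, and RSEI
    correlations with the indicators only).

    Constant layers yield NaN correlations (flagged by the NaN itself).
    """
    names = list(stack.names)
    cols = [stack.layers[n].values[stack.valid_mask] for n in names]
    if rsei is not None:
        assert_coregistered(stack.reference, rsei)
        names = names + ["RSEI"]
        cols = cols + [rsei.values[stack.valid_mask]]
    X = np.column_stack(cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    matrix = pd.DataFrame(corr, index=names, columns=names)
    n_ind = len(stack.names)
    means = {}
    for i, n in enumerate(names):
        others = [j for j in range(n_ind) if j != i]
        vals = np.abs(corr[i, others])
        # a constant layer yields all-NaN correlations; report NaN, flagged
        # by the NaN itself
        means[n] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
    return matrix, pd.Series(means, name="mean_abs_r")


def summary(
    stack: NormalizedIndexStack, rsei: RasterGrid | None = None
) -> pd.DataFrame:
    """Masked mean and standard deviation per layer (and RSEI)."""
    rows = []
    for n in stack.names:
        v = stack.layers[n].values[stack.valid_mask]
        rows.append({"index": n, "mean": float(v.mean()), "sd": float(v.std())})
    if rsei is not None:
        v = rsei.values[stack.valid_mask]
        rows.append({"index": "RSEI", "mean": float(np.nanmean(v)),
                     "sd": float(np.nanstd(v))})
    return pd.DataFrame(rows)
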