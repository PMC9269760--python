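"""Published reference values for the Changyi coastal *Tamarix chinensis*
reserve study (Laizhou Bay, Shandong).

These constants are the printed inputs of the original field/remote-sensing
campaign: a sample of the HJ1-CCD aerosol lookup table, the fitted
multispectral soil-salinity regression, the soluble-salt validation pairs,
the spatial-PCA contribution rates and the per-date ecological grade and
change-detection area tables. They let the toolkit's reporting arithmetic be
exercised and checked offline, without the original satellite scenes.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "HJ1_LUT_SAMPLE",
    "CHANGYI_LINEAR_MODEL_COEFFS",
    "CHANGYI_LINEAR_MODEL_INTERCEPT",
    "SALINITY_VALIDATION_PAIRS",
    "PC_CONTRIBUTION_RATES_2019",
    "GRADE_TABLES",
    "CHANGE_AREAS",
    "STUDY_AREA_KM2",
    "hj1_lut_sample_frame",
    "grade_table_frame",
]

#: Sample rows of the HJ1-CCD aerosol lookup table (red band):
#: (rho_a path reflectance, T total transmissivity, S spherical albedo,
#:  solar zenith deg, satellite zenith deg, relative azimuth deg, AOD tau).
HJ1_LUT_SAMPLE: list[tuple[float, float, float, float, float, float, float]] = [
    (0.13766, 0.83489, 0.06554, 0, 0, 0, 0.0001),
    (0.13766, 0.83489, 0.06554, 0, 0, 12, 0.0001),
    (0.13766, 0.83489, 0.06554, 0, 0, 24, 0.0001),
    (0.13766, 0.83489, 0.06554, 0, 0, 36, 0.0001),
    (0.17874, 0.73011, 0.08739, 6, 3, 48, 0.25),
    (0.17874, 0.73011, 0.08706, 6, 3, 60, 0.25),
    (0.17874, 0.73011, 0.08671, 6, 3, 72, 0.25),
    (0.17874, 0.73011, 0.08637, 6, 3, 84, 0.25),
    (0.26870, 0.28913, 0.17870, 24, 30, 96, 1.50),
    (0.26870, 0.28913, 0.17731, 24, 30, 108, 1.50),
    (0.26870, 0.28913, 0.17640, 24, 30, 120, 1.50),
    (0.26870, 0.28913, 0.17588, 24, 30, 132, 1.50),
    (0.28252, 0.12120, 0.32403, 60, 60, 144, 1.95),
    (0.28252, 0.12120, 0.33546, 60, 60, 156, 1.95),
    (0.28252, 0.12120, 0.34339, 60, 60, 168, 1.95),
    (0.28252, 0.12120, 0.34623, 60, 60, 180, 1.95),
]

#: Fitted multiple linear regression for soluble salt content (g/kg) from
#: Sentinel-2A surface reflectance at the five diagnostic bands.
CHANGYI_LINEAR_MODEL_COEFFS: dict[str, float] = {
    "B2": 23.25,
    "B6": -119.43,
    "B7": 375.46,
    "B8": -123.36,
    "B8A": -237.96,
}
CHANGYI_LINEAR_MODEL_INTERCEPT: float = 31.20

#: Ten hold-out validation samples: (measured g/kg, regression-inverted g/kg).
SALINITY_VALIDATION_PAIRS: list[tuple[float, float]] = [
    (8.18, 14.70),
    (1.53, 10.96),
    (12.4, 6.89),
    (0.08, 3.12),
    (0.22, 4.60),
    (0.14, 3.26),
    (0.07, 4.37),
    (0.04, 3.56),
    (0.06, 2.98),
    (0.08, 3.61),
]

#: Contribution rate (%) of each principal component for the September 2019
#: six-indicator spatial PCA over the reserve.
PC_CONTRIBUTION_RATES_2019: list[float] = [56.95, 24.70, 7.95, 7.27, 2.42, 0.70]

#: Per-date ecological grade statistics: grade -> (area km^2, ratio %).
GRADE_TABLES: dict[int, dict[str, tuple[float, float]]] = {
    2000: {
        "Worst": (2.15, 13.91),
        "Worse": (8.99, 58.07),
        "Medium": (3.71, 23.98),
        "Good": (0.47, 3.03),
        "Excellent": (0.16, 1.02),
    },
    2007: {
        "Worst": (3.77, 24.34),
        "Worse": (7.06, 45.61),
        "Medium": (3.95, 25.50),
        "Good": (0.66, 4.27),
        "Excellent": (0.04, 0.28),
    },
    2014: {
        "Worst": (0.04, 0.27),
        "Worse": (1.37, 8.86),
        "Medium": (6.42, 41.44),
        "Good": (5.83, 37.66),
        "Excellent": (1.82, 11.76),
    },
    2019: {
        "Worst": (1.26, 8.17),
        "Worse": (2.40, 15.49),
        "Medium": (3.25, 21.01),
        "Good": (5.57, 35.96),
        "Excellent": (3.00, 19.37),
    },
}

#: Change-detection areas (km^2) per period: class -> area.
CHANGE_AREAS: dict[str, dict[str, float]] = {
    "2000-2007": {"Worse": 7.42, "Unchanged": 4.84, "Better": 3.22},
    "2007-2014": {"Worse": 2.90, "Unchanged": 1.29, "Better": 11.29},
    "2014-2019": {"Worse": 3.21, "Unchanged": 3.10, "Better": 9.17},
}

#: Total area of the protection zone (km^2).
STUDY_AREA_KM2: float = 15.48


def hj1_lut_sample_frame() -> pd.DataFrame:
    """The HJ1-CCD lookup-table sample as a tidy frame (band column 'red')."""
    df = pd.DataFrame(
        HJ1_LUT_SAMPLE,
        columns=["rho_a", "T", "S", "theta_s", "theta_v", "phi", "tau"],
    )
    df["band"] = "red"
    return df


def grade_table_frame(year: int) -> pd.DataFrame:
    """A published grade table as the frame layout the grading stage emits."""
    rows = GRADE_TABLES[year]
    return pd.DataFrame(
        {
            "grade": list(rows),
            "area_km2": [a for a, _ in rows.values()],
            "ratio_pct": [r for _, r in rows.values()],
        }
    )
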