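"""Keeling-plot estimation of the daily mixed CH4 source signature.

When one source mixes into background air, delta13C_obs is linear in
1/CH4_obs and the intercept at 1/CH4 -> 0 is the source signature
delta13C_mix.  Fits are done per local calendar day and per observation
height on the calibrated 5-min samples, by ordinary least squares of
delta on 1/CH4, and filtered on the coefficient of determination
(default keep R^2 > 0.5).
"""

from __future__ import annotations

import logging
import math
from typing import Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIT_COLUMNS = [
    "date",
    "height_m",
    "delta13c_mix_permil",
    "intercept_se_permil",
    "slope_permil_ppb",
    "r_squared",
    "n_points",
    "valid",
    "invalid_reason",
    "retained",
]


def _ols_inverse(ch4: np.ndarray, delta: np.ndarray) -> Tuple[float, float, float, float]:
    """Closed-form OLS of delta on 1/CH4.

    Returns (intercept, slope, r_squared, intercept_se)."""
    x = 1.0 / ch4
    y = delta
    n = x.size
    mx, my = x.mean(), y.mean()
    sxx = float(((x - mx) ** 2).sum())
    sxy = float(((x - mx) * (y - my)).sum())
    syy = float(((y - my) ** 2).sum())
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = max(syy - slope * sxy, 0.0)
    r2 = 1.0 if syy == 0.0 else 1.0 - ss_res / syy
    if n > 2:
        s2 = ss_res / (n - 2)
        se = math.sqrt(s2 * (1.0 / n + mx**2 / sxx))
    else:
        se = float("nan")
    return intercept, slope, r2, se


def fit_keeling_day(samples: pd.DataFrame, min_points: int = 20) -> dict:
    """Keeling fit for one date x height group of calibrated samples.

    Returns a dict of the fit fields; an invalid fit (too few points, or
    no variance in CH4) carries ``valid=False`` and a reason instead of
    raising.
    """
    date = samples["date"].iloc[0]
    height = samples["height_m"].iloc[0]
    base = {"date": date, "height_m": height, "n_points": len(samples)}
    nan = float("nan")
    if len(samples) < min_points:
        return {
            **base,
            "delta13c_mix_permil": nan,
            "intercept_se_permil": nan,
            "slope_permil_ppb": nan,
            "r_squared": nan,
            "valid": False,
            "invalid_reason": "too_few_points",
        }
    ch4 = samples["ch4_dry_ppb"].to_numpy(dtype=float)
    if np.ptp(1.0 / ch4) == 0.0:
        return {
            **base,
            "delta13c_mix_permil": nan,
            "intercept_se_permil": nan,
            "slope_permil_ppb": nan,
            "r_squared": nan,
            "valid": False,
            "invalid_reason": "zero_variance",
        }
    intercept, slope, r2, se = _ols_inverse(
        ch4, samples["delta13c_obs_permil"].to_numpy(dtype=float)
    )
    return {
        **base,
        "delta13c_mix_permil": intercept,
        "intercept_se_permil": se,
        "slope_permil_ppb": slope,
        "r_squared": r2,
        "valid": True,
        "invalid_reason": "",
    }


def fit_keeling(samples: pd.DataFrame, min_points: int = 20) -> pd.DataFrame:
    """Daily Keeling fits for every (date, height) group of samples."""
    if "date" not in samples:
        samples = samples.assign(date=samples["timestamp"].dt.normalize())
    rows = [
        fit_keeling_day(g, min_points=min_points)
        for _, g in samples.groupby(["date", "height_m"], sort=True)
    ]
    fits = pd.DataFrame(rows)
    fits["retained"] = False
    return fits[FIT_COLUMNS[:-1] + ["retained"]] if not fits.empty else fits


def filter_fits(fits: pd.DataFrame, r2_threshold: float = 0.5) -> Tuple[pd.DataFrame, float]:
    """Apply the strict R^2 filter to valid fits.

    Sets ``retained = valid & (r_squared > r2_threshold)`` and returns
    (fits, retention_fraction) with the fraction as a percent of valid
    fits, rounded to 2 decimals.
    """
    if fits.empty:
        raise ValueError("no fits to filter")
    fits = fits.copy()
    fits["retained"] = fits["valid"] & (fits["r_squared"] > r2_threshold)
    n_valid = int(fits["valid"].sum())
    retention = round(100.0 * int(fits["retained"].sum()) / n_valid, 2) if n_valid else float("nan")
    return fits, retention


def summarize_daily(fits: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-date, per-height table of retained delta13C_mix.

    Every (date, height) combination of the input span is present;
    filtered-out or missing combinations carry NaN.
    """
    kept = fits[fits["retained"]]
    if kept.empty:
        logger.warning("no retained Keeling fits to summarize")
        return pd.DataFrame(
            columns=["date", "height_m", "delta13c_mix_permil", "intercept_se_permil", "n_points"]
        )
    idx = pd.MultiIndex.from_product(
        [sorted(fits["date"].unique()), sorted(fits["height_m"].unique())],
        names=["date", "height_m"],
    )
    table = (
        kept.set_index(["date", "height_m"])[
            ["delta13c_mix_permil", "intercept_se_permil", "n_points"]
        ]
        .reindex(idx)
        .reset_index()
    )
    return table
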