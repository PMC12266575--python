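"""Ecosystem-driver associations and regional flux-weighted aggregation.

Pearson correlations of the source signature (or any series) with daily
ecosystem covariates (GPP, respiration, wind, soil water content),
optionally per phenological stage, and the emission-weighted regional
mean of delta13C_source from a region table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


def correlate(
    x: pd.Series,
    y: pd.Series,
    groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Pearson correlation of paired series, optionally by group.

    Pairs with a missing value in either series are dropped.  Returns a
    tidy table with columns ``group, n, r, r_squared, p_value, defined``;
    a group with a constant series (or fewer than 3 pairs) is flagged
    ``defined=False`` rather than propagating NaN silently.
    """
    df = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)})
    df["group"] = "all" if groups is None else pd.Series(groups).to_numpy()
    rows = []
    for g, sub in df.groupby("group", sort=True):
        sub = sub.dropna(subset=["x", "y"])
        n = len(sub)
        if n < 3 or sub["x"].nunique() == 1 or sub["y"].nunique() == 1:
            rows.append(
                {"group": g, "n": n, "r": np.nan, "r_squared": np.nan,
                 "p_value": np.nan, "defined": False}
            )
            continue
        r, p = stats.pearsonr(sub["x"], sub["y"])
        rows.append(
            {"group": g, "n": n, "r": float(r), "r_squared": float(r) ** 2,
             "p_value": float(p), "defined": True}
        )
    return pd.DataFrame(rows)


def flux_weighted_delta(regions: pd.DataFrame) -> float:
    """Emission-weighted mean source signature over a region table.

    ``regions`` needs columns ``annual_ch4_emission`` (any consistent
    mass/yr unit, >= 0) and ``delta_source_permil``.  Invariant under a
    common positive rescaling of the emissions.
    """
    w = regions["annual_ch4_emission"].to_numpy(dtype=float)
    d = regions["delta_source_permil"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("annual_ch4_emission must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("total emission must be positive")
    return float(np.sum(w * d) / total)


def stage_windows(dates, stage_table: pd.DataFrame) -> pd.Series:
    """Phenological-stage label per date.

    ``stage_table`` rows carry ``label, start_date, end_date`` describing
    half-open intervals [start, end); overlapping intervals are a
    configuration error; dates outside every interval get NaN (flagged
    by the caller).
    """
    dates = pd.to_datetime(pd.Series(list(dates))).dt.normalize()
    st = stage_table.copy()
    st["start_date"] = pd.to_datetime(st["start_date"])
    st["end_date"] = pd.to_datetime(st["end_date"])
    st = st.sort_values("start_date").reset_index(drop=True)
    for i in range(1, len(st)):
        if st.loc[i, "start_date"] < st.loc[i - 1, "end_date"]:
            raise ValueError(
                f"overlapping stages {st.loc[i - 1, 'label']!r} and {st.loc[i, 'label']!r}"
            )
    labels = pd.Series(pd.NA, index=dates.index, dtype="object")
    for _, row in st.iterrows():
        mask = (dates >= row["start_date"]) & (dates < row["end_date"])
        labels[mask] = row["label"]
    n_missing = int(labels.isna().sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).warning("%d dates have no stage label", n_missing)
    return labels
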