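"""Calibration of raw CRDS analyzer streams.

Turns raw wet 12CH4/13CH4 records into drift-corrected, water-corrected,
calibrated 5-min ambient samples per height:

1. wet-to-dry conversion with the empirical humidity polynomials,
2. block averaging (last 2 min of each 5-min ambient visit, last 5 min
   of each 10-min reference visit; earlier records flush the line),
3. time interpolation of the reference-gas means across the campaign,
4. a per-step least-squares line through the three (interpolated
   measured, assigned) reference pairs, per isotopologue, applied to the
   ambient means,
5. delta13C from the calibrated isotopologue pair against VPDB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import WATER_POLY, combine_isotopologues, ratio_to_delta

REF_PORTS = ("REF1", "REF2", "REF3")

#: CSV column contract of calibrated samples.
CALIBRATED_COLUMNS = [
    "timestamp",
    "height_m",
    "ch4_dry_ppb",
    "delta13c_obs_permil",
    "n_raw_points",
]


@dataclass
class ReferenceGasAssignment:
    """Assigned values of one reference cylinder (WMO X2004A / VPDB)."""

    id: str
    assigned_ch4_ppb: float
    assigned_delta_permil: float


def check_assignments(assignments: Sequence[ReferenceGasAssignment]) -> None:
    if len(assignments) != 3:
        raise ValueError("exactly three reference gases are required")
    ch4 = [a.assigned_ch4_ppb for a in sorted(assignments, key=lambda a: a.id)]
    if not (ch4[0] < ch4[1] < ch4[2]):
        raise ValueError("reference gases must span a strictly increasing CH4 range")


@dataclass
class RejectionLedger:
    """Counts of dropped records/blocks, keyed by reason."""

    counts: Dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + int(n)


def water_correction_factor(h2o_percent, species: str):
    """Wet/dry ratio for the given isotopologue at the analyzer-reported
    humidity (percent).  Quadratic empirical interference polynomial;
    strictly decreasing in humidity for 12CH4 on the field range."""
    if species not in WATER_POLY:
        raise ValueError(f"unknown species {species!r}")
    h = np.asarray(h2o_percent, dtype=float)
    if np.any(h < 0):
        raise ValueError("h2o_percent must be >= 0")
    lin, quad = WATER_POLY[species]
    return 1.0 + lin * h + quad * h**2


def correct_water_vapor(raw: pd.DataFrame, ledger: RejectionLedger | None = None) -> pd.DataFrame:
    """Add dry mole fraction columns ``dry_12ch4_ppb``/``dry_13ch4_ppb``.

    Records whose correction factor is non-positive (unphysically high
    humidity) are dropped and counted.
    """
    f12 = water_correction_factor(raw["h2o_percent"], "12CH4")
    f13 = water_correction_factor(raw["h2o_percent"], "13CH4")
    ok = (f12 > 0) & (f13 > 0)
    if ledger is not None and (~ok).any():
        ledger.add("nonpositive_water_factor", int((~ok).sum()))
    out = raw.loc[ok].copy()
    out["dry_12ch4_ppb"] = out["wet_12ch4_ppb"] / f12[ok]
    out["dry_13ch4_ppb"] = out["wet_13ch4_ppb"] / f13[ok]
    return out


def label_blocks(raw: pd.DataFrame) -> pd.Series:
    """Block id for consecutive same-port runs (one valve visit each)."""
    port = raw["port"]
    return (port != port.shift()).cumsum() - 1


def aggregate_block(
    block: pd.DataFrame,
    ambient_slot_min: int = 5,
    ref_slot_min: int = 10,
    min_points: int = 3,
) -> dict | None:
    """Average one valve visit, discarding the line-flush records.

    Ambient visits keep the final 2 minutes of the 5-min slot; reference
    visits keep the final 5 minutes of the 10-min slot.  Returns a dict
    of means with the visit-center timestamp, or None when fewer than
    ``min_points`` records survive.
    """
    port = block["port"].iloc[0]
    t0 = block["timestamp"].iloc[0]
    slot = ref_slot_min if port.startswith("REF") else ambient_slot_min
    keep_from = t0 + pd.Timedelta(minutes=slot - (5 if port.startswith("REF") else 2))
    kept = block[block["timestamp"] >= keep_from]
    if len(kept) < min_points:
        return None
    return {
        "timestamp": t0 + pd.Timedelta(minutes=slot / 2),
        "port": port,
        "dry_12ch4_ppb": kept["dry_12ch4_ppb"].mean(),
        "dry_13ch4_ppb": kept["dry_13ch4_ppb"].mean(),
        "n_raw_points": len(kept),
    }


def aggregate_stream(
    raw_dry: pd.DataFrame,
    ambient_slot_min: int = 5,
    ref_slot_min: int = 10,
    min_points: int = 3,
    ledger: RejectionLedger | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`aggregate_block` over the whole stream."""
    df = raw_dry.copy()
    df["_block"] = label_blocks(df)
    g = df.groupby("_block", sort=True)
    t0 = g["timestamp"].first()
    port = g["port"].first()
    is_ref = port.str.startswith("REF")
    slot_min = np.where(is_ref, ref_slot_min, ambient_slot_min)
    tail_min = np.where(is_ref, 5, 2)
    keep_from = t0 + pd.to_timedelta(slot_min - tail_min, unit="m")
    df["_keep"] = df["timestamp"] >= keep_from.loc[df["_block"]].to_numpy()
    kept = df[df["_keep"]]
    gk = kept.groupby("_block", sort=True)
    out = pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(slot_min / 2, unit="m"),
            "port": port,
            "dry_12ch4_ppb": gk["dry_12ch4_ppb"].mean(),
            "dry_13ch4_ppb": gk["dry_13ch4_ppb"].mean(),
            "n_raw_points": gk.size().reindex(t0.index, fill_value=0),
        }
    )
    bad = out["n_raw_points"] < min_points
    if ledger is not None and bad.any():
        ledger.add("too_few_points_in_block", int(bad.sum()))
    return out.loc[~bad].reset_index(drop=True)


def interpolate_reference(
    ref_blocks: pd.DataFrame, at_times: pd.Series
) -> Dict[str, Dict[str, np.ndarray]]:
    """Interpolate each reference gas's block means to arbitrary times.

    Linear in time between visits, constant beyond the first/last visit.
    Raises if any gas has fewer than two visits.
    Returns ``{port: {"dry_12ch4_ppb": array, "dry_13ch4_ppb": array}}``.
    """
    t_query = pd.to_datetime(at_times).astype("int64").to_numpy() / 1e9
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for port in REF_PORTS:
        sub = ref_blocks[ref_blocks["port"] == port].sort_values("timestamp")
        if len(sub) < 2:
            raise ValueError(f"reference gas {port} has fewer than 2 visits")
        t_ref = sub["timestamp"].astype("int64").to_numpy() / 1e9
        out[port] = {
            sp: np.interp(t_query, t_ref, sub[sp].to_numpy())
            for sp in ("dry_12ch4_ppb", "dry_13ch4_ppb")
        }
    return out


def _fit_lines(measured: np.ndarray, assigned: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-row OLS line assigned = slope*measured + intercept through the
    three reference points.  measured: (n, 3); assigned: (3,)."""
    mx = measured.mean(axis=1)
    my = assigned.mean()
    sxx = ((measured - mx[:, None]) ** 2).sum(axis=1)
    sxy = ((measured - mx[:, None]) * (assigned - my)).sum(axis=1)
    slope = sxy / sxx
    intercept = my - slope * mx
    return slope, intercept


def build_and_apply_drift(
    ambient_blocks: pd.DataFrame,
    ref_blocks: pd.DataFrame,
    assignments: Sequence[ReferenceGasAssignment],
    ledger: RejectionLedger | None = None,
) -> pd.DataFrame:
    """Drift-correct and calibrate ambient block means.

    For every ambient 5-min step, the three reference gases' measured
    values (interpolated to that step) are regressed against their
    assigned values, separately per isotopologue; the resulting affine
    map calibrates the ambient means.  Steps whose fitted gain is
    non-positive are dropped and counted.  Adds ``cal_12ch4_ppb``,
    ``cal_13ch4_ppb`` and drift diagnostics columns.
    """
    check_assignments(assignments)
    by_id = {a.id: a for a in assignments}
    from .constants import split_isotopologues

    assigned = {}
    for port in REF_PORTS:
        a = by_id[port]
        c12, c13 = split_isotopologues(a.assigned_ch4_ppb, a.assigned_delta_permil)
        assigned[port] = (float(c12), float(c13))

    interp = interpolate_reference(ref_blocks, ambient_blocks["timestamp"])
    out = ambient_blocks.copy()
    for sp_idx, sp in enumerate(("dry_12ch4_ppb", "dry_13ch4_ppb")):
        measured = np.column_stack([interp[p][sp] for p in REF_PORTS])
        target = np.array([assigned[p][sp_idx] for p in REF_PORTS])
        slope, intercept = _fit_lines(measured, target)
        cal = slope * out[sp].to_numpy() + intercept
        tag = sp.split("_")[1]
        out[f"cal_{tag}_ppb"] = cal
        out[f"drift_gain_{tag}"] = slope
        out[f"drift_offset_{tag}"] = intercept
    bad = (out["drift_gain_12ch4"] <= 0) | (out["drift_gain_13ch4"] <= 0)
    if ledger is not None and bad.any():
        ledger.add("nonpositive_drift_gain", int(bad.sum()))
    return out.loc[~bad].reset_index(drop=True)


def compute_delta13c(ch4_12_ppb, ch4_13_ppb):
    """delta13C (permil, VPDB) from the calibrated isotopologue pair."""
    c12 = np.asarray(ch4_12_ppb, dtype=float)
    c13 = np.asarray(ch4_13_ppb, dtype=float)
    if np.any(c12 <= 0) or np.any(c13 <= 0):
        raise ValueError("isotopologue mole fractions must be positive")
    return ratio_to_delta(c13 / c12)


def calibrate_stream(
    raw: pd.DataFrame,
    assignments: Sequence[ReferenceGasAssignment],
    min_points: int = 3,
) -> Tuple[pd.DataFrame, RejectionLedger]:
    """Full raw-to-calibrated chain.

    Returns the calibrated 5-min ambient samples (columns
    ``timestamp, height_m, ch4_dry_ppb, delta13c_obs_permil,
    n_raw_points`` plus ``date``) and the rejection ledger; every ambient
    visit in the input is either a returned sample or a ledger count.
    """
    ledger = RejectionLedger()
    dry = correct_water_vapor(raw, ledger)
    blocks = aggregate_stream(dry, min_points=min_points, ledger=ledger)
    refs = blocks[blocks["port"].str.startswith("REF")]
    amb = blocks[blocks["port"].str.startswith("H")].reset_index(drop=True)
    cal = build_and_apply_drift(amb, refs, assignments, ledger)
    total, delta = combine_isotopologues(
        cal["cal_12ch4_ppb"].to_numpy(), cal["cal_13ch4_ppb"].to_numpy()
    )
    samples = pd.DataFrame(
        {
            "timestamp": cal["timestamp"],
            "height_m": cal["port"].str.removeprefix("H").astype(float),
            "ch4_dry_ppb": total,
            "delta13c_obs_permil": delta,
            "n_raw_points": cal["n_raw_points"],
        }
    )
    samples["date"] = samples["timestamp"].dt.normalize()
    return samples, ledger


def assignments_from_config(refgas_values) -> List[ReferenceGasAssignment]:
    """Build assignment records from a scenario's (CH4, delta) pairs."""
    return [
        ReferenceGasAssignment(f"REF{i+1}", ch4, d)
        for i, (ch4, d) in enumerate(refgas_values)
    ]
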