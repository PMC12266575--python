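"""Synthetic rice-paddy campaign generator.

Produces, from a seeded :class:`~paddyiso.config.ScenarioConfig`:

* ground-truth daily curves (``simulate_truth``): plant-pathway and
  non-plant source signatures, plant-mediated fraction k_p, CH4 flux and
  the pathway-weighted source signature
  delta13C_source = k_p * delta13C_P + (1 - k_p) * delta13C_NP;
* the clean atmospheric mixing stream at three heights
  (``simulate_atmosphere``): CH4 enhancements above background scale with
  the daily flux, are damped by wind and attenuated with height; each
  observation mixes background air with source air of signature
  delta13C_source + epsilon by exact Keeling mass balance, so noise-free
  daily regressions of delta on 1/CH4 recover delta13C_source + epsilon;
* the raw analyzer stream (``simulate_analyzer``): isotopologue split,
  linear gain/offset drift, water-vapor interference, reference-gas
  injections and white noise — the exact forward model the calibration
  module inverts;
* daily ecosystem covariates and the two process-model k_p input tables.
"""

from __future__ import annotations

import logging
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .constants import delta_to_ratio, ratio_to_delta, split_isotopologues

logger = logging.getLogger(__name__)

REF_PORTS = ("REF1", "REF2", "REF3")

# Fixed spawn order of the per-purpose random substreams.
_STREAMS = {"wind": 0, "atmosphere": 1, "analyzer": 2, "ecosystem": 3, "kp": 4}


def _rng(config: ScenarioConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.rng_seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def season_dates(config: ScenarioConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.year, 1, 1) + pd.Timedelta(days=config.season_start_doy - 1)
    return pd.date_range(start, periods=config.season_length_d, freq="D")


def height_port(height_m: float) -> str:
    return f"H{height_m:g}"


def simulate_truth(config: ScenarioConfig) -> pd.DataFrame:
    """Daily ground truth for one season.

    Returns one row per day with columns ``doy``, ``date``,
    ``true_deltaP_permil``, ``true_deltaNP_permil``, ``true_kp``,
    ``true_flux`` and ``true_delta_source_permil``; the source identity
    delta_source = kp*deltaP + (1-kp)*deltaNP holds exactly.
    """
    days = np.arange(config.season_length_d)
    deltaP = config.deltaP_curve.evaluate(days)
    deltaNP = np.full_like(deltaP, config.deltaNP_permil)
    kp = config.kp_curve.evaluate(days)
    flux = config.flux_curve.evaluate(days)
    dates = season_dates(config)
    return pd.DataFrame(
        {
            "day_index": days,
            "doy": config.season_start_doy + days,
            "date": dates,
            "true_deltaP_permil": deltaP,
            "true_deltaNP_permil": deltaNP,
            "true_kp": kp,
            "true_flux": flux,
            "true_delta_source_permil": kp * deltaP + (1.0 - kp) * deltaNP,
        }
    )


def daily_wind(config: ScenarioConfig) -> np.ndarray:
    """Daily-mean wind speed (m/s) as a stationary AR(1) series, clipped
    at the configured floor."""
    rng = _rng(config, "wind")
    n = config.season_length_d
    phi = config.wind.autocorrelation
    innov_sd = config.wind.sd_ms * np.sqrt(max(1.0 - phi**2, 0.0))
    w = np.empty(n)
    w[0] = config.wind.mean_ms + config.wind.sd_ms * rng.standard_normal()
    for i in range(1, n):
        w[i] = (
            config.wind.mean_ms
            + phi * (w[i - 1] - config.wind.mean_ms)
            + innov_sd * rng.standard_normal()
        )
    n_clip = int(np.sum(w < config.wind.floor_ms))
    if n_clip:
        logger.info("clipped %d daily wind draws to floor %.2f m/s", n_clip, config.wind.floor_ms)
    return np.maximum(w, config.wind.floor_ms)


def build_schedule(config: ScenarioConfig) -> pd.DataFrame:
    """Valve-manifold sampling schedule for the whole campaign.

    Ambient air is sampled 5 min per height cyclically; after every
    600 min of ambient sampling the three reference gases run 10 min
    each.  A reference visit opens the campaign and a closing visit is
    appended at season end so every ambient block is bracketed by
    reference measurements.
    """
    end_min = config.season_length_d * 1440
    amb = float(config.ambient_slot_min)
    rows = []
    t = 0.0
    while True:
        for port in REF_PORTS:
            rows.append((t, port, float(config.ref_slot_min)))
            t += config.ref_slot_min
        if t >= end_min:
            break
        amb_end = t + config.ambient_cycle_min
        h_idx = 0
        while t < amb_end and t < end_min:
            rows.append((t, height_port(config.heights_m[h_idx]), amb))
            t += amb
            h_idx = (h_idx + 1) % len(config.heights_m)
    df = pd.DataFrame(rows, columns=["t_start_min", "port", "duration_min"])
    df.index.name = "block_id"
    return df.reset_index()


def simulate_atmosphere(truth: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Clean (noise-free instrument) ambient stream.

    One record per analyzer cadence step inside each ambient block, with
    columns ``timestamp``, ``block_id``, ``height_m``, ``day_index``,
    ``true_ch4_ppb``, ``true_delta_permil``.  Within a day all points lie
    exactly on the Keeling line with intercept
    ``true_delta_source + epsilon_truth``.
    """
    if len(truth) < config.season_length_d:
        raise ValueError("truth must cover every simulated day")
    sched = build_schedule(config)
    amb = sched[sched.port.str.startswith("H")].reset_index(drop=True)
    per_block = int(config.ambient_slot_min * 60 // config.cadence_s)
    offsets = np.arange(per_block) * config.cadence_s  # seconds

    t0 = season_dates(config)[0]
    starts_s = amb.t_start_min.to_numpy() * 60.0
    rec_t = (np.repeat(starts_s, per_block) + np.tile(offsets, len(amb)))
    block_id = np.repeat(amb.block_id.to_numpy(), per_block)
    heights = np.repeat(
        amb.port.str.removeprefix("H").astype(float).to_numpy(), per_block
    )
    day_idx = np.minimum(
        (rec_t // 86400).astype(int), config.season_length_d - 1
    )

    wind = daily_wind(config)
    flux = truth["true_flux"].to_numpy()
    d_src = truth["true_delta_source_permil"].to_numpy() + config.epsilon_truth_permil

    atten = np.array([config.height_attenuation[h] for h in config.heights_m])
    atten_of = dict(zip(config.heights_m, atten))
    att_rec = np.vectorize(atten_of.get)(heights).astype(float)

    base = (
        config.enhancement_scale_ppb
        * flux[day_idx]
        * att_rec
        * (config.wind.mean_ms / wind[day_idx])
    )
    # one enhancement draw per 5-min slot; records within a slot share it
    rng = _rng(config, "atmosphere")
    sig = config.slot_lognormal_sigma
    if sig > 0:
        factor = np.repeat(
            np.exp(rng.normal(-0.5 * sig**2, sig, size=len(amb))), per_block
        )
    else:
        factor = 1.0
    enh = base * factor

    ch4 = config.background_ch4_ppb + enh
    # Keeling mass balance: CH4*delta conserved between background and
    # source air, hence delta is exactly linear in 1/CH4.
    delta = d_src[day_idx] + config.background_ch4_ppb * (
        config.background_delta_permil - d_src[day_idx]
    ) / ch4

    return pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(rec_t, unit="s"),
            "block_id": block_id,
            "height_m": heights,
            "day_index": day_idx,
            "true_ch4_ppb": ch4,
            "true_delta_permil": delta,
        }
    )


def _h2o_percent(config: ScenarioConfig, t_seconds: np.ndarray) -> np.ndarray:
    """Diurnal humidity cycle of the sampled (undried) ambient air."""
    hour = (t_seconds / 3600.0) % 24.0
    h = config.h2o_mean_percent + config.h2o_amplitude_percent * np.sin(
        2.0 * np.pi * (hour - 8.0) / 24.0
    )
    return np.clip(h, 0.02, 3.0)


def _water_factor(h2o: np.ndarray, lin: float) -> np.ndarray:
    return 1.0 + lin * h2o - 0.0003 * h2o**2


def simulate_analyzer(clean: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Raw analyzer stream: the forward instrument model.

    Applies, per record: isotopologue split of (CH4, delta); linear
    gain/offset drift on the dry isotopologue readings; multiplicative
    water-vapor interference at the sampled humidity (reference gases are
    dry); white noise on wet 12CH4 (ppb) and on delta (permil); and
    interleaves the reference-gas blocks of the sampling schedule.
    Columns: ``timestamp``, ``port``, ``wet_12ch4_ppb``, ``wet_13ch4_ppb``,
    ``h2o_percent``.
    """
    t0 = season_dates(config)[0]
    t_s = (clean["timestamp"] - t0).dt.total_seconds().to_numpy()

    c12, c13 = split_isotopologues(
        clean["true_ch4_ppb"].to_numpy(), clean["true_delta_permil"].to_numpy()
    )
    amb_ports = clean["height_m"].map(height_port).to_numpy()
    amb_h2o = _h2o_percent(config, t_s)
    # Drift is slow relative to a valve visit: evaluate the gain/offset at
    # the visit center (the calibration's slot-center convention), so one
    # affine map describes each 5/10-min block exactly.
    amb_start = clean.groupby("block_id")["timestamp"].transform("first")
    amb_drift_t = (
        (amb_start - t0).dt.total_seconds().to_numpy()
        + config.ambient_slot_min * 30.0
    )

    sched = build_schedule(config)
    refs = sched[sched.port.str.startswith("REF")].reset_index(drop=True)
    per_ref = int(config.ref_slot_min * 60 // config.cadence_s)
    ref_t = (
        np.repeat(refs.t_start_min.to_numpy() * 60.0, per_ref)
        + np.tile(np.arange(per_ref) * config.cadence_s, len(refs))
    )
    ref_drift_t = (
        np.repeat(refs.t_start_min.to_numpy() * 60.0, per_ref)
        + config.ref_slot_min * 30.0
    )
    ref_port = np.repeat(refs.port.to_numpy(), per_ref)
    assigned = {
        p: split_isotopologues(ch4, d)
        for p, (ch4, d) in zip(REF_PORTS, config.refgas_values)
    }
    r12 = np.array([assigned[p][0] for p in ref_port])
    r13 = np.array([assigned[p][1] for p in ref_port])
    ref_h2o = np.zeros_like(ref_t)

    all_t = np.concatenate([t_s, ref_t])
    all_12 = np.concatenate([c12, r12])
    all_13 = np.concatenate([c13, r13])
    all_h2o = np.concatenate([amb_h2o, ref_h2o])
    all_port = np.concatenate([amb_ports, ref_port])

    t_days = np.concatenate([amb_drift_t, ref_drift_t]) / 86400.0
    d = config.drift
    m12 = (1.0 + d.gain_per_day_12 * t_days) * all_12 + d.offset_ppb_per_day_12 * t_days
    m13 = (1.0 + d.gain_per_day_13 * t_days) * all_13 + d.offset_ppb_per_day_13 * t_days

    wet12 = m12 * _water_factor(all_h2o, -0.0099)
    wet13 = m13 * _water_factor(all_h2o, -5.0344e-5)

    if config.noise.sd_12ch4_ppb > 0 or config.noise.sd_delta_permil > 0:
        rng = _rng(config, "analyzer")
        delta_m = ratio_to_delta(wet13 / wet12)
        wet12 = wet12 + rng.normal(0.0, config.noise.sd_12ch4_ppb, size=wet12.shape)
        delta_m = delta_m + rng.normal(0.0, config.noise.sd_delta_permil, size=wet12.shape)
        wet13 = wet12 * delta_to_ratio(delta_m)

    out = pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(all_t, unit="s"),
            "port": all_port,
            "wet_12ch4_ppb": wet12,
            "wet_13ch4_ppb": wet13,
            "h2o_percent": all_h2o,
        }
    )
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def simulate_ecosystem(truth: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Daily ecosystem covariates (flux-tower style series).

    GPP follows the flux curve's seasonal shape (root exudates and
    aerenchyma development tie photosynthesis to CH4 emission), so the
    true delta13C_source is anticorrelated with GPP by construction.
    """
    rng = _rng(config, "ecosystem")
    n = len(truth)
    wind = daily_wind(config)
    flux_norm = truth["true_flux"].to_numpy() / config.flux_curve.peak_value
    gpp = 25.0 * flux_norm + rng.normal(0.0, 0.8, n)
    resp = 0.55 * gpp + 2.0 + rng.normal(0.0, 0.5, n)
    day = truth["day_index"].to_numpy()
    drain_day = int(0.75 * config.season_length_d)
    swc = np.where(day < drain_day, 0.55, 0.55 - 0.004 * (day - drain_day))
    swc = np.clip(swc + rng.normal(0.0, 0.01, n), 0.0, 1.0)
    stage = np.select(
        [day < n // 3, day < 2 * n // 3],
        ["vegetative", "reproductive"],
        default="ripening",
    )
    return pd.DataFrame(
        {
            "date": truth["date"],
            "ch4_flux": truth["true_flux"] * (1.0 + rng.normal(0.0, 0.05, n)),
            "gpp": gpp,
            "respiration": resp,
            "wind_speed": wind,
            "friction_velocity": 0.08 * wind + rng.normal(0.0, 0.01, n),
            "swc": swc,
            "phenostage": stage,
        }
    )


def simulate_kp_tables(truth: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Daily plant-mediated fraction tables of the two process models.

    Both are the truth k_p plus independent model error (sd
    ``kp_model_error_sd``), clipped to [0, 1]; long format with columns
    ``date``, ``model_label``, ``kp``.
    """
    rng = _rng(config, "kp")
    frames = []
    for label in ("IBIS", "BEPS"):
        kp = np.clip(
            truth["true_kp"].to_numpy()
            + rng.normal(0.0, config.kp_model_error_sd, len(truth)),
            0.0,
            1.0,
        )
        frames.append(
            pd.DataFrame({"date": truth["date"], "model_label": label, "kp": kp})
        )
    return pd.concat(frames, ignore_index=True)


def simulate_campaign(config: ScenarioConfig) -> Dict[str, pd.DataFrame]:
    """Run the full generator; returns truth, clean stream, raw stream,
    ecosystem dailies and k_p tables keyed by name."""
    truth = simulate_truth(config)
    clean = simulate_atmosphere(truth, config)
    raw = simulate_analyzer(clean, config)
    return {
        "truth": truth,
        "clean": clean,
        "raw": raw,
        "ecosystem": simulate_ecosystem(truth, config),
        "kp": simulate_kp_tables(truth, config),
    }
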