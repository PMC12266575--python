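"""Scenario configuration for the synthetic field campaign.

The defaults describe one rice growing season observed from transplanting
(DOY 176) to maturity (DOY 283): a "U-shaped" seasonal curve for the
plant-pathway source signature delta13C_P, a near-constant non-plant
signature delta13C_NP, a logistic rise of the plant-mediated emission
fraction k_p as aerenchyma develops, and a rise-and-fall CH4 flux curve.
A cavity ring-down analyzer samples three heights (0.5/1.5/3.0 m) for
5 min each in rotation, with three reference gases injected for 10 min
each after every 600 min of ambient sampling.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

# Admissible end-member boxes of the mixing-model inversion.  The
# generator keeps its truth curves inside these so that recovery is
# well posed.
DELTA_P_BOUNDS: Tuple[float, float] = (-80.0, -55.0)
DELTA_NP_BOUNDS: Tuple[float, float] = (-75.0, -40.0)
EPSILON_BOUNDS: Tuple[float, float] = (0.0, 3.0)


class ConfigurationError(ValueError):
    """Raised when a scenario field is inconsistent; names the field."""


class SeasonalDipCurve(BaseModel):
    """U-shaped seasonal curve: starts at ``start_permil``, reaches
    ``minimum_permil`` at ``day_of_minimum`` (days after season start),
    then recovers quadratically."""

    start_permil: float = -61.3
    minimum_permil: float = -72.3
    day_of_minimum: int = 84

    def evaluate(self, day: np.ndarray) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        t = (day - self.day_of_minimum) / float(self.day_of_minimum)
        return self.minimum_permil + (self.start_permil - self.minimum_permil) * t**2


class LogisticCurve(BaseModel):
    """Logistic rise between ``floor`` and ``ceiling`` with midpoint at
    ``midpoint_day`` (days after season start) and rate ``steepness``/day."""

    floor: float = 0.30
    ceiling: float = 0.90
    midpoint_day: float = 35.0
    steepness: float = 0.12

    def evaluate(self, day: np.ndarray) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        z = self.steepness * (day - self.midpoint_day)
        return self.floor + (self.ceiling - self.floor) / (1.0 + np.exp(-z))


class RiseFallCurve(BaseModel):
    """Asymmetric rise-and-fall curve (piecewise Gaussian) for the daily
    CH4 flux, in arbitrary emission units; a small floor keeps the
    source on even in the shoulder season."""

    peak_value: float = 1.0
    peak_day: float = 55.0
    rise_width_d: float = 25.0
    fall_width_d: float = 18.0
    floor_value: float = 0.15

    def evaluate(self, day: np.ndarray) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        width = np.where(day < self.peak_day, self.rise_width_d, self.fall_width_d)
        bump = self.peak_value * np.exp(-0.5 * ((day - self.peak_day) / width) ** 2)
        return np.maximum(bump, self.floor_value)


class WindParams(BaseModel):
    """Daily-mean wind as an AR(1) process (m/s)."""

    mean_ms: float = 2.5
    sd_ms: float = 0.8
    autocorrelation: float = 0.5
    floor_ms: float = 0.3


class NoiseParams(BaseModel):
    """Per-record analyzer noise: sd of wet 12CH4 (ppb) and of delta (permil)."""

    sd_12ch4_ppb: float = 1.0
    sd_delta_permil: float = 0.8


class DriftParams(BaseModel):
    """Linear per-day gain/offset drift of the analyzer, per isotopologue.

    Default gain drift is 5e-5/day (~0.5% over a 100-day season)."""

    gain_per_day_12: float = 5.0e-5
    offset_ppb_per_day_12: float = 0.005
    gain_per_day_13: float = -4.0e-5
    offset_ppb_per_day_13: float = 5.0e-5


class ScenarioConfig(BaseModel):
    """Full description of one synthetic campaign."""

    year: int = 2018
    season_start_doy: int = 176
    season_length_d: int = 108
    heights_m: List[float] = Field(default_factory=lambda: [0.5, 1.5, 3.0])
    background_ch4_ppb: float = 1950.0
    background_delta_permil: float = -47.4

    deltaP_curve: SeasonalDipCurve = Field(default_factory=SeasonalDipCurve)
    deltaNP_permil: float = -62.0
    epsilon_truth_permil: float = 0.8
    kp_curve: LogisticCurve = Field(default_factory=LogisticCurve)
    flux_curve: RiseFallCurve = Field(default_factory=RiseFallCurve)
    wind: WindParams = Field(default_factory=WindParams)
    noise: NoiseParams = Field(default_factory=NoiseParams)
    drift: DriftParams = Field(default_factory=DriftParams)

    #: Assigned (CH4 ppb, delta13C permil) of the three reference gases.
    refgas_values: List[Tuple[float, float]] = Field(
        default_factory=lambda: [
            (2004.32, -47.2),
            (3592.80, -39.5),
            (5017.03, -33.2),
        ]
    )

    # Observation model knobs (no counterpart in the admissible boxes).
    enhancement_scale_ppb: float = 800.0
    slot_lognormal_sigma: float = 0.6
    height_attenuation: Dict[float, float] = Field(
        default_factory=lambda: {0.5: 1.0, 1.5: 0.7, 3.0: 0.5}
    )
    cadence_s: int = 30
    ambient_slot_min: int = 5
    ref_slot_min: int = 10
    ambient_cycle_min: int = 600
    h2o_mean_percent: float = 1.5
    h2o_amplitude_percent: float = 1.2
    #: sd of the model error added to the truth k_p when building the two
    #: process-model k_p input tables.
    kp_model_error_sd: float = 0.02

    rng_seed: int = 42

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.season_length_d < 30:
            raise ConfigurationError("season_length_d must be >= 30")
        days = np.arange(self.season_length_d)
        if not (0 < self.deltaP_curve.day_of_minimum):
            raise ConfigurationError("deltaP_curve.day_of_minimum must be positive")
        if self.deltaP_curve.day_of_minimum >= self.season_length_d:
            raise ConfigurationError(
                "deltaP_curve.day_of_minimum lies outside the season"
            )
        dP = self.deltaP_curve.evaluate(days)
        if dP.min() < DELTA_P_BOUNDS[0] or dP.max() > DELTA_P_BOUNDS[1]:
            raise ConfigurationError(
                "deltaP_curve leaves the admissible range "
                f"[{DELTA_P_BOUNDS[0]}, {DELTA_P_BOUNDS[1]}] permil"
            )
        if not (DELTA_NP_BOUNDS[0] <= self.deltaNP_permil <= DELTA_NP_BOUNDS[1]):
            raise ConfigurationError(
                "deltaNP_permil outside the admissible range "
                f"[{DELTA_NP_BOUNDS[0]}, {DELTA_NP_BOUNDS[1]}] permil"
            )
        if not (EPSILON_BOUNDS[0] <= self.epsilon_truth_permil <= EPSILON_BOUNDS[1]):
            raise ConfigurationError("epsilon_truth_permil must lie in [0, 3] permil")
        kp = self.kp_curve.evaluate(days)
        if kp.min() < 0.0 or kp.max() > 1.0:
            raise ConfigurationError("kp_curve must evaluate within [0, 1]")
        for name, v in [
            ("noise.sd_12ch4_ppb", self.noise.sd_12ch4_ppb),
            ("noise.sd_delta_permil", self.noise.sd_delta_permil),
            ("wind.sd_ms", self.wind.sd_ms),
        ]:
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.refgas_values) != 3:
            raise ConfigurationError("refgas_values must list exactly three gases")
        ch4s = [c for c, _ in self.refgas_values]
        if not (ch4s[0] < ch4s[1] < ch4s[2]):
            raise ConfigurationError(
                "refgas_values must span a strictly increasing CH4 range"
            )
        missing = [h for h in self.heights_m if h not in self.height_attenuation]
        if missing:
            raise ConfigurationError(
                f"height_attenuation missing heights {missing}"
            )
        return self
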