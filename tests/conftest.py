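import pytest

from paddyiso.calibration import assignments_from_config, calibrate_stream
from paddyiso.config import (
    LogisticCurve,
    NoiseParams,
    RiseFallCurve,
    ScenarioConfig,
    SeasonalDipCurve,
)
from paddyiso.synthetic import (
    simulate_analyzer,
    simulate_atmosphere,
    simulate_campaign,
    simulate_truth,
)


def small_scenario(**overrides) -> ScenarioConfig:
    """A 40-day campaign, small enough for fast unit tests but with the
    same structure as the full season."""
    params = dict(
        season_length_d=40,
        deltaP_curve=SeasonalDipCurve(day_of_minimum=28),
        kp_curve=LogisticCurve(midpoint_day=14.0, steepness=0.2),
        flux_curve=RiseFallCurve(peak_day=20.0, rise_width_d=10.0, fall_width_d=8.0),
        rng_seed=7,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


@pytest.fixture(scope="session")
def scenario_small():
    return small_scenario()


@pytest.fixture(scope="session")
def scenario_small_noisefree():
    return small_scenario(noise=NoiseParams(sd_12ch4_ppb=0.0, sd_delta_permil=0.0))


@pytest.fixture(scope="session")
def campaign_small(scenario_small):
    return simulate_campaign(scenario_small)


@pytest.fixture(scope="session")
def clean_small_noisefree(scenario_small_noisefree):
    truth = simulate_truth(scenario_small_noisefree)
    clean = simulate_atmosphere(truth, scenario_small_noisefree)
    return truth, clean


@pytest.fixture(scope="session")
def calibrated_small_noisefree(scenario_small_noisefree, clean_small_noisefree):
    _, clean = clean_small_noisefree
    raw = simulate_analyzer(clean, scenario_small_noisefree)
    samples, ledger = calibrate_stream(
        raw, assignments_from_config(scenario_small_noisefree.refgas_values)
    )
    return samples, ledger


@pytest.fixture(scope="session")
def calibrated_small(scenario_small, campaign_small):
    samples, ledger = calibrate_stream(
        campaign_small["raw"], assignments_from_config(scenario_small.refgas_values)
    )
    return samples, ledger
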