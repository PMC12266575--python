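"""Calibration chain: water correction, block averaging, drift removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddyiso.calibration import (
    RejectionLedger,
    ReferenceGasAssignment,
    aggregate_block,
    aggregate_stream,
    assignments_from_config,
    build_and_apply_drift,
    calibrate_stream,
    compute_delta13c,
    correct_water_vapor,
    interpolate_reference,
    water_correction_factor,
)
from paddyiso.constants import R_VPDB, combine_isotopologues, split_isotopologues


class TestWaterCorrection:
    def test_dry_gas_factor_is_unity(self):
        assert water_correction_factor(0.0, "12CH4") == 1.0
        assert water_correction_factor(0.0, "13CH4") == 1.0

    def test_printed_polynomial_at_three_percent(self):
        # 1 - 0.0099*3 - 0.0003*9 = 0.9676
        assert water_correction_factor(3.0, "12CH4") == pytest.approx(0.9676, abs=1e-12)

    def test_heavy_isotopologue_factor_at_driest_point(self):
        f = water_correction_factor(0.02, "13CH4")
        assert 0.999998 < f < 1.0

    def test_negative_humidity_rejected(self):
        with pytest.raises(ValueError):
            water_correction_factor(-0.1, "12CH4")

    @given(st.floats(min_value=0.0, max_value=4.99))
    @settings(max_examples=50, derandomize=True)
    def test_factor_strictly_decreasing_for_light_isotopologue(self, h):
        assert water_correction_factor(h + 0.01, "12CH4") < water_correction_factor(h, "12CH4")

    def test_wet_to_dry_division(self):
        raw = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp("2018-06-25")],
                "port": ["H0.5"],
                "wet_12ch4_ppb": [1935.2],
                "wet_13ch4_ppb": [21.0],
                "h2o_percent": [3.0],
            }
        )
        out = correct_water_vapor(raw)
        assert out.dry_12ch4_ppb.iloc[0] == pytest.approx(1935.2 / 0.9676, rel=1e-12)


class TestAggregation:
    def _block(self, values, port, start="2018-06-25 00:00:00"):
        t0 = pd.Timestamp(start)
        return pd.DataFrame(
            {
                "timestamp": [t0 + pd.Timedelta(seconds=30 * i) for i in range(len(values))],
                "port": port,
                "dry_12ch4_ppb": values,
                "dry_13ch4_ppb": [v * 0.011 for v in values],
            }
        )

    def test_ambient_block_averages_last_two_minutes(self):
        out = aggregate_block(self._block(list(range(1, 11)), "H0.5"))
        assert out["dry_12ch4_ppb"] == pytest.approx(8.5)  # mean of 7..10
        assert out["n_raw_points"] == 4
        assert out["timestamp"] == pd.Timestamp("2018-06-25 00:02:30")

    def test_reference_block_of_constant_value(self):
        out = aggregate_block(self._block([5.0] * 20, "REF1"))
        assert out["dry_12ch4_ppb"] == pytest.approx(5.0)
        assert out["n_raw_points"] == 10  # last 5 of 10 min at 30-s cadence

    def test_step_change_before_window_excluded(self):
        values = [100.0] * 5 + [2.0] * 5  # step at 2.5 min, window starts at 3 min
        out = aggregate_block(self._block(values, "H0.5"))
        assert out["dry_12ch4_ppb"] == pytest.approx(2.0)

    def test_too_few_points_rejected(self):
        ledger = RejectionLedger()
        out = aggregate_stream(self._block([1.0, 2.0], "H0.5"), min_points=3, ledger=ledger)
        assert out.empty and ledger.counts["too_few_points_in_block"] == 1


class TestReferenceInterpolation:
    def _refs(self, times_values):
        return pd.DataFrame(
            {
                "timestamp": [pd.Timestamp(t) for t, _ in times_values],
                "port": "REF1",
                "dry_12ch4_ppb": [v for _, v in times_values],
                "dry_13ch4_ppb": [v * 0.011 for _, v in times_values],
            }
        )

    def test_midpoint_and_constant_extrapolation(self):
        refs = pd.concat(
            [
                self._refs([("2018-06-25 00:00", 2000.0), ("2018-06-25 00:10", 2010.0)]),
                *[
                    self._refs([("2018-06-25 00:00", 1.0), ("2018-06-25 00:10", 1.0)]).assign(
                        port=p
                    )
                    for p in ("REF2", "REF3")
                ],
            ]
        )
        t = pd.Series(pd.to_datetime(["2018-06-25 00:05", "2018-06-24 23:00", "2018-06-25 01:00"]))
        out = interpolate_reference(refs, t)
        assert out["REF1"]["dry_12ch4_ppb"] == pytest.approx([2005.0, 2000.0, 2010.0])

    def test_unequally_spaced_segments(self):
        refs = pd.concat(
            [
                self._refs(
                    [("2018-06-25 00:00", 10.0), ("2018-06-25 00:10", 20.0), ("2018-06-25 00:40", 80.0)]
                ),
                *[
                    self._refs([("2018-06-25 00:00", 1.0), ("2018-06-25 00:40", 1.0)]).assign(port=p)
                    for p in ("REF2", "REF3")
                ],
            ]
        )
        t = pd.Series(pd.to_datetime(["2018-06-25 00:05", "2018-06-25 00:25"]))
        out = interpolate_reference(refs, t)
        assert out["REF1"]["dry_12ch4_ppb"] == pytest.approx([15.0, 50.0])

    def test_single_visit_is_hard_error(self):
        refs = self._refs([("2018-06-25 00:00", 2000.0)])
        with pytest.raises(ValueError, match="fewer than 2"):
            interpolate_reference(refs, pd.Series(pd.to_datetime(["2018-06-25 00:05"])))


class TestDriftCorrection:
    ASSIGN = [
        ReferenceGasAssignment("REF1", 2004.32, -47.2),
        ReferenceGasAssignment("REF2", 3592.80, -39.5),
        ReferenceGasAssignment("REF3", 5017.03, -33.2),
    ]

    def _blocks(self, distort):
        times = pd.to_datetime(["2018-06-25 00:05", "2018-06-25 12:00", "2018-06-26 00:05"])
        rows = []
        for t in (times[0], times[2]):
            for a in self.ASSIGN:
                c12, c13 = split_isotopologues(a.assigned_ch4_ppb, a.assigned_delta_permil)
                rows.append(
                    {
                        "timestamp": t,
                        "port": a.id,
                        "dry_12ch4_ppb": distort(float(c12)),
                        "dry_13ch4_ppb": distort(float(c13)),
                        "n_raw_points": 10,
                    }
                )
        refs = pd.DataFrame(rows)
        c12, c13 = split_isotopologues(2100.0, -52.0)
        amb = pd.DataFrame(
            [
                {
                    "timestamp": times[1],
                    "port": "H0.5",
                    "dry_12ch4_ppb": distort(float(c12)),
                    "dry_13ch4_ppb": distort(float(c13)),
                    "n_raw_points": 4,
                }
            ]
        )
        return amb, refs

    def test_identity_when_measured_equals_assigned(self):
        amb, refs = self._blocks(lambda v: v)
        out = build_and_apply_drift(amb, refs, self.ASSIGN)
        total, delta = combine_isotopologues(out.cal_12ch4_ppb, out.cal_13ch4_ppb)
        assert total[0] == pytest.approx(2100.0, abs=1e-9)
        assert delta[0] == pytest.approx(-52.0, abs=1e-9)

    def test_affine_distortion_removed_exactly(self):
        amb, refs = self._blocks(lambda v: 1.01 * v + 5.0)
        out = build_and_apply_drift(amb, refs, self.ASSIGN)
        total, delta = combine_isotopologues(out.cal_12ch4_ppb, out.cal_13ch4_ppb)
        assert total[0] == pytest.approx(2100.0, abs=1e-8)
        assert delta[0] == pytest.approx(-52.0, abs=1e-9)


class TestDelta13C:
    def test_reference_material_is_zero(self):
        assert compute_delta13c(1000.0, 1000.0 * R_VPDB) == pytest.approx(0.0, abs=1e-12)

    def test_definition_at_minus_sixty(self):
        assert compute_delta13c(1000.0, 1000.0 * R_VPDB * 0.940) == pytest.approx(-60.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_delta13c(0.0, 20.0)

    @given(
        st.floats(min_value=1800, max_value=6000),
        st.floats(min_value=-80, max_value=-30),
    )
    @settings(max_examples=50, derandomize=True)
    def test_split_then_recombine_round_trip(self, total, delta):
        c12, c13 = split_isotopologues(total, delta)
        assert compute_delta13c(c12, c13) == pytest.approx(delta, abs=1e-9)
        assert float(c12 + c13) == pytest.approx(total, rel=1e-12)


class TestFullChain:
    def test_noise_free_round_trip(self, scenario_small_noisefree, clean_small_noisefree,
                                   calibrated_small_noisefree):
        """Calibration inverts the analyzer's drift+humidity chain exactly."""
        _, clean = clean_small_noisefree
        samples, _ = calibrated_small_noisefree
        last4 = clean.sort_values("timestamp").groupby("block_id").tail(4)
        c12, c13 = split_isotopologues(
            last4.true_ch4_ppb.to_numpy(), last4.true_delta_permil.to_numpy()
        )
        agg = last4.assign(c12=c12, c13=c13).groupby("block_id")[["c12", "c13"]].mean()
        total, delta = combine_isotopologues(agg.c12.to_numpy(), agg.c13.to_numpy())
        assert np.abs(samples.ch4_dry_ppb.to_numpy() - total).max() < 1e-6
        assert np.abs(samples.delta13c_obs_permil.to_numpy() - delta).max() < 1e-6

    def test_every_ambient_slot_accounted_for(self, scenario_small, campaign_small,
                                              calibrated_small):
        samples, ledger = calibrated_small
        raw = campaign_small["raw"]
        n_ambient_blocks = (
            (raw.port != raw.port.shift()).cumsum()[raw.port.str.startswith("H")].nunique()
        )
        rejected = sum(ledger.counts.values())
        assert len(samples) + rejected == n_ambient_blocks
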