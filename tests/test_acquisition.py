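"""SiPM/electronics digital twin: gain, saturation, averaging, drift, noise."""

import numpy as np
import pytest

import nirstwin as nt
from nirstwin.acquisition import (
    AnalogChain,
    DriftConfig,
    NoiseConfig,
    SipmModel,
    photon_energy_j,
    ELEMENTARY_CHARGE_C,
)
from nirstwin.metrics import snr_db


class TestSipmGain:
    def test_parking_bias_gives_zero_gain(self):
        assert nt.sipm_gain(24.0) == 0.0

    def test_anchor_points(self):
        assert nt.sipm_gain(33.0) == pytest.approx(8.2e6)
        assert nt.sipm_gain(28.0) == pytest.approx(1.4e6)

    def test_linear_interpolation_between_anchors(self):
        assert nt.sipm_gain(30.5) == pytest.approx(4.8e6, rel=1e-9)

    def test_breakdown_voltage_from_linear_fit(self):
        assert SipmModel().breakdown_voltage_v == pytest.approx(26.97, abs=0.01)

    def test_bias_out_of_range_rejected(self):
        for bias in (23.0, 34.0):
            with pytest.raises(ValueError):
                nt.sipm_gain(bias)

    def test_gain_monotone_above_breakdown(self):
        biases = np.linspace(27.0, 33.0, 13)
        gains = [nt.sipm_gain(b) for b in biases]
        assert all(b < a for b, a in zip(gains, gains[1:]))


class TestSipmResponse:
    def test_zero_power_gives_zero_current(self):
        assert nt.sipm_response(0.0, 774.0, 33.0) == 0.0

    def test_low_power_response_linear_within_one_percent(self):
        model = SipmModel()
        p = 1e-12  # photon rate far below the cell-count ceiling
        got = nt.sipm_response(p, 774.0, 33.0, model)
        rate = p / photon_energy_j(774.0) * model.pde_at(774.0)
        linear = rate * nt.sipm_gain(33.0, model) * ELEMENTARY_CHARGE_C
        assert got == pytest.approx(linear, rel=0.01)

    def test_saturation_plateaus_at_the_cell_count_ceiling(self):
        model = SipmModel()
        ceiling = (
            model.n_cells
            / model.recovery_window_s
            * nt.sipm_gain(33.0, model)
            * ELEMENTARY_CHARGE_C
        )
        big = nt.sipm_response(1.0, 774.0, 33.0, model)
        bigger = nt.sipm_response(10.0, 774.0, 33.0, model)
        assert big <= ceiling and bigger <= ceiling
        assert bigger == pytest.approx(ceiling, rel=1e-6)

    def test_monotone_in_power(self):
        powers = np.logspace(-12, -3, 10)
        resp = nt.sipm_response(powers, 774.0, 30.0)
        assert np.all(np.diff(resp) >= 0)  # flat only once fully saturated
        linear_range = nt.sipm_response(np.logspace(-12, -7, 6), 774.0, 30.0)
        assert np.all(np.diff(linear_range) > 0)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            nt.sipm_response(-1e-9, 774.0, 33.0)


class TestSafetyLimit:
    def test_series_below_limit_stays_active(self):
        assert nt.safety_limit(np.full(10, 1e-3)).all()

    def test_deactivated_from_first_over_limit_sample(self):
        series = np.array([1e-3, 1e-3, 2e-3, 1e-3, 1e-3])
        active = nt.safety_limit(series)
        assert active.tolist() == [True, True, False, False, False]

    def test_other_channels_unaffected(self):
        ok = np.full(5, 1e-4)
        bad = np.array([1e-4, 2e-3, 1e-4, 1e-4, 1e-4])
        mask_ok_before = nt.safety_limit(ok).copy()
        nt.safety_limit(bad)
        assert np.array_equal(nt.safety_limit(ok), mask_ok_before)
        assert mask_ok_before.all()


class TestSlotAverage:
    def test_constant_input_preserved(self):
        assert nt.slot_average(np.full(120, 1.25)) == pytest.approx(1.25)

    def test_pre_plateau_ramp_excluded(self):
        # 30 settling samples ramp up, plateau afterwards
        slot = np.concatenate([np.linspace(0, 2.0, 30), np.full(90, 2.0)])
        assert nt.slot_average(slot) == pytest.approx(2.0)

    def test_white_noise_reduced_by_sqrt_64(self, rng):
        outs = [
            nt.slot_average(rng.standard_normal(120)) for _ in range(4000)
        ]
        assert np.std(outs) == pytest.approx(1.0 / 8.0, rel=0.05)

    def test_short_slot_rejected(self):
        with pytest.raises(ValueError):
            nt.slot_average(np.ones(80))


class TestDriftModel:
    def test_local_slopes_match_the_anchor_values(self):
        cfg = DriftConfig()
        assert cfg.local_relative_slope(60.0) == pytest.approx(-3e-4, rel=1e-9)
        assert cfg.local_relative_slope(600.0) == pytest.approx(-1e-4, rel=1e-9)

    def test_factor_consistent_with_analytic_slope(self):
        cfg = DriftConfig()
        t, dt = 120.0, 1e-3
        num = (np.log(nt.drift_model(t + dt, cfg)) - np.log(nt.drift_model(t - dt, cfg))) / (2 * dt)
        assert num == pytest.approx(float(cfg.local_relative_slope(t)), rel=1e-6)

    def test_disabled_drift_is_unity(self):
        cfg = DriftConfig(enabled=False)
        assert np.all(nt.drift_model(np.linspace(0, 1000, 11), cfg) == 1.0)

    def test_starts_at_one_and_decays(self):
        t = np.linspace(0, 900, 91)
        f = nt.drift_model(t)
        assert f[0] == pytest.approx(1.0)
        assert np.all(np.diff(f) < 0)


class TestSimulateRecording:
    def _flat(self, duration=4.0, fs=50.0):
        return nt.ChromophoreTimecourse.zeros(duration, fs, "extracerebral")

    def test_noiseless_flat_recording_constant_within_one_lsb(self, single_module_network):
        rec = nt.simulate_recording(single_module_network, self._flat(), seed=0)
        lsb = AnalogChain().lsb_v
        for j in range(4):
            assert np.ptp(rec.intensity[0, j]) <= lsb + 1e-12
        assert np.ptp(rec.backlight[0]) <= lsb + 1e-12

    def test_backlight_offset_recorded_and_added_to_slots(self, single_module_network):
        b = 0.2
        rec = nt.simulate_recording(
            single_module_network, self._flat(), backlight_v=b, seed=0
        )
        lsb = AnalogChain().lsb_v
        assert rec.backlight[0].mean() == pytest.approx(b, abs=lsb)
        rec0 = nt.simulate_recording(
            single_module_network, self._flat(), backlight_v=0.0, seed=0
        )
        shift = rec.intensity[0, 0] - rec0.intensity[0, 0]
        assert shift.mean() == pytest.approx(b, abs=2 * lsb)

    def test_deterministic_under_fixed_seed(self, two_module_network):
        extra = nt.systemic_oscillations(nt.RestSpec(duration_s=5.0), fs=25, seed=1)
        kw = dict(noise=NoiseConfig.calibrated(), seed=11)
        a = nt.simulate_recording(two_module_network, extra, **kw)
        b = nt.simulate_recording(two_module_network, extra, **kw)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.backlight, b.backlight)

    def test_calibrated_noise_yields_64_db_on_flat_channel(self, single_module_network):
        rec = nt.simulate_recording(
            single_module_network,
            self._flat(duration=40.0, fs=100.0),
            noise=NoiseConfig.calibrated(target_snr_db=64.0),
            backlight_v=0.0,
            seed=5,
        )
        for j in range(4):
            assert snr_db(rec.intensity[0, j]) == pytest.approx(64.0, abs=0.5)

    def test_snr_decreases_with_optical_loss_at_fixed_settings(self, phantom_850):
        """Fixed-settings (non-leveled) mode: longer channels receive less
        light against the same electronic floor, so SNR drops as OL grows."""
        snrs = []
        for d in (20.0, 30.0, 40.0):
            net = nt.OptodeNetwork.from_positions([(0.0, 0.0), (d, 0.0)])
            rec = nt.simulate_recording(
                net,
                self._flat(duration=20.0, fs=50.0),
                noise=NoiseConfig.calibrated(),
                leveled=False,
                medium=phantom_850,
                backlight_v=0.0,
                seed=6,
            )
            i = rec.channel_index("S0D1")
            snrs.append(snr_db(rec.intensity[i, 0]))
        assert snrs[0] > snrs[1] > snrs[2]

    def test_calibration_rejects_unreachable_target(self):
        with pytest.raises(ValueError):
            NoiseConfig.calibrated(target_snr_db=90.0, bias_v=33.0)
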