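import numpy as np
import pytest

from multivenc.phantom import build_scene
from multivenc.quantify import (
    FlowWaveform,
    aggregate,
    estimate_lag,
    extract_waveform,
    markers,
    resample_to_cycle,
    segment_rois,
    shift_by_encode_time,
)
from conftest import make_series


def dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestExtraction:
    def test_uniform_velocity_flow_identity(self):
        # 10 cm/s over 0.5 cm^2 -> 300 mL/min at every phase
        n = 32
        mask = np.zeros((n, n), bool)
        mask[10:15, 10:20] = True  # 50 px * (1 mm)^2 = 0.5 cm^2
        v = np.zeros((4, n, n))
        v[:, mask] = 10.0
        series = make_series(v, pixel_mm=1.0)
        w = extract_waveform(series, mask, 0)
        np.testing.assert_allclose(w.values, 300.0)

    def test_zero_velocity_zero_flow(self):
        series = make_series(np.zeros((4, 16, 16)))
        mask = np.ones((16, 16), bool)
        assert np.all(extract_waveform(series, mask, 0).values == 0)

    def test_empty_mask_rejected(self):
        series = make_series(np.zeros((4, 16, 16)))
        with pytest.raises(ValueError):
            extract_waveform(series, np.zeros((16, 16), bool), 0)


class TestMarkers:
    def test_sinusoid_delta_v_within_one_percent_at_30_phases(self):
        t = np.arange(30) / 30
        w = FlowWaveform(300.0 * np.sin(2 * np.pi * t), 1000.0)
        expected = 300.0 * (1.0 / 60.0) / np.pi * 1e3  # A*T/pi in uL
        assert markers(w).delta_v == pytest.approx(expected, rel=0.01)

    def test_constant_waveform(self):
        w = FlowWaveform(np.full(30, 500.0), 1000.0)
        mk = markers(w)
        assert (mk.mean, mk.range, mk.delta_v) == (500.0, 0.0, 0.0)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(0)
        q = rng.uniform(100, 400, 30)
        a = markers(FlowWaveform(q, 900.0))
        b = markers(FlowWaveform(q[::-1].copy(), 900.0))
        assert a.mean == pytest.approx(b.mean)
        assert a.range == pytest.approx(b.range)
        assert a.delta_v == pytest.approx(b.delta_v, rel=1e-9)

    def test_delta_v_scales_linearly(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(-50, 350, 30)
        base = markers(FlowWaveform(q, 1000.0)).delta_v
        assert markers(FlowWaveform(3.0 * q, 1000.0)).delta_v == pytest.approx(
            3.0 * base, rel=1e-9
        )


class TestAggregation:
    def _vessel_waveforms(self, value=100.0):
        labels = ("ICA_L", "ICA_R", "VA_L", "VA_R", "IJV_L", "IJV_R")
        sign = {"IJV_L": -1, "IJV_R": -1}
        return {
            l: FlowWaveform(np.full(30, sign.get(l, 1) * value), 1000.0, l)
            for l in labels
        }

    def test_sums_and_net(self):
        wfs = self._vessel_waveforms(100.0)
        agg = aggregate(wfs)
        assert np.all(agg["tCBF"].values == 400.0)
        assert np.all(agg["tJBF"].values == 200.0)
        assert np.all(agg["net"].values == 200.0)

    def test_all_zero(self):
        agg = aggregate(self._vessel_waveforms(0.0))
        for k in ("tCBF", "tJBF", "net"):
            assert np.all(agg[k].values == 0.0)

    def test_missing_vessel_rejected(self):
        wfs = self._vessel_waveforms()
        del wfs["VA_L"]
        with pytest.raises(ValueError, match="VA_L"):
            aggregate(wfs)

    def test_default_scene_tcbf_scale(self):
        gt = build_scene({}).ground_truth_markers()
        assert 550.0 <= gt["tCBF"].mean <= 680.0

    def test_marker_mean_linearity(self):
        wfs = self._vessel_waveforms(123.0)
        agg = aggregate(wfs)
        total = sum(markers(wfs[l]).mean for l in ("ICA_L", "ICA_R", "VA_L", "VA_R"))
        assert markers(agg["tCBF"]).mean == pytest.approx(total)


class TestLags:
    def _arterial(self, cycle=1000.0, delay_ms=0.0, n=30):
        t = (np.arange(n) / n - delay_ms / cycle) % 1.0
        q = np.exp(-0.5 * ((t - 0.25) / 0.08) ** 2) + 0.3 * np.sin(2 * np.pi * t)
        return FlowWaveform(q, cycle, "w")

    def test_identical_zero_lag(self):
        a = self._arterial()
        assert estimate_lag(a, a).lag_ms == 0.0

    def test_known_delay_recovered(self):
        a = self._arterial()
        b = self._arterial(delay_ms=20.0)
        lr = estimate_lag(a, b)
        assert lr.grid_spacing_ms == pytest.approx(2.0)
        assert lr.lag_ms == pytest.approx(20.0, abs=lr.grid_spacing_ms)

    def test_antisymmetry(self):
        a = self._arterial()
        b = self._arterial(delay_ms=14.0)
        assert estimate_lag(a, b).lag_ms == pytest.approx(
            -estimate_lag(b, a).lag_ms, abs=2.0
        )

    def test_mismatched_cycles_rejected(self):
        a = self._arterial(cycle=1000.0)
        b = self._arterial(cycle=900.0)
        with pytest.raises(ValueError):
            estimate_lag(a, b)

    def test_linear_mode_agrees_on_small_lags(self):
        a = self._arterial()
        b = self._arterial(delay_ms=10.0)
        assert estimate_lag(a, b, mode="linear").lag_ms == pytest.approx(
            estimate_lag(a, b, mode="circular").lag_ms, abs=2.0
        )


class TestResampleShift:
    def test_resample_to_own_cycle_identity(self):
        w = FlowWaveform(np.arange(30.0), 870.0)
        out = resample_to_cycle(w, 870.0)
        np.testing.assert_array_equal(out.values, w.values)

    def test_zero_shift_identity(self):
        w = FlowWaveform(np.sin(2 * np.pi * np.arange(30) / 30), 1000.0)
        out = shift_by_encode_time(w, 0.0, 10.1)
        np.testing.assert_allclose(out.values, w.values, atol=1e-9)

    def test_shift_round_trip(self):
        w = FlowWaveform(np.sin(2 * np.pi * np.arange(30) / 30), 1000.0)
        out = shift_by_encode_time(shift_by_encode_time(w, 1.0, 10.1), -1.0, 10.1)
        np.testing.assert_allclose(out.values, w.values, atol=0.01)

    def test_shift_moves_peak_earlier(self):
        n = 30
        q = np.exp(-0.5 * ((np.arange(n) / n - 0.5) / 0.1) ** 2)
        w = FlowWaveform(q, 1000.0)
        out = shift_by_encode_time(w, 3.0, 20.0)  # 60 ms earlier
        assert np.argmax(out.values) < np.argmax(q)


class TestSegmentation:
    def test_dice_against_ground_truth(self, noisy_series):
        scene, series = noisy_series
        masks = segment_rois(series)
        truth = scene.masks()
        for label in truth:
            assert dice(masks[label], truth[label]) >= 0.9, label

    def test_override_masks_pass_through(self, noisy_series):
        scene, series = noisy_series
        truth = scene.masks()
        out = segment_rois(series, override_masks=truth)
        for label in truth:
            np.testing.assert_array_equal(out[label], truth[label])

    def test_static_scene_has_no_csf_component(self):
        rng = np.random.default_rng(0)
        n = 64
        mag = np.ones((6, n, n))
        v = 0.005 * rng.standard_normal((6, n, n))
        series = make_series([v, v], vencs=[75.0, 8.0], magnitude=mag)
        with pytest.raises(ValueError):
            segment_rois(series)
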