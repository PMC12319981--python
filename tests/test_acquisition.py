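import numpy as np
import pytest

from multivenc.acquisition import encode_timestamps, simulate_scan
from multivenc.encoding import build_scheme
from multivenc.phantom import build_scene, generate_triggers
from multivenc.recon import bin_cardiac, phase_difference, recon_bins


def _static_scene(n=48, pixel_mm=2.0, background=False):
    cfg = {
        "n": n, "pixel_mm": pixel_mm, "noise_sigma": 0.0,
        "rois": {l: {"waveform": {"mean_flow": 0.0, "pulse_amplitude": 0.0}}
                 for l in ("ICA_L", "ICA_R", "VA_L", "VA_R", "IJV_L", "IJV_R")},
    }
    if not background:
        cfg["background_poly"] = [0.0] * 6
    return build_scene(cfg)


class TestSignalModel:
    def test_zero_velocity_encodes_identical(self, toy_setup):
        _, scheme, traj = toy_setup
        scene = _static_scene()
        trig = generate_triggers(10, 65.0, 0.0, seed=0)
        raw = simulate_scan(scene, scheme, traj, 8.0, seed=0, triggers=trig)
        d = raw.data
        for e in range(1, scheme.n_encodes):
            np.testing.assert_allclose(d[e::scheme.n_encodes],
                                       d[0::scheme.n_encodes], atol=1e-12)

    def test_static_disk_round_trip(self, toy_setup):
        _, scheme, traj = toy_setup
        scene = _static_scene()
        trig = generate_triggers(16, 65.0, 0.0, seed=0)
        raw = simulate_scan(scene, scheme, traj, 14.0, seed=0, triggers=trig)
        binning = bin_cardiac(raw, 2)
        imgs = recon_bins(raw, binning, 48, 2.0)
        from multivenc.acquisition import _magnitude_image

        truth = _magnitude_image(scene, scheme)
        rec = np.abs(imgs[0, 0])
        interior = scene.support_mask()
        from scipy import ndimage

        interior = ndimage.binary_erosion(interior, iterations=4)
        err = np.abs(rec - truth)[interior].mean() / truth[interior].mean()
        assert err < 0.1

    def test_seed_determinism(self, toy_setup):
        _, scheme, traj = toy_setup
        scene = build_scene({"n": 48, "pixel_mm": 2.0, "noise_sigma": 2e-6})
        trig = generate_triggers(8, 65.0, 0.0, seed=1)
        a = simulate_scan(scene, scheme, traj, 5.0, seed=7, triggers=trig)
        b = simulate_scan(scene, scheme, traj, 5.0, seed=7, triggers=trig)
        np.testing.assert_array_equal(a.data, b.data)

    def test_phase_linear_in_velocity(self, toy_setup):
        # doubling all scene flows doubles the measured phase difference
        _, scheme, traj = toy_setup
        trig = generate_triggers(10, 65.0, 0.0, seed=0)
        phases = []
        for s in (1.0, 2.0):
            cfg = {"n": 48, "pixel_mm": 2.0, "noise_sigma": 0.0,
                   "background_poly": [0.0] * 6,
                   "rois": {"ICA_R": {"waveform": {
                       "mean_flow": 60.0 * s, "pulse_amplitude": 0.0}}}}
            for l in ("ICA_L", "VA_L", "VA_R", "IJV_L", "IJV_R"):
                cfg["rois"][l] = {"waveform": {"mean_flow": 0.0,
                                               "pulse_amplitude": 0.0}}
            scene = build_scene(cfg)
            raw = simulate_scan(scene, scheme, traj, 8.0, seed=0, triggers=trig)
            binning = bin_cardiac(raw, 1)
            imgs = recon_bins(raw, binning, 48, 2.0)
            m = scene.masks()["ICA_R"]
            dphi = np.angle(imgs[1, 0] * np.conj(imgs[0, 0]))[m].mean()
            phases.append(dphi)
        assert phases[1] / phases[0] == pytest.approx(2.0, rel=0.02)

    def test_block_shares_arm_and_cycles_encodes(self, toy_raw):
        scene, raw = toy_raw
        n_enc = raw.scheme.n_encodes
        arms = raw.arm_index.reshape(-1, n_enc)
        assert np.all(arms == arms[:, :1])
        np.testing.assert_array_equal(
            raw.encode_index[: 2 * n_enc], np.tile(np.arange(n_enc), 2)
        )


class TestEncodeTimestamps:
    def test_referenced_offsets_in_tr_units(self, toy_raw):
        scene, raw = toy_raw
        ts = encode_timestamps(raw)
        np.testing.assert_allclose(ts["channel_offsets_tr"], [1.0, 2.0])

    def test_balanced_midpoint(self, toy_setup):
        p, _, traj = toy_setup
        scheme = build_scheme("single_balanced", [8.0], p, tr_ms=9.2)
        scene = _static_scene()
        trig = generate_triggers(8, 65.0, 0.0, seed=0)
        raw = simulate_scan(scene, scheme, traj, 5.0, seed=0, triggers=trig)
        ts = encode_timestamps(raw)
        np.testing.assert_allclose(ts["channel_offsets_tr"], [0.5])


class TestVelocityNoise:
    def test_noise_scales_with_venc(self, toy_setup):
        # same noise realization, larger venc => proportionally larger
        # velocity noise (venc/SNR law at fixed SNR)
        p, _, traj = toy_setup
        scene = _static_scene()
        scene = build_scene({"n": 48, "pixel_mm": 2.0, "noise_sigma": 1e-6,
                             "background_poly": [0.0] * 6,
                             "rois": {l: {"waveform": {"mean_flow": 0.0,
                                                       "pulse_amplitude": 0.0}}
                                      for l in ("ICA_L", "ICA_R", "VA_L",
                                                "VA_R", "IJV_L", "IJV_R")}})
        trig = generate_triggers(12, 65.0, 0.0, seed=0)
        sds = []
        for venc in (25.0, 100.0):
            # fixed TR so both scans share block timing and noise draws
            scheme = build_scheme("single_balanced", [venc], p, tr_ms=10.0)
            raw = simulate_scan(scene, scheme, traj, 10.0, seed=4,
                                triggers=trig)
            binning = bin_cardiac(raw, 2)
            imgs = recon_bins(raw, binning, 48, 2.0)
            series = phase_difference(imgs, scheme, 100.0, 2.0)
            sup = scene.support_mask()
            sds.append(series.channels[0].velocity[:, sup].std())
        assert sds[1] / sds[0] == pytest.approx(4.0, rel=0.25)
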