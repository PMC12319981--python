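import numpy as np
import pytest

from multivenc.encoding import build_scheme
from multivenc.recon import (
    background_correct,
    bin_cardiac,
    laplacian_unwrap,
    llr_denoise,
    phase_difference,
    static_mask,
    unwrap_dual,
)
from conftest import make_series


class TestBinning:
    def test_bin_is_floor_of_phase_fraction(self, toy_raw):
        # every record lands in floor(n_phases * (t - t_trig)/RR); a record
        # exactly at mid-RR goes to bin n_phases//2
        scene, raw = toy_raw
        n_phases = 30
        binning = bin_cardiac(raw, n_phases)
        tt = raw.triggers.trigger_times_ms
        t = raw.times_ms
        idx = np.searchsorted(tt, t, side="right") - 1
        ok = (idx >= 0) & (idx < len(tt) - 1)
        frac = (t[ok] - tt[idx[ok]]) / np.diff(tt)[idx[ok]]
        expected = np.minimum((n_phases * frac).astype(int), n_phases - 1)
        assigned = np.full(len(t), -1)
        for (e, b), recs in binning["groups"].items():
            assigned[recs] = b
        np.testing.assert_array_equal(assigned[ok], expected)
        assert binning["n_discarded"] == (~ok).sum()
        assert int(n_phases * 0.5) == 15  # mid-RR convention

    def test_constant_rr_bins_near_uniform(self, toy_raw):
        scene, raw = toy_raw
        binning = bin_cardiac(raw, 10)
        counts = np.array([len(binning["groups"][(0, b)]) for b in range(10)])
        assert counts.min() > 0
        assert np.ptp(counts) <= max(2, 0.25 * counts.mean())

    def test_requires_triggers(self, toy_raw):
        import dataclasses

        scene, raw = toy_raw
        from multivenc.phantom import TriggerStream

        with pytest.raises(ValueError):
            TriggerStream(trigger_times_ms=np.array([0.0]), mean_hr_bpm=60,
                          hr_sd_bpm=0)


class TestPhaseDifference:
    def test_known_phase_to_velocity(self):
        scheme = build_scheme("dual", [75.0, 8.0], tr_ms=10.1)
        n = 8
        imgs = np.ones((3, 1, n, n), dtype=complex)
        imgs[2] *= np.exp(1j * np.pi / 2)  # low-venc encode
        series = phase_difference(imgs, scheme, 30.0, 1.0)
        assert series.channels[1].velocity[0, 0, 0] == pytest.approx(4.0)

    def test_phase_pi_maps_to_venc(self):
        scheme = build_scheme("dual", [75.0, 8.0], tr_ms=10.1)
        imgs = np.ones((3, 1, 4, 4), dtype=complex)
        imgs[2] *= np.exp(1j * np.pi)
        series = phase_difference(imgs, scheme, 30.0, 1.0)
        assert series.channels[1].velocity[0, 0, 0] == pytest.approx(8.0)

    def test_above_venc_wraps_negative(self):
        scheme = build_scheme("dual", [75.0, 8.0], tr_ms=10.1)
        imgs = np.ones((3, 1, 4, 4), dtype=complex)
        imgs[2] *= np.exp(1j * np.pi * 12.0 / 8.0)  # true 12 cm/s at venc 8
        series = phase_difference(imgs, scheme, 30.0, 1.0)
        assert series.channels[1].velocity[0, 0, 0] == pytest.approx(-4.0)

    def test_wrapped_range_invariant(self, toy_raw):
        scene, raw = toy_raw
        binning = bin_cardiac(raw, 6)
        from multivenc.recon import recon_bins

        imgs = recon_bins(raw, binning, 48, 2.0)
        series = phase_difference(imgs, raw.scheme, 100.0, 2.0)
        for ch in series.channels:
            assert ch.velocity.max() <= ch.effective_venc
            assert ch.velocity.min() > -ch.effective_venc


class TestDualVencUnwrap:
    def test_paper_example(self):
        v = unwrap_dual(np.array([-40.0]), np.array([60.0]), 50.0, 100.0)
        assert v[0] == pytest.approx(60.0)

    def test_below_venc_unchanged(self):
        v_low = np.linspace(-49, 49, 25)
        assert np.allclose(unwrap_dual(v_low, v_low, 50.0), v_low)

    def test_matches_bruteforce_wrap_search(self):
        venc_low, venc_high = 50.0, 100.0
        truth = np.linspace(-99.0, 99.0, 397)
        wrap = lambda v, venc: (v + venc) % (2 * venc) - venc
        v_low = wrap(truth, venc_low)
        v_high = wrap(truth, venc_high)
        got = unwrap_dual(v_low, v_high, venc_low, venc_high)
        # oracle: exhaustive integer wrap-count search minimizing |.-v_high|
        cands = v_low[None, :] + 2 * venc_low * np.arange(-3, 4)[:, None]
        oracle = cands[np.argmin(np.abs(cands - v_high[None, :]), axis=0),
                       np.arange(truth.size)]
        np.testing.assert_allclose(got, oracle, atol=1e-9)
        np.testing.assert_allclose(got, truth, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            unwrap_dual(np.zeros(3), np.zeros(4), 50.0)


class TestLaplacianUnwrap:
    def test_smooth_phase_unchanged(self):
        c = np.linspace(-1, 1, 64)
        xx, yy = np.meshgrid(c, c)
        phi = 0.8 * xx + 0.5 * yy**2  # within (-pi, pi]
        out = laplacian_unwrap(phi)
        np.testing.assert_allclose(out, phi, atol=1e-9)

    def test_wrapped_quadratic_recovered(self):
        from multivenc.pipeline import make_fixtures

        fx = make_fixtures("wrapped_phase")
        out = laplacian_unwrap(fx["wrapped"])
        resid = out - fx["true"]
        # recovery up to a global 2 pi k constant
        k = np.round(np.median(resid) / (2 * np.pi))
        np.testing.assert_allclose(resid, 2 * np.pi * k, atol=1e-6)

    def test_correction_is_integer_cycles(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-np.pi, np.pi, (32, 32))
        out = laplacian_unwrap(phi)
        cycles = (out - phi) / (2 * np.pi)
        np.testing.assert_allclose(cycles, np.round(cycles), atol=1e-9)


class TestLLR:
    def _rank1_series(self, n_phases=12, n=16):
        t = np.linspace(0, 2 * np.pi, n_phases)
        spatial = np.outer(np.hanning(n), np.hanning(n))
        return np.exp(1j * 0.3) * spatial[None] * (2.0 + np.sin(t))[:, None, None]

    def test_zero_threshold_identity(self):
        x = self._rank1_series()
        np.testing.assert_allclose(llr_denoise(x, threshold_frac=0.0), x,
                                   atol=1e-10)

    def test_full_threshold_reduces_to_rank_le_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 16, 16)) + 1j * rng.standard_normal((10, 16, 16))
        y = llr_denoise(x, threshold_frac=1.0)
        assert np.linalg.norm(y) < np.linalg.norm(x)
        cas = y[:, :8, :8].reshape(10, -1).T
        assert np.linalg.matrix_rank(cas, tol=1e-8) <= 1

    def test_some_threshold_denoises(self):
        rng = np.random.default_rng(2)
        clean = self._rank1_series(n_phases=16, n=16)
        noisy = clean + 0.05 * (rng.standard_normal(clean.shape)
                                + 1j * rng.standard_normal(clean.shape))
        mse_in = np.mean(np.abs(noisy - clean) ** 2)
        best = min(
            np.mean(np.abs(llr_denoise(noisy, threshold_frac=f) - clean) ** 2)
            for f in (0.01, 0.05, 0.1, 0.2, 0.4)
        )
        assert best < mse_in


class TestBackgroundCorrection:
    def _series_with_field(self, coef, n=48, n_phases=5):
        from multivenc.recon import _poly_basis

        field = _poly_basis(n) @ np.asarray(coef)
        v = np.repeat(field[None], n_phases, axis=0)
        return make_series(v, venc=8.0), field

    def test_exact_polynomial_removal(self):
        coef = [0.2, -0.1, 0.15, 0.05, -0.08, 0.03]
        series, field = self._series_with_field(coef)
        from multivenc.recon import StaticMask

        mask = StaticMask(np.ones(field.shape, bool), 0, 0)
        out = background_correct(series, mask)
        assert np.abs(out.channels[0].velocity).max() < 1e-9

    def test_constant_offset_removed(self):
        series, _ = self._series_with_field([0.7, 0, 0, 0, 0, 0])
        from multivenc.recon import StaticMask

        mask = StaticMask(np.ones((48, 48), bool), 0, 0)
        out = background_correct(series, mask)
        assert abs(out.channels[0].velocity.mean()) < 1e-9

    def test_waveform_shape_preserved(self):
        rng = np.random.default_rng(3)
        n, n_phases = 48, 8
        dyn = np.sin(2 * np.pi * np.arange(n_phases) / n_phases)
        v = np.zeros((n_phases, n, n))
        v[:, 20:28, 20:28] = dyn[:, None, None] * 5.0
        from multivenc.recon import _poly_basis

        v = v + (_poly_basis(n) @ np.array([0.3, 0.1, -0.1, 0.02, 0.0, 0.05]))[None]
        series = make_series(v, venc=8.0)
        from multivenc.recon import StaticMask

        m = np.ones((n, n), bool)
        m[18:30, 18:30] = False
        out = background_correct(series, StaticMask(m, 0, 0))
        roi = out.channels[0].velocity[:, 22:26, 22:26].mean(axis=(1, 2))
        np.testing.assert_allclose(roi - roi.mean(), 5.0 * (dyn - dyn.mean()),
                                   atol=1e-6)

    def test_small_mask_rejected(self):
        series, _ = self._series_with_field([0.1, 0, 0, 0, 0, 0])
        from multivenc.recon import StaticMask

        m = np.zeros((48, 48), bool)
        m[0, :10] = True
        with pytest.raises(ValueError):
            background_correct(series, StaticMask(m, 0, 0))


class TestStaticMask:
    def test_excludes_flow_and_respects_thresholds(self, noisy_series):
        scene, series = noisy_series
        sm = static_mask(series)
        mag = series.magnitude.mean(axis=0)
        low = min(series.channels, key=lambda ch: ch.effective_venc)
        vstd = low.velocity.std(axis=0)
        assert np.all(mag[sm.mask] > sm.magnitude_threshold)
        assert np.all(vstd[sm.mask] < sm.velocity_std_threshold)
        for label, m in scene.masks().items():
            frac = (sm.mask & m).sum() / m.sum()
            assert frac < 0.1, f"static mask overlaps {label}"

    def test_all_static_scene_covers_support(self):
        rng = np.random.default_rng(4)
        n, n_phases = 48, 6
        mag = np.zeros((n_phases, n, n))
        yy, xx = np.mgrid[0:n, 0:n]
        sup = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 < 18**2
        mag[:, sup] = 1.0
        v = 0.01 * rng.standard_normal((n_phases, n, n))
        series = make_series(v, venc=8.0, magnitude=mag)
        sm = static_mask(series)
        assert (sm.mask & sup).sum() / sup.sum() > 0.95
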