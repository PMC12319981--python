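import math

import numpy as np
import pytest

from multivenc.encoding import (
    PHASE_PER_MOMENT_VELOCITY,
    GradientWaveform,
    ProtocolConfig,
    build_scheme,
    design_bipolar,
    ernst_angle,
    relative_snr_reduction,
    scan_time,
    spgr_signal,
    temporal_resolution,
    theoretical_resolution,
    venc_to_moment,
)


class TestVencMoment:
    @pytest.mark.parametrize("venc,expected", [(8.0, 146.8), (75.0, 15.66)])
    def test_known_moments(self, venc, expected):
        assert venc_to_moment(venc) == pytest.approx(expected, rel=1e-3)

    def test_phase_at_venc_is_pi(self):
        for venc in (8.0, 50.0, 75.0, 100.0):
            m1 = venc_to_moment(venc)
            assert PHASE_PER_MOMENT_VELOCITY * m1 * venc == pytest.approx(math.pi)

    def test_nonpositive_venc_rejected(self):
        with pytest.raises(ValueError):
            venc_to_moment(0.0)
        with pytest.raises(ValueError):
            venc_to_moment(-5.0)


def brute_force_min_duration(m1_target, gmax, smax, raster_us):
    """Independent timing oracle: exhaustive search over trapezoid lobe ramp
    and flat raster counts for the shortest bipolar meeting the moment."""
    dt = raster_us * 1e-3
    best = None
    for r in range(1, 3000):
        g = min(gmax, smax * r * dt)
        for f in range(0, 3000):
            tr, tf = r * dt, f * dt
            m1 = g * (tr + tf) * (2 * tr + tf)
            if m1 >= m1_target:
                dur = 2 * (2 * r + f) * dt
                if best is None or dur < best:
                    best = dur
                break  # larger f only lengthens
        if best is not None and 2 * (2 * r) * dt > best:
            break
    return best


class TestBipolarDesign:
    def test_zero_moment_is_empty(self):
        wf = design_bipolar(0.0)
        assert wf.duration_ms == 0.0

    @pytest.mark.parametrize("venc", [8.0, 50.0, 75.0, 100.0])
    def test_moment_achieved_and_constraints(self, venc):
        m1 = venc_to_moment(venc)
        wf = design_bipolar(m1)
        m0, m1_achieved = wf.moments()
        assert abs(m0) < 1e-9
        assert m1_achieved == pytest.approx(m1, rel=1e-3)
        wf.validate(80.0, 200.0)  # raises on violation
        # encoded phase at v = venc is exactly pi
        assert PHASE_PER_MOMENT_VELOCITY * m1_achieved * venc == pytest.approx(
            math.pi, rel=1e-3
        )

    def test_matches_exhaustive_timing_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            m1 = float(rng.uniform(2.0, 200.0))
            gmax = float(rng.uniform(30.0, 80.0))
            smax = float(rng.uniform(80.0, 200.0))
            wf = design_bipolar(m1, gmax, smax, raster_us=4.0)
            oracle = brute_force_min_duration(m1, gmax, smax, 4.0)
            assert wf.duration_ms == pytest.approx(oracle, abs=1e-9)

    def test_duration_monotone_in_moment(self):
        durations = [design_bipolar(m).duration_ms for m in (5, 20, 80, 150)]
        assert durations == sorted(durations)


class TestSchemes:
    def test_dual_block_structure(self):
        s = build_scheme("dual", [75.0, 8.0])
        roles = [e.role for e in s.encodes]
        assert roles == ["flow_compensated", "velocity_encoded", "velocity_encoded"]
        assert [e.venc for e in s.encodes] == [None, 75.0, 8.0]
        assert s.channel_map == ((0, 1, 75.0), (0, 2, 8.0))

    def test_multi_block_structure(self):
        s = build_scheme("multi", [100.0, 50.0, 8.0])
        assert s.n_encodes == 4
        assert [e.venc for e in s.encodes] == [None, 100.0, 50.0, 8.0]
        assert len(s.channel_map) == 3

    def test_encodes_share_te_via_padding(self):
        s = build_scheme("multi", [100.0, 50.0, 8.0])
        lengths = {len(e.waveform.samples) for e in s.encodes}
        assert len(lengths) == 1

    def test_balanced_splits_moment(self):
        venc = 8.0
        s = build_scheme("single_balanced", [venc])
        m1s = [e.waveform.moments()[1] for e in s.encodes]
        assert m1s[0] == pytest.approx(-m1s[1], rel=1e-9)
        delta = abs(m1s[0] - m1s[1])
        assert PHASE_PER_MOMENT_VELOCITY * delta * venc == pytest.approx(
            math.pi, rel=1e-3
        )

    def test_venc_order_and_count_validated(self):
        with pytest.raises(ValueError):
            build_scheme("dual", [8.0, 75.0])  # increasing order
        with pytest.raises(ValueError):
            build_scheme("dual", [75.0])
        with pytest.raises(ValueError):
            build_scheme("multi", [100.0, 8.0])


class TestProtocolArithmetic:
    @pytest.mark.parametrize(
        "n_arms,n_enc,tr,expected",
        [(3300, 2, 8.0, 53), (3300, 2, 9.2, 61), (2000, 3, 10.1, 61),
         (1500, 4, 10.2, 61)],
    )
    def test_scan_times(self, n_arms, n_enc, tr, expected):
        _, rounded = scan_time(n_arms, n_enc, tr)
        assert rounded == expected

    def test_snr_reduction(self):
        assert round(relative_snr_reduction(3300, 1500)) == 33
        assert round(relative_snr_reduction(2000, 1500)) == 13
        assert relative_snr_reduction(1500, 1500) == 0.0

    def test_spgr_csf_flip_tradeoff(self):
        ratio = spgr_signal(4.0, 10.2, 4500.0) / spgr_signal(8.0, 10.2, 4500.0)
        assert round(ratio, 2) == 1.28

    def test_ernst_angle_for_csf(self):
        ea = ernst_angle(10.2, 4500.0)
        assert ea == pytest.approx(3.9, abs=0.05)
        assert round(ea) == 4

    def test_spgr_maximized_at_ernst_angle(self):
        ea = ernst_angle(10.2, 4500.0)
        s_ea = spgr_signal(ea, 10.2, 4500.0)
        for a in np.linspace(0.5, 89.5, 200):
            assert s_ea >= spgr_signal(float(a), 10.2, 4500.0) - 1e-12

    def test_temporal_resolution(self):
        assert temporal_resolution(65.0, 30) == pytest.approx(30.8, abs=0.05)
        assert temporal_resolution(130.0, 30) == pytest.approx(
            temporal_resolution(65.0, 30) / 2
        )

    def test_theoretical_resolution_by_scheme(self):
        dual = build_scheme("dual", [75.0, 8.0], tr_ms=10.1)
        assert theoretical_resolution(dual) == pytest.approx(10.1)
        bal = build_scheme("single_balanced", [8.0], tr_ms=9.2)
        assert theoretical_resolution(bal) == pytest.approx(18.4)

    def test_protocol_requires_positive_fields(self):
        with pytest.raises(ValueError):
            ProtocolConfig(fov_cm=-1.0)
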