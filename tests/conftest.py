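import numpy as np
import pytest

from multivenc.encoding import build_scheme
from multivenc.experiments import desk_protocol
from multivenc.phantom import build_scene, generate_triggers
from multivenc.acquisition import simulate_scan
from multivenc.recon import CardiacSeries, VelocityChannel
from multivenc.trajectory import make_golden_spiral


def make_series(velocity_maps, venc=75.0, magnitude=None, pixel_mm=1.0,
                phase_duration_ms=30.0, vencs=None):
    """Synthetic CardiacSeries from per-channel [phase, y, x] velocity stacks."""
    if isinstance(velocity_maps, np.ndarray):
        velocity_maps = [velocity_maps]
    if vencs is None:
        vencs = [venc] * len(velocity_maps)
    n_phases, ny, nx = velocity_maps[0].shape
    if magnitude is None:
        magnitude = np.ones((n_phases, ny, nx))
    channels = tuple(
        VelocityChannel(velocity=np.asarray(v, dtype=float),
                        effective_venc=float(vc), time_offset_ms=0.0)
        for v, vc in zip(velocity_maps, vencs)
    )
    return CardiacSeries(magnitude=magnitude, channels=channels,
                         phase_duration_ms=phase_duration_ms, pixel_mm=pixel_mm)


@pytest.fixture(scope="session")
def toy_setup():
    """Small dual-venc protocol/scheme/trajectory shared by fast tests.

    2 mm resolution to match the 48^2 / 2 mm toy scenes (trajectory kmax must
    not exceed the scene pixel-comb Nyquist).
    """
    from multivenc.encoding import ProtocolConfig

    p = ProtocolConfig(fov_cm=9.6, in_plane_resolution_mm=2.0, n_arms=120,
                       oversampling_factor=5, samples_per_arm=96)
    scheme = build_scheme("dual", [75.0, 8.0], p, tr_ms=10.1)
    traj = make_golden_spiral(p)
    return p, scheme, traj


@pytest.fixture(scope="session")
def toy_raw(toy_setup):
    """Tiny noiseless dual-venc acquisition of a 48^2 scene."""
    _, scheme, traj = toy_setup
    scene = build_scene({"n": 48, "pixel_mm": 2.0, "noise_sigma": 0.0})
    trig = generate_triggers(16, 65.0, 0.0, seed=3)
    raw = simulate_scan(scene, scheme, traj, 14.0, seed=3, triggers=trig,
                        n_coils=1)
    return scene, raw


@pytest.fixture(scope="session")
def noisy_series():
    """Reconstructed dual-venc series at the default SNR (for segmentation)."""
    from multivenc.recon import reconstruct

    p = desk_protocol(n_arms=660, samples_per_arm=192)
    scheme = build_scheme("dual", [75.0, 8.0], p, tr_ms=10.1)
    traj = make_golden_spiral(p)
    scene = build_scene({})  # default noise level
    trig = generate_triggers(63, 65.0, 0.0, seed=5)
    raw = simulate_scan(scene, scheme, traj, 60.0, seed=5, triggers=trig,
                        n_coils=1)
    series = reconstruct(raw, n=96, pixel_mm=1.0, n_phases=30)
    return scene, series


@pytest.fixture(scope="session")
def recovery_result():
    """Noiseless end-to-end recovery benchmark (shared with acceptance)."""
    from multivenc.experiments import recovery_experiment

    return recovery_experiment(seed=1)
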