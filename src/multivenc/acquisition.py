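"""Per-TR multi-venc spiral signal synthesis.

The simulator plays the interleaved encode block continuously: block ``b``
acquires every encode of the scheme on spiral arm ``b mod n_arms`` (identical
k-space sampling within a block; the golden-angle arm index advances once per
completed block).  For each TR record the k-space samples are the exact
discrete Fourier sum over phantom pixels,

``s(k) = sum_px coil * mag * exp(i (phi_v + phi_enc)) * exp(-2i pi k.r) + eta``

with ``mag`` from the SPGR steady-state model at the scheme's flip angle and
the pixel's T1, ``phi_v = gamma * M1_e * v(t)`` the velocity-encoded phase at
the record time, ``phi_enc = (M1_e / M1_max) * phi_bg`` the moment-scaled
residual background phase, and ``eta`` complex Gaussian noise.

For uniform-profile ROIs the sum factorizes into a static part plus one
phasor per ROI, which makes simulation time independent of the grid size per
record; parabolic profiles fall back to an exact per-record sum over ROI
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    PHASE_PER_MOMENT_VELOCITY,
    EncodingScheme,
    spgr_signal,
)
from .nufft import nudft_forward
from .phantom import PhantomScene, TriggerStream, make_coil_maps, roi_mean_velocity
from .trajectory import SpiralTrajectory

__all__ = ["RawAcquisition", "simulate_scan", "encode_timestamps"]


@dataclass(frozen=True)
class RawAcquisition:
    """Continuously acquired multi-venc spiral raw data.

    ``data`` has shape (n_records, n_coils, samples_per_arm); record ``r``
    belongs to block ``r // n_encodes``, encode ``r % n_encodes``.
    """

    data: np.ndarray
    times_ms: np.ndarray  # acquisition time of each record
    encode_index: np.ndarray
    arm_index: np.ndarray
    scheme: EncodingScheme
    trajectory: SpiralTrajectory
    triggers: TriggerStream
    coil_maps: np.ndarray
    seed: int

    @property
    def n_records(self) -> int:
        return self.data.shape[0]


def _magnitude_image(scene: PhantomScene, scheme: EncodingScheme) -> np.ndarray:
    """SPGR steady-state magnitude per pixel for the scheme's flip/TR."""
    t1 = scene.t1_map()
    pd = scene.proton_density_map()
    mag = np.zeros_like(pd)
    for t1v in np.unique(t1[np.isfinite(t1)]):
        sel = t1 == t1v
        mag[sel] = spgr_signal(scheme.flip_angle_deg, scheme.tr_ms, float(t1v))
    return pd * mag


def simulate_scan(
    scene: PhantomScene,
    scheme: EncodingScheme,
    traj: SpiralTrajectory,
    duration_s: float,
    seed: int = 0,
    triggers: TriggerStream | None = None,
    n_coils: int = 1,
) -> RawAcquisition:
    """Simulate a continuous interleaved multi-venc golden-angle spiral scan.

    ``duration_s`` determines the number of complete encode blocks played;
    triggers default to a 65 bpm stream generated from ``seed``.  Noise level
    is taken from ``scene.noise_sigma`` (std per complex k-space sample and
    coil, in units of the k-space signal).
    """
    from .phantom import generate_triggers

    if traj.samples_per_arm != traj.coords.shape[1]:
        raise ValueError("inconsistent trajectory")
    n_enc = scheme.n_encodes
    tr = scheme.tr_ms
    n_blocks = int(duration_s * 1000.0 / (tr * n_enc))
    if n_blocks < 1:
        raise ValueError("duration too short for one encode block")
    if triggers is None:
        triggers = generate_triggers(duration_s, seed=seed)

    n_rec = n_blocks * n_enc
    times = np.arange(n_rec) * tr
    encode_index = np.tile(np.arange(n_enc), n_blocks)
    arm_index = np.repeat(np.arange(n_blocks) % traj.n_arms, n_enc)

    coil_maps = make_coil_maps(scene.n, n_coils)
    pixel_m = scene.pixel_mm * 1e-3
    mag = _magnitude_image(scene, scheme)
    phi_bg = scene.background_phase()
    masks = scene.masks()
    m1 = np.array([e.delta_m1 for e in scheme.encodes])
    m1_max = np.max(np.abs(m1))
    m1_scale = m1 / m1_max if m1_max > 0 else m1 * 0.0

    arms_used = np.arange(n_blocks) % traj.n_arms
    unique_arms = np.unique(arms_used)
    ns = traj.samples_per_arm

    # static complex image per encode (v = 0): magnitude with the
    # moment-scaled background phase
    static_imgs = np.stack(
        [mag * np.exp(1j * s * phi_bg) for s in m1_scale]
    )  # (n_enc, n, n)

    # per-(coil, encode, arm) forward transforms of the static image and of
    # each ROI's static sub-image; ROI contributions are phasor-scaled per TR
    uniform = all(r.profile == "uniform" for r in scene.rois)
    kx = traj.coords[unique_arms, :, 0].reshape(-1)
    ky = traj.coords[unique_arms, :, 1].reshape(-1)
    arm_pos = {a: i for i, a in enumerate(unique_arms)}

    def fwd(image_stack):
        # image_stack (..., n, n) -> (..., len(unique_arms), ns)
        out = nudft_forward(image_stack, kx, ky, pixel_m)
        return out.reshape(*image_stack.shape[:-2], len(unique_arms), ns)

    coil_static = fwd(coil_maps[:, None, :, :] * static_imgs[None, :, :, :])
    roi_labels = [r.label for r in scene.rois if r.waveform is not None]
    c_mm = (np.arange(scene.n) - scene.n // 2) * scene.pixel_mm
    xx_m, yy_m = np.meshgrid(c_mm * 1e-3, c_mm * 1e-3)
    coil_roi = {}
    for lab in roi_labels:
        m = masks[lab]
        vals = (coil_maps[:, None] * static_imgs[None])[..., m]  # (nc, ne, npx)
        out = _masked_forward(vals, xx_m[m], yy_m[m], kx, ky, pixel_m)
        coil_roi[lab] = out.reshape(*vals.shape[:-1], len(unique_arms), ns)

    # per-record ROI mean velocities (cm/s)
    v_mean = roi_mean_velocity(scene, times, triggers)

    rng = np.random.default_rng(seed)
    n_coils_eff = coil_maps.shape[0]
    data = np.empty((n_rec, n_coils_eff, ns), dtype=np.complex128)
    enc_of_rec = encode_index
    ai = np.array([arm_pos[a] for a in arm_index])
    for c in range(n_coils_eff):
        data[:, c, :] = coil_static[c, enc_of_rec, ai, :]
        for lab in roi_labels:
            theta = PHASE_PER_MOMENT_VELOCITY * m1[enc_of_rec] * v_mean[lab]
            if not uniform and scene.roi(lab).profile == "parabolic":
                data[:, c, :] += _parabolic_contrib(
                    scene, lab, coil_maps[c], static_imgs, enc_of_rec, ai,
                    v_mean[lab], m1, traj, unique_arms, pixel_m
                ) - coil_roi[lab][c, enc_of_rec, ai, :]
            else:
                data[:, c, :] += (np.exp(1j * theta) - 1.0)[:, None] * coil_roi[lab][
                    c, enc_of_rec, ai, :
                ]
    if scene.noise_sigma > 0:
        data += scene.noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    return RawAcquisition(
        data=data, times_ms=times, encode_index=encode_index, arm_index=arm_index,
        scheme=scheme, trajectory=traj, triggers=triggers, coil_maps=coil_maps,
        seed=seed,
    )


def _masked_forward(vals, xs_m, ys_m, kx, ky, pixel_m, chunk=65536):
    """Forward NUDFT restricted to a pixel subset; ``vals`` is (..., npx)."""
    npx = len(xs_m)
    out = np.empty((*vals.shape[:-1], kx.size), dtype=np.complex128)
    for lo in range(0, kx.size, chunk):
        hi = min(lo + chunk, kx.size)
        ph = np.exp(
            -2j * np.pi * (np.outer(kx[lo:hi], xs_m) + np.outer(ky[lo:hi], ys_m))
        )
        out[..., lo:hi] = vals @ ph.T
    return out * pixel_m**2


def _parabolic_contrib(scene, label, coil, static_imgs, enc_of_rec, ai,
                       v_mean, m1, traj, unique_arms, pixel_m):
    """Exact per-record forward over one parabolic-profile ROI's pixels."""
    r = scene.roi(label)
    m = r.mask(scene.n, scene.pixel_mm)
    c = (np.arange(scene.n) - scene.n // 2) * scene.pixel_mm
    xx, yy = np.meshgrid(c, c)
    rho2 = ((xx - r.center_mm[0]) ** 2 + (yy - r.center_mm[1]) ** 2)[m]
    prof = 1.0 - rho2 / r.radius_mm**2
    prof = prof / prof.mean()
    xs = (xx * 1e-3)[m]
    ys = (yy * 1e-3)[m]
    n_rec = len(enc_of_rec)
    ns = traj.samples_per_arm
    out = np.empty((n_rec, ns), dtype=np.complex128)
    base = (coil * static_imgs)[..., m]  # (n_enc, npx) after mask
    for rec in range(n_rec):
        e = enc_of_rec[rec]
        k = traj.coords[unique_arms[ai[rec]]]
        phase = PHASE_PER_MOMENT_VELOCITY * m1[e] * v_mean[rec] * prof
        px = base[e] * np.exp(1j * phase)
        ph = np.exp(-2j * np.pi * (np.outer(k[:, 0], xs) + np.outer(k[:, 1], ys)))
        out[rec] = (ph @ px) * pixel_m**2
    return out


def encode_timestamps(raw: RawAcquisition) -> dict:
    """Per-record acquisition times and per-channel reference offsets.

    Returns ``record_times_ms`` (acquisition time of every record),
    ``channel_times_ms`` (the timestamp each velocity channel inherits, per
    block) and ``channel_offsets_tr`` (offset from the block start in TR
    units: 1 TR for the first encode after the reference, 2 TR for the
    second, ...; the balanced pair reports its midpoint, 0.5 TR).
    """
    scheme = raw.scheme
    n_enc = scheme.n_encodes
    block_starts = raw.times_ms[::n_enc]
    offsets = [scheme.channel_time_offset_ms(c) / scheme.tr_ms
               for c in range(len(scheme.channel_map))]
    channel_times = {
        c: block_starts + scheme.channel_time_offset_ms(c)
        for c in range(len(scheme.channel_map))
    }
    return {
        "record_times_ms": raw.times_ms,
        "channel_times_ms": channel_times,
        "channel_offsets_tr": np.array(offsets),
    }
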