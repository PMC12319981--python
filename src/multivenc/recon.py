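"""Cardiac-resolved reconstruction and velocity processing.

Pipeline: retrospective binning of the continuously acquired records into 30
cardiac phases using the trigger stream and actual per-encode acquisition
times; density-compensated adjoint gridding of each (encode, phase) bin with
conjugate-sensitivity coil combination; optional locally-low-rank temporal
denoising; phase-difference velocity mapping per channel; dual-venc and
single-step Laplacian phase unwrapping; and 2nd-order polynomial background
phase correction fitted on static tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft

from .acquisition import RawAcquisition
from .encoding import EncodingScheme
from .nufft import nudft_adjoint, nudft_forward
from .trajectory import SpiralTrajectory

__all__ = [
    "CardiacSeries",
    "StaticMask",
    "bin_cardiac",
    "recon_bins",
    "llr_denoise",
    "phase_difference",
    "unwrap_dual",
    "laplacian_unwrap",
    "background_correct",
    "static_mask",
    "reconstruct",
]


@dataclass(frozen=True)
class VelocityChannel:
    velocity: np.ndarray  # (n_phases, ny, nx), cm/s
    effective_venc: float  # cm/s
    time_offset_ms: float


@dataclass(frozen=True)
class CardiacSeries:
    """30-phase magnitude and per-channel velocity image series."""

    magnitude: np.ndarray  # (n_phases, ny, nx)
    channels: tuple[VelocityChannel, ...]
    phase_duration_ms: float
    pixel_mm: float

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[0]


@dataclass(frozen=True)
class StaticMask:
    mask: np.ndarray
    magnitude_threshold: float
    velocity_std_threshold: float


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_cardiac(raw: RawAcquisition, n_phases: int = 30) -> dict:
    """Assign each record to a cardiac-phase bin via its channel timestamp.

    Record at time ``t`` inside the RR interval ``[t_k, t_k+1)`` goes to bin
    ``floor(n_phases * (t - t_k)/RR)``.  For the balanced scheme both encodes
    of a pair are binned at the pair midpoint; referenced schemes use each
    encode's own time (this realizes the 1 TR / 2 TR encode-time referencing
    at the binning stage).  Records outside any complete RR interval are
    discarded and counted.

    Returns ``{"groups": {(encode, bin): record-index array},
    "n_discarded": int}``.
    """
    tt = np.asarray(raw.triggers.trigger_times_ms)
    if tt.size < 2:
        raise ValueError("need at least one complete RR interval")
    scheme = raw.scheme
    t = raw.times_ms.astype(float).copy()
    if scheme.scheme_type == "single_balanced":
        # channel timestamp = midpoint of the +/- pair
        e = raw.encode_index
        t = t + (0.5 - e) * scheme.tr_ms

    idx = np.searchsorted(tt, t, side="right") - 1
    valid = (idx >= 0) & (idx < tt.size - 1)
    groups: dict[tuple[int, int], np.ndarray] = {}
    rr = np.where(valid, tt[np.clip(idx + 1, 0, tt.size - 1)] - tt[np.clip(idx, 0, tt.size - 1)], 1.0)
    frac = np.where(valid, (t - tt[np.clip(idx, 0, tt.size - 1)]) / rr, 0.0)
    bins = np.minimum((n_phases * frac).astype(int), n_phases - 1)
    for e in range(scheme.n_encodes):
        for b in range(n_phases):
            sel = np.nonzero(valid & (raw.encode_index == e) & (bins == b))[0]
            if sel.size:
                groups[(e, b)] = sel
    return {"groups": groups, "n_discarded": int((~valid).sum()), "n_phases": n_phases}


# ---------------------------------------------------------------------------
# gridding reconstruction
# ---------------------------------------------------------------------------


_GAIN_CACHE: dict = {}


def _adjoint_gain(traj: SpiralTrajectory, n: int, pixel_m: float) -> float:
    """Wide-area gain of the density-weighted adjoint (exact PSF sum).

    The disk-shaped k-space coverage of a pixel-comb image makes the PSF
    integral differ from its peak; reconstructions are divided by this gain
    so uniform regions read at their true values.
    """
    key = (traj.n_arms, traj.samples_per_arm, traj.kmax, traj.n_turns,
           traj.angle_increment_deg, n, pixel_m)
    if key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    kx = traj.coords[..., 0].ravel()
    ky = traj.coords[..., 1].ravel()
    w = np.tile(traj.dcf, traj.n_arms)
    ones = np.ones((n, n))
    s1 = nudft_forward(ones, kx, ky, pixel_m)
    norm = 1.0 / (pixel_m**2 * np.pi * traj.kmax**2)
    gain = float(np.real(np.sum(w * np.conj(s1))) * norm)
    _GAIN_CACHE[key] = gain
    return gain


def recon_bins(
    raw: RawAcquisition,
    binning: dict,
    n: int,
    pixel_mm: float,
    llr_threshold: float | None = None,
) -> np.ndarray:
    """Coil-combined complex image per (encode, cardiac phase).

    Density-compensated adjoint gridding of each bin's spiral samples (bin
    weights rescaled for the number of arms present), conjugate-sensitivity
    coil combination, and optional locally-low-rank temporal denoising.
    Raises naming the bin if any (encode, phase) bin is empty.
    """
    groups = binning["groups"]
    n_phases = binning["n_phases"]
    scheme = raw.scheme
    traj = raw.trajectory
    pixel_m = pixel_mm * 1e-3
    norm = 1.0 / (pixel_m**2 * np.pi * traj.kmax**2)
    gain = _adjoint_gain(traj, n, pixel_m)
    cmaps = raw.coil_maps
    csum = np.sum(np.abs(cmaps) ** 2, axis=0)
    csum = np.where(csum > 0, csum, 1.0)

    images = np.zeros((scheme.n_encodes, n_phases, n, n), dtype=np.complex128)
    for e in range(scheme.n_encodes):
        for b in range(n_phases):
            recs = groups.get((e, b))
            if recs is None or len(recs) == 0:
                raise ValueError(f"empty cardiac bin: encode {e}, phase {b}")
            arms = raw.arm_index[recs]
            kx = traj.coords[arms, :, 0].ravel()
            ky = traj.coords[arms, :, 1].ravel()
            # azimuthal Voronoi share per arm: a cardiac bin holds an
            # irregular subset of golden-angle arms, so each arm covers the
            # angular gap to its neighbors rather than a uniform 2 pi / A
            ang = np.deg2rad(traj.angle_increment_deg) * arms % (2 * np.pi)
            order = np.argsort(ang)
            sa = ang[order]
            gaps = np.diff(np.concatenate([sa, [sa[0] + 2 * np.pi]]))
            share = np.empty_like(sa)
            share = (gaps + np.roll(gaps, 1)) / 2.0
            arm_w = np.empty(len(recs))
            arm_w[order] = share / (2 * np.pi / len(recs))
            w = (
                np.repeat(arm_w, traj.samples_per_arm)
                * np.tile(traj.dcf, len(recs))
                * (traj.n_arms / len(recs))
            )
            coil_imgs = nudft_adjoint(
                raw.data[recs].transpose(1, 0, 2).reshape(cmaps.shape[0], -1),
                w, kx, ky, n, pixel_m,
            ) * (norm / gain)
            images[e, b] = np.sum(np.conj(cmaps) * coil_imgs, axis=0) / csum
    if llr_threshold is not None:
        images = llr_denoise(images, threshold_frac=llr_threshold)
    return images


def llr_denoise(images: np.ndarray, block: int = 8,
                threshold_frac: float = 0.1) -> np.ndarray:
    """Block-wise low-rank temporal denoising by singular-value soft
    thresholding.

    For each spatial ``block x block`` patch the (block^2 x n_phases)
    Casorati matrix is soft-thresholded on its singular values at
    ``threshold_frac`` times the largest singular value.  A fixed-fraction
    threshold is used (simple, deterministic); images are zero-padded so the
    block tiles the grid.
    """
    out = np.array(images, dtype=complex, copy=True)
    *lead, n_phases, ny, nx = out.shape
    py = (-ny) % block
    px = (-nx) % block
    arr = np.pad(out.reshape(-1, n_phases, ny, nx),
                 [(0, 0), (0, 0), (0, py), (0, px)])
    _, _, nyp, nxp = arr.shape
    for s in range(arr.shape[0]):
        for by in range(0, nyp, block):
            for bx in range(0, nxp, block):
                patch = arr[s, :, by:by + block, bx:bx + block]
                cas = patch.reshape(n_phases, -1).T  # (block^2, n_phases)
                u, sv, vh = np.linalg.svd(cas, full_matrices=False)
                thr = threshold_frac * sv[0] if sv.size else 0.0
                sv = np.maximum(sv - thr, 0.0)
                cas = (u * sv) @ vh
                arr[s, :, by:by + block, bx:bx + block] = cas.T.reshape(patch.shape)
    return arr[:, :, :ny, :nx].reshape(out.shape)


# ---------------------------------------------------------------------------
# velocity mapping and unwrapping
# ---------------------------------------------------------------------------


def phase_difference(images: np.ndarray, scheme: EncodingScheme,
                     phase_duration_ms: float, pixel_mm: float) -> CardiacSeries:
    """Velocity maps from encode/reference phase differences.

    Per channel ``(ref, enc, venc)``:
    ``v = venc * angle(img[enc] * conj(img[ref])) / pi`` (cm/s), wrapped into
    ``(-venc, venc]``; magnitude is the mean |image| over encodes.
    """
    mag = np.mean(np.abs(images), axis=0)
    channels = []
    for c, (ref, enc, venc) in enumerate(scheme.channel_map):
        d = images[enc] * np.conj(images[ref])
        v = venc * np.angle(d) / np.pi
        channels.append(
            VelocityChannel(
                velocity=v, effective_venc=float(venc),
                time_offset_ms=scheme.channel_time_offset_ms(c),
            )
        )
    return CardiacSeries(
        magnitude=mag, channels=tuple(channels),
        phase_duration_ms=phase_duration_ms, pixel_mm=pixel_mm,
    )


def unwrap_dual(v_low: np.ndarray, v_high: np.ndarray,
                venc_low: float, venc_high: float | None = None) -> np.ndarray:
    """Unwrap a low-venc velocity map using a high-venc map.

    ``v = v_low + 2 venc_low round((v_high - v_low) / (2 venc_low))``; exact
    whenever |true v| < venc_high and the high-venc noise is below venc_low.
    """
    v_low = np.asarray(v_low, dtype=float)
    v_high = np.asarray(v_high, dtype=float)
    if v_low.shape != v_high.shape:
        raise ValueError("velocity maps must share shape")
    if venc_high is not None and venc_high <= venc_low:
        raise ValueError("venc_high must exceed venc_low")
    n = np.round((v_high - v_low) / (2.0 * venc_low))
    return v_low + 2.0 * venc_low * n


def _spectral_laplacian(f: np.ndarray, inverse: bool) -> np.ndarray:
    """Discrete Laplacian (or its pseudo-inverse) via DCT-II, Neumann
    boundaries; the zero mode is gauged to zero."""
    ny, nx = f.shape
    ly = 2.0 * np.cos(np.pi * np.arange(ny) / ny) - 2.0
    lx = 2.0 * np.cos(np.pi * np.arange(nx) / nx) - 2.0
    lam = ly[:, None] + lx[None, :]
    fh = scipy.fft.dctn(f, type=2, norm="ortho")
    if inverse:
        with np.errstate(divide="ignore", invalid="ignore"):
            fh = np.where(lam != 0, fh / lam, 0.0)
    else:
        fh = fh * lam
    return scipy.fft.idctn(fh, type=2, norm="ortho")


def laplacian_unwrap(phase: np.ndarray) -> np.ndarray:
    """Single-step Laplacian phase unwrapping of a 2D map.

    Estimates the true phase from
    ``L^-1(cos(phi) L(sin phi) - sin(phi) L(cos phi))`` and snaps the
    correction to the nearest multiple of 2 pi, so output - input is
    everywhere an integer multiple of 2 pi (up to a global constant fixed by
    the zero-mean gauge of the spectral inverse).
    """
    phi = np.asarray(phase, dtype=float)
    est = _spectral_laplacian(
        np.cos(phi) * _spectral_laplacian(np.sin(phi), inverse=False)
        - np.sin(phi) * _spectral_laplacian(np.cos(phi), inverse=False),
        inverse=True,
    )
    k = np.round((est - phi) / (2.0 * np.pi))
    return phi + 2.0 * np.pi * k


def laplacian_unwrap_series(series: CardiacSeries, channel: int) -> CardiacSeries:
    """Apply single-step Laplacian unwrapping to every phase of one channel."""
    ch = series.channels[channel]
    venc = ch.effective_venc
    out = np.empty_like(ch.velocity)
    for p in range(out.shape[0]):
        phi = ch.velocity[p] * np.pi / venc
        out[p] = laplacian_unwrap(phi) * venc / np.pi
    channels = list(series.channels)
    channels[channel] = replace(ch, velocity=out)
    return replace(series, channels=tuple(channels))


# ---------------------------------------------------------------------------
# background phase correction
# ---------------------------------------------------------------------------


def _poly_basis(n: int) -> np.ndarray:
    c = (np.arange(n) - n // 2) / (n // 2)
    xx, yy = np.meshgrid(c, c)
    return np.stack([np.ones_like(xx), xx, yy, xx**2, xx * yy, yy**2], axis=-1)


def static_mask(series: CardiacSeries, mag_frac: float = 0.3,
                bright_factor: float = 1.35, std_factor: float = 2.0,
                mean_factor: float = 5.0) -> StaticMask:
    """Static-tissue mask: tissue-bright pixels with stable, near-zero
    velocity.

    Criteria on the lowest-venc (most flow-sensitive) channel:
    magnitude between ``mag_frac`` x max and ``bright_factor`` x the median
    support magnitude (flowing blood is hyperintense from inflow, CSF is
    hypointense); temporal velocity std below ``std_factor`` x its support
    median (excludes oscillatory CSF and pulsatile arteries); |time-mean
    velocity| below ``mean_factor`` x its support median (excludes steady
    venous flow, which velocity std alone cannot).
    """
    mag = series.magnitude.mean(axis=0)
    mag_thr = mag_frac * mag.max()
    support = mag > mag_thr
    low = min(series.channels, key=lambda ch: ch.effective_venc)
    vstd = low.velocity.std(axis=0)
    vmean = np.abs(low.velocity.mean(axis=0))
    bright_thr = bright_factor * float(np.median(mag[support]))
    std_thr = std_factor * float(np.median(vstd[support]))
    mean_thr = mean_factor * float(np.median(vmean[support]))
    mask = (support & (mag < bright_thr) & (vstd < std_thr)
            & (vmean < mean_thr))
    if not mask.any():
        raise ValueError("static-tissue mask is empty")
    return StaticMask(mask=mask, magnitude_threshold=mag_thr,
                      velocity_std_threshold=std_thr)


def background_correct(series: CardiacSeries, mask: StaticMask) -> CardiacSeries:
    """Remove residual background phase by a 2nd-order polynomial fit.

    The shared background field is estimated from the across-channel average
    of the time-averaged velocity (the moment-scaled eddy-current model makes
    the velocity-domain offset identical across channels), fitted over the
    static mask with unweighted least squares on {1, x, y, x^2, xy, y^2}, and
    subtracted from every phase of every channel.
    """
    m = mask.mask
    if m.sum() < 60:
        raise ValueError("static mask too small for a well-posed 2nd-order fit")
    basis = _poly_basis(series.magnitude.shape[-1])
    a = basis[m]  # (npx, 6)
    vbar = np.mean([ch.velocity.mean(axis=0) for ch in series.channels], axis=0)
    coef, _, rank, _ = np.linalg.lstsq(a, vbar[m], rcond=None)
    if rank < 6:
        raise ValueError("rank-deficient polynomial design")
    field = basis @ coef
    channels = tuple(
        replace(ch, velocity=ch.velocity - field[None]) for ch in series.channels
    )
    return replace(series, channels=channels)


# ---------------------------------------------------------------------------
# end-to-end reconstruction
# ---------------------------------------------------------------------------


def reconstruct(
    raw: RawAcquisition,
    n: int,
    pixel_mm: float,
    n_phases: int = 30,
    llr_threshold: float | None = None,
    unwrap: bool = True,
    correct_background: bool = True,
) -> CardiacSeries:
    """Full reconstruction: bin, grid, velocity-map, unwrap, correct.

    Dual-venc unwrapping is applied to adjacent channel pairs with a venc
    ratio <= 4 (e.g. 100 -> 50 cm/s); the lowest-venc channel is unwrapped
    with the single-step Laplacian.  Background correction (after
    unwrapping) uses an automatically derived static-tissue mask.
    """
    binning = bin_cardiac(raw, n_phases)
    images = recon_bins(raw, binning, n, pixel_mm, llr_threshold=llr_threshold)
    mean_rr = raw.triggers.mean_rr_ms
    series = phase_difference(images, raw.scheme, mean_rr / n_phases, pixel_mm)

    if unwrap and len(series.channels) >= 2:
        chs = list(series.channels)
        for i in range(1, len(chs)):
            hi, lo = chs[i - 1], chs[i]
            if hi.effective_venc / lo.effective_venc <= 4.0:
                v = np.stack([
                    unwrap_dual(lo.velocity[p], hi.velocity[p],
                                lo.effective_venc, hi.effective_venc)
                    for p in range(series.n_phases)
                ])
                chs[i] = replace(lo, velocity=v)
        series = replace(series, channels=tuple(chs))
    if unwrap:
        lowest = int(np.argmin([c.effective_venc for c in series.channels]))
        series = laplacian_unwrap_series(series, lowest)
    if correct_background:
        series = background_correct(series, static_mask(series))
    return series
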