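"""ROI segmentation, flow-waveform extraction, flow markers, and lags.

Flow rate per cardiac phase is ``Q = v_mean * A * 60`` (cm/s x cm^2 x s/min
-> mL/min).  Markers: temporal mean, range (max - min), and the pulsatile
volume change deltaV -- the range of the cumulative integral of the demeaned
flow waveform over one cycle (stroke-volume-like, reported in uL).  Temporal
lags between waveforms are estimated by cross-correlation on 500-point
linearly interpolated curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import FlowMarkers, VESSEL_LABELS
from .recon import CardiacSeries

__all__ = [
    "FlowWaveform",
    "LagResult",
    "segment_rois",
    "extract_waveform",
    "markers",
    "aggregate",
    "estimate_lag",
    "resample_to_cycle",
    "shift_by_encode_time",
]


@dataclass(frozen=True)
class FlowWaveform:
    """Cardiac-resolved flow rate (mL/min) on a uniform phase grid."""

    values: np.ndarray
    cycle_length_ms: float
    roi_label: str = ""
    sign_convention: int = 1

    def __post_init__(self):
        if self.cycle_length_ms <= 0:
            raise ValueError("cycle_length_ms must be positive")


@dataclass(frozen=True)
class LagResult:
    lag_ms: float
    grid_spacing_ms: float
    pair: tuple[str, str]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_rois(
    series: CardiacSeries,
    expected_centers_mm: dict[str, tuple[float, float]] | None = None,
    override_masks: dict[str, np.ndarray] | None = None,
    mag_percentile: float = 75.0,
    sc_std_factor: float = 2.0,
) -> dict[str, np.ndarray]:
    """Semi-automatic ROI segmentation on the reconstructed series.

    Vessels: time-averaged magnitude threshold (percentile of the object
    support) + connected components on the highest-venc channel, labeled by
    nearest expected center (left/right, anterior/posterior location priors).
    Spinal canal: temporal velocity-std threshold on the lowest-venc channel
    (CSF oscillates where static tissue does not).  Ground-truth masks may be
    passed through unchanged via ``override_masks``.
    """
    if override_masks is not None:
        return dict(override_masks)
    if expected_centers_mm is None:
        from .phantom import _DEFAULT_ROIS

        expected_centers_mm = {
            k: tuple(v["center_mm"]) for k, v in _DEFAULT_ROIS.items()
        }
    n = series.magnitude.shape[-1]
    pix = series.pixel_mm
    c = (np.arange(n) - n // 2) * pix
    xx, yy = np.meshgrid(c, c)

    mag = series.magnitude.mean(axis=0)
    support = mag > 0.15 * mag.max()
    thr = np.percentile(mag[support], mag_percentile)
    cand = mag >= thr
    lab_img, n_comp = ndimage.label(cand)
    comp_centers = ndimage.center_of_mass(cand, lab_img, range(1, n_comp + 1))
    out: dict[str, np.ndarray] = {}
    vessel_targets = {k: v for k, v in expected_centers_mm.items() if k != "SC"}
    for label, (ex, ey) in vessel_targets.items():
        best, best_d = None, np.inf
        for i, (cy, cx) in enumerate(comp_centers, start=1):
            d = np.hypot((cx - n // 2) * pix - ex, (cy - n // 2) * pix - ey)
            if d < best_d:
                best, best_d = i, d
        if best is None or best_d > 10.0:
            found = [((cx - n // 2) * pix, (cy - n // 2) * pix)
                     for cy, cx in comp_centers]
            raise ValueError(
                f"expected vessel {label} near {(ex, ey)} not found; "
                f"components at {found}"
            )
        out[label] = lab_img == best

    # spinal canal from the velocity std on the most CSF-sensitive channel.
    # Cardiac flow waveforms are band-limited, so the std is computed on a
    # harmonic-filtered series (DC + 6 harmonics), which suppresses the white
    # velocity-noise floor without touching the CSF oscillation; the noise
    # baseline is the median over bright (static-tissue) pixels, where the
    # per-pixel velocity noise is lowest (CSF itself is hypointense and
    # noisier).  The thresholded component is closed to recover
    # partial-volume rim pixels.
    low = min(series.channels, key=lambda ch: ch.effective_venc)
    v = low.velocity
    if v.shape[0] >= 15:
        spec = np.fft.rfft(v, axis=0)
        spec[7:] = 0.0
        v = np.fft.irfft(spec, n=v.shape[0], axis=0)
    vstd = v.std(axis=0)
    bright = support & (mag > np.median(mag[support]))
    bg = np.median(vstd[bright])
    sc_cand = support & (vstd >= sc_std_factor * bg)
    for m in out.values():
        sc_cand &= ~m
    lab_sc, n_sc = ndimage.label(sc_cand)
    if n_sc == 0:
        raise ValueError("no oscillatory CSF component found (all-static scene?)")
    sizes = ndimage.sum_labels(np.ones_like(lab_sc), lab_sc, range(1, n_sc + 1))
    out["SC"] = ndimage.binary_closing(
        lab_sc == (1 + int(np.argmax(sizes))), iterations=2
    )
    return out


# ---------------------------------------------------------------------------
# waveforms and markers
# ---------------------------------------------------------------------------


def extract_waveform(
    series: CardiacSeries,
    mask: np.ndarray,
    channel: int,
    roi_label: str = "",
    sign_convention: int = 1,
) -> FlowWaveform:
    """ROI flow waveform from spatial-mean velocity and ROI area."""
    if not np.any(mask):
        raise ValueError("empty ROI mask")
    area_cm2 = mask.sum() * (series.pixel_mm * 0.1) ** 2
    v = series.channels[channel].velocity[:, mask].mean(axis=1)  # cm/s
    q = v * area_cm2 * 60.0
    return FlowWaveform(
        values=q,
        cycle_length_ms=series.phase_duration_ms * series.n_phases,
        roi_label=roi_label,
        sign_convention=sign_convention,
    )


def markers(w: FlowWaveform) -> FlowMarkers:
    """Mean, range, and pulsatile volume change deltaV of a flow waveform.

    deltaV is the range of the trapezoidal cumulative integral of the
    demeaned waveform over one (periodically closed) cycle, in uL.
    """
    q = np.asarray(w.values, dtype=float)
    mean = float(q.mean())
    rng = float(q.max() - q.min())
    dt_min = (w.cycle_length_ms / len(q)) / 60000.0
    qd = np.concatenate([q - mean, [q[0] - mean]])
    cum = np.concatenate([[0.0], np.cumsum((qd[:-1] + qd[1:]) / 2.0 * dt_min)])
    return FlowMarkers(mean=mean, range=rng, delta_v=float(np.ptp(cum)) * 1e3)


def aggregate(waveforms: dict[str, FlowWaveform]) -> dict[str, FlowWaveform]:
    """tCBF (ICAs + VAs), tJBF (IJV outflow magnitude), and net = tCBF - tJBF."""
    missing = [l for l in VESSEL_LABELS if l not in waveforms]
    if missing:
        raise ValueError(f"missing vessel waveforms: {missing}")
    cyc = {waveforms[l].cycle_length_ms for l in VESSEL_LABELS}
    if len(cyc) > 1:
        raise ValueError("waveforms must share a cardiac cycle length")
    cycle = cyc.pop()
    tcbf = sum(waveforms[l].values for l in ("ICA_L", "ICA_R", "VA_L", "VA_R"))
    tjbf = sum(-waveforms[l].values for l in ("IJV_L", "IJV_R"))
    return {
        "tCBF": FlowWaveform(tcbf, cycle, "tCBF"),
        "tJBF": FlowWaveform(tjbf, cycle, "tJBF"),
        "net": FlowWaveform(tcbf - tjbf, cycle, "net"),
    }


# ---------------------------------------------------------------------------
# resampling, shifting, lags
# ---------------------------------------------------------------------------


def _interp_periodic(w: FlowWaveform, n_interp: int) -> np.ndarray:
    """Linear interpolation to ``n_interp`` points over one cycle."""
    nv = len(w.values)
    tp = np.arange(nv + 1) / nv
    vp = np.concatenate([w.values, w.values[:1]])
    t = np.arange(n_interp) / n_interp
    return np.interp(t, tp, vp)


def resample_to_cycle(w: FlowWaveform, target_cycle_ms: float) -> FlowWaveform:
    """Phase-fraction-preserving resampling to a different cycle length."""
    if target_cycle_ms <= 0:
        raise ValueError("target cycle must be positive")
    return replace(w, cycle_length_ms=float(target_cycle_ms))


def shift_by_encode_time(w: FlowWaveform, offset_trs: float,
                         tr_ms: float, n_interp: int = 500) -> FlowWaveform:
    """Circularly shift a waveform by ``offset_trs * TR`` in time.

    Positive offsets shift the waveform earlier in the cardiac cycle
    (compensating a later acquisition).  Interpolation on the 500-point grid.
    """
    shift_ms = offset_trs * tr_ms
    if shift_ms % w.cycle_length_ms == 0.0:
        return replace(w, values=np.array(w.values, copy=True))
    fine = _interp_periodic(w, n_interp)
    t = np.arange(n_interp) / n_interp
    tq = (t + shift_ms / w.cycle_length_ms) % 1.0
    shifted = np.interp(tq, np.concatenate([t, [1.0]]),
                        np.concatenate([fine, fine[:1]]))
    nv = len(w.values)
    back = np.interp(np.arange(nv) / nv, np.concatenate([t, [1.0]]),
                     np.concatenate([shifted, shifted[:1]]))
    return replace(w, values=back)


def estimate_lag(a: FlowWaveform, b: FlowWaveform, n_interp: int = 500,
                 mode: str = "circular", invert_b: bool = False) -> LagResult:
    """Lag of waveform ``b`` relative to ``a`` by cross-correlation.

    Both waveforms are linearly interpolated to ``n_interp`` points over the
    cycle and demeaned; the lag is the argmax cross-correlation offset in ms
    on that grid, positive when ``b`` trails ``a``, circularly normalized
    into [-cycle/2, cycle/2).  CSF waveforms flow opposite to arterial blood
    and should be compared inverted (``invert_b=True``).
    """
    if abs(a.cycle_length_ms - b.cycle_length_ms) > 1e-9:
        raise ValueError("cycle lengths differ; resample_to_cycle first")
    cycle = a.cycle_length_ms
    xa = _interp_periodic(a, n_interp)
    xb = _interp_periodic(b, n_interp)
    if invert_b:
        xb = -xb
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    if mode == "circular":
        # c[l] = sum_t xa[t] xb[t + l]; argmax l => b trails a by l samples
        c = np.fft.ifft(np.conj(np.fft.fft(xa)) * np.fft.fft(xb)).real
        lag_samples = int(np.argmax(c))
        if lag_samples >= n_interp // 2:
            lag_samples -= n_interp
    elif mode == "linear":
        c = np.correlate(xb, xa, mode="full")
        lag_samples = int(np.argmax(c)) - (n_interp - 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    spacing = cycle / n_interp
    return LagResult(lag_ms=lag_samples * spacing, grid_spacing_ms=spacing,
                     pair=(a.roi_label, b.roi_label))
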