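"""Synthetic cranio-spinal flow scene with analytically known ground truth.

The scene emulates an axial neck slice at the C1/C2 level: paired internal
carotid arteries (ICA_L/R) and vertebral arteries (VA_L/R) carrying pulsatile
arterial inflow, paired internal jugular veins (IJV_L/R) carrying damped
venous outflow, and the spinal canal (SC), an annulus of CSF around the cord
with oscillatory, near-zero-mean bidirectional flow.  Under the fixed-cranium
(Monro-Kellie) constraint the SC CSF waveform is constructed as the negated,
lag-shifted, demeaned net transcranial blood waveform (tCBF - tJBF) scaled by
a coupling factor, so the ground-truth pulsatile volume change of CSF equals
``coupling * deltaV_net`` analytically.

Sign convention: caudo-cranial (arterial inflow) velocity is positive;
venous outflow and systolic CSF displacement are negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROIWaveformParams",
    "ROIRecord",
    "PhantomScene",
    "TriggerStream",
    "FlowMarkers",
    "build_scene",
    "default_scene_config",
    "sample_velocity",
    "generate_triggers",
    "analytic_markers",
    "make_coil_maps",
]

VESSEL_LABELS = ("ICA_L", "ICA_R", "VA_L", "VA_R", "IJV_L", "IJV_R")
ALL_LABELS = VESSEL_LABELS + ("SC",)

# stylized periodic templates (unit scale, zero mean enforced numerically):
# arterial = systolic-peaked 4-harmonic; venous = damped 2-harmonic
_TEMPLATE_HARMONICS = {
    "arterial": ((1.0, 0.0), (0.48, -1.2), (0.22, -2.2), (0.10, -3.1)),
    "venous": ((1.0, 0.3), (0.22, -0.9)),
}


from functools import lru_cache


@lru_cache(maxsize=None)
def _template_norm(family: str) -> tuple[float, float]:
    harmonics = _TEMPLATE_HARMONICS[family]
    fine = 2.0 * np.pi * np.arange(4096) / 4096
    ref = sum(a * np.cos(k * fine + p) for k, (a, p) in enumerate(harmonics, start=1))
    return float(ref.mean()), float(ref.max() - ref.min())


def _template(family: str, phase_frac: np.ndarray) -> np.ndarray:
    """Zero-mean, unit peak-to-peak periodic waveform template."""
    harmonics = _TEMPLATE_HARMONICS[family]
    phi = 2.0 * np.pi * np.asarray(phase_frac, dtype=float)
    s = sum(a * np.cos(k * phi + p) for k, (a, p) in enumerate(harmonics, start=1))
    mean, ptp = _template_norm(family)
    return (s - mean) / ptp


@dataclass(frozen=True)
class ROIWaveformParams:
    """Parametric cardiac flow waveform of one ROI.

    ``mean_flow`` and ``pulse_amplitude`` are in mL/min; ``pulse_amplitude``
    is the peak-to-peak range of the flow-rate curve.  ``lag_ms`` delays the
    waveform; ``sign`` is the through-plane direction (+1 caudo-cranial).
    For the ``csf`` family the waveform values are provided explicitly
    (derived from blood-CSF coupling) via ``csf_values`` on a uniform
    phase-fraction grid.
    """

    family: str  # arterial | venous | csf
    mean_flow: float
    pulse_amplitude: float
    lag_ms: float = 0.0
    sign: int = 1
    csf_values: tuple[float, ...] | None = None  # mL/min on uniform phase grid

    def flow(self, phase_frac: np.ndarray, period_ms: float) -> np.ndarray:
        """Signed flow rate (mL/min) at cardiac phase fractions in [0, 1)."""
        pf = (np.asarray(phase_frac, dtype=float) - self.lag_ms / period_ms) % 1.0
        if self.family == "csf":
            vals = np.asarray(self.csf_values, dtype=float)
            grid = np.arange(len(vals)) / len(vals)
            return np.interp(pf, np.concatenate([grid, [1.0]]),
                             np.concatenate([vals, vals[:1]]))
        q = self.mean_flow + self.pulse_amplitude * _template(self.family, pf)
        return self.sign * q


@dataclass(frozen=True)
class ROIRecord:
    label: str
    shape: str  # disk | annulus
    center_mm: tuple[float, float]  # (x, y) from image center
    radius_mm: float
    inner_radius_mm: float = 0.0
    waveform: ROIWaveformParams | None = None
    t1_ms: float = 1650.0
    proton_density: float = 1.0
    profile: str = "uniform"  # uniform | parabolic

    def mask(self, n: int, pixel_mm: float) -> np.ndarray:
        c = (np.arange(n) - n // 2) * pixel_mm
        xx, yy = np.meshgrid(c, c)
        r2 = (xx - self.center_mm[0]) ** 2 + (yy - self.center_mm[1]) ** 2
        m = r2 <= self.radius_mm**2
        if self.shape == "annulus":
            m &= r2 >= self.inner_radius_mm**2
        return m


@dataclass(frozen=True)
class FlowMarkers:
    """Cardiac flow markers: temporal mean and range of the flow-rate curve
    (mL/min) and pulsatile volume change deltaV (uL), the range of the
    cumulative integral of the demeaned waveform over one cycle."""

    mean: float
    range: float
    delta_v: float


@dataclass(frozen=True)
class TriggerStream:
    """Cardiac trigger times (ms, strictly increasing) with HR statistics."""

    trigger_times_ms: np.ndarray
    mean_hr_bpm: float
    hr_sd_bpm: float

    def __post_init__(self):
        t = np.asarray(self.trigger_times_ms, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("trigger times must be strictly increasing (>= 2)")

    @property
    def mean_rr_ms(self) -> float:
        return float(np.mean(np.diff(self.trigger_times_ms)))


@dataclass(frozen=True)
class PhantomScene:
    """Scene: geometry, waveforms, tissue parameters, background phase, noise.

    ``background_poly`` holds 6 coefficients (rad) of the 2nd-order residual
    phase field ``c0 + c1 x + c2 y + c3 x^2 + c4 x y + c5 y^2`` on normalized
    coordinates in [-1, 1]; in acquisition it scales with each encode's first
    moment (eddy-current-like), so it survives phase differencing and must be
    removed by the polynomial background correction.
    """

    n: int
    pixel_mm: float
    rois: tuple[ROIRecord, ...]
    background_poly: tuple[float, ...]
    noise_sigma: float
    seed: int
    coupling: float = 1.0
    csf_lag_ms: float = 0.0
    tissue_t1_ms: float = 1000.0
    csf_t1_ms: float = 4500.0
    support_radius_mm: float = 44.0

    def roi(self, label: str) -> ROIRecord:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def masks(self) -> dict[str, np.ndarray]:
        return {r.label: r.mask(self.n, self.pixel_mm) for r in self.rois}

    def support_mask(self) -> np.ndarray:
        c = (np.arange(self.n) - self.n // 2) * self.pixel_mm
        xx, yy = np.meshgrid(c, c)
        return xx**2 + yy**2 <= self.support_radius_mm**2

    def t1_map(self) -> np.ndarray:
        t1 = np.where(self.support_mask(), self.tissue_t1_ms, np.inf)
        for r in self.rois:
            t1[r.mask(self.n, self.pixel_mm)] = r.t1_ms
        return t1

    def proton_density_map(self) -> np.ndarray:
        pd = self.support_mask().astype(float)
        for r in self.rois:
            pd[r.mask(self.n, self.pixel_mm)] = r.proton_density
        return pd

    def background_phase(self) -> np.ndarray:
        c = (np.arange(self.n) - self.n // 2) / (self.n // 2)
        xx, yy = np.meshgrid(c, c)
        c0, c1, c2, c3, c4, c5 = self.background_poly
        return c0 + c1 * xx + c2 * yy + c3 * xx**2 + c4 * xx * yy + c5 * yy**2

    def ground_truth_markers(self, n_grid: int = 12000) -> dict[str, FlowMarkers]:
        """Analytic markers per ROI plus tCBF / tJBF / net aggregates."""
        out = {r.label: analytic_markers(r.waveform, n_grid=n_grid)
               for r in self.rois if r.waveform is not None}
        pf = np.arange(n_grid) / n_grid
        art = sum(self.roi(l).waveform.flow(pf, 1000.0)
                  for l in ("ICA_L", "ICA_R", "VA_L", "VA_R"))
        ven = -sum(self.roi(l).waveform.flow(pf, 1000.0) for l in ("IJV_L", "IJV_R"))
        out["tCBF"] = _markers_from_samples(art, 1000.0)
        out["tJBF"] = _markers_from_samples(ven, 1000.0)
        out["net"] = _markers_from_samples(art - ven, 1000.0)
        return out


def _markers_from_samples(q: np.ndarray, period_ms: float) -> FlowMarkers:
    q = np.asarray(q, dtype=float)
    mean = float(q.mean())
    rng = float(q.max() - q.min())
    dt_min = (period_ms / len(q)) / 60000.0  # minutes per step
    # cumulative trapezoid of the demeaned curve, periodic closure
    qd = np.concatenate([q - mean, [q[0] - mean]])
    cum = np.concatenate([[0.0], np.cumsum((qd[:-1] + qd[1:]) / 2.0 * dt_min)])
    return FlowMarkers(mean=mean, range=rng, delta_v=float(cum.max() - cum.min()) * 1e3)


def analytic_markers(params: ROIWaveformParams, period_ms: float = 1000.0,
                     n_grid: int = 12000) -> FlowMarkers:
    """Ground-truth mean/range/deltaV by dense quadrature of the waveform."""
    pf = np.arange(n_grid) / n_grid
    return _markers_from_samples(params.flow(pf, period_ms), period_ms)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

#: default ROI geometry (mm from image center) and Table-1-scale flows
#: (per-ICA mean ~ 210-230 mL/min, tCBF ~ 615, IJV outflow ~ 405 total);
#: radii are generous relative to anatomy so that desk-scale grids (1 mm
#: pixels) resolve each lumen with an adequate pixel count
_DEFAULT_ROIS = {
    "ICA_R": dict(shape="disk", center_mm=(-16.0, 14.0), radius_mm=4.0,
                  waveform=dict(family="arterial", mean_flow=230.0,
                                pulse_amplitude=200.0, sign=1)),
    "ICA_L": dict(shape="disk", center_mm=(16.0, 14.0), radius_mm=4.0,
                  waveform=dict(family="arterial", mean_flow=210.0,
                                pulse_amplitude=185.0, lag_ms=4.0, sign=1)),
    "VA_R": dict(shape="disk", center_mm=(-12.0, -11.0), radius_mm=3.0,
                 waveform=dict(family="arterial", mean_flow=85.0,
                               pulse_amplitude=70.0, lag_ms=-13.0, sign=1)),
    "VA_L": dict(shape="disk", center_mm=(12.0, -11.0), radius_mm=3.0,
                 waveform=dict(family="arterial", mean_flow=90.0,
                               pulse_amplitude=80.0, lag_ms=-13.0, sign=1)),
    "IJV_R": dict(shape="disk", center_mm=(-27.0, 3.0), radius_mm=5.0,
                  waveform=dict(family="venous", mean_flow=260.0,
                                pulse_amplitude=150.0, lag_ms=60.0, sign=-1)),
    "IJV_L": dict(shape="disk", center_mm=(27.0, 3.0), radius_mm=5.0,
                  waveform=dict(family="venous", mean_flow=145.0,
                                pulse_amplitude=70.0, lag_ms=60.0, sign=-1)),
    "SC": dict(shape="annulus", center_mm=(0.0, 0.0), radius_mm=9.0,
               inner_radius_mm=5.0),
}

BLOOD_T1_MS = 1650.0
CSF_T1_MS = 4500.0
#: inflow-enhancement surrogate: fresh blood spins are not saturated by the
#: SPGR steady state, so lumina appear bright; modeled as elevated PD
BLOOD_PD = 2.0
CSF_PD = 1.0


def default_scene_config() -> dict:
    """Editable configuration dict for :func:`build_scene`."""
    return {
        "n": 96,
        "pixel_mm": 1.0,
        "coupling": 1.0,
        "csf_lag_ms": 0.0,
        # per-sample complex noise std; yields image SNR ~ 30 (peak magnitude
        # over noise-floor std) at the desk-scale reference protocol
        "noise_sigma": 1.0e-6,
        "seed": 0,
        "profile": "uniform",
        "background_poly": [0.12, 0.08, -0.06, 0.05, 0.03, -0.04],
        "rois": {k: _deep_copy(v) for k, v in _DEFAULT_ROIS.items()},
    }


def _deep_copy(d):
    import copy

    return copy.deepcopy(d)


def build_scene(config: dict | None = None) -> PhantomScene:
    """Assemble a :class:`PhantomScene` from a configuration dict.

    The SC CSF waveform is derived from the vessel waveforms: the net blood
    waveform (tCBF - tJBF) is demeaned, negated, lag-shifted, and scaled by
    ``coupling``, so ground-truth ``deltaV_SC = coupling * deltaV_net``.
    Raises on overlapping ROIs.
    """
    cfg = default_scene_config()
    if config:
        for k, v in config.items():
            if k == "rois":
                for label, roi_cfg in v.items():
                    base = cfg["rois"].setdefault(label, {})
                    for kk, vv in roi_cfg.items():
                        if kk == "waveform" and isinstance(vv, dict):
                            base.setdefault("waveform", {}).update(vv)
                        else:
                            base[kk] = vv
            else:
                cfg[k] = v

    rois = []
    vessel_params: dict[str, ROIWaveformParams] = {}
    for label in VESSEL_LABELS:
        rc = cfg["rois"][label]
        wf = ROIWaveformParams(**rc["waveform"])
        vessel_params[label] = wf
        rois.append(
            ROIRecord(
                label=label, shape=rc["shape"], center_mm=tuple(rc["center_mm"]),
                radius_mm=rc["radius_mm"], waveform=wf, t1_ms=BLOOD_T1_MS,
                proton_density=BLOOD_PD, profile=cfg["profile"],
            )
        )

    # SC CSF waveform from Monro-Kellie coupling on a fine phase grid
    n_grid = 3000
    pf = np.arange(n_grid) / n_grid
    art = sum(vessel_params[l].flow(pf, 1000.0) for l in ("ICA_L", "ICA_R", "VA_L", "VA_R"))
    ven = -sum(vessel_params[l].flow(pf, 1000.0) for l in ("IJV_L", "IJV_R"))
    net = art - ven
    csf = -cfg["coupling"] * (net - net.mean())
    sc_cfg = cfg["rois"]["SC"]
    sc_wf = ROIWaveformParams(
        family="csf", mean_flow=0.0, pulse_amplitude=float(csf.max() - csf.min()),
        lag_ms=cfg["csf_lag_ms"], sign=1, csf_values=tuple(csf),
    )
    rois.append(
        ROIRecord(
            label="SC", shape="annulus", center_mm=tuple(sc_cfg["center_mm"]),
            radius_mm=sc_cfg["radius_mm"], inner_radius_mm=sc_cfg["inner_radius_mm"],
            waveform=sc_wf, t1_ms=CSF_T1_MS, proton_density=CSF_PD,
            profile=cfg["profile"],
        )
    )

    scene = PhantomScene(
        n=int(cfg["n"]), pixel_mm=float(cfg["pixel_mm"]), rois=tuple(rois),
        background_poly=tuple(cfg["background_poly"]),
        noise_sigma=float(cfg["noise_sigma"]), seed=int(cfg["seed"]),
        coupling=float(cfg["coupling"]), csf_lag_ms=float(cfg["csf_lag_ms"]),
    )
    _check_disjoint(scene)
    return scene


def _check_disjoint(scene: PhantomScene) -> None:
    total = np.zeros((scene.n, scene.n), dtype=int)
    for r in scene.rois:
        total += r.mask(scene.n, scene.pixel_mm)
    if total.max() > 1:
        raise ValueError("ROIs overlap on the pixel grid")


# ---------------------------------------------------------------------------
# continuous-time evaluation
# ---------------------------------------------------------------------------


def sample_velocity(scene: PhantomScene, t_ms: float,
                    triggers: TriggerStream) -> np.ndarray:
    """Per-pixel through-plane velocity map (cm/s) at absolute time ``t_ms``.

    Within each ROI the velocity is spatially uniform (or parabolic), scaled
    so spatial-mean x pixel area x 60 equals the ROI flow waveform at the
    cardiac phase fraction ``(t - last_trigger)/RR``.
    """
    tt = np.asarray(triggers.trigger_times_ms)
    if t_ms < tt[0]:
        raise ValueError("t precedes the first cardiac trigger")
    i = int(np.searchsorted(tt, t_ms, side="right") - 1)
    i = min(i, tt.size - 2)
    rr = tt[i + 1] - tt[i]
    frac = (t_ms - tt[i]) / rr

    v = np.zeros((scene.n, scene.n))
    for r in scene.rois:
        if r.waveform is None:
            continue
        m = r.mask(scene.n, scene.pixel_mm)
        area_cm2 = m.sum() * (scene.pixel_mm * 0.1) ** 2
        q = float(r.waveform.flow(np.array([frac]), rr)[0])  # mL/min
        v_mean = q / (area_cm2 * 60.0)  # cm/s
        if r.profile == "parabolic" and r.shape == "disk":
            c = (np.arange(scene.n) - scene.n // 2) * scene.pixel_mm
            xx, yy = np.meshgrid(c, c)
            rho2 = ((xx - r.center_mm[0]) ** 2 + (yy - r.center_mm[1]) ** 2)[m]
            prof = 1.0 - rho2 / r.radius_mm**2
            v[m] = v_mean * prof / prof.mean()
        else:
            v[m] = v_mean
    return v


def roi_mean_velocity(scene: PhantomScene, t_ms: np.ndarray,
                      triggers: TriggerStream) -> dict[str, np.ndarray]:
    """Spatial-mean ROI velocity (cm/s) at each time; vectorized fast path
    used by the simulator for uniform-profile scenes."""
    tt = np.asarray(triggers.trigger_times_ms)
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < tt[0]):
        raise ValueError("t precedes the first cardiac trigger")
    i = np.clip(np.searchsorted(tt, t, side="right") - 1, 0, tt.size - 2)
    rr = tt[i + 1] - tt[i]
    frac = (t - tt[i]) / rr
    out = {}
    for r in scene.rois:
        if r.waveform is None:
            continue
        area_cm2 = r.mask(scene.n, scene.pixel_mm).sum() * (scene.pixel_mm * 0.1) ** 2
        q = r.waveform.flow(np.atleast_1d(frac), np.atleast_1d(rr))
        out[r.label] = q / (area_cm2 * 60.0)
    return out


def generate_triggers(duration_s: float, mean_hr_bpm: float = 65.0,
                      hr_sd_bpm: float = 0.0, seed: int = 0) -> TriggerStream:
    """Cardiac trigger stream with Gaussian i.i.d. RR variability.

    RR intervals are drawn from N(60000/HR, sd_RR) truncated at +/- 3 sd,
    with ``sd_RR = 60000 * hr_sd / HR^2`` (first-order propagation).  The
    stream covers slightly more than ``duration_s`` so every acquired sample
    falls inside a complete RR interval.
    """
    if mean_hr_bpm <= 0:
        raise ValueError("mean heart rate must be positive")
    rng = np.random.default_rng(seed)
    rr_mean = 60000.0 / mean_hr_bpm
    rr_sd = 60000.0 * hr_sd_bpm / mean_hr_bpm**2
    times = [0.0]
    horizon = duration_s * 1000.0 + 2 * rr_mean
    while times[-1] < horizon:
        rr = rr_mean if rr_sd == 0 else float(
            np.clip(rng.normal(rr_mean, rr_sd), rr_mean - 3 * rr_sd, rr_mean + 3 * rr_sd)
        )
        rr = max(rr, 0.2 * rr_mean)
        times.append(times[-1] + rr)
    return TriggerStream(
        trigger_times_ms=np.array(times), mean_hr_bpm=mean_hr_bpm, hr_sd_bpm=hr_sd_bpm
    )


def make_coil_maps(n: int, n_coils: int = 4) -> np.ndarray:
    """Analytic smooth coil sensitivities: complex Gaussians at the corners.

    ``n_coils=1`` returns a single uniform map.
    """
    if n_coils == 1:
        return np.ones((1, n, n), dtype=complex)
    c = (np.arange(n) - n // 2) / n
    xx, yy = np.meshgrid(c, c)
    centers = [(-0.5, -0.5), (0.5, -0.5), (-0.5, 0.5), (0.5, 0.5)][:n_coils]
    maps = []
    for j, (cx, cy) in enumerate(centers):
        g = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.45**2)))
        maps.append(g * np.exp(1j * (0.5 * j + 0.8 * (xx * cy - yy * cx))))
    return np.stack(maps)
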