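"""Velocity encoding: gradient first moments, bipolar design, encode schemes.

Phase-contrast MRI encodes through-plane velocity ``v`` into signal phase via
the first moment ``M1`` of a bipolar gradient waveform played on the
slice-normal axis: ``phi = gamma * M1 * v``.  The venc (velocity-encoding
parameter) is the velocity that accrues exactly pi radians relative to the
reference encode, so ``deltaM1 = pi / (gamma * venc)``.

Units used throughout this module:

* gradient amplitude: mT/m
* time: ms (gradient raster specified in microseconds)
* first moment: mT.ms^2/m
* venc and velocities: cm/s

With these units the phase per (moment x velocity) is
``PHASE_PER_MOMENT_VELOCITY = gamma * 1e-9 * 1e-2`` rad per (mT.ms^2/m)(cm/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GAMMA",
    "PHASE_PER_MOMENT_VELOCITY",
    "GradientWaveform",
    "FlowEncode",
    "EncodingScheme",
    "ProtocolConfig",
    "venc_to_moment",
    "moment_to_venc",
    "design_bipolar",
    "build_scheme",
    "scan_time",
    "relative_snr_reduction",
    "spgr_signal",
    "ernst_angle",
    "temporal_resolution",
    "theoretical_resolution",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA = 2.6752e8

#: phase (rad) accrued per unit (mT.ms^2/m first moment) x (cm/s velocity)
PHASE_PER_MOMENT_VELOCITY = GAMMA * 1e-9 * 1e-2


def venc_to_moment(venc: float) -> float:
    """First-moment difference (mT.ms^2/m) that makes ``venc`` accrue pi rad.

    Parameters
    ----------
    venc : float
        Velocity-encoding parameter in cm/s; must be positive.
    """
    if venc <= 0:
        raise ValueError(f"venc must be positive, got {venc!r}")
    return math.pi / (PHASE_PER_MOMENT_VELOCITY * venc)


def moment_to_venc(delta_m1: float) -> float:
    """Effective venc (cm/s) of a first-moment difference (mT.ms^2/m)."""
    if delta_m1 <= 0:
        raise ValueError(f"delta_m1 must be positive, got {delta_m1!r}")
    return math.pi / (PHASE_PER_MOMENT_VELOCITY * delta_m1)


# ---------------------------------------------------------------------------
# gradient waveforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientWaveform:
    """Sampled gradient waveform on a fixed raster.

    ``samples`` are amplitudes (mT/m) at times ``i * raster_us`` and the
    continuous waveform is the piecewise-linear interpolant; moments are
    integrated exactly on that interpolant.
    """

    samples: np.ndarray  # mT/m, shape (n,)
    raster_us: float = 4.0
    axis: str = "z"

    @property
    def duration_ms(self) -> float:
        n = len(self.samples)
        return 0.0 if n < 2 else (n - 1) * self.raster_us * 1e-3

    def moments(self) -> tuple[float, float]:
        """Exact (M0, M1) of the piecewise-linear waveform.

        M0 in mT.ms/m, M1 in mT.ms^2/m, time origin at the first sample.
        """
        g = np.asarray(self.samples, dtype=float)
        if g.size < 2:
            return 0.0, 0.0
        dt = self.raster_us * 1e-3
        g0, g1 = g[:-1], g[1:]
        t0 = np.arange(g.size - 1) * dt
        m0 = dt * (g0 + g1) / 2.0
        # int t*(g0 + (g1-g0)*(t-t0)/dt) dt over [t0, t0+dt]
        m1 = dt * (t0 * (g0 + g1) / 2.0 + dt * (g0 / 6.0 + g1 / 3.0))
        return float(m0.sum()), float(m1.sum())

    def validate(self, gmax: float, smax: float, m0_tol: float = 1e-9) -> None:
        g = np.asarray(self.samples, dtype=float)
        if g.size == 0:
            return
        if np.max(np.abs(g)) > gmax * (1 + 1e-9):
            raise ValueError("waveform exceeds Gmax")
        if g.size > 1:
            slew = np.abs(np.diff(g)) / (self.raster_us * 1e-3)  # mT/m/ms == T/m/s
            if slew.max() > smax * (1 + 1e-9):
                raise ValueError("waveform exceeds Smax")
        m0, _ = self.moments()
        if abs(m0) > m0_tol * max(1.0, np.max(np.abs(g)) * self.duration_ms):
            raise ValueError("waveform is not net-refocused (M0 != 0)")


def _lobe_m1(ramp_steps: int, flat_steps: int, g: float, dt_ms: float) -> float:
    """|M1| of a back-to-back bipolar with trapezoid lobes (analytic).

    Each lobe: ramp ``r`` steps up, ``f`` steps flat, ``r`` steps down, at
    amplitude ``g``; two opposite-polarity lobes abutted.  For such a pair
    |M1| = g * (tr + tf) * (2 tr + tf) with tr = r*dt, tf = f*dt.
    """
    tr = ramp_steps * dt_ms
    tf = flat_steps * dt_ms
    return g * (tr + tf) * (2 * tr + tf)


def design_bipolar(
    delta_m1: float,
    gmax: float = 80.0,
    smax: float = 200.0,
    raster_us: float = 4.0,
    polarity: int = 1,
) -> GradientWaveform:
    """Minimum-time bipolar gradient achieving a target first moment.

    Two opposite-polarity trapezoid (or triangle) lobes played back-to-back;
    lobe ramp and flat times are integer raster multiples chosen to minimize
    total duration subject to ``gmax`` (mT/m) and ``smax`` (T/m/s), then the
    amplitude is scaled down so the achieved |M1| equals ``delta_m1`` exactly.

    Parameters
    ----------
    delta_m1 : float
        Target |first moment| in mT.ms^2/m (>= 0).
    polarity : int
        Sign of the *second* lobe; with ``polarity=+1`` the waveform's M1 is
        positive (first lobe negative, second positive).
    """
    if delta_m1 < 0:
        raise ValueError("delta_m1 must be >= 0")
    if gmax <= 0 or smax <= 0 or raster_us <= 0:
        raise ValueError("hardware limits must be positive")
    if delta_m1 == 0:
        return GradientWaveform(samples=np.zeros(0), raster_us=raster_us)

    dt = raster_us * 1e-3  # ms
    # smallest half-duration n (lobe steps, n = 2r + f) whose best-r moment
    # reaches the target
    n = 2
    while True:
        best = 0.0
        r_cap = int(n // 2)
        # amplitude grows with r until Gmax; moment maximised at the cap
        r_star = max(1, min(r_cap, math.ceil(gmax / (smax * dt))))
        for r in {max(1, r_star - 1), r_star, min(r_cap, r_star + 1)}:
            if r < 1 or r > r_cap:
                continue
            g = min(gmax, smax * r * dt)
            best = max(best, _lobe_m1(r, n - 2 * r, g, dt))
        if best >= delta_m1 or n > 2_000_000:
            break
        n += 1
    if n < 2:
        raise ValueError("duration below 2 raster steps is unachievable")

    # pick the r at this n that meets the target with the smallest amplitude
    candidates = []
    for r in range(1, n // 2 + 1):
        g = min(gmax, smax * r * dt)
        m1 = _lobe_m1(r, n - 2 * r, g, dt)
        if m1 >= delta_m1:
            candidates.append((g, r))
    g_nom, r = min(candidates)
    f = n - 2 * r
    scale = delta_m1 / _lobe_m1(r, f, g_nom, dt)
    g_amp = g_nom * scale

    ramp_up = np.linspace(0.0, g_amp, r + 1)
    lobe = np.concatenate([ramp_up, np.full(f, g_amp), ramp_up[::-1][1:]])
    # first lobe negative, second positive => positive M1 (for polarity=+1)
    samples = np.concatenate([-lobe[:-1], lobe])
    wf = GradientWaveform(samples=polarity * samples, raster_us=raster_us)
    wf.validate(gmax, smax)
    return wf


# ---------------------------------------------------------------------------
# encode blocks and protocol
# ---------------------------------------------------------------------------

ROLE_FLOW_COMPENSATED = "flow_compensated"
ROLE_VELOCITY_ENCODED = "velocity_encoded"
ROLE_BALANCED_PLUS = "balanced_plus"
ROLE_BALANCED_MINUS = "balanced_minus"


@dataclass(frozen=True)
class FlowEncode:
    """One encode of a measurement block."""

    role: str
    venc: float | None  # cm/s; None for the flow-compensated reference
    delta_m1: float  # signed own M1 (mT.ms^2/m), 0 for flow-compensated
    waveform: GradientWaveform
    index_in_block: int


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition geometry/hardware parameters.

    Defaults mirror the in-vivo protocol: 22 cm FOV, 0.68 mm in-plane
    resolution, 4 mm slice, 8 deg flip, 30 cardiac phases, ~3.7 ms spiral
    readout, 80 mT/m and 200 T/m/s gradient limits.
    """

    fov_cm: float = 22.0
    in_plane_resolution_mm: float = 0.68
    slice_thickness_mm: float = 4.0
    flip_angle_deg: float = 8.0
    n_arms: int = 3300
    oversampling_factor: int = 34
    n_cardiac_phases: int = 30
    readout_duration_ms: float = 3.7
    samples_per_arm: int = 256
    gmax: float = 80.0
    smax: float = 200.0
    raster_us: float = 4.0
    golden_angle_deg: float = 137.508

    def __post_init__(self):
        for name in (
            "fov_cm", "in_plane_resolution_mm", "slice_thickness_mm",
            "flip_angle_deg", "n_arms", "oversampling_factor",
            "n_cardiac_phases", "readout_duration_ms", "samples_per_arm",
            "gmax", "smax", "raster_us",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EncodingScheme:
    """Ordered interleaved encode block with shared TE/TR.

    ``channel_map`` lists velocity channels as
    ``(reference_index, encode_index, effective_venc)``; the channel velocity
    is obtained from the phase of ``img[encode] * conj(img[reference])``.
    """

    scheme_type: str  # single_balanced | dual | multi
    encodes: tuple[FlowEncode, ...]
    tr_ms: float
    te_ms: float
    flip_angle_deg: float
    channel_map: tuple[tuple[int, int, float], ...]

    @property
    def n_encodes(self) -> int:
        return len(self.encodes)

    def channel_time_offset_ms(self, channel: int) -> float:
        """Acquisition-time offset of a channel within its block (ms).

        Referenced schemes: the offset of the velocity encode itself (1 TR for
        the first encode after the reference, etc.).  Balanced scheme: the
        midpoint of the +/- pair.
        """
        ref, enc, _ = self.channel_map[channel]
        if self.scheme_type == "single_balanced":
            return 0.5 * (ref + enc) * self.tr_ms
        return enc * self.tr_ms


_SCHEME_VENC_COUNT = {"single_balanced": 1, "dual": 2, "multi": 3}

# excitation-to-encode and post-readout overheads (ms); calibrated once so the
# four protocol presets reproduce their nominal TE/TR, informational only
TE_OVERHEAD_MS = 1.05
TR_OVERHEAD_MS = 2.2


def build_scheme(
    scheme_type: str,
    vencs: list[float] | tuple[float, ...],
    protocol: ProtocolConfig | None = None,
    tr_ms: float | None = None,
    te_ms: float | None = None,
) -> EncodingScheme:
    """Build the ordered interleaved encode block for a scheme.

    ``dual`` -> [flow-compensated, high venc, low venc];
    ``multi`` -> [flow-compensated, high, middle, low];
    ``single_balanced`` -> two encodes with +/- half the moment.
    Vencs must be given strictly decreasing.  All waveforms are left-padded
    with zeros to the duration of the largest-moment encode so every encode
    shares the same TE.
    """
    protocol = protocol or ProtocolConfig()
    if scheme_type not in _SCHEME_VENC_COUNT:
        raise ValueError(f"unknown scheme_type {scheme_type!r}")
    vencs = [float(v) for v in vencs]
    if len(vencs) != _SCHEME_VENC_COUNT[scheme_type]:
        raise ValueError(
            f"{scheme_type} requires {_SCHEME_VENC_COUNT[scheme_type]} venc(s), "
            f"got {len(vencs)}"
        )
    if any(v <= 0 for v in vencs):
        raise ValueError("vencs must be positive")
    if any(b >= a for a, b in zip(vencs, vencs[1:])):
        raise ValueError("vencs must be strictly decreasing")

    kw = dict(gmax=protocol.gmax, smax=protocol.smax, raster_us=protocol.raster_us)
    encodes: list[FlowEncode]
    if scheme_type == "single_balanced":
        venc = vencs[0]
        half = venc_to_moment(venc) / 2.0
        wf_plus = design_bipolar(half, **kw)
        wf_minus = GradientWaveform(
            samples=-wf_plus.samples, raster_us=wf_plus.raster_us
        )
        encodes = [
            FlowEncode(ROLE_BALANCED_PLUS, venc, +half, wf_plus, 0),
            FlowEncode(ROLE_BALANCED_MINUS, venc, -half, wf_minus, 1),
        ]
        channel_map = ((1, 0, venc),)
    else:
        encodes = [
            FlowEncode(
                ROLE_FLOW_COMPENSATED, None, 0.0,
                GradientWaveform(samples=np.zeros(0), raster_us=protocol.raster_us), 0,
            )
        ]
        for i, venc in enumerate(vencs, start=1):
            m1 = venc_to_moment(venc)
            encodes.append(
                FlowEncode(ROLE_VELOCITY_ENCODED, venc, m1, design_bipolar(m1, **kw), i)
            )
        channel_map = tuple((0, i, v) for i, v in enumerate(vencs, start=1))

    # pad every waveform (leading zeros) to the longest encode duration; a
    # bipolar has M0 = 0 so its M1 is invariant under the time shift
    n_max = max(len(e.waveform.samples) for e in encodes)
    padded = []
    for e in encodes:
        n_pad = n_max - len(e.waveform.samples)
        if n_pad:
            wf = GradientWaveform(
                samples=np.concatenate([np.zeros(n_pad), e.waveform.samples]),
                raster_us=e.waveform.raster_us,
            )
            e = replace(e, waveform=wf)
        padded.append(e)

    encode_dur = padded[-1].waveform.duration_ms if n_max > 1 else 0.0
    te = te_ms if te_ms is not None else TE_OVERHEAD_MS + encode_dur
    tr = tr_ms if tr_ms is not None else te + protocol.readout_duration_ms + TR_OVERHEAD_MS
    return EncodingScheme(
        scheme_type=scheme_type,
        encodes=tuple(padded),
        tr_ms=float(tr),
        te_ms=float(te),
        flip_angle_deg=protocol.flip_angle_deg,
        channel_map=channel_map,
    )


# ---------------------------------------------------------------------------
# protocol arithmetic
# ---------------------------------------------------------------------------


def scan_time(n_arms: int, n_encodes: int, tr_ms: float) -> tuple[float, int]:
    """Total scan time: every arm is acquired once per encode.

    Returns ``(seconds, rounded_seconds)``.
    """
    if n_arms <= 0 or n_encodes <= 0 or tr_ms <= 0:
        raise ValueError("all inputs must be positive")
    seconds = n_arms * n_encodes * tr_ms * 1e-3
    return seconds, int(round(seconds))


def relative_snr_reduction(n_samples_a: int, n_samples_b: int) -> float:
    """Percent SNR loss of acquisition b relative to a, with SNR ~ sqrt(N)."""
    if n_samples_a <= 0 or n_samples_b <= 0:
        raise ValueError("sample counts must be positive")
    return (1.0 - math.sqrt(n_samples_b / n_samples_a)) * 100.0


def spgr_signal(flip_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Relative transverse SPGR steady-state signal.

    ``sin(a) (1 - E1) / (1 - E1 cos(a))`` with ``E1 = exp(-TR/T1)``.
    """
    if not (0 < flip_deg < 90):
        raise ValueError("flip angle must be in (0, 90) degrees")
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    a = math.radians(flip_deg)
    e1 = math.exp(-tr_ms / t1_ms)
    return math.sin(a) * (1 - e1) / (1 - e1 * math.cos(a))


def ernst_angle(tr_ms: float, t1_ms: float) -> float:
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(-TR/T1))."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    return math.degrees(math.acos(math.exp(-tr_ms / t1_ms)))


def temporal_resolution(heart_rate_bpm: float, n_phases: int) -> float:
    """Reconstructed temporal resolution (ms): RR interval / cardiac phases."""
    if heart_rate_bpm <= 0 or n_phases <= 0:
        raise ValueError("inputs must be positive")
    return (60000.0 / heart_rate_bpm) / n_phases


def theoretical_resolution(scheme: EncodingScheme) -> float:
    """Theoretical temporal resolution (ms) of the encoding scheme.

    Referenced (interleaved) schemes deliver one velocity sample per TR; the
    balanced +/- pair needs two TRs per sample.
    """
    return 2.0 * scheme.tr_ms if scheme.scheme_type == "single_balanced" else scheme.tr_ms
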