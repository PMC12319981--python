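"""Center-out golden-angle 2D spiral trajectory and sampling bookkeeping.

One spiral "arm" traces an Archimedean spiral from the k-space center to
``kmax = 1/(2 * resolution)``; successive arms are rotated by the golden
angle (137.508 deg by default), which distributes any contiguous subset of
arms near-uniformly in azimuth and so supports retrospective cardiac binning
with arbitrary bin boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .encoding import ProtocolConfig

__all__ = [
    "SpiralTrajectory",
    "make_golden_spiral",
    "density_compensation",
    "arms_per_phase",
    "undersampling_factor",
]

GOLDEN_ANGLE_DEG = 137.508
GOLDEN_ANGLE_CONJUGATE_DEG = 222.492


@dataclass(frozen=True)
class SpiralTrajectory:
    """Golden-angle spiral arm set.

    ``coords`` has shape (n_arms, samples_per_arm, 2) in m^-1, ``dcf`` shape
    (samples_per_arm,) -- density weights are identical across arms and carry
    k-space area units assuming all ``n_arms`` arms contribute.
    """

    coords: np.ndarray
    dcf: np.ndarray
    angle_increment_deg: float
    kmax: float
    n_turns: int
    readout_duration_ms: float

    @property
    def n_arms(self) -> int:
        return self.coords.shape[0]

    @property
    def samples_per_arm(self) -> int:
        return self.coords.shape[1]


def make_golden_spiral(
    protocol: ProtocolConfig,
    n_arms: int | None = None,
    angle_increment_deg: float | None = None,
) -> SpiralTrajectory:
    """Build the center-out golden-angle Archimedean spiral arm set.

    The radial law is ``|k|(tau) = kmax * tau`` with ``tau`` uniform in time
    across the readout.  The number of azimuthal turns is chosen so that one
    fully-sampled set of ``n_arms / oversampling_factor`` uniformly rotated
    arms satisfies Nyquist (radial ring spacing <= 1/FOV) at the FOV edge.
    """
    n_arms = int(n_arms if n_arms is not None else protocol.n_arms)
    ga = (
        angle_increment_deg
        if angle_increment_deg is not None
        else protocol.golden_angle_deg
    )
    res_m = protocol.in_plane_resolution_mm * 1e-3
    fov_m = protocol.fov_cm * 1e-2
    kmax = 1.0 / (2.0 * res_m)
    n_full = max(1, round(n_arms / protocol.oversampling_factor))
    n_turns = max(1, math.ceil(kmax * fov_m / n_full))

    ns = protocol.samples_per_arm
    tau = np.arange(ns) / (ns - 1)
    theta0 = 2.0 * np.pi * n_turns * tau
    base = kmax * tau * np.exp(1j * theta0)
    rot = np.exp(1j * np.deg2rad(ga) * np.arange(n_arms))
    k = base[None, :] * rot[:, None]
    coords = np.stack([k.real, k.imag], axis=-1)

    traj = SpiralTrajectory(
        coords=coords,
        dcf=np.zeros(ns),
        angle_increment_deg=float(ga),
        kmax=kmax,
        n_turns=n_turns,
        readout_duration_ms=protocol.readout_duration_ms,
    )
    object.__setattr__(traj, "dcf", density_compensation(traj))
    return traj


def density_compensation(traj: SpiralTrajectory) -> np.ndarray:
    """Analytic polar-Jacobian density weights for a uniform Archimedean arm.

    Sample ``j`` at radius ``|k| = kmax * tau_j`` receives the k-space area of
    its polar annulus sector, ``2 pi |k| kmax dtau / n_arms`` (the center
    sample gets the enclosed half-step disk), so the weighted adjoint NUDFT
    approximates the continuous inverse FT over the sampled disk.  Weights are
    nonnegative and, per arm, sum to ``pi kmax^2 / n_arms``.
    """
    ns = traj.samples_per_arm
    tau = np.arange(ns) / (ns - 1)
    dtau = 1.0 / (ns - 1)
    w = 2.0 * np.pi * traj.kmax**2 * tau * dtau
    w[0] = np.pi * (traj.kmax * dtau / 2.0) ** 2
    # normalize exactly: all arms together tile the |k| <= kmax disk
    w *= (np.pi * traj.kmax**2) / (w.sum() * traj.n_arms) * 1.0
    return w


def arms_per_phase(n_arms: int, n_phases: int) -> int:
    """Average spiral arms contributing to each reconstructed cardiac phase."""
    if n_arms <= 0 or n_phases <= 0:
        raise ValueError("inputs must be positive")
    return round(n_arms / n_phases)


def undersampling_factor(oversampling_factor: int, n_phases: int) -> float:
    """Times k-space was oversampled over cardiac phases reconstructed, 2 d.p."""
    if oversampling_factor <= 0 or n_phases <= 0:
        raise ValueError("inputs must be positive")
    return round(oversampling_factor / n_phases, 2)
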