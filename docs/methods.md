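# Methods

## Signal and encoding model

Through-plane velocity `v` contributes phase `phi = gamma * M1 * v` with
`gamma = 2.6752e8 rad s^-1 T^-1`. An encode's sensitivity is its first
gradient moment relative to the block's reference; the venc of a channel is
`pi / (gamma * deltaM1)`, so velocity maps follow from
`v = venc * angle(img_encode * conj(img_reference)) / pi`, wrapped to
(−venc, venc].

Bipolar encoding gradients are two opposite-polarity trapezoid (or triangle)
lobes on the slice-normal axis, on a 4 µs raster, designed minimum-time: for
each candidate lobe duration the ramp split maximizing the achievable moment
under Gmax (80 mT/m) and Smax (200 T/m/s) is evaluated, the shortest feasible
duration is kept, and the amplitude is scaled down so the achieved moment —
integrated exactly on the piecewise-linear waveform — equals the target. A
brute-force grid search over lobe timings is kept in the test suite as an
independent oracle.

Encode blocks: `dual` = [flow-compensated, 75, 8 cm/s], `multi` =
[flow-compensated, 100, 50, 8 cm/s], `single_balanced` = ±half-moment pair.
All encodes of a block are left-padded to the longest waveform so they share
TE (a bipolar's M1 is shift-invariant because its M0 is zero). Velocity
encoded moments are positive relative to the reference; caudo-cranial flow is
positive. TE is modeled as a fixed 1.05 ms excitation-to-encode overhead plus
the encode duration (the spiral echoes at readout start); TR adds the 3.7 ms
readout and a 2.2 ms end overhead. These reproduce the nominal protocol
TE/TRs and are informational — binning and quantification depend only on TR.

The balanced pair is treated as one velocity sample centered between its two
encodes (timestamp at the pair midpoint, theoretical temporal resolution
2 TR); referenced schemes deliver one sample per TR, each velocity channel
inheriting the actual acquisition time of its encode (1 TR, 2 TR, 3 TR after
the block start).

## Trajectory and reconstruction

Arms are uniform-density Archimedean spirals, `|k|(tau) = kmax * tau` with
`kmax = 1/(2 * resolution)`, rotated by the golden angle (137.508° default;
the conjugate 222.492° is selectable). The turn count is the smallest for
which one fully-sampled set of `n_arms / oversampling_factor` uniformly
rotated arms meets Nyquist at the FOV edge.

The non-uniform Fourier transform is an exact separable NUDFT: the per-sample
phase factor factorizes over image axes, reducing the forward transform to
two matrix products per sample chunk and the weighted adjoint to one. At the
desk grids used here (≤ 96–128 squared) this is faster to reason about and
test than kernel gridding, and the simulator and reconstructor share the same
discretization, so forward-model error is exactly zero.

Density compensation is the analytic polar Jacobian (annulus-sector area per
sample), with two per-reconstruction refinements: (i) each arm in a cardiac
bin is weighted by its azimuthal Voronoi share, because a bin holds an
irregular subset of golden-angle arms whose angular gaps are far from
uniform — with uniform weights the bin-to-bin aliasing jitter is several
times larger; (ii) the reconstruction is divided by the exact PSF sum of the
weighted adjoint (computed from a ones-image forward transform) so that
extended regions read at their true intensity — disk-shaped k-space coverage
of a pixel-comb image otherwise biases wide-area gain by ~25%. Neither
affects phase differences.

Binning assigns each record to `floor(n_phases * (t - t_trig)/RR)` using its
channel timestamp; records outside complete RR intervals are discarded and
counted. Coils are combined with conjugate sensitivities. The cited in-vivo
reconstruction (iterative SENSE with adaptively thresholded local low-rank)
is replaced by this density-compensated adjoint plus an optional fixed-
fraction locally-low-rank stand-in: per 8×8 spatial block the
(64 × n_phases) Casorati matrix is soft-thresholded at a fixed fraction of
its largest singular value. Because the static anatomy dominates that
spectrum, useful fractions are small (~0.002–0.01) and the option is off by
default; the noiseless benchmarks do not use it.

Unwrapping: the high-venc channel unwraps the adjacent lower-venc channel by
integer wrap counts whenever their venc ratio is ≤ 4 (100 → 50); the lowest
venc (8 cm/s) channel is unwrapped with the single-step spectral Laplacian
(DCT/Neumann boundaries, zero-mean gauge, correction snapped to 2π
multiples). Background correction runs after unwrapping: a 2nd-order
polynomial is fitted (unweighted least squares) to the across-channel average
of the time-averaged velocity over a static-tissue mask and subtracted from
all phases of all channels.

The residual background phase is modeled in the scene as a 2nd-order field
scaled per encode by `M1_e / M1_max` — an eddy-current-like term that grows
with the encoding moment. This choice makes the background offset identical
across channels *in velocity units*, which is why a single shared fit
suffices; a moment-independent field would cancel entirely in phase
differences and leave the correction untestable.

Static-tissue selection uses four criteria on the lowest-venc channel:
magnitude above 0.3× the maximum and below 1.35× the median support
magnitude (blood is hyperintense from inflow, CSF hypointense), temporal
velocity std below 2× its support median, and |time-mean velocity| below 5×
its support median. The last criterion exists because steady venous flow is
invisible to a variance-only test.

## Phantom

The scene is an axial neck slice at C1/C2 on a 96² grid of 1 mm pixels
(9.6 cm sub-FOV; the full 22 cm / 0.68 mm geometry is configurable): disks
for ICA_L/R (r = 4 mm), VA_L/R (3 mm), IJV_L/R (5 mm) and a CSF annulus
SC (5–9 mm) around the cord, all inside a 44 mm tissue disk. Radii are
generous relative to anatomy so 1 mm pixels resolve each lumen; flows stay
physiological (per-ICA ≈ 220 mL/min, tCBF ≈ 615 mL/min, IJV outflow ≈ 405
mL/min total), so lumen velocities are correspondingly lower than in vivo.

Waveforms are stylized periodic templates: arterial = systolic-peaked
4-harmonic, venous = damped 2-harmonic, each parameterized by mean flow and
peak-to-peak amplitude; human waveform shapes are not printed anywhere usable
and the templates only aim at qualitative morphology. The SC CSF waveform is
not free: it is the negated, demeaned, lag-shifted net blood waveform
(tCBF − tJBF) scaled by a coupling factor (default 1), so
`deltaV_SC = coupling * deltaV_net` holds analytically and every marker has a
closed-form (dense-quadrature) truth. Note that `deltaV` scales with the
cardiac period: ground truths must be evaluated at the trigger stream's mean
RR, not at a nominal 1 s cycle.

Tissue contrast is SPGR steady state at the scheme's flip angle and TR with
T1 = 1000 ms (tissue), 1650 ms (blood), 4500 ms (CSF). Blood proton density
is set to 2× tissue as an inflow-enhancement surrogate — unsaturated inflowing
spins make lumina bright in vivo, and without this the SPGR equation alone
would make blood darker than tissue and defeat magnitude-based segmentation.
Trigger streams have i.i.d. Gaussian RR intervals (truncated at ±3 sd);
hr_sd = 0 gives perfectly periodic triggers.

What the phantom does **not** model: respiration, bulk or through-plane
motion, partial-volume cord tissue, smaller cervical venous channels,
off-resonance/T2* blur, eddy currents beyond the polynomial field, and
g-factor noise amplification. Passing benchmarks therefore demonstrate
correctness of the encoding/reconstruction/quantification chain, not in-vivo
performance.

## Quantification and statistics

Flow per phase is `Q = v̄ * A * 60` (cm/s · cm² · s/min → mL/min) over a
mask; markers are the temporal mean, range (max − min), and ΔV — the range of
the trapezoidal cumulative integral of the demeaned waveform over one
periodically closed cycle, in µL. At 30 phases the ΔV discretization error of
a sinusoid is < 1%.

Vessel segmentation thresholds the time-averaged magnitude at the 75th
percentile of the object support and labels connected components by nearest
expected anatomical position; the SC is segmented from the temporal velocity
std of the lowest-venc channel computed on a harmonic-filtered series (DC + 6
harmonics — cardiac waveforms are band-limited, the noise floor is white),
thresholded at 2× the bright-tissue median and morphologically closed. The
raw-std threshold of 3× was evaluated and misses the annulus rim at the
default SNR because partial-volume rim pixels hold only a fraction of the
CSF oscillation; the filtered 2× criterion recovers Dice ≈ 0.99 against
ground truth. Ground-truth masks can always be passed through as overrides.

Lags are estimated by cross-correlation of demeaned, 500-point linearly
interpolated waveforms — circular by default (the waveforms are periodic),
with the linear variant selectable; positive lag means the second waveform
trails the first, and CSF waveforms are inverted before comparison since CSF
flows opposite to arterial blood. Recovered lags are compared against the
same estimator applied to the analytic waveforms, which isolates pipeline
error from the morphology-dependent offset inherent to cross-correlating
waveforms of different shape.

Bland–Altman reports bias, 1.96·sd limits, and the repeatability coefficient
`RPC = 1.96 * sd(d/m) * 100` with the sample (n−1) standard deviation (the
population-sd variant is reported alongside). ICC is
`sigma²_participant / (sigma²_participant + sigma²_error)` with components
from a REML linear mixed model (statsmodels MixedLM: fixed scan-type and
heart-rate effects, random participant intercepts). No multiple-testing
correction is applied.

## Benchmark problem sizes and numerical choices

* End-to-end recovery: dual-venc, 1320 arms, 120 s, 96², 30 phases, single
  coil, noiseless, periodic 65 bpm triggers. All per-ROI markers recover
  within 5% of analytic truth and the SC–ICA lag within one interpolation
  step plus one temporal bin. Periodic triggers define this idealized
  benchmark; heart-rate variability is exercised separately (binning
  properties, the cohort below) because with irregular per-bin arm subsets
  the plain-gridding stand-in reconstruction — unlike the iterative low-rank
  original — retains azimuthal-gap aliasing jitter of a few percent.
* Noise law: pulseless scene, balanced encodes at venc 25/50/100 cm/s, 20 s,
  6 bins; static-region velocity sd vs venc/SNR fits with R² > 0.999.
* Coupling cohort: 10 scenes, amplitudes jittered ±30%, heart rates 55–80
  bpm with 3 bpm in-scan sd, default noise (image SNR ≈ 30), 60 s dual-venc
  runs; regression of reconstructed ΔV_SC on ΔV_net.
* ICC recovery: 100 synthetic participants × 3 scan types × 2 repeats with a
  9:1 between:within variance split; the cohort is sized so the χ² sampling
  error of the between-participant variance (sd(ICC) ≈ 0.015) does not
  dominate the check.
* Default noise `sigma = 1e-6` per complex k-space sample was calibrated once
  to give image SNR ≈ 30 at the desk reference protocol.
* The published multi-venc undersampling-factor table entry 0.50 differs from
  its own defining ratio 16/30 ≈ 0.53; the package computes and reports 0.53.

## Known limitations

The adjoint-gridding reconstruction under heavy per-bin undersampling leaves
structured aliasing that behaves like correlated noise in small ROIs; the
low-rank stand-in trades it against temporal attenuation rather than
removing it. TE/TR modeling is nominal. Segmentation location priors assume
the default scene layout (override masks bypass them). The exact NUDFT costs
O(samples × grid) and is intended for desk-scale grids, not 320² clinical
matrices.
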