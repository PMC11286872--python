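# Model and methods

`cortisim` simulates the perceptual consequences of electrically stimulating
human primary visual cortex (V1): given an electrode's geometry and cortical
position and a biphasic pulse train, it predicts the phosphene a patient
would report — its location, size, shape, brightness, and detection
threshold — and provides the electrode-array design math built on the same
model.  The model is deliberately simple and almost entirely constrained by
the neurophysiological literature; a single per-electrode sensitivity scale
`s` is the only free parameter intended to vary between electrodes.

## Temporal cascade

A pulse train `p(t)` (amplitude in uA, phase width in ms, rate in Hz,
duration in s, cathodic- or anodic-first) is converted to perceived
brightness in four stages.

1. **Fast leaky integration.**  `dR1/dt = p(t) - R1/tau1` with
   `tau1 = 0.3 ms`, representing cellular integration of current.  The
   solver uses exponential stepping, which is exact for the sampled
   piecewise-constant waveform; phase boundaries are apportioned to samples
   by sub-sample overlap so the rasterised waveform is exactly charge
   balanced at any pulse width.  Default sampling step 0.01 ms (guarded to
   at most pulse_width/10).

2. **Spike-strength extraction and refractoriness.**  One spiking event per
   pulse, placed analytically at the offset of the positive phase (second
   phase for cathodic-first trains, first for anodic-first), with strength
   `max(R1, 0)` evaluated from the per-phase closed form rather than by
   peak-picking, so event strengths are independent of the sampling step.
   Each event is attenuated by the refractory factor
   `1 - exp(-tau_r (Delta_i + delta))` where `Delta_i` is the inter-event
   interval, `tau_r = 50 s^-1` and `delta = 1 ms`.  At 50 Hz the factor is
   0.6501.  The first event of a train has no predecessor and is
   unattenuated.  (The literature prints `tau_r` variously as 100 and as
   "50 ms"; only a *rate* of 50 s^-1 with a 1 ms offset reproduces the
   0.6501 worked value, so that is the default, and both constants are
   configurable.)

3. **Slow integration.**  The event train is convolved with the impulse
   response of an n-stage leaky integrator, a gamma density
   `G(t) = (t/tau2)^(n-1) exp(-t/tau2) / (tau2 (n-1)!)` with
   `tau2 = 150 ms`, `n = 3` (an alternative published value of 25 ms is
   exposed in the same config; the 150 ms value is stated jointly with the
   kernel definition and is the default).  G is normalised as a unit-mass
   density over *seconds* while event strengths carry uA*ms; this
   normalisation anchors the response scale so that a detection-threshold
   stimulus maps to a compressed brightness near 1, the "dimmest visible"
   anchor of the 0-10 rating scale (with a per-millisecond density the
   drawing threshold `theta_draw = 1` would be unreachable at clinically
   plausible currents).  R2 is evaluated on a 1 ms grid (guarded to
   tau2/20); halving either time step changes the calibrated threshold
   constant by well under 1%.

4. **Compression.**  `brightness(t) = s_out * tanh(s * R2 / p)` with
   `s_out = 10` (the top of the rating scale), `p = 15.6`, and `s` the
   electrode sensitivity (default 0.57).  Everything before this stage is
   linear in amplitude, so the pre-compression response is homogeneous of
   degree 1 in current — the key structural fact behind thresholds and
   separability.

**Thresholds.**  The detection threshold constant `theta_thresh` is defined
operationally from a "standard" electrode: one whose threshold is 3 uA for
a 50 Hz cathodic-first train of 0.25 ms phases lasting 0.5 s, at
sensitivity `s = 0.43`.  `calibrate_theta_thresh()` computes the
max-over-time pre-compression response of that stimulus; `find_threshold`
then solves `s * A * max_R2_unit >= theta_thresh` for the amplitude.
Because of pre-compression linearity the solve is exact (the default
"linear" method); a conventional bisection over full simulations
(`method="bisect"`) is provided and agrees to its tolerance.  The exact
path is what makes threshold surfaces over (pulse width x frequency) for
electrodes differing only in `s` rank-1 to near machine precision.
Thresholds are compared on the pre-compression scale; in the small-signal
regime near threshold the compressed comparison is equivalent.  Searches
cap at 10 mA (a typical device safety bound) and return a not-found
sentinel beyond it.

## Retinotopy

Visual space (complex z, degrees) maps to the flattened cortex (complex w,
mm) by the log-polar conformal template `w = k log(z + a)` with `a = 0.5
deg`, `k = 15 mm`, and an optional cortical-y anisotropy `squish`
(default 1).  The inverse is `z = exp(w/k) - a`; linear cortical
magnification along the horizontal meridian is `k/(ecc + a)` mm/deg
(30 mm/deg at the fovea).  A second preset (`beauchamp2020`: a = 0.15,
k = 16.6, squish = 0.63) ships for the published 24-electrode surface-grid
geometry; it is a fixed preset, not re-fit.  One map instance covers one
hemifield; the left field is handled by mirroring.

## Cortical property maps

Orientation, ocular-dominance (OD) and on/off-subunit maps are synthesised
from a single seeded complex white-noise field, bandpass filtered with an
isotropic radial Gabor `F(r) = exp(-r^2/2 sigma_F^2) cos(omega r) / (2 pi
sigma_F^2)` (mean-subtracted so the filter has zero DC gain):

- **Orientation** is half the angle of the filtered field, mapped into the
  pi-periodic range (-pi/2, pi/2] — the angle of a complex field is
  2pi-periodic while orientation is pi-periodic, and halving preserves
  pinwheel topology.
- **Ocular dominance** is the normal CDF of the z-scored x-derivative of
  the field's real part, giving balanced values in [0, 1] with stripe-like
  columns.
- **On/off maps** come from the same noise filtered at twice the radial
  frequency: the (uniform) angle `u` of that field becomes the signed
  subunit separation `delta = A_rf sign(u) (-log|u/pi|)/2`, exponentially
  distributed with rate 2 relative to the RF ellipse area
  `A_rf = pi sigma_rf (sigma_rf/4)`; its x-gradient through the normal CDF
  gives the on/off balance `w_onoff`.

The filter is parameterised by the mean OD column period (default
0.863 mm).  Because the gradient step weights the filter's spectral ring by
kx^2, the radially averaged power peak of the finished OD map sits ~15%
above the ring frequency; the generator therefore solves analytically (a
deterministic computation on the filter spectrum and discrete-gradient
transfer, no noise involved) for the ring frequency whose predicted OD
power peak lies at the requested period.  Generated maps measure
0.85-0.88 mm across seeds.  The envelope scale defaults to
`sigma_F = 0.5 mm` (the tabulated filter scale; the accompanying prose
gives the filter width in frequency units that do not parse as an envelope
length, so the tabulated millimetre value is used).

Noise is drawn in the frequency domain ring-by-ring (modes ordered by
max(|jx|, |jy|)), so regenerating a sheet with the same seed at a finer
grid spacing assigns identical coefficients to the shared low-frequency
modes: refinement preserves the large-scale map structure (correlation
> 0.98 between shared grid points at halved spacing).

A known limitation: the construction does *not* reproduce the
optical-imaging statistic that OD borders cross iso-orientation contours
orthogonally.  Measured over whole maps, at OD borders, and at
high-gradient pixels, the angle between the OD and orientation gradients is
at chance (~45 deg); locally the filtered field behaves like a plane wave,
which makes the two gradients tend weakly parallel rather than orthogonal.
The package does not claim or test orthogonality.

Receptive-field size grows linearly with eccentricity:
`sigma_rf = 0.16 + 0.08 ecc` deg (long axis; short axis `sigma_rf/4`),
the smallest published single-study electrophysiological estimate.  An
alternative `"meta"` preset (0.25 + 0.115 ecc) represents the larger
meta-analytic estimates and is strictly larger at every eccentricity.

## Receptive fields and percept rendering

Each cortical location contributes a two-subunit receptive field: ON and
OFF anisotropic Gaussians (axes `sigma_rf` and `sigma_rf/4`, both oriented
at the local preferred orientation), displaced `+/- delta/2` along the
short axis, each analytically normalised to unit mass (per-subunit
normalisation is our reading of "normalized by area"; per-cell
normalisation would differ only by a bounded factor).  Only excitatory
subunit components are modeled.  The rendered percept is the
current-weighted linear sum

    R_sp(x) = sum_i I_i eye_i [ w_onoff,i ON_i - 0.8 (1 - w_onoff,i) OFF_i ]

so OFF subunits contribute *negative* (darker-than-background) intensity
with relative weight `omega = 0.8`; suprathreshold percepts stay net
bright while near-threshold percepts can contain dark regions.  Eye
weighting uses the OD map (`left` = w_od, `right` = 1 - w_od, default
`both` = 1).

Because every stage before compression is linear, space and time factor
exactly: a movie frame is `compress(R_sp(x) * drive(t))` with `drive` the
slow-stage response of the train at unit amplitude.  This separable
implementation is an exact restructuring, not an approximation.
Multi-electrode schedules superpose their per-electrode spatiotemporal
drives *before* compression (the model contains no electric-field or
nonlinear neural interactions).

The rendering grid covers all stimulated receptive fields to >= 3 sigma
(subunit offsets included) at spacing `min(0.02 deg, sigma_rf_min/5)` by
default; a grid coarser than `sigma_rf_min/4` is rejected.  Locations
receiving less than 1% of the peak current are skipped (the 675 mm^-2
current-distance constant makes their contribution negligible).

**Quantification.**  Two size metrics mirror the two experimental
traditions: (a) a moment-based best-fit ellipse of the binarised percept
(`|intensity| >= theta_draw = 1`, dark regions counting toward the drawn
shape), reporting area, axis diameters (4 sqrt(eigenvalue) of the
second-central-moment matrix, i.e. the equivalent solid ellipse),
orientation, and mean diameter; an all-subthreshold frame yields an empty
sentinel, not an exception; and (b) a threshold-free isotropic 2-D
Gaussian least-squares fit (sigma), robust for the irregular percepts of
very small electrodes.

## Electrodes and arrays

Current spread follows the current-distance relation with a plateau over
the electrode footprint: `I = I_in` for `rad <= rad_e`, else
`I = I_in / (1 + K (rad - rad_e)^2)` with distance to the nearest point of
the circular footprint.  `K = 675` for surface electrodes and `1e5` for
depth electrodes (modeled as surface points with near-point spread — the
only depth modification).  K carries the literature's printed uA/mm^2
units but functions as mm^-2.  Edge current pooling on large electrodes is
not modeled; the disk is uniform.

**Optimal sampling.**  With phosphene size `sigma(x) = m x + b` deg and
magnification `k/(x+a)`, the cortical spacing that keeps phosphene
separation a constant proportion of phosphene size is the first-order
form `rho(x) = (m x + b) k/(x + a)`: 4.8 mm at the fovea (k b / a),
1.3 mm at 20 deg, asymptoting to `k m = 1.2 mm`.  The first-order form
agrees with the exact spacing `y(x + sigma/2) - y(x - sigma/2)` to within
10% for ecc >= 1 deg.  (The companion closed form printed for 1 deg
evaluates to ~3.2 mm with the stated parameters, not the published
2.2 mm; the package implements the first-order form and leaves the 1 deg
figure unreproduced.)  Array generators support regular-in-visual-space,
regular-on-cortex, and optimal layouts, bisecting a global density scale
to hit a target electrode count within 15%.

## Psychophysics drivers

`run_strength_duration` produces threshold curves over pulse width and
frequency; the pulse-width curve's shape is set entirely by the fast
stage and is identical across electrodes up to 1/s.  Charge per phase at
threshold is minimised near `pw = 1.256 tau1 ~ 0.38 ms` and then rises
(~25% per doubling), so lengthening pulses beyond ~0.4 ms buys no charge
efficiency; likewise the relative amplitude saving per frequency doubling
decays with frequency, leaving little efficiency benefit above ~64 Hz.
Note these are statements about the *minimum* and about *diminishing
returns*, not about the charge curve flattening.

`fit_sensitivity` recovers per-electrode `s` from measured thresholds by
linear-space least squares through the origin on predicted-vs-measured
thresholds (predictions scale as 1/s); a log-space option averages log
ratios.  `run_size_experiments`/`simulate_phosphene` build a local
cortical patch per configuration (extent `max(6 rad_e + 3, 4)` mm; grid
0.1 mm, refined to 0.05 mm for electrodes under 0.5 mm radius so the
stimulated population is sampled finely enough), drive it at a multiple of
its spatial detection threshold, and tabulate both size metrics.
Phosphene sizes for sub-0.5 mm electrodes vary substantially across map
seeds — the "complicated structure" regime — so radius comparisons are
made on seed-averaged sizes (8 seeds by default in the tests).

## Synthetic data and what the tests show

All test inputs are generated programmatically: pulse trains and electrode
specs from their parametric definitions, cortical sheets from seeded
noise, and threshold tables by running the forward model at a known
sensitivity (optionally with lognormal noise).  The generators emulate the
study conditions — standard-train calibration at 3 uA / s = 0.43, 0.25 mm
surface electrodes for eccentricity series, the 0.1-2 mm radius sweep at
5 deg, 10% lognormal threshold noise for recovery.  They do not emulate
patient response variability, electrode-surface nonidealities (tilt, edge
pooling), long-timescale desensitisation, or anatomical deviations from
the template map; passing tests therefore validate the model's internal
structure and its published anchor values, not fit quality to any
individual patient.

## Problem sizes

The shipped experiments are sized for a single CPU: map-statistics patches
of 24 x 24 mm at 0.1 mm spacing (5-8 seeds), percept patches of 4-15 mm at
0.05-0.1 mm, rendering grids of order 100-300 pixels per side, threshold
matrices of 4 x 4 stimulus conditions, and 20-replicate recovery
simulations.  All scale up by parameter without code changes.

## Known limitations

- No desensitisation over seconds-to-minutes; predictions do not
  generalise to prolonged stimulation protocols.
- No electric-field or nonlinear neuronal interactions between electrodes.
- Template retinotopy only (no subject anatomy), V1 only.
- The OD/orientation orthogonality statistic is not reproduced (above).
- Anodic-first trains reuse the positive-phase-offset convention; the
  known anodic/cathodic threshold asymmetry is not modeled.
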