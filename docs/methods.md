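# Methods

This note documents the models, the synthetic data, and the numerical
choices in `rgctwin`, in the spirit of a model-description appendix.

## The encoding model

The digital twin is a core+readout architecture. The shared core is a
two-layer CNN: sixteen 2×11×11×21 kernels (channels × height × width ×
frames) applied as valid convolution in space and time, then sixteen
16×5×5×11 kernels zero-padded in space, each layer followed by batch
normalisation and an ELU. Every 3D kernel is space-time separable by
construction — a spatial map times a temporal vector — so the stored
parameters are spatial maps plus temporal coefficients.

Temporal kernels are truncated Fourier series on an evenly spaced unit
grid: k = 7 sine/cosine pairs for the 21-tap first layer and k = 3 for the
11-tap second layer (k = length/3, keeping the kernels well under the
Nyquist limit). A single learnable stretch factor τ per recording rescales
the grid, masked by a logistic envelope ε(τ) = 1/(1 + exp(−(t + 21·0.95·τ)))
so that stretching does not add cycles:

w = Σ_j α_j sin(2π·j·τ·t·ε) + β_j cos(2π·j·τ·t·ε).

Two remarks on this parameterisation. First, the harmonic index j
multiplies the phase ("the first k sines and cosines"); a switch
(`harmonics=False`) recovers the degenerate single-frequency form. Second,
the printed envelope evaluates to ≈1 for τ near 1 and is almost certainly
a typographical slip in its source; we implement it verbatim with the
constants configurable, and note that with ε ≈ 1 it is simply inert.

The per-neuron readout is an isotropic 2D Gaussian mask N(μx, μy; σ) over
the core feature map (coordinates in pixels, origin at the canvas centre),
a 16-vector of feature weights, a bias and a softplus. The LN variant is
the identical architecture with both ELUs replaced by the identity, making
everything before the softplus affine.

All convolutions are "valid in time": a prediction at index t depends on
input frames t…t+30 and is aligned with the last frame of its receptive
window. Forward and backward passes are hand-written numpy; the test suite
checks every parameter gradient and the input gradient against central
finite differences.

## Training

Poisson loss Σ(r̂ − r·log r̂), Adam at initial learning rate 0.01, batches
of 32 chunks of 50 frames, early stopping (patience 5) on validation
correlation, four restore-and-decay cycles with decay factor 0.3,
15 validation clips out of 108 training clips, and a 5-member ensemble
whose prediction is the arithmetic member mean. Those are the defaults;
the desk-scale schedule used in the tests and the acceptance script is
two cycles of up to 12 epochs, batch 16, 5 validation clips, and 1–2
members, which trains in minutes on one CPU.

Two additions make the readout parameters identifiable at this scale:

* position-like parameters get larger Adam steps (μ ×20, log σ ×5) —
  Adam's per-coordinate normalisation otherwise caps μ movement at
  ~lr pixels per step, so readout centres could never travel the few
  pixels from their random initialisation to the true RF within a short
  schedule;
* a radial weight decay on the spatial kernels (strength 0.05 at desk
  scale) pulls each kernel's energy toward its own centre, resolving the
  translation ambiguity between core kernels and readout locations.

With these, on a noiseless homogeneous-polarity LN population (ON and
slow-ON cells) and a 40-clip movie, the fitted readout centres land within
1 px of the generator's RF locations. Mixed-polarity populations at very
small cell counts localise less precisely (the core's few features
specialise for the majority polarity); this is a data-scale effect, not a
model defect.

## The synthetic data generator

The generator defines the study conditions; its defaults are fixed.

**Movie.** 113 clips × 150 frames at 30 Hz (5 clips form the test
sequence, recorded three times), 18×16 px, two channels. Per-clip mean
intensities are drawn uniformly within [0.04, 0.22]; the label's dominant
channel (UV for sky, green for ground) draws from the upper half of that
range and the other channel from the lower half, so ground-to-sky
transitions always have positive UV and negative green contrast. Texture
is Gaussian noise smoothed with σ = (0.8, 2, 2) (frames, rows, cols) at
amplitude 0.04. The mild temporal smoothing is deliberate: a strongly
low-passed movie leaves the trained model unconstrained at high temporal
frequencies, and MEI ascent will exploit that freedom with adversarial
~10 Hz oscillations that the true cells barely see. Real camera footage
differs from this texture in having 1/f spatial structure, occlusions and
self-motion; none of the downstream analyses depend on those properties,
only on clip structure, intensity range and the sky/ground chromatic
separation. Passing tests therefore demonstrate correctness of the
analysis chain, not realism of natural-scene statistics.

**Cells.** Each cell is a linear-nonlinear unit: unit-L2 Gaussian spatial
filter per channel (SD 1.6–2.4 px, centres ≥6 px from the border so every
RF lies strictly inside the model readout's field of view), unit-L2
biphasic temporal kernel (fast and slow lobes with 85% of the fast lobe's
area cancelled on the discrete grid, giving transient, band-pass kernels
peaking near 1–1.5 Hz), signed chromatic weights jittered around ±1, a
fixed drive normalisation (÷6, giving ~unit-SD drives under the default
movie), and rate = 4·softplus(z + baseline) Hz. OFF cells get a higher
baseline (maintained discharge suppressed by increments). The ON-OFF
family full-wave rectifies its drive.

The opponent-SbC family is nonlinearly colour-opponent through
multiplicative gating, the circuit motif of presynaptic inhibition:

z = w_uv · s_uv · 2σ(g·w_g·s_g),  w_g < 0 < w_uv, gate gain g = 1.5.

Green decrements double the gain of the UV pathway, green increments
silence it, and — because green contrast enters only through a cross-term
with the zero-mean UV drive — a purely linear fit sees no first-order
green component at movie contrasts. This is the property that makes the
CNN-vs-LN comparison meaningful: subtractive opponency with any odd
rectifier leaves a first-order green term that a linear fit recovers
exactly on clean data, while thresholded (rare-event) opponency starves
any model of training signal at desk scale.

**Recording.** Rates are convolved with a unit-sum exponential calcium
kernel (decay 1 s), sampled at 7.8125 Hz, and corrupted with sinusoidal
drift (amplitude 0.2, period 120 s, random phase) and white noise
(SD 0.3 — repeat-to-repeat correlations of 0.5–0.7 and quality indices of
0.67–0.92, the upper range of real two-photon data, chosen so desk-scale
training stays signal-dominated). A 30 s pre-stimulus baseline precedes
the movie; the test sequence is re-recorded three times with independent
noise.

## Preprocessing

Detrending follows the standard recipe: subtract a third-order
Savitzky–Golay smooth (60 s window), clip below the 2.5th percentile,
subtract that percentile, divide by the SD of the pre-stimulus segment
(the full pre-stimulus window; it may overlap the smoothing filter's
support, which is harmless for drift-free baselines). Rate inference
inverts the exponential kernel in closed form (AR(1) differencing with a
non-negativity clip); since differencing amplifies measurement noise
~tenfold at this sampling rate, a 0.2 s Gaussian smoother is applied
before linear-interpolation resampling to 30 Hz. A ground-truth
passthrough mode exists for pipeline tests. The synthetic recording has no
chirp or moving-bar presentations, so the repeated test sequence stands in
for both in the quality indices, and type labels come from the generator
with confidence 1.

## MEIs

Synthesis maximises the model neuron's time-averaged response over frames
30–50 by plain gradient ascent (learning rate 10) on the ensemble mean,
with the neuron's readout moved to the canvas centre and batch-norm
statistics frozen. After every step the tensor is rescaled to the L2
budget b = 30 jointly over channels, then clipped per channel to the range
of the standardised training movie (rescale before clip guarantees range
feasibility; the norm may then sit slightly below b). Convergence: 10
consecutive iterations with activation change below 0.001, never before
100 iterations, cap 1000.

Characterisation: per-channel SVD of the [50 × 288] flattening; the sign
convention makes the spatial component positive at the canvas centre. The
concentric anisotropic DoG fit uses `scipy.optimize.least_squares` with
soft-L1 loss, seeded by whichever of the spatial extrema lies closer to
the centre and a single-Gaussian pre-fit, with a small multi-start over
surround initialisations; orientations are wrapped into (−π/2, π/2] and
reported with σx ≤ σy (the rotated-Gaussian cross term uses the standard
sin2θ(1/(4σy²) − 1/(4σx²)) form, and σ² appears in the exponents). Centre
size is (σx + σy)·50 μm/px (the scale approximates a ~30° crop across 18
px at ~31 μm/°, and is configurable). The centre mask is the convex hull
of the level set through (μx+σx, μy+σy). Temporal frequency is the
power-weighted mean frequency after a fifth-order 10 Hz Butterworth
low-pass.

Chromatic contrast γ per channel is the mask-mean difference between two
time points t1 < t2: the last two extrema of the **absolute** UV temporal
component (on oscillatory components, raw-signal maxima come in same-sign
pairs whose difference is numerical noise; the |·| extrema give the final
trough/peak pair). The same t1, t2 serve both channels. The opponency flag
requires opposite signs and each |γ| to exceed 10% of the larger one, so a
near-zero channel cannot flip the flag by noise.

## Chromatic tuning maps

The 2-D subspace is spanned by e1 (the green rank-1 component,
sign-flipped, zeros in UV) and e2 (the UV component, zeros in green),
scaled so both channel parts have equal L2 norm while the whole-stimulus
norm is preserved — concretely s1 = N/(√2·n_g), s2 = N/(√2·n_uv) with N
the MEI norm. The point (−1, 1) then reproduces the contrast-scaled MEI.
Responses and input gradients (projected onto e1, e2 by orthogonal
projection; the supports are disjoint) are evaluated on an 11×11 grid in
[−1, 1]². Because e1 carries the *negated* green component, basis
coordinates map to physical chromatic contrast as (−a·γ_green^MEI,
b·γ_UV^MEI); that conversion places an opponent cell's optimum in the
green-negative/UV-positive quadrant and a non-opponent ON cell's on the
green-positive side, although both sit at (−1, 1) in basis coordinates.

## Detection analysis

Movie transition events are adjacent clip pairs; their chromatic contrast
is the post-minus-pre mean full-field luminance over 1 s windows (a
Michelson variant is available). The transition response is the
baseline-subtracted mean rate over the 30 frames after the boundary. ROC
curves sweep 40 equally spaced thresholds over the cell's full response
range (both classes), with (0,0) and (1,1) appended and trapezoidal AUC;
at the event counts of this analysis the AUC matches the exact pairwise
probability to well under 0.02.

The moving-window simulator slides a 72×64 crop along a square trajectory
with 220 px edges (90.6° of visual angle) over a static horizon-bisected
scene, at 4/12/20/28 px per frame (50–350 °/s), block-averages each crop
to 18×16, and pads to 60 frames by duplicating the first and last frames.
Vertical edges cross the horizon (context changes; upward motion is
ground-to-sky), horizontal edges stay within one region. Responses are
anchored at the mid-edge frame — the moment the window crosses the horizon
— so all velocities are scored on the second containing the potential
context change.

## Statistics

The permutation test uses |mean difference|, 100,000 label shuffles
(groups of ≥4 by default), and the proportion of shuffled statistics
strictly larger than the observed one; shuffled statistics numerically
equal to the observed value count as ties, an observed statistic of
exactly 0 reports p = 1, and the finite-sample-safe (k+1)/(n+1) variant is
always reported alongside. Bootstrap CIs are percentile intervals from 100
resamples (configurable; 100 keeps fidelity with the protocol but is
noisy). Cohen's d uses the pooled SD. Under the null, the permutation
test's type-I error at α = 0.05 calibrates to 5% ± 1% over 2000
simulations.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale: 40-clip
movies (60 for detection), 8–25 cells, two 12-epoch cycles at batch 16,
1–2 ensemble members, and MEI synthesis capped at 1000 iterations (it
typically converges within 100–250). These sizes are the package's own
defaults for self-verification; the full-scale configuration (113 clips,
5 members, four cycles) is available through the same interfaces.

## Known limitations

* The generator's texture is band-limited Gaussian noise, not natural
  scenes; spatial-frequency-dependent analyses would need a richer movie.
* The deconvolution stand-in assumes the (known) exponential kernel;
  model-based spike inference is out of scope.
* With heavy trace noise and few clips, CNN and LN fits both degrade and
  the opponency contrast loses power; the default noise level keeps the
  desk-scale regime signal-dominated.
* Readout-location recovery at 1 px precision is demonstrated on
  homogeneous-polarity LN populations; small mixed populations localise
  minority-polarity cells less precisely.
* The per-recording stretch τ is exercised with a single recording in the
  tests; multi-recording fits share the core but have not been profiled.
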