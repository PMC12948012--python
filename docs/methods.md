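# Methods

## Physical model

Scanning modulated-pattern imaging records two stacks of N frames each: a
*reference* stack of the modulator pattern (coded mask, checkerboard
grating, or sandpaper) scanned across N positions without a sample, and a
*sample* stack with the sample in the beam. A thin sample with complex
transmission acts on each frame through three channels:

    I_s(x, y, i) = T(x, y) · [ (1 − D) · I_r(x + δx, y + δy, i)
                               + D · Ī_r(x + δx, y + δy, i) ]

* `T` — transmission (absorption channel), unitless in (0, 1];
* `D` — dark-field, the damping of the local pattern contrast by
  unresolved small-angle scattering, in [0, 1] (`D = 0`: full contrast,
  `D = 1`: contrast fully washed out toward the local average `Ī_r`);
* `(δx, δy)` — pattern displacement in detector pixels caused by
  refraction: α = (λ/2π)∇φ and δ[px] = d·α/p for propagation distance `d`
  and pixel size `p`.

`Ī_r` is the locally averaged reference, realized as a Gaussian blur with
σ = 2 × (modulator pitch in pixels) — the window is not pinned down by the
physics beyond "larger than one speckle grain", and this choice makes the
dark-field channel act purely on the speckle modulation around its local
envelope. The alternative convention with `D` multiplying the contrast
term directly is available as a switch.

Coordinates: images are `[row, col] = [y, x]`, origin top-left; positive
`(dx, dy)` means the sample frame samples the reference at
`(x + dx, y + dy)`. `OpticsConfig` owns every unit conversion.

## Forward simulation

The modulator is rasterized from its cell description with 4× area
supersampling (5 µm cells on a 0.65 µm grid are ~7.69 px, so cells and
pixels never align). Reference frames translate the complex transmission
by each scan offset with a Fourier phase ramp and propagate it to the
detector with the angular-spectrum transfer function
H = exp(−iπλd(f_x²+f_y²)); the central detector region is cropped so that
periodic wrap-around from the Fourier shift never enters. A sampling
guard enforces d ≤ N·p²/λ per axis and names the offending parameter.

Fourier shifting is exact for the *uniform* per-frame scan offsets. The
sample-induced displacement varies per pixel, so `apply_sample` resamples
each frame at `(x + δx, y + δy)` with a cubic spline instead; spline
overshoot is clipped at zero intensity. The algebraic form
`T·[(1−D)·I + D·Ī]` is used verbatim because it is bit-exact for a vacuum
phantom (T=1, D=0 reduces to `1.0·I + 0.0`), which the test suite relies
on. Poisson noise (expected photons per pixel) is applied last and is off
by default.

Scan trajectories: diagonal scans step by `i·step·(1,1)` with uniform
jitter of ±0.5·step per axis; XY grids build positions from cumulative
Gaussian steps (mean `step`, configurable σ, default 0.1·step).

## Phantoms

Random phantoms follow a three-step recipe: (1) a closed smooth outline —
quadratic Bézier segments through the midpoints of a random star-shaped
control polygon, scan-filled; (2) white noise Gaussian-filtered with a
per-phantom smoothing length σ and rescaled to an exact peak-to-peak
amplitude drawn from the configured range; (3) maps assembled as
φ = field·w, T = 1 − field·w, D = field·w, where `w` is a support window
built from the Euclidean distance to the outline:
w = 1 − exp(−d²/2σ_e²). The window is exactly zero outside the outline
(the vacuum contract is exact) and rises over ~3σ_e inside, so one
resolution scale governs both the interior structure and the support
edge and the displacement field remains bandlimited. Default full-scale
ranges: φ peak in [0, 10π] rad, T and D deviations in [0.02, 0.2],
smoothing σ in [1, 31] px. The transmission range is read as a *deviation
from vacuum* (T spans [0.8, 0.98] at the extremes); the literal reading
(T itself in [0.02, 0.2], strongly absorbing samples) is available via
`literal_transmission=True`.

The analytic lens phantom is a parabolic refractive element:
φ(r) = −(2π/λ)·δ·r²/R with apex radius R (200 µm reference), material
thickness t = r²/R feeding `T = exp(−µt)`, `D ≡ 0`, and a smoothed
aperture edge.

## Classical tracking (XSVT)

For every pixel, the intensity vector across the scan dimension of the
sample stack is compared with reference vectors at all integer offsets in
a search window via zero-normalized cross-correlation; `N_w > 0` pools a
surrounding window of vectors for robustness at small N. Sub-pixel
refinement is *not* the textbook 3-point parabola by default: on speckle
from a propagated coded mask the correlation peak is tent-shaped (the
autocorrelation decays near-linearly), and a parabolic fit is biased by
~0.3 px. The default `subpixel="gradient"` instead solves, per pixel and
iteration, the linearized warp model

    v_s ≈ a · I_r(x + δ) + c

for (δx, δy, a, c) over the scan dimension, re-warping the reference and
its spectral gradients each iteration (4 by default). The gain `a` and
offset `c` absorb transmission and dark-field exactly as they enter the
forward model. The integer peak field is median-filtered (3×3) before
refinement to remove isolated wrong peaks — displacement fields are
smooth at detector resolution. Measured on a uniform 1.4/−0.6 px shift at
N = 20 this reaches 0.044 px RMS versus ~0.3 px for the parabola.
Pixels whose peak correlation falls below a threshold, whose search
window leaves the frame, or whose refinement runs away from its integer
peak are flagged invalid and filled from the nearest valid neighbour
before integration (mask retained).

Transmission and dark-field follow from warped-stack statistics:
T = mean_i(I_s)/mean_i(Ĩ_r) and D = 1 − CoV(I_s)/CoV(Ĩ_r), clipped to
[0, 1].

## Phase integration

Displacements convert to refraction angles (α = δ·p/d) and then to
per-pixel phase gradients (g = (2π/λ)·α·p), which Frankot–Chellappa
integrates in the Fourier domain: Φ = −i(k_x G_x + k_y G_y)/(k_x²+k_y²),
zero-frequency set to zero (phase is defined up to a constant; the output
mean is exactly zero). Mirror (even) extension by one image per side is
the default boundary treatment; `padding="none"` assumes periodicity.
The default `kernel="central"` replaces k by sin(k), the transfer
function of the central-difference operator, so integration exactly
inverts the package's gradient convention (round trips on bandlimited
periodic fields close to machine precision); `kernel="spectral"` is the
classical continuous form. Pure Nyquist modes lie in the null space of
the central kernel and are dropped — irrelevant for bandlimited fields.

## Network

The retrieval network is a multi-resolution cost-volume architecture.
A shared convolutional encoder (per level: stride-2 conv block then
stride-1 conv block, each Conv3×3 → BatchNorm → LeakyReLU) turns both
scan stacks into L-level feature pyramids; at full scale the input is
512×512×20 with level-1 width 32 growing to a 16×16×196 deepest volume
over L = 5 levels. From the coarsest level downward, reference features
are warped by the upsampled flow from the previous level (zero at the
coarsest), a local correlation cost volume over a (2n_w+1)² offset window
(n_w = 3 → 49 channels) is built, and a per-level estimator (PhaseNet:
stride-1 conv blocks plus a 1×1 output conv, 2 channels) predicts the
flow at that level in that level's pixel units. Learnable upsampling is
nearest-neighbour ×2 → replicate pad → Conv3×3, with flow values
additionally rescaled by 2. TNet and DNet (1 output channel each) consume
the scan-axis mean and standard deviation of the warped reference and
sample stacks plus the final flow; refiners (PhaseRefiner/TRefiner/
DRefiner) add residual corrections at full resolution. Both stacks are
divided by the *reference* global mean before the network — flux
invariance without destroying the absolute transmission scale.

Stacks with N ≠ N_net frames are adjusted by the data-scaling step:
N ≥ N_net takes the first N_net raw frames (sub-sampling would change the
effective scan step); N < N_net interpolates along the scan axis
(nearest, the default, repeats frames in order; linear, bilinear and
cubic-spline variants are provided for the comparison harness).

Two additions make the architecture trainable in the reduced CPU-scale
configuration (both are config switches, on by default):

* **Exact correlation** (`normalize_cost`): features are zero-mean,
  unit-norm normalized along the channel axis before the cost volume, so
  the channel-mean product is exactly the local ZNCC in [−1, 1]. The
  unnormalized product is only a correlation for zero-biased features; at
  short training schedules the estimators never recover from the
  uncalibrated scales.
* **Correlation-peak prior** (`cost_peak_prior`): a classical sub-pixel
  peak readout (argmax + 3-point parabola over a doubled search window,
  3×3 median, two Gauss-Newton iterations) is computed once per pair from
  the raw normalized stacks, outside the autodiff graph. Its pooled
  version and peak-correlation confidence map join every estimator's
  input, and per-level flows are residuals on the pooled prior, with
  zero-initialized output convolutions — the untrained network therefore
  starts exactly at the classical solution and learns corrections
  (denoising, inpainting of low-confidence regions, T/D regression).
  Measured on held-out desk scenes the trained network improves the flow
  RMSE over this starting point and learns T and D essentially from
  scratch (MAE 0.44/0.19 → below 0.01).

Inference is deterministic: normalization layers use running statistics,
there is no dropout, and the same input pair always produces the same
output.

The tensor backend is a compact reverse-mode autodiff engine on numpy
(im2col + BLAS matmul convolutions with hand-written adjoints, batchnorm,
bilinear warping, cost volume, replicate padding, nearest upsampling,
MAE losses). Bilinear warping propagates gradients to the features only;
each level's flow has direct supervision, so the flow path still trains,
and the T/D losses reach the flow through concatenation channels.

## Training

Loss: L = |δx−δx_gt| + |δy−δy_gt| + β₁|T−T_gt| + β₂|D−D_gt| with
mean-absolute-error norms and β₁ = β₂ = 10. During the staged schedule
every active pyramid level contributes a flow term against average-pooled
(and value-rescaled) ground truth; each level's term is rescaled by
2^level into full-resolution pixel units so coarse supervision is not
drowned by the β-weighted terms.

Staged schedule (coarse → fine, refiners last): stage i stops the pyramid
at a progressively finer level with no refiners; the final stage runs the
full network. The full-scale configuration uses stage epochs
200/500/800 then 1500 with batch sizes 128/72/64/64 and Adam at 1e-4.
The desk configuration — the configuration actually exercised by the test
suite — uses 300 scenes of 64×64 px with 5 scans, stage epochs (2, 2, 4)
plus 6 final epochs at batch 8 and Adam at 1e-3 (learning rate scaled up
for the ~500-step schedule). A NaN loss aborts training and restores the
last epoch-end state. After training, batch-norm running statistics are
recomputed exactly (one cumulative-average pass over the training set) so
that inference mode matches training mode; with momentum-based running
averages alone, the short schedule leaves the statistics lagging the
weights. Earlier-level weights stay trainable in later stages (a freeze
flag exists). Datasets split 80/20 by index; per-scene seeds are drawn
from one master generator, so train and validation seeds are disjoint.

### Desk generator conditions

Scenes are 64×64 px at 0.65 µm with a 5 µm coded mask, 14 keV, d = 0.5 m,
five diagonal scan steps of 3 µm with ±0.5-step uniform jitter — the
full-scale study conditions with only the frame count, scan number and
phantom amplitudes reduced. Phase peaks are drawn from [1.0, 2.5] rad
with smoothing σ in [3, 7] px and support-edge scale 5 px, scaled so
displacements occupy the same regime relative to the tracker's search
range as the full-scale recipe: ground-truth flow RMS ≈ 0.43 px with a
tail to ~7 px at support edges. A zero predictor then fails the 0.3 px
recovery bar while a working tracker passes it, which makes held-out flow
RMSE a meaningful test of learning rather than of output shrinkage.

## What the synthetic data does and does not show

The simulator reproduces the geometry, modulator statistics, scan
trajectories, noise model and the three contrast channels of the
scanning measurement, with exact ground truth. It does not model partial
coherence or source-size blur, scintillator PSF (available as an option,
off by default), polychromaticity, detector non-linearity, or
sample-thickness effects beyond the thin-object transmission model.
Passing tests therefore demonstrate correctness of the retrieval
algorithms under the stated forward model, not end-to-end performance on
beamline data; the quantitative claims that require real detector data
(absolute wavefront accuracy, hardware latency) are out of scope.

## Numerical choices and degenerate inputs

* Fourier sub-pixel shifts fix the Nyquist bin of real inputs to the real
  part of the ramp so real images stay exactly real and fractional shifts
  compose invertibly on bandlimited content.
* `generate_smooth_field` raises when the requested smoothing flattens
  the noise below 1e-6 peak-to-peak (the amplitude contract would become
  meaningless); peak 0 returns an exactly zero map.
* Parabolic sub-pixel fits clamp to ±0.5 px and flag window-edge peaks
  invalid rather than clamping values.
* Tracking Gauss-Newton updates are clamped to ±1 px per iteration; the
  2×2/4×4 normal systems carry a 1e-9 diagonal regularizer.
* `brute_force_track` refuses inputs above 64×64, N > 20 — it exists as
  a test oracle and must stay literal.
* Cost-volume offsets that leave the frame contribute zero; the warp
  layer zero-fills out-of-frame samples.

## Known limitations

* The desk network leans on its classical correlation prior for the flow
  channel; the learned correction improves but does not replace it. At
  full scale (long schedules, 10⁴ scenes) the architecture is designed to
  learn the readout end to end; that regime is not exercised here.
* Per-level encoder widths beyond the pinned endpoints (level-1: 32,
  deepest volume: 196) are a choice; parameter counts of the full-scale
  configuration are therefore indicative (≈1.8 M here), not a reproduced
  figure.
* The scan-number and data-scaling studies run on single scenes and
  inherit their scene-to-scene variability.
* Dark-field recovery from very few scans (N ≤ 3) is noisy for any
  method — the scan-axis standard deviation is estimated from 3 samples.
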