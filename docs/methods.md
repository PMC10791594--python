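# Methods

## Problem and model

A standard one-minute 3D cone-beam CT (CBCT) scan of the thorax acquires a few
hundred 2-D projections while the patient breathes.  Sorting projections into
respiratory phases (4DCBCT) trades severe undersampling artifacts for motion
blur and assumes periodic breathing.  This package instead estimates the
motion *at every projection* and a single motion-free volume directly from the
unsorted projections.

Motion is described by a surrogate-driven correspondence model.  For frame
`t` with surrogate values `S_t = (S_1t, ..., S_Nst)`:

    M_t = Σ_i S_it · C_i                  control-point displacements
    D_t = φ(M_t)                          cubic B-spline FFD → dense DVF
    I_t(x) = I_0(x + D_t(x))              pull-back warp of the reference
    P'_t = A_t · I_t                      cone-beam forward projection

and the components `C_i` minimize `f = −Σ_t LNCC(P_t, P'_t)` over the
measured projections `P_t`.  Two surrogate signals are used: with one signal
only the dominant (superior-inferior) motion is identifiable; two capture
hysteresis (out-of-phase chest/diaphragm motion); more invite overfitting.
The surrogates are either supplied externally or extracted from the
projections themselves (intensity analysis, below).  Model fitting alternates
with motion-compensated FDK reconstruction of `I_0`, since the initial
(uncompensated) FDK reference is blurred by the very motion being estimated.

The gradient used for fitting is assembled analytically through the entire
chain: LNCC gradient w.r.t. the estimated projection → adjoint projection
`A_t*` → exact spatial derivative of the warp → FFD adjoint → weighting by
`S_it`.  Every factor is the exact adjoint/derivative of the corresponding
forward factor, so the assembled gradient matches finite differences of the
implemented loss to ~1e-7 relative; this is verified exhaustively in the test
suite on a small problem.

## Operators

**Projector pair.**  Ray-driven forward projection with trilinear sampling at
a step of half the smallest voxel spacing; the backprojector scatters through
the transposed weights of the identical ray samples and is therefore the
exact adjoint (verified to ~1e-16).  The circular trajectory has the source
at `sid·(cos θ, sin θ, 0)`, a centered flat panel at distance `sdd`, and the
z axis as rotation axis.  Voxels outside the inscribed axial FOV cylinder are
null (NaN) and contribute nothing to projections.  A per-frame validity mask
over detector pixels is kept; the fitting loss uses the "intersects" mode
(pixels whose rays miss the FOV entirely carry no information and are
excluded), while a stricter mode excluding any ray that grazes the null
region is available for data that may contain out-of-FOV attenuation.

**FDK.**  Kak–Slaney flat-panel weighting with detector coordinates rescaled
to the isocenter plane, band-limited Ram-Lak kernel with a Hann rolloff
(window unspecified in the protocol; Hann is the common choice), frequency
domain filtering with power-of-two zero padding, voxel-driven distance-
weighted backprojection with the `2π/N_t` angular weight, accumulation in
double precision, final cast to single.  A 120-view scan of a 0.02 mm⁻¹
sphere reconstructs its interior mean to within 0.1%.

**Motion-compensated FDK.**  Each per-frame filtered backprojection volume is
resampled through the reference→frame mapping before accumulation.  Stored
fields follow the pull-back convention (`I_t(x) = I_0(x + D_t(x))`), so the
needed inverse is computed per frame by fixed-point iteration
(`E ← −D(x + E)`, at most 20 iterations, stop at mean update < 0.01 voxel) —
one stored DVF per frame.  The warped quantity is the fully weighted filtered
backprojection.  With zero motion MC-FDK reduces to FDK bitwise-near.

**B-spline FFD.**  Node displacements (mm) on a lattice with spacing of
8 level-image voxels, covering the image with a one-node margin.  Evaluation
and its exact adjoint are tensor-product cubic B-splines; level transfer uses
the exact dyadic subdivision masks, so the represented deformation is
preserved across levels.  Image warping is trilinear with zero padding
outside the volume; the chain-rule factor ∂I_t/∂D_t is the *exact* derivative
of that trilinear interpolant at the warped positions (per-cell slopes), not
a smoothed central-difference gradient — exactness of the full gradient chain
takes precedence over smoothness of the gradient image.

**LNCC.**  Gaussian-windowed (σ = 5 detector pixels at native resolution,
scaled with the level, floor 1 px) local means/variances/covariance via
normalized convolution restricted to the validity mask.  Windows whose local
variance in the *measured* image is below the texture threshold (local std
1% of the dynamic range) are excluded from the mean: they carry no
correlation information, a perfect match would read as cc≈0 there, and their
near-zero variances otherwise dominate the gradient.  Because the exclusion
depends only on the measured image, the loss stays smooth in the estimate.
Denominator variances are floored at 1e-6 × range².  The analytic gradient
accounts for the masked normalization and the floor branch and matches
finite differences to <1e-9.

## Fitting schedule and optimizer

Two resolution levels, 1/4 and 1/2 of native resolution (full-resolution
fitting costs much and gains little); projections are block-averaged, the
control lattice is refined dyadically, and `I_0` is re-reconstructed at each
new level (standard FDK at the first level, MC-FDK with the carried-over
model afterwards).  Per level, up to 6 alternations of (a) stochastic subset
gradient descent on `C` — evenly spaced one-tenth subsets, visiting order
reshuffled each epoch by the seeded RNG, at most 100 subset steps per fit
phase — and (b) MC-FDK update of `I_0`.

Each gradient step uses a backtracking line search: starting from the
warm-started step (initially scaled so the largest node moves 5 mm), halve
until the loss on the current subset decreases, and grow the step by 1.5×
after an immediate acceptance.  A fit phase ends early when two consecutive
epochs improve the epoch-mean loss by less than 1e-5 relative; a level ends
early when a whole fit phase achieves no improvement.  A phase-constant step
(chosen once per level) was tried first and was not robust: the gradient
scale changes by orders of magnitude after each reconstruction, so a fixed
step either stalls or oscillates.  The per-step search costs one extra
loss-only evaluation per accepted step and keeps every accepted update a
descent step on its subset.

Iteration accounting: one "fit iteration" = one subset gradient step.  The
seeded RNG governs subset visiting order only.  No deformation regularization
(e.g. bending energy) is applied by default.

## Surrogate extraction (intensity analysis)

The per-projection sum of pixel intensities (computed on the line-integral,
i.e. log-converted, projections) is split into a low-frequency part that
tracks the slow gantry-rotation dependence of the traversed path lengths and
a high-frequency part that tracks respiration.  The split is a zero-phase
2nd-order Butterworth high-pass at 0.1 Hz — below quiet respiration
(0.2–0.5 Hz) and above the gantry fundamental of a one-minute rotation
(~0.017 Hz; its low harmonics dominate because the thorax cross-section is
roughly 2-fold symmetric).  The second model signal is the temporal gradient
of the first (breathing-rate information, as in 5-D lung motion models),
computed by central differences with a 3-sample moving average, and both are
normalized to zero mean and unit sample (n−1) standard deviation.  The
signal's overall sign is arbitrary; the linear model absorbs it.

This separation argument fixes the admissible scan timing: scaled-down test
scans must keep the one-minute duration and subsample *frames* (60 frames at
~1.05 fps), not compress time.  An 11-second 60-frame scan would place the
gantry harmonics inside the respiration band, making intensity-based
extraction impossible for any method.

## Synthetic data generator

The generator emulates an anthropomorphic 4-D thorax simulation with an
analytic phantom: smoothed ellipsoids for body, two lungs, a liver dome under
the right lung and a spine column, plus a 15 mm spherical tumor in the lower
left lung; default grid 128³ at 2 mm (a 375×375×343 @ 1 mm full-scale option
exists), scan geometry SID 1000 mm / SDD 1536 mm, 360°, 310 projections at
5.4 fps on a 409.6 mm panel.  A smooth ±20% multiplicative soft-tissue
texture (12 mm correlation length, fixed anatomy seed) is applied inside the
body: real anatomy is not piecewise constant, and without internal texture
projection-domain similarity is blind to motion inside homogeneous regions.

Breathing: `sin²`-shaped traces with a 4 s period.  The regular regime is
in-phase with fixed amplitude (diaphragm 25 mm peak-to-peak, chest 3 mm; the
chest waveform carries a mild harmonic difference so the two signals are not
numerically collinear).  The irregular regime is shallower (diaphragm 15 mm)
with a 40° chest phase lag (hysteresis) and seeded ±30% per-cycle amplitude
variability interpolated smoothly between cycles.  Both traces are zero-mean,
so the reference volume is the time-average position.

Ground-truth motion ("model-class" mechanism): two fixed B-spline components
— an SI field peaking at the diaphragm dome, broad enough that the lower-lobe
tumor rides the diaphragm, and an AP field peaking at the anterior chest —
driven linearly by the raw traces.  The component lattice has a node spacing
of 16 phantom voxels, which is exactly the lattice of the finest
(half-resolution) fitting level, so a two-signal fit can represent the truth
exactly.  Amplitudes and envelope widths keep the numerically checked
Jacobian determinant above 0.2 (invertibility).  An "analytic" mechanism
evaluates the same envelope fields per voxel without a lattice.  Projections
are generated frame by frame as warp-then-project; optional Poisson noise in
the intensity domain is off by default.

What the generator does **not** emulate: sliding motion at the chest
wall/pleura (the fields are globally smooth — consistent with what a B-spline
transform can represent, and a known limitation of this transform class on
real data), detailed organ anatomy and CT-number calibration, scatter and
beam hardening, detector lag/offset.  Passing tests therefore demonstrate
correct mechanics and recoverability under a faithful-but-smooth motion
model, not clinical performance.

## Evaluation

Five metrics compare scenarios on simulated scans: mean DVF error E_D (mm)
over frames and the VOI (body ∩ FOV cylinder, attenuation > 0.01 mm⁻¹); Dice
of warped tumor masks; tumor centroid distance E_center (mm); NRMSE of the
model-motion MC-FDK against the ground-truth-motion MC-FDK over the VOI,
normalized to the latter's maximum; and SSIM between the same pair, averaged
over the VOI (whole-volume SSIM is dominated by empty air).  Estimated tumor
masks are the reference mask trilinearly warped by the model DVF and
thresholded at 0.5.  Scenarios: `S_uncorr` (zero motion, standard FDK,
static mask), `S_truth_signals` (model fitted with the generating traces)
and `S_IA` (model fitted with the extracted signal and its temporal
gradient); all metrics use every frame.

## Problem sizes

The bundled study runs at desk scale: 64³ phantom at 4 mm, 64×64 detector at
6.4 mm, 60-frame one-minute scan for fitting and reconstruction checks, and
the full 310-frame scan for surrogate-extraction checks.  Operator-level
checks (adjointness, gradient vs finite differences) run at 16³.  These sizes
were chosen so the whole study re-runs from scratch in minutes on one CPU
core; the phantom, geometry and schedule otherwise follow the full-scale
protocol, and all sizes are configurable.

## Known limitations

* Truncated projections (anatomy outside the FOV) are not handled; the loss
  masking assumes non-truncated data.
* No short-scan (Parker) weighting, offset-detector weighting, or helical
  trajectories.
* The transform cannot represent sliding interfaces.
* The optimizer is first-order; badly chosen surrogate signals degrade the
  model (by design, the model trusts its inputs).
* Real-scanner effects (scatter, beam hardening) are not simulated; LNCC is
  designed to tolerate them via local affine intensity invariance, but this
  is only exercised synthetically here.
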