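# cbctmoco

Surrogate-driven respiratory motion modelling and motion-compensated FDK
reconstruction for cone-beam CT (CBCT), fitted directly to **unsorted 2-D
projections** of a standard one-minute 3D scan.

## The problem

Thoracic CBCT scans acquired on linac-mounted scanners are blurred by
breathing, and respiratory-sorted 4DCBCT trades that blur for severe
undersampling streaks, longer scans and a periodicity assumption.  This
package implements the alternative: estimate the motion *at every
projection* together with a single motion-free volume, from nothing but the
projection stack itself.

## The model

For projection `t` with surrogate signal values `S_it` (two signals by
default):

```
M_t   = Σ_i S_it · C_i          correspondence model (control-point lattice)
D_t   = φ(M_t)                  cubic B-spline free-form deformation
I_t   = I_0(x + D_t(x))         warp of the motion-free reference
P'_t  = A_t · I_t               cone-beam forward projection
f     = − Σ_t LNCC(P_t, P'_t)   projection-domain loss
```

The components `C_i` are fitted by stochastic gradient descent over evenly
spaced one-tenth projection subsets, with the gradient assembled analytically
through the whole chain (LNCC gradient → adjoint projector → exact warp
derivative → FFD adjoint → surrogate weighting).  Fitting alternates with a
motion-compensated FDK reconstruction of `I_0` (each per-projection filtered
backprojection is deformed into the reference frame before accumulation), in
a two-level multi-resolution schedule.  Surrogate signals are extracted from
the projections themselves: the high-frequency component of the
per-projection intensity sums plus its temporal gradient, both normalized to
zero mean and unit standard deviation.

A synthetic-data module provides the full study environment: an analytic
4-D thorax phantom with a 15 mm lung tumor, regular and irregular breathing
traces, smooth invertible ground-truth deformation fields, and simulated
scans in an Elekta-like geometry (SID 1000 mm, SDD 1536 mm, 360°, 310
projections at 5.4 fps).  See `docs/methods.md` for the full model and
generator description.

## Worked example

Simulate a desk-scale dynamic scan (64³ phantom at 4 mm, one-minute scan
subsampled to 60 projections), fit the model with the true breathing traces
and with signals extracted from the projections, and compare three scenarios
against the ground truth:

```python
import numpy as np
from cbctmoco import PhantomSpec, FitConfig, simulate_study, fit_motion_model
from cbctmoco.metrics import evaluate_scenario, truth_surrogates
from cbctmoco.surrogate import ia_surrogates

sim = simulate_study(PhantomSpec(shape=(64, 64, 64), spacing=4.0),
                     regime="regular", n_frames=60,
                     frame_rate_hz=5.4 * 60 / 310, seed=1)

surr = truth_surrogates(sim)                      # the generating traces
model, i0, log = fit_motion_model(sim.projections, surr,
                                  FitConfig(seed=1), sim.reference)

ia = ia_surrogates(sim.projections)               # extracted from projections
model_ia, _, _ = fit_motion_model(sim.projections, ia,
                                  FitConfig(seed=1), sim.reference)

for name, m, s in [("S_uncorr", None, None),
                   ("S_truth_signals", model, surr),
                   ("S_IA", model_ia, ia)]:
    r = evaluate_scenario(sim, name, m, s)
    print(f"{name:16s} E_D {r.e_d:5.2f} mm  DSC {r.dsc:.3f}  "
          f"E_center {r.e_center:5.2f} mm  NRMSE {r.nrmse:.4f}  SSIM {r.ssim:.4f}")
```

Output (a few minutes on one CPU core):

```
S_uncorr         E_D  3.67 mm  DSC 0.747  E_center  5.12 mm  NRMSE 0.0116  SSIM 0.9890
S_truth_signals  E_D  0.68 mm  DSC 0.988  E_center  0.26 mm  NRMSE 0.0020  SSIM 0.9997
S_IA             E_D  1.56 mm  DSC 0.946  E_center  1.16 mm  NRMSE 0.0070  SSIM 0.9966
```

Without compensation the moving tumor is displaced by ~5 mm on average and
its mask overlaps the truth poorly (DSC 0.75).  Fitting the model with the
true breathing traces recovers the motion almost completely (sub-voxel
centroid error); fitting with the self-extracted signals is, as expected,
intermediate — worse than perfect signals, far better than no compensation.

## Command line

`cbctmoco` exposes the pipeline as subcommands:

```
cbctmoco simulate --regime irregular --out-dir sim/
cbctmoco extract-surrogate --projections sim/projections.mha --out signals.csv
cbctmoco fit --projections sim/projections.mha --surrogates signals.csv \
             --out-model model.npz --out-image i0.mha --log fit_log.csv
cbctmoco reconstruct --projections sim/projections.mha --model model.npz \
             --surrogates signals.csv --output mc.mha
cbctmoco animate --image i0.mha --model model.npz --surrogates signals.csv \
             --out-dir frames/
cbctmoco evaluate --out report.json
```

All commands accept `--config run.yaml` (strictly validated; defaults carry
the published protocol: control grid spacing 8 voxels, levels 1/4 and 1/2,
at most 6 motion-compensated reconstructions per level, at most 100 fit
iterations, one-tenth subsets) and `--seed`.

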