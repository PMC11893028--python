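# fetalflow

Motion-corrected reconstruction and flow validation for **fetal 4D flow MRI**,
with a pulsatile digital vessel phantom so every stage can be exercised and
tested without clinical data.

Fetal cardiovascular MRI fights two motion sources at once: quasi-periodic
maternal respiration and abrupt fetal bulk movements. Both corrupt a
continuously sampled, velocity-encoded acquisition that already relies on
heavy undersampling. `fetalflow` implements a retrospective correction
pipeline for this setting, aimed at researchers developing or evaluating
fetal flow protocols:

1. **Respiratory gating** — keep the ~60% of readouts nearest the expiration
   plateau of the belt signal;
2. **Bulk-motion correction** — sort readouts into 15-s chronological bins,
   reconstruct a phase-contrast angiogram (PC-MRA) per bin, estimate each
   bin's rigid translation by registration to a reference bin (mean-squares
   metric, regular-step gradient descent, 4x cubic upsampling), reject bins
   with extreme motion or signal loss, and apply the surviving translations
   to the raw k-space as exact Fourier phase ramps — identically across the
   velocity-encoding segments, so the encoding itself is untouched;
3. **Outlier-rejecting compressed sensing (CORe)** — reconstruct the
   cardiac-binned data by solving

   ```
   min_{x,v}  (1/σ²)‖A x − (y − v)‖₂² + λ₁‖W x‖₁ + λ₂‖v‖₂,₁
   ```

   where `A` is the coil-weighted Fourier sampling operator, `W` an
   undecimated 4D wavelet over 3D space and cardiac time, and `v` holds one
   complex outlier group per readout — residual motion corrupts whole
   readouts, and the ℓ₂,₁ penalty lets the solver discount them via a
   closed-form block soft-threshold (`θ = λ₂σ²/2`);
4. **Validation statistics** — four-point Hadamard velocity decoding
   (venc = 150 cm/s), PC-MRA computation, and the two internal-consistency
   metrics: conservation of mass at the ductal insertion
   (`Q_DA + Q_isthmus = Q_DAo`, reported as a symmetric percent difference
   over three 20 × 20 mm planes per vessel) and the coefficient of variation
   of net flow along the descending aorta's centerline.

The package also contains the phantom and acquisition simulator: a branching
pulsatile-vessel scene whose analytic flux balance holds exactly (so any
measured conservation-of-mass error is method error), sampled with a
pseudo-spiral Cartesian schedule, Hadamard-encoded, coil-weighted, corrupted
by simulated respiration and bulk motion as k-space phase ramps, and
degraded by complex Gaussian noise. See `docs/methods.md` for the model,
parameter defaults, and limitations.

## Worked example

```python
import numpy as np
from fetalflow import (PipelineConfig, PhantomConfig, MotionConfig,
                       make_phantom, generate_pseudo_spiral_trajectory,
                       simulate_triggers, simulate_motion,
                       simulate_acquisition, run_pipeline)

# 24^3 phantom at 1.25 mm, 90 s scan, R = 4, corrupted by two 5 mm
# fetal bulk shifts plus 3 mm maternal respiration
scene = make_phantom(PhantomConfig(matrix_size=(24, 24, 24)))
traj = generate_pseudo_spiral_trajectory(scene.matrix_size, r=4.0,
                                         tr=0.01, duration=90.0)
trig = simulate_triggers(mean_hr=140, jitter_sd=0.01, duration=91.0, seed=4)
motion = simulate_motion(
    MotionConfig(resp_amplitude_mm=3.0, bulk_change_times=[30.0, 60.0],
                 bulk_shifts_mm=[[5.0, 0.0, 0.0], [0.0, 3.0, 4.0]]),
    duration=90.0, readout_times=traj.time, seed=5)
ks = simulate_acquisition(scene, traj, motion, trig, noise_sd=0.02, seed=6)

cfg = PipelineConfig()
out = run_pipeline(cfg, kspace=ks)
print(f"CoM % difference: uncorrected "
      f"{out.flow_uncorrected.com.percent_difference:.1f} -> corrected "
      f"{out.flow_corrected.com.percent_difference:.1f}")
print(f"CoV along DAo:    uncorrected "
      f"{out.flow_uncorrected.cov.cov:.4f} -> corrected "
      f"{out.flow_corrected.cov.cov:.4f}")
```

prints

```
CoM % difference: uncorrected 14.7 -> corrected 3.7
CoV along DAo:    uncorrected 0.0046 -> corrected 0.0044
```

Uncorrected, the two bulk shifts blur the three vessels against the fixed
measurement planes and the inflow/outflow balance at the ductal insertion is
violated by ~15%; after gating, per-bin registration and k-space correction,
the balance closes to under the 5% consistency target. The CoV on this clean
cylindrical phantom is an order of magnitude below clinical values and is
essentially unchanged here — consistent with flow consistency along the
vessel being the less motion-sensitive of the two metrics.

The same run is available from the shell:

```bash
fetalflow all --config cfg.yaml --out results/   # or: simulate / gate /
                                                 # moco / recon / quantify
```

Exit codes: 0 success, 3 unrecoverable acquisition (all motion bins
rejected), 1 error.

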