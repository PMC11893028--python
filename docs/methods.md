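# Methods

## Problem and pipeline

Fetal 4D flow MRI acquires velocity-encoded k-space continuously over several
minutes while the fetus moves and the mother breathes. `fetalflow` implements
a retrospective motion-correction pipeline for such data and a digital
phantom to exercise it end to end:

1. **Respiratory gating.** The fraction of readouts (default 60%) whose belt
   signal lies nearest the expiration plateau is retained. The plateau is
   operationalized as the 5th-percentile signal level (belt convention:
   expiration = low signal; polarity configurable). Exactly
   `round(efficiency * N)` readouts are kept, ties broken by earlier
   acquisition time, chronological order preserved. Without a belt signal the
   data passes through with a warning.
2. **Bulk-motion binning.** Readouts are split into chronological 15-s bins;
   a trailing bin shorter than half a bin merges into its predecessor. Each
   bin is reconstructed jointly (CS with temporal total variation across the
   bin dimension), Hadamard-decoded, and summarized as a phase-contrast
   angiogram (PC-MRA).
3. **Rigid registration.** Each bin's PC-MRA is registered to a reference bin
   (automatically the bin of maximum angiogram signal in the analysis region;
   a manual index is honored) with a translation-only transform, mean-squares
   metric, and regular-step gradient descent (100 iterations maximum,
   gradient-magnitude tolerance 1e-4) on 4x cubically upsampled volumes.
   Both volumes are intensity-normalized to the reference's maximum (x100)
   first, so the gradient tolerance is meaningful regardless of the
   reconstruction's arbitrary signal scale; the metric is evaluated on a 5%
   random sample of the upsampled grid (fixed seed), which leaves translation
   accuracy unchanged while keeping registration fast.
4. **Rejection and correction.** Bins whose translation exceeds 10 mm or
   whose angiogram signal falls below 50% of the reference are rejected
   (automated surrogates for visual exclusion; manual override lists are
   supported). Accepted translations are applied to the original k-space
   readouts as exact Fourier phase ramps — identical across the four
   velocity-encoding segments, so velocity encoding is untouched. Rejected
   bins' data is removed. If every bin is rejected the pipeline raises an
   unrecoverable-acquisition error (CLI exit code 3).
5. **Final reconstruction.** Cardiac binning into 10 frames (frame =
   `floor(n_frames * (t - T_k) / RR_k)` between successive Doppler-ultrasound
   trigger times), then compressed sensing with readout-level outlier
   rejection (CORe):

   `min_{x,v} (1/sigma^2) ||A x - (y - v)||_2^2 + lambda1 ||W x||_1
   + lambda2 ||v||_{2,1}`

   where `A` is the coil-weighted Fourier sampling operator, `W` the
   undecimated 4D wavelet over 3D space and cardiac time, and `v` one complex
   outlier group per readout (all kx samples and coils of a line). The
   uncorrected baseline reconstructs all acquired data with
   `min ||Ax - y||^2 + 0.01 * TV_t(x)` and no motion-correction steps.

## Solvers and numerical choices

* All FFTs are centered and orthonormal; with sum-of-squares-normalized coil
  maps the squared operator norm is bounded by the maximum per-line visit
  count, which serves as the Lipschitz constant (no power iteration needed).
* Both solvers are proximal-gradient schemes initialized from the
  density-compensated adjoint (visit-averaged zero-filled recon). The
  temporal-TV proximal operator is computed by dual projected gradient along
  the short bin/frame axis; the wavelet proximal step soft-thresholds the
  coefficients of the Parseval undecimated transform (the standard
  approximation for tight frames). A backtracking safeguard halves the step
  on any objective increase; five consecutive increases abort with a
  divergence error. Objective traces are returned for QC.
* The outlier update is exact: `v_g = r_g * max(0, 1 - theta/||r_g||_2)` with
  `theta = lambda2 * sigma2 / 2` per readout group.
* k-space is pre-scaled so `max |y| = 0.1` before either solver; the defaults
  `lambda1 = 2.55e-4`, `lambda2 = 1.125e-1`, `lambda_tv = 0.01` are defined
  relative to that scaling. Re-running the prescribed tuning procedure
  (grid over `(lambda1, lambda2)`, lexicographically minimizing the CoV of
  DAo net flow, then maximizing PC-MRA SNR and peak flow) on the phantom
  selects the same `lambda1`, so the defaults are kept.
* `sigma2` defaults to 1, i.e. a noise-normalized data term. Estimating it
  from the highest-frequency 5% of samples is available
  (`sigma2="estimate"`), but at realistic phantom SNR that estimate is so
  small that `theta` collapses and the closed-form outlier update absorbs the
  entire residual — every readout would be flagged an outlier and the image
  update would stall. The outlier threshold must sit between thermal-noise
  group norms and corrupted-readout group norms, which the unit data term
  achieves under the 0.1 scaling.
* The per-bin angiogram reconstruction uses a deliberately mild TV weight
  (0.002, config key `recon.bin_lambda_tv`): across bins the TV couples
  *different fetal positions*, and the baseline's 0.01 can merge them into
  one average angiogram, biasing every translation estimate toward zero.
* The undecimated wavelet is Daubechies-2, 2 levels spatially and 1
  temporally, periodic boundaries (natural for the cyclic cardiac axis),
  energy-normalized (Parseval). Sizes must be divisible by 4 spatially; a
  temporal axis shorter than 2 (or odd) skips the temporal stage with a
  warning.

## Velocity encoding and decoding

Four-point Hadamard encoding with sign matrix rows
`(-1,-1,-1), (+1,+1,-1), (+1,-1,+1), (-1,+1,+1)` and per-segment phase
`phi0 + (pi / (2 venc)) * S_i . v`, venc = 150 cm/s. Decoding solves the
pairwise phase differences by least squares with a small integer wrap search,
keeping the candidate of minimal maximum speed. With a known constant
background phase `phi0` the decode is exact for every `|v_j| < venc`; without
it (the clinical situation) the unaliased range is bounded by pairwise
component sums — velocities a few times below venc, as in the phantom, decode
exactly either way. Decoded components are clipped to `[-venc, venc]` and
flagged where at the limit. The PC-MRA is the time average of the
magnitude-weighted speed (an RMS variant is available).

## Flow validation statistics

* **Net flow** through a plane: trilinear sampling of the velocity field on a
  20 x 20 mm grid at 0.5 mm spacing, signed along the plane normal, summed
  over the contour; `1 cm/s across 1 mm^2 = 0.6 mL/min`. Contours default to
  the vessel segmentation dilated by one voxel (capturing the profile rim);
  explicit contours are accepted.
* **Conservation of mass (CoM)** at the ductal insertion:
  `100 |Q_DA + Q_isthmus - Q_DAo| / ((Q_DA + Q_isthmus + Q_DAo)/2)`, i.e. a
  symmetric percent difference, each flow the time-mean net flow averaged
  over three planes 1.25 mm apart placed orthogonally to the local vessel
  axis (principal component of mask voxels within a 5 mm ball).
* **Coefficient of variation (CoV)** along the descending aorta: static
  contours at one-voxel spacing along the skeletonization-derived centerline
  (longest path by double BFS), per-contour net flow time-averaged over the
  cardiac frames, CoV = population std / mean. Two end contours are trimmed
  on each side by default (the analysis span is a configuration key). A
  per-phase variant (CoV per frame, averaged) is available.

## The phantom: what it emulates, and what it does not

The scene is the fetal great-vessel junction: the ductus arteriosus (DA) and
aortic isthmus descend at ±35° and merge into the descending aorta (DAo) at
the grid center. Each vessel is a straight cylinder with a parabolic
(Poiseuille) profile modulated by a shared 10-frame pulsatile waveform
(systolic peak, diastolic baseline 0.25, max normalized to 1). The DAo peak
speed is derived from the branch radii/speeds so the analytic flux balance
`Q_DA + Q_isthmus = Q_DAo` is exact — CoM on the ground truth is zero by
construction, so any measured CoM is method error. Defaults: 5 mm branch
diameters (6.4 mm DAo) at 1.25 mm isotropic voxels, DA/isthmus peak speeds
60/40 cm/s, venc 150 cm/s, background tissue at 20% of vessel magnitude with
a smooth static texture, 4 coils with smooth complex sensitivities
(sum-of-squares = 1), constant background phase 0.1 rad.

Magnitude and velocity volumes are partial-volume averaged over 3^3
supersampled points per voxel, emulating a scanner's voxel averaging; without
it, rim quantization of 2-voxel-radius vessels biases plane flux by several
percent and dominates the CoM budget. With it the ground-truth CoM floor is
about 1.5% at 24^3.

Motion: maternal respiration is a quasi-periodic (4 s) anteroposterior
translation with a `sin^4` profile — zero displacement on the expiration
plateau — at 3 mm amplitude by default (the amplitude is a configuration
choice, not a literature value); fetal bulk motion is piecewise-constant
3D translation with seeded random change points (about one per 45 s, up to
8 mm) or an explicit schedule. Triggers are jittered around a mean fetal
heart rate of 140 bpm (120-160 supported), covering the scan.

The acquisition model samples a pseudo-spiral Cartesian phase-encode schedule
(outward spiral arms on the (ky, kz) grid, golden-angle interleave rotation,
quadratic variable density, four encoding segments interleaved per point; the
master point set holds `~Ny Nz / R` points and is cycled for the scan
duration), applies the total translation per readout as an exact k-space
phase ramp, and adds complex white Gaussian noise (default sd 0.02 per
sample, vessel signal 1).

Not emulated: spin physics (relaxation, inflow enhancement), rotational or
non-rigid motion, within-bin motion faster than the bin length, moving coil
sensitivities, anatomy beyond three cylinders. Two consequences matter for
interpreting tests. First, because the coils stay fixed while the fetus
moves, a shifted bin reconstructs as the shifted object modulated by the
stationary coil profiles; at the desk-scale FOV (30-40 mm) this modulation is
visible for multi-millimeter shifts, whereas at a clinical 300 mm FOV it is
negligible — registration-precision tests therefore use a flat single-coil
scene. Second, a bulk shift that is a large fraction of the small FOV wraps
content circularly; shift magnitudes in the validation studies stay within
the range where the vessels remain in view.

## Study sizes used by the test suite and acceptance script

Desk-scale problem sizes are chosen so the full suite runs on one CPU:
translation-recovery studies run at 32^3 (R = 4, 60 s scans, per-bin
positions up to 8 mm, 3 mm respiration); the corrected-vs-uncorrected flow
studies at 24^3 (90 s scans corrupted by two 5 mm bulk shifts — the
uncorrected CoM error then sits in the 5-27% range with a median near the
clinically reported uncorrected values, and correction brings the median
under 5%); outlier-rejection studies at 24^3 with 5% of readouts corrupted
at 10x signal scale; solver identity checks at 8^3-16^3. The phantom's CoV
is an order of magnitude below clinical values (a clean cylinder has no
intercostal branches or segmentation error), so only its relative
corrected-vs-uncorrected behavior is meaningful.

## Known limitations

* Translation estimates for bins containing a motion change mid-bin land
  between the two true positions (the model assumes one position per bin);
  the recovery studies therefore align change points with bin boundaries,
  matching the model the correction actually implements.
* The wavelet proximal step is the tight-frame thresholding approximation;
  monotonicity is enforced by backtracking rather than guaranteed a priori.
* The outlier support threshold (`v_g` nonzero) has no hysteresis; readouts
  with residuals marginally above `theta` enter `v` with tiny amplitude.
* Conservation-of-mass planes use the simulator's (or user's) segmentation;
  on corrected reconstructions the segmentation is moved onto the reference
  bin's position using the simulated ground-truth shift, standing in for the
  clinical workflow of segmenting the corrected image itself.
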