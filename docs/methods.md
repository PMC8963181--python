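# Methods

## Pipeline contract

Stages form a simple chain; `ready()` initializes every stage, `do_proc`
pushes one volume through, `end_run` writes artifacts and resets. A stage
may buffer volumes and emit several at once (the regression stage's
retrospective burn-in), so the processing hook returns a list. Disabled
stages pass data through untouched. Online saving (rewriting the 4D
output after each volume) happens only after downstream processing has
completed and never changes the final file. A regression stage that uses
motion parameters or tissue means must have an enabled motion-correction
stage upstream; `chain()` enforces this and wires the motion stage to
push `(transform, unsmoothed resliced volume)` to the regression stage,
because the global-signal / white-matter / ventricle means are defined on
*unsmoothed* motion-corrected data.

The file watcher polls the directory (20 ms default) and considers a file
complete when two size probes 50 ms apart agree; the acquisition index is
parsed from the last integer group of the file name, ties in arrival
broken by modification time. A missing index in the sequence produces a
warning, not an abort — in a live scan, dropping a feedback value is
preferable to stopping the run.

## Slice-timing correction

Every slice is aligned to the earliest-acquired slice (no extrapolation
into the future). For slice shift δ ∈ [0,1) TR:

* linear: `x̂(k-δ) = (1-δ)x[k] + δx[k-1]` — identical online and offline;
* cubic (default): 4-point Lagrange through samples `k-2,k-1,k,k+1` with
  the pseudo future point `x[k+1] := x[k]`.

Cold start: volume 0 unshifted, volume 1 linear, cubic from volume 2.
Slices with δ=0 are copied bit-for-bit. Note a genuine property of the
pseudo-point rule: it is *not* exact on linear-in-time series — the
substitution biases the estimate by `-b·L1(-δ)` for slope `b`, where `L1`
is the Lagrange weight of the future node. It is exact whenever the true
future sample equals the present one; the tests assert exactly this.

## Motion correction

Six rigid parameters (rotations in degrees about the volume-center axes
composed `Rz·Ry·Rx`, then translations in mm) are estimated by
Gauss–Newton on the weighted SSD to a fixed reference, with a numerically
differenced Jacobian (step 1e-3), backtracking line search, `tol=1e-5`
(largest parameter update) and `max_iter=19`. The objective samples the
moving volume with a prefiltered cubic B-spline; reslicing uses separable
Lagrange interpolation of order 1/3/7 (heptic default) with clamp-to-edge
boundaries, exact for integer-voxel shifts and for per-axis degree-≤7
polynomial fields. The weight grid is the reference smoothed at 2-voxel
sigma, thresholded at 10% of max, with the outer 2-voxel shell zeroed so
edge-clamp artifacts cannot bias the fit. Estimation is stateless across
volumes (each starts from zero), which makes streaming and batch
processing bit-identical by construction. On the synthetic phantom,
single-axis injections of 1.5 mm / 2° are recovered within 0.02 units and
a 40-volume ≤3 mm/≤3° course within RMSE ≤0.1. No claim of numerical
compatibility with any external registration tool is made.

## Masked smoothing

`out(v) = Σ_{u∈mask} w(u-v)x(u) / Σ_{u∈mask} w(u-v)` with per-axis
`σ = FWHM/(2√(2 ln 2))/voxel_size`, kernel truncated at 4σ, zero outside
the mask. Renormalization makes constants invariant inside the mask and
keeps outside values from leaking in. Implemented as two Gaussian
filters (numerator and denominator); the stage is stateless.

## Physiological regressors

Cardiac phase rises linearly from 0 to 2π between consecutive detected
heartbeats; respiratory phase is the signed amplitude-histogram phase
(100 bins over the smoothed belt trace, sign of the smoothed derivative).
The RETROICOR bank is sin/cos of the first two harmonics of each phase,
sampled at volume onsets: exactly 4 cardiac + 4 respiratory columns.
Peak detection: moving-average smoothing (0.1 s cardiac, 0.5 s
respiration), threshold mean + 0.4·SD, 0.25 s refractory period — a
declared substitute for unpublished reference thresholds, validated
against analytic oracles. During a run the bank is recomputed every TR
from the record available at that moment; cardiac rows whose bracketing
peaks are final never change, respiratory rows can shift slightly because
the amplitude histogram spans the whole trace. RVT regressors are
deliberately not implemented (unreliable online).

## Scaling and cumulative GLM

The per-voxel baseline is the mean over the `wait_num` pre-regression
volumes (default 40), frozen thereafter; signals become
`100·(x-μ)/μ`, with voxels below `1e-6·max(μ)` masked. At each TR ≥
`wait_num` the design is rebuilt from scratch over all rows: Legendre
drift (order `1 + int(d/150)`, support remapped to [-1,1] over the rows
currently in the model), 12 motion columns (6 parameters + first
differences, row 0 of the derivative set to 0), mean-centered tissue
means, the RETROICOR bank, and optional extra covariates. Zero-variance
columns are dropped with a warning; the fit is one dense SVD-based least
squares shared by all voxels. The first fit refuses to run unless rows
strictly exceed columns and warns when rows < 2×columns. Emitted volumes
are pure residuals (no signal add-back); the burn-in volumes are emitted
retrospectively at the first fit so output count always equals input
count.

## Synthetic phantom: what it emulates, and what a green test means

Three concentric ellipsoidal compartments (ventricle 600, white matter
900, gray matter 1000 intensity units) with unequal axes and an
off-center bright inclusion — both asymmetries exist so that no rigid
rotation leaves the image invariant and registration is identifiable.
Contamination, all returned as ground truth:

* per-tissue Legendre drift (≈0.5-0.8% amplitude); an optional
  independent smooth per-tissue component (`drift_tissue_sd_pct`,
  default 0) emulates spatially varying scanner drift, but the default
  keeps the nuisance within what the tissue-mean regressors can
  represent, which is the right world for verifying the machinery;
* cardiac (1 Hz, 5% beat jitter) and respiratory (0.25 Hz) amplitude
  modulation at the analytic phase, strongest in ventricle (1.5%/1.0%)
  and gray matter (0.5%);
* slow head drift: a seeded random-phase sum of 1-3 whole-run sinusoids,
  0.3 mm / 0.3° peak — band-limited, hence orthogonal to any task
  cycling faster than 3 blocks per run;
* 2% block activation of a small gray-matter ROI, 20 s on / 20 s off;
* i.i.d. Gaussian noise, 1% of gray-matter baseline (temporal SNR ≈100).

Rigid motion is applied with the same heptic interpolator the pipeline
uses for reslicing; noise is added after motion. Defaults: 32×32×16
voxels of 3 mm, TR 2 s, 120 volumes. The phantom has no hemodynamic
response, no spatial noise correlation, no spin-history or distortion
effects; green recovery tests establish numerical correctness of the
stages on idealized data, not performance on real EPI.

## A structural property of cumulative-OLS denoising

Because OLS residualization is linear in the data, the task content of
the emitted series equals what a pure task regressor would leave after
passing through the same emission rule. With the full nuisance family
(~26 columns) on a 120-volume run this retention is low: early fits have
barely more rows than columns (40 vs 26), noise-dominated columns
(motion estimates, tissue means) absorb a chance share ≈ p/n of any
fixed direction, and slowly wandering columns (aliased cardiac
harmonics) track block structure adaptively. Measured on the phantom,
the emitted series retains only ~0.1-0.4 correlation with a 2% block
design even though motion is recovered to millidegrees; nuisance removal
is mostly clean (|r| ≤ 0.1 for most seeds), but the leading-edge
overshoot of the per-TR drift refit can also leave a systematic
anticorrelation with the injected drift for some noise realizations. This is a property of online
residual emission at desk-scale run lengths, not an implementation
defect; longer runs, fewer nuisance columns, or explicit task-regressor
protection would all raise retention. Users extracting task-locked
feedback should be aware that aggressive nuisance families shrink the
feedback signal itself.

## Numerical and design choices

* Scaling is zero-centered percent change (`100·(x-μ)/μ`).
* Rotation convention `Rz·Ry·Rx` about the grid center in mm space;
  motion log columns `rot_x rot_y rot_z shift_x shift_y shift_z`
  (degrees, mm).
* Erosion and the EPI automask use 6-connectivity; automask threshold is
  half the mean of above-global-mean voxels, then largest component and
  hole filling.
* TCP protocol: one line `NF <index> <onset> <value>` per message (6
  significant digits), `END` sentinel at end of run; round-trip identity
  holds to that precision.
* `wait_num` default 40 volumes; `ignore_init` default 0 — discarded
  volumes never enter any stage.
* Only single-file NIfTI-1 volumes are supported.
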