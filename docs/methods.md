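# Methods

## Tracer-kinetic model

Contrast concentration is assumed linear in CT number, so all curves are HU
enhancement above each voxel's first-frame baseline.  A tissue time-density
curve (TDC) is modelled as the convolution of the arterial input function
(AIF) `Ca(t)` with a scaled impulse residue function,

    Q(t) = F · (Ca ⊛ R)(t),

with the Johnson–Wilson–Lee residue

    R(t) = 0                      t < T0
         = 1                      T0 ≤ t < T0 + W
         = E · exp(−k (t−T0−W))   t ≥ T0 + W,

where `T0` (s) is the artery-to-tissue arrival delay, `W` (s) the minimum
capillary transit time, `F` the flow amplitude (HU-tissue per HU-artery per
second), and `E ∈ [0, 1]` the fraction of tracer with transit time longer
than `W`.  The clearance `k` is fixed at 0: the slow late washout visible at
the end of a one-minute dynamic scan is represented as a constant tail, which
keeps the model linear in `(F, F·E)` once `(T0, W)` are fixed.

Summary parameters derive from the residue: `CBV = ∫₀^T_end F·R(t) dt`
(with `k = 0`, in closed form `F·(W + E·(T_end − T0 − W))`, truncated at the
last timestamp of the fitted series), `MTT = CBV / CBF` by the Central
Volume Principle, and `Tmax = T0 + MTT/2`.  The convention for `F = 0` is
`CBV = MTT = 0`, `Tmax = T0`.  Flow is kept in relative units internally; all
lesion thresholds are percent-of-contralateral, so absolute calibration
cancels (a display scale of `6000/1.04` converts to ml/min/100g assuming
1.04 g/ml brain density).

## Acquisition protocols

* **CTP** — 5 s prep delay, 22 frames at 2.8 s, then 6 frames at 15 s
  (28 frames, ~154 s).
* **mCTA-P** — NCCT baseline at t = 0, then the three mCTA phases at 16, 24
  and 32 s.  The 16 s baseline-to-arterial-peak interval is a protocol
  constant (test-bolus timing places the first phase at peak arterial
  enhancement).  A constant `bias_hu` (default 4 HU) models the CT-number
  shift of the wider-collimation mCTA scans relative to NCCT; it is
  subtracted from brain voxels of the post-baseline frames before map
  computation (zeroth-order scatter correction).
* **dCTP** — the CTP study down-sampled to 4 frames: baseline, the frame at
  peak arterial enhancement `t_p`, and the frames nearest `t_p+8` and
  `t_p+16` s (ties to the earlier frame; timestamps preserved).

## Preprocessing

Frames are rigidly registered in-plane to the baseline (Powell refinement of
a masked SSD objective, translation initialised by cross-correlation of
slice-averaged images; synthetic inputs are already aligned, so the step is
opt-in), linearly interpolated to a 1 s virtual grid, and smoothed in-plane
with a Gaussian of FWHM 4.8 mm (σ = FWHM/√(8 ln 2)).  Smoothing is a
noise/resolution trade-off: on noiseless synthetic data it only blurs region
boundaries, so the recovery experiments run with `fwhm_mm = 0` while 4.8 mm
remains the default for noisy data.

AIF/VOF detection scores candidate voxels (above the 99th percentile of peak
enhancement, capped at half the global maximum so a taller vein cannot crowd
out the artery) by peak² / (AUC · first-moment) — tall, narrow and early —
averaging each candidate's curve over its in-plane 3×3 neighbourhood; the
VOF is the largest-AUC candidate peaking no earlier than the AIF.  The
anatomical-target selection of clinical software is not emulated; the
heuristic is validated on phantoms with known vessel locations.

## Fitting

With `(T0, W)` fixed, `Q = a1·b1 + a2·b2` where `b1 = Ca ⊛ 1_[T0,T0+W)`,
`b2 = Ca ⊛ 1_[T0+W,∞)`, `a1 = F`, `a2 = F·E`.  The fit is an exhaustive
search over `T0 ∈ {0, 0.5, …, 12}` and `W ∈ {0.5, 1, …, 20}` s with the
constrained two-variable least-squares problem (`0 ≤ a2 ≤ a1`) solved in
closed form for every pair (unconstrained solution if feasible, else the
better of the edges `a2 = 0` and `a2 = a1`).  Ties prefer smaller `T0`,
then smaller `W`.  Voxels whose peak enhancement is below 1 HU are flagged
invalid rather than fitted.

Two basis conventions are provided.  The default treats the sampled AIF as
piecewise linear and convolves it with the residue segments exactly (closed
form via the running integral of the AIF polyline) — appropriate for data
sampled from continuous curves, and self-consistent with the 1 s linear
interpolation for densely sampled studies.  `basis="discrete"` uses
left-edge sample-and-hold on the grid and is the exact inverse of the
discrete forward generator `tissue_forward` (note that half-step `T0`/`W`
values alias onto the same integer-lag bases there).

**Sparse studies** (any frame gap > 5 s) get three additions, selected
automatically by `perfusion_pipeline`:

1. *Bolus restoration.*  A linearly interpolated 4-point AIF is grossly
   widened and flattened, which biases every fit it enters.  The AIF is
   instead restored by a gamma-variate fit
   `A·((t−t_a)/(αβ))^α e^{α−(t−t_a)/β}` to the acquired arterial samples;
   with ≤ 5 samples the shape parameter is pinned at α = 3 (the 4-point
   gamma family is itself non-unique), with dense samples α is free.
2. *Measurement-operator projection.*  Model bases are sampled at the
   acquired frame times and linearly re-interpolated to the 1 s grid — the
   same operator the data went through — so the fit does not penalise the
   model's (correct) curvature between frames.
3. *Valley regularisation.*  The projected objective leaves a near-degenerate
   valley (below); a later `(T0, W)` pair must improve the SSE by more than
   `10⁻³·‖y‖²` to replace the incumbent, so the smallest `(T0, W)` member of
   the valley is returned deterministically.

### What four frames do and do not identify

A 4-frame study has three informative samples (the baseline is zero by
construction) against four kinetic unknowns.  Even with the true AIF there
is a one-parameter family of `(T0, W, F, E)` combinations that reproduces
all frames to numerical precision while spanning several-fold in `F`; the
family conserves `F·W` (≈ CBV) and `T0 + W/2` (= Tmax with `E = 0`).
Voxelwise CBF from such a protocol is therefore a regularisation choice, not
a measurement; CBV-like and Tmax-like quantities are the stable outputs.
On the default noiseless phantom the deterministic valley selection yields
CBF within 27 % of truth at worst (normal tissue sits at the valley's
`T0 = 0` edge) with Tmax within 0.2 s, and it *compresses* lesion-to-normal
CBF contrast — the inner core's relative CBF rises from its true 12 % toward
~13–19 % — which is precisely why the sparse studies need the relaxed 25 %
core threshold rather than the 15 % used for dense CTP.  Dense-protocol
recovery is essentially exact (max CBF error 0.35 %, Tmax 0.002 s).

## Lesion analysis

All thresholds are strict as stated: hypoperfusion is ipsilateral tissue
with `Tmax > 4` s; core is hypoperfused tissue with relative CBF (percent of
the mean CBF over valid contralateral brain voxels, vessels not excluded)
below 15 % (CTP) or 25 % (sparse); penumbra is hypoperfused tissue with
`Tmax > 6` s (CTP) or `> 5` s (sparse), excluding core.  Masks are closed
and opened with a 2 mm spherical element scaled anisotropically to the voxel
grid (at 5 mm slices this degenerates to an in-plane disk), holes are filled
per axial slice, and 26-connected components below 1 ml are removed; core
and penumbra are kept nested in the processed hypoperfusion mask and
disjoint.  The ipsilateral side is supplied explicitly or auto-selected as
the hemisphere with the larger `Tmax > 4` s volume.  The mismatch ratio is
penumbra/core (infinite for a zero core with non-zero penumbra; undefined
and unfavourable when both are zero), and the profile is favourable iff
core < 70 ml, penumbra ≥ 15 ml and ratio ≥ 1.8.

## Agreement statistics

Cohen's κ uses `po = (tp+tn)/n`, `pe` from the marginals, and a 95 % CI from
the exact large-sample (delta-method) variance; the simpler
`√(po(1−po)/(n(1−pe)²))` is available as `se_method="simple"`.  On the
cohort's 2×2 tables the delta-method CI reproduces both published intervals
(0.56–0.94 and 0.22–0.74) at two decimals, which the simple formula does not.
Sensitivity/specificity/accuracy treat the favourable profile as the
positive class with the dense-CTP call as reference.  Bland–Altman
differences are reference minus comparison, limits `MD ± 1.96·SD` with the
sample (n−1) SD.  The threshold calibrator sweeps an `(rCBF %, Tmax s)` grid
and minimises the mean over cases of |core error| + |penumbra error| in ml
(ties to the smaller thresholds); the objective table is returned in full.

## Digital phantoms

The dynamic brain phantom is a 64×64×8 grid at 2×2×5 mm (chosen so a full
pipeline run completes in seconds): an ellipsoidal brain (56×56×18 mm
semi-axes) split into hemispheres, normal tissue `(T0, W, F, E) =
(1 s, 4 s, 0.01, 0)` (Tmax 3 s, below the hypoperfusion gate), and a
right-hemisphere lesion of two nested ellipsoids — a penumbra-like shell
(40 % of normal flow, Tmax 7 s) and an inner core (12 % of normal flow,
Tmax 9 s).  The AIF is a gamma-variate peaking at 200 HU at 16 s (onset
7 s, α = 3, β = 3 s), matching the protocol's fixed NCCT-to-first-phase
interval; a broader, later vein curve (260 HU peak at 21 s) with the larger
area under the curve exercises VOF detection.  Artery and vein occupy 3×3
in-plane blocks so a centre voxel's neighbourhood average is undiluted.
Tissue curves are generated by convolution on a fine (0.1 s) grid —
approximating the continuous response rather than the fitter's discrete
model — sampled at the protocol frame times on top of a 35 HU baseline;
Gaussian noise (default SD 2 HU, the scale of smoothed clinical CTP data
relative to a 7 HU normal-tissue peak) is added i.i.d. under a fixed seed.
Under the mCTA-P protocol the protocol's `bias_hu` is added to brain voxels
of the post-baseline frames.  Ground-truth maps come from the closed-form
summary formulas; vessel voxels are excluded from the truth validity mask.

What the phantom does *not* emulate: recirculation and non-gamma bolus
shapes (the restoration prior matches the generator exactly, so sparse-AIF
results are optimistic), spatially varying scatter bias (the generator's
bias is constant; the ring analysis supports radial profiles), partial
volume at vessel and brain boundaries, motion (available but off by
default), and realistic vascular trees.  Passing recovery tests therefore
demonstrates correctness of the estimator under the stated model, not
clinical-grade accuracy.

The head phantom is a 1000 HU skull annulus (70–80 mm radius) around a
150 HU plexiglass-like interior with an optional radial bias profile
(`offset + slope·r`) and Gaussian noise.  The ring analysis thresholds
[100, 200] HU, keeps the largest connected component, erodes by a 5 mm
in-plane disk, and averages CT number in 10 mm rings around the per-slice
centroid; the NCCT↔mCTA bias estimate is the count-weighted pooled per-ring
difference (common rings only, with a warning on count mismatch).

## Numerical choices and degenerate inputs

1 s interpolation preserves values at on-grid timestamps; integer output
times span the acquisition.  Gaussian smoothing uses `mode="nearest"`
boundaries.  The gamma-variate AIF fit multi-starts over onset (and α when
free) to escape local minima.  Empty vessel-candidate sets, empty
contralateral hemispheres, sub-slab axial extents, AIF peaks at the first
frame, and `t_p + 16 s` beyond the last frame all raise informative errors;
flat tissue curves are flagged invalid instead of raising so maps remain
computable on partial data.  All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bitwise-identical
phantoms.

## Known limitations

The sparse-protocol CBF identifiability limit above is the main one.  The
kappa CI uses the asymptotic variance (no small-sample correction); the
calibrator's objective is a design choice among several reasonable ones; the
mCTA-P bias correction is zeroth-order while real scatter bias is spatially
dependent; and through-plane motion, DICOM ingestion and registration of
independently acquired real scans are out of scope (inputs must be
pre-aligned).
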