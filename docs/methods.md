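# Methods

## The prediction problem

In image-guided brachytherapy for locally advanced cervical cancer, the plan
quality indicators are the target coverage dose D90 (dose received by 90% of
the high-risk clinical target volume, HR-CTV) and the organ-at-risk hot-spot
dose D2cm³ (minimum dose to the most-irradiated 2 cm³ of bladder, rectum or
sigmoid colon).  Before a plan exists, the achievable D2cm³ of each OAR is
unknown, so planners optimize against population-level constraints rather
than patient-specific ones.  The method implemented here predicts, from
anatomy alone, the scale-free ratio D2cm³/D90 per OAR, so that a freshly
optimized plan can be audited against its own anatomy: a planned ratio far
above the prediction indicates a plan that should be re-optimized.

## Sub-organ (ring) features

The HR-CTV is expanded outward into concentric shells ("rings") of width
0.3 cm; the intersection of ring *k* with an OAR is sub-organ *k*, and its
volume divided by the whole-OAR volume is the normalized sub-organ volume
V_k.  Up to 15 rings are kept; absent rings contribute zeros so the feature
vector has fixed length.  The feature vector per OAR is
[V_1 … V_15, HR-CTV volume in cm³], 16 entries.  The ratio target makes the
overall plan normalization irrelevant, and the scalers (below) make raw
feature units irrelevant.

Rings are derived from a Euclidean distance transform of the HR-CTV mask
with anisotropic voxel spacing handled inside the transform (never by
resampling).  Ring membership is the half-open interval ((k−1)w, kw]; OAR
voxels inside the HR-CTV are booked to a separate `inside` volume and are
not a model feature, and voxels beyond ring 15 to a `far` volume, so ring ∪
inside ∪ far partitions the OAR exactly.

**Sub-voxel boundary offset.**  A voxel-centre distance transform measures
distance to the outermost region voxel *centres*, overestimating the
distance to the region *boundary*.  Measured against voxelized spheres of
radius 8–30 mm at 1–2.5 mm spacing, the offset is 0.27–0.35 voxels, stable
across geometries; exterior distances therefore subtract 0.3 × mean spacing
(capped below half the smallest spacing so exterior voxels stay positive).
Without the correction, ring volumes at CT resolution are biased by several
percent against analytic shell volumes; with it they agree within ~2%.
`boundary_offset_voxels=0` recovers the raw transform.

## DVH metrics

D(v) metrics are read off the cumulative dose-volume histogram: masked voxel
doses are sorted descending and the curve through (i · voxel-volume, d_i) is
interpolated linearly in cumulative volume.  Volumes below one voxel clamp
to the hottest voxel; the full mask volume returns the minimum dose.  This
dialect is validated against a closed form: for a 1/r² point source over a
20–40 mm spherical shell the hottest 2 cm³ is the sub-shell [20 mm, r₁] with
4/3·π·(r₁³−20³) = 2000 mm³, and the computed D2cm³ matches S/r₁² within 1%
at 0.5 mm spacing.

EQD2 conversion uses the linear-quadratic model,
EQD2 = D · (d + α/β) / (2 + α/β), with α/β = 10 Gy for the target and 3 Gy
for OARs (standard convention; config-exposed).  Constraint auditing uses
inclusive limits: HR-CTV D90 EQD2 ≥ 85 Gy; bladder ≤ 90 Gy; rectum and
sigmoid ≤ 75 Gy.

## The network and its training

One network per OAR: 16 inputs → tanh hidden layer (10 units) → linear
output.  Inputs and target are min-max scaled to [−1, 1] on the training
split only.  Training is full-batch Levenberg–Marquardt on the scaled
squared error: Δw = (JᵀJ + μI)⁻¹ Jᵀe with the Jacobian assembled
analytically (validated against central differences).  A step is accepted
only when the training MSE decreases, after which μ ← μ/10; otherwise
μ ← 10 μ and the step is retried (μ₀ = 10⁻³, μ_max = 10¹⁰).  Stopping: 1000
epochs, μ exceeding μ_max, gradient norm below 10⁻⁷, or validation MSE
failing to improve for 6 consecutive accepted epochs; the returned weights
are those of the best validation epoch.

Hidden weights initialize uniform(−0.5, 0.5) scaled by fan-in.  The output
bias initializes at the scaled train-target mean, and after the best-epoch
weights are restored the output bias is re-centred on the training
residuals.  Both choices address the same optimizer artifact: at a full
least-squares optimum the output-bias stationarity condition forces the mean
training residual to zero, but early stopping halts first, and a surviving
offset of even ~0.005 in the ratio is enough to fail a paired t test at
n ≈ 200.  The re-centring uses training data only.

The training protocol runs 100 independent random restarts (20 in the
desk-scale tests) and keeps the run with the lowest validation MSE.  The
70/15/15 train/validation/test split uses a uniform random permutation with
largest-remainder size allocation (218 rows → 152/33/33); splitting can
optionally be grouped by patient so that all fractions of one patient share
a set (plan-level splitting is the default, matching the protocol this
package replicates, but it does leak patient anatomy across sets —
group splitting is the statistically safer variant).

## Evaluation and QA

Per split and overall: regression R (Pearson correlation of predictions vs
targets), MSE, and Δ = |actual − predicted| of the ratio reported as
mean ± sample SD (n−1).  Predicted and planned ratios are compared with a
two-sided paired t test over all sets; p > 0.05 supports the "no systematic
difference" reading.  The QA gate flags a plan when |predicted − planned|
strictly exceeds a threshold (default 0.10 of the ratio; config-exposed).

## The synthetic phantom cohort

No clinical plans ship with this package, so a synthetic pelvic cohort
stands in, designed so that the D2cm³/D90 targets are genuinely
geometry-driven — the property the prediction method relies on.

Per fraction plan, on a 96³ lattice at 2 mm isotropic spacing:

- **HR-CTV**: a compact ovoid — base radius uniform 15–35 mm, per-axis
  eccentricity multipliers uniform 0.85–1.15.  Independent per-axis sampling
  was rejected: it makes the surface curvature facing each OAR vary in a way
  ring features cannot see, destroying the feature→dose relationship that
  clinical anatomy (a roughly ovoid cervix + tumour) does exhibit.
- **OARs**: bladder an anterior ellipsoid; rectum a posterior tube along the
  cranio-caudal axis; sigmoid a tube draped across the superior HR-CTV dome
  (the sigmoid loops over the uterine fundus; a version rising straight off
  the pole presents too little facing surface for ring features to encode
  its stand-off).  Each is placed at a sampled HR-CTV surface gap, drawn
  from a decreasing-triangular law on 0–12 mm: OARs usually abut the target,
  larger stand-offs are increasingly rare.  Masks are pairwise disjoint.
- **Implant**: an intrauterine tandem through the HR-CTV centroid plus 2–8
  needles (probabilities 0.25/0.28/0.20/0.12/0.08/0.04/0.03 on 2…8, mean
  3.74 per fraction) at template-regular angular positions around the tandem
  with small jitter, dwells every 5 mm, all inside the HR-CTV.
- **Dose**: bare inverse-square point kernel, dose(v) = Σ w_i·K/max(r,1 mm)²
  — no anisotropy or radial dose function, since only relative geometry
  matters to the learning task.  Dwell weights are optimized by nonnegative
  least squares toward a uniform dose on sampled HR-CTV surface points,
  emulating the repeated manual/graphic optimization of clinical planning;
  D90 rescaling alone (the obvious shortcut) leaves the dose shaped by the
  raw source cloud rather than the target surface and removes most of the
  geometric signal.  Two noise sources then model planner and delivery
  variability: a smooth stationary random field modulating the surface-dose
  objective (four random low-frequency sinusoidal components, RMS amplitude
  0.12 — stationarity matters: a polynomial basis tried first concentrated
  its variance at the surface poles and silently gave the sigmoid twice the
  noise of the other OARs) and multiplicative log-normal noise on the final
  dwell weights (σ = 0.1).
  Finally the grid is rescaled so HR-CTV D90 equals the prescription (6 or
  7 Gy/fraction), exact to 10⁻⁹ by construction.
- **Cohort**: consecutive groups of 2–5 plans share a patient id, mimicking
  multi-fraction courses without modelling inter-fraction anatomy change.
  Everything is reproducible from one seed (per-plan streams are spawned
  from (seed, plan index, stage)).

The noise amplitudes were calibrated so the cohort's irreducible prediction
error sits in the clinically reported range (Δ ≈ 0.03–0.05, per-OAR MSE of
order 10⁻³, R ≈ 0.8–0.95): an essentially noise-free phantom makes the
paired t test pathologically sensitive (any 0.005 offset is "significant" at
n = 220), while heavier noise degrades R below clinically observed values.

**What the phantom does not emulate**: real pelvic anatomy (organ shapes are
geometric primitives), inter-fraction deformation, applicator/ovoid
geometry, TG-43 dosimetry (radial dose/anisotropy functions), or contouring
variability.  Passing tests on this cohort demonstrates that the pipeline
recovers geometry-driven dose relationships of realistic strength; it does
not validate clinical accuracy on human anatomy.

## Numerical and interface choices

- World coordinates in mm, voxel indices 0-based, values at voxel centres;
  volumes as voxel count × voxel volume, in cm³.
- Masks/doses as NIfTI (lattice in the affine); cohorts as CSV with a
  name-keyed schema; models as JSON (weights, scalers, restart log); run
  configuration as YAML with documented defaults, unknown keys rejected, and
  a semantic hash stamped into artifacts.
- Degenerate inputs fail loudly (empty masks, v_cc beyond the mask volume,
  constant vectors in correlations/t tests), except constant features, which
  scale to 0 with a warning.
- Problem sizes in the test suite (220-plan cohort, 20 restarts, ≤32³ oracle
  phantoms) are desk-scale choices that keep the full protocol able to run
  end to end on one CPU in minutes.

## Known limitations

- The ring features discard angular information; two OARs with identical
  ring profiles but different positions relative to the implant get the same
  prediction.  The phantom's template-regular implant keeps this mostly
  harmless; irregular clinical implants weaken it.
- Per-fraction physical dose ratios are modelled, not EQD2-converted course
  sums; the ratio target makes the distinction largely immaterial.
- The sigmoid remains the hardest OAR: it faces the superior pole, where
  dose falls in the point-source regime beyond the top dwell positions, so
  its ratio carries more feature-invisible variance than bladder or rectum.
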