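# Methods

This note records the models, parameter choices and numerical conventions
behind `vfa`, and what the synthetic studies do and do not demonstrate.

## Spot-map generation

The membrane is a `rows × cols` lattice (default 9×9, 1.3 mm pitch) with
0-based row-major `(row, col)` coordinates; radii are measured from the
grid centroid in lattice units. Because vertical flow rate varies radially,
a condition concentrated near the center or rim would be systematically
biased, so the generator requires every condition's mean spot radius to lie
within a tolerance (default 10%) of the all-spot mean. The algorithm is a
seeded random assignment followed by best-improvement swap search on the
maximum per-condition relative radial deviation, bounded at 10,000 swaps
and 20 restarts, with lexicographic tie-breaks for determinism. When a
tolerance is infeasible the error reports the best imbalance achieved —
small grids can be provably infeasible at 10% (for 3 conditions × 3
replicates on 3×3, exhaustive enumeration gives a 12.07% optimum, driven
by the center cell at radius 0).

Default replicate split over the seven conditions is 12,12,12,12,11,11,11
(a near-even split; the true per-condition counts of the original 81-spot
panel are not public). Per-spot reagent costs in `default_conditions()` are
configurable placeholders.

## Synthetic cohorts

The generator reproduces the phenomenology that matters to the analysis,
not the underlying chemistry:

* **Dose–response.** Sandwich channel (Ab):
  `A·(c/(K_a+c))·(1/(1+c/K_h))` — a Langmuir binding term times a
  prozone-inhibition term, peaking at `√(K_a·K_h)`. Competitive channel
  (Ag): `A/(1+c/K_c)`, strictly decreasing. Defaults `K_a = 2 mg/L`,
  `K_h = 150 mg/L`, `K_c = 20 mg/L` put the hook peak (~17 mg/L) between
  the hsCRP range and the acute spikes, so acute samples fold back onto
  hsCRP-range signal levels on the sandwich channel alone — the failure
  mode the multiplexed design must overcome. Ag-low is the competitive
  form at one-third amplitude; Mix1/Mix2 are weighted sums of the Ab and
  Ag responses (0.5/0.5 and 0.65/0.35); SecondaryAb and Control are
  analyte-independent constants (0.9 and 0.15).
* **Batch and flow effects.** Multiplicative reagent-batch gains
  (RID ∈ {1, 2}: 1.00, 1.08) and fabrication-batch gains
  (FID ∈ {1, 2, 3}: 1.00, 0.93, 1.05), plus a radial attenuation
  `1/(1 + α(r/r_max)²)` with α = 0.3, so edge spots carry less signal and
  proportionally more background noise.
* **Noise.** Per-spot unit-mean lognormal factor at CV 10% (the scale of
  replicate scatter a well-behaved membrane shows) and an additive
  background `b ~ N(0.08, 0.01)` recorded per spot.
* **Cohort design.** 85 hsCRP-range samples drawn log-uniform over
  [0.1, 10] mg/L, measured in triplicate, plus acute samples in
  triplicate: one clinical-style outlier at 83.6 mg/L and three spiked
  samples at each of 200, 500 and 1000 mg/L. RID/FID assigned round-robin
  over samples.
* **Noise-spot probe.** For robustness studies, selected spots can be made
  dose-independent: their response is a unit-mean lognormal draw (CV 100%)
  around the condition's typical intensity (its response averaged over a
  log-spaced hsCRP grid). This models an unstable or contaminated dispense
  at the right intensity scale; a scale-free draw would instead perturb
  the like-spot mean of low-amplitude conditions and penalize innocent
  spots.

What passing tests on these cohorts show: the pipeline's arithmetic,
selection logic, routing behaviour and noise robustness under the stated
conditions. What they do not show: performance on real membranes, whose
noise is not exactly lognormal, whose batch effects are not purely
multiplicative, and whose dose–response curves differ between reagent
lots.

## Rendering and segmentation

Membranes are rasterized at 20 px/mm in absorbance-like polarity (larger =
more binding; photographic input is inverted on load, using the green
channel by default, where gold-nanoparticle contrast is strongest). The
membrane base level is the test's mean recorded background; each spot is a
filled disk of amplitude `s − b` (printed radius 0.52 mm, 2× supersampled
edges), with optional Gaussian texture. Ground-truth lattice geometry is
stored in the image metadata.

Detection cross-correlates the image once with a disk template via
normalized cross-correlation (template radius 0.40 × pitch, matching the
printed spot so the correlation peak is unique), then maximizes the mean
correlation at predicted lattice centers over rotation ±5° (step 0.25°)
and offsets ± one period (step 1 px), refined by parabolic interpolation.
A fit whose peak mean correlation falls below 0.20 is reported as failed
(a QC flag, not an exception). Typical recovery on rendered membranes is
~0.1 px RMS; the tested envelope is ≤ 1 px over offsets up to 10 px and
rotations up to 3°.

Extraction averages a disk of radius 0.35 × pitch (strictly inside the
printed spot, so rim pixels do not dilute the average) and a background
annulus [0.55, 0.75] × pitch, excluding pixels within 0.45 × pitch of any
other spot center; an empty annulus is widened once to 1.5× the outer
radius, then the spot is QC-failed. QC flags misalignment (failed fit or
residual > 0.8), low total signal (the signature of abnormal non-specific
binding sequestering the conjugate), and non-finite values; it never
raises.

## Normalization and feature semantics

`s'` values are normalized to the total over a *pool* of spots and summed
checks hold to 1e−9. The pool is the membrane's spot subset: by default
the full grid, or the selected spots after feature selection (matching the
view that a reduced membrane would only print those spots; the all-spot
denominator remains available). Selecting *conditions* as model inputs
only picks per-condition mean columns and never changes the denominator —
this keeps training and inference features identical and means dropping an
input channel does not rescale the survivors. In channel-restricted
ablations the pool defaults to the chosen conditions' spots, so the model
genuinely sees only those channels' pixel information.

## Feature selection

The per-spot cost `j_{m,p}` accumulates each spot's relative deviation
from its like-condition mean over the training tests; training tests with
a zero like-spot mean contribute no term (counted on the cost map). The
vectorized computation is verified against a naive triple loop to 1e−12.
Spot elimination removes the highest-cost survivor per iteration
(lexicographic tie-break), never a condition's last spot, from 81 spots
down to one per condition — a 75-entry trace including the initial full
set. Cross-validated MSLE/R² of the quantifier is recorded per iteration
with fold assignment fixed across iterations (stratified by concentration
quintile and FID) so the curve is comparable; the operating subset is the
minimum of a centered moving average (window 5, ties to the larger
subset). Condition elimination greedily removes, per round, the condition
whose removal minimizes CV MSLE. Elimination-phase CV restricts the
quantification metrics to hsCRP-range tests, consistent with the
quantifier's training domain.

## Networks and training

The networks are a self-contained numpy MLP: ReLU hidden layers, inverted
dropout (training only), L2 penalty, Adam (lr 1e−3), early stopping on a
held-out validation split with best-weight restoration, all randomness
from one seeded generator. For the binary acute classifier the validation
split is stratified by class — with ~20 acute tests among ~220 a random
split can contain none, leaving early stopping blind to the rare class —
and the cross-entropy is class-weighted.

The quantifier regresses `z = ln(1 + c)`; squared error on `z` is exactly
the MSLE objective and `exp(z) − 1` (clipped at 0) enforces non-negative
concentrations. Acute samples are excluded from quantifier training. The
classifier's sigmoid output is the confidence score, thresholded at 0.5.

Architecture defaults: the classic two-hidden-layer 512/64 ReLU network
with 50% dropout is available and is the `NetworkConfig` default, but at
this feature dimensionality (~12 inputs, ~200 training tests) the
study-scale runs use compact strongly regularized nets — quantifier
(32, 16) with L2 3e−3, classifier (16,) with L2 1e−2 — which cut
prediction variance substantially (replicate %CV roughly halves) and place
the acute decision boundary smoothly across the wide feature gap between
the hsCRP cloud and the spiked acute cluster. CV-heavy loops (elimination
traces) default to a (32,) net at 200 epochs, and structural checks use 10
epochs, sizes chosen to keep a full selection run in seconds. A random
hyper-parameter search over user-constrained lists (layer sizes, dropout,
L2, batch size), scored by k-fold CV MSLE, is provided.

RID/FID enter as one-hot vectors (integer labels carry no ordinality; a
raw-integer mode would impose it). The linear baseline is ordinary least
squares from the same features to concentration; the reference level of
each one-hot block is absorbed into the intercept, and the remaining exact
constraint among condition averages (Σ P_m·x_m = 1 over a full pool) makes
the design rank-deficient by construction, handled by a pseudoinverse fit
with a warning.

## Evaluation conventions

Risk strata are left-closed on the upper category: [0, 1) low, [1, 3)
intermediate, [3, 10] high, > 10 mg/L acute. Replicate %CV uses the n−1
sample SD, per sample, averaged unweighted over samples; samples with
near-zero mean prediction are excluded with a warning. The regression line
is prediction on ground truth; R² is the squared Pearson correlation.
Bland–Altman differences are prediction − truth with ±1 SD limits (1.96 SD
also reported). Reagent-cost reductions are reported both exact and
truncated to whole percent (the headline convention). Train/test
partitioning keeps replicates of a sample together and draws test samples
at evenly spaced concentration ranks within each (risk stratum, FID) cell,
so the test set covers the range linearly and batches proportionally.

## Reproducibility

Every stochastic operation takes a seed or generator; the pipeline fans a
single master seed to per-stage seeds by hashing the stage name, records
it in every manifest alongside content hashes, and identical configs
reproduce identical manifests for deterministic stages. `scripts/
acceptance.py` derives all sub-seeds from its `--seed` argument.

## Known limitations

* The dose–response forms are minimal qualitative models; no attempt is
  made to calibrate them to a specific reagent system.
* Raw camera formats and demosaicing are out of scope; inputs are
  single-channel or RGB rasters.
* The segmentation assumes an approximately axis-aligned lattice within
  ±5°; grossly rotated or warped membranes are QC-failed, not recovered.
* The confidence score is the raw classifier sigmoid; it is not a
  calibrated probability.
* Condition-elimination CV uses the phase's fixed spot pool; a
  re-normalized per-subset pool is a defensible alternative the package
  does not currently expose.
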