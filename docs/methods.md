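# Methods

## Problem setting

A planning CT for breast radiotherapy images the ipsilateral lung before
any dose is delivered. The hypothesis under test is that five first-order
densitometry statistics of that lung — HU minimum, maximum, mean, standard
deviation, and volume — already carry signal about which patients will
later show radiologically visible radiation-induced lung injury (RILI).
The package implements the feature extraction, a closed-form risk score
(HPF), the rank-based group statistics, and three fixed-hyperparameter
classifiers, all exercised on synthetic data.

## Feature extraction

Statistics are computed over the voxels selected by a binary lung mask;
voxels outside the mask never influence any feature (tested as an
invariance). `hu_sd` uses the sample convention (n−1); the population
convention is a one-line change but the sample convention matches common
clinical analysis software, and the choice is recorded here because
source material for the cohort statistics does not state it. Volume is
`count x prod(spacing_mm) / 1000` cm³. Masks are binarised at > 0;
partial-volume weighting is not modelled. At least two foreground voxels
are required (the sample SD is undefined on one). NIfTI I/O goes through
nibabel; a DICOM-series reader is out of scope in this build.

## The HPF score

`HPF = V^e / (HU_max − HU_min)` with `e = (HU_mean + HU_sd)/(HU_mean −
HU_sd)`. For physical lungs (HU_mean < 0, 0 < HU_sd < |HU_mean|) the
exponent lies in (0, 1), so the score increases with volume and decreases
with the HU range. The power is evaluated in log space; this agrees with
direct evaluation to 1e−10 relative wherever the latter is finite, and
avoids overflow for large volumes with exponents near 1. Degenerate
inputs (HU_mean = HU_sd, zero HU range, non-positive volume) raise rather
than being clamped: a silent clamp would move scores across the decision
cutoff.

The classification direction is fixed by the score's interpretation: low
HPF (≈ 0.11 ± 0.05 in injured lungs vs ≈ 0.14 in healthy ones) means
damaged tissue, so a score **at or below** the cutoff predicts RILI, with
boundary equality assigned to the positive class. The cutoff itself is
not published; it is fitted by maximising Youden's J over midpoints of
the sorted unique training scores, ties resolved toward the larger
cutoff (the more conservative, fewer-positives choice among equally good
thresholds).

## Group statistics

Mann–Whitney U with midranks; Z from the tie-corrected variance

    sigma^2 = n1 n2 / 12 * [(N + 1) − sum(t^3 − t) / (N (N − 1))]

and **no continuity correction by default**. This convention was chosen
because it makes the Z-based effect size r = |Z|/√N exactly recoverable
from a two-sided p via r = Φ⁻¹(1 − p/2)/√N, which reproduces the three
published (p, r) pairs at N = 242 (0.003 → 0.19, 0.001 → 0.21,
0.123 → 0.10). The continuity correction is available as a flag, and the
rank-biserial correlation is reported as an alternative effect size.

Accuracy of the normal approximation, quantified by complete enumeration
(all C(16,8) label assignments at n = 8 vs 8): worst-case
|p_approx − p_exact| is 0.047 uncorrected and 0.011 corrected; at
n = 30 vs 30 the corresponding typical errors drop to under 0.01 / 0.005.
A stricter-than-0.011 uniform bound at n = 8 is not achievable by either
variant, which the test suite records explicitly. The exact enumeration
test (`exact_mann_whitney_p`, limited to N ≤ 16) exists precisely to make
such statements checkable.

## Classifiers

All three are binary, authored in this package; scikit-learn supplies
estimator plumbing only, and is used in the tests as an independent
cross-check, never as the implementation.

**Gini tree.** "Fine" granularity is implemented as a *tree-wide budget
of 100 splits* consumed best-first: at each step the frontier split with
the largest weighted Gini decrease is taken, with deterministic
tie-breaks (node creation order across the frontier; lowest feature
index, then lowest midpoint threshold within a node). A budget is the
semantics under which a "maximum of 100 splits" is well-defined for
best-first growth; a depth cap would not be. Zero-gain splits of impure
nodes are permitted: parity patterns (XOR) have no positive-gain first
split, yet are separable in three splits, and refusing zero-gain splits
would leave such nodes impure forever. Gini gain is never negative, so
this admits exactly the splits that do not increase impurity. Surrogate
splits are omitted and non-finite inputs are rejected.

**Distance-weighted kNN.** k = 84 Euclidean neighbours on standardized
features, vote weight 1/d². Zero-distance dominance: if any neighbour
coincides with the query, the majority label among the coincident
neighbours wins outright. This limit behaviour (the 1/d² weight diverges)
is what makes resubstitution accuracy exactly 100% on training sets with
pairwise-distinct rows — the headline "test accuracy 100%" of this model
family is a statement about memorisation, not generalisation, and the
evaluation layer therefore always reports cross-validated accuracy next
to it. Distance ties at the k-boundary include every tied neighbour, so
predictions do not depend on row order.

**Random-feature kernel logistic.** z(x) = √(2/D)·cos(Wx/σ + b), W
standard normal, b uniform on [0, 2π), D = 115. E[z(x)ᵀz(x′)] equals the
Gaussian kernel exp(−‖x−x′‖²/2σ²); at D = 10⁴ the inner products agree
within 0.05 (tested). The head minimises mean log-loss + λ‖w‖²/2
(λ = 0.55035, intercept unpenalised) by damped full-batch Newton
iteration, stopping at gradient norm < 1e−8 or 1000 iterations; with
D = 115 the Newton system is 116x116 and the fit is deterministic given
the seed. The mean-loss convention matches the environment in which
λ = 0.55035 was originally selected (equivalently, an inverse
regularisation C = 1/(nλ), which the tests use to cross-check against an
unregularised-limit logistic fit). σ defaults to √(n_features); only the
searched range, not the selected value, is published, so this is a
recorded package default, as is kNN standardization (the published
search tried both).

## Evaluation conventions

- Stratified 5-fold CV: per class, shuffled members are split into chunks
  of size ⌊n_c/k⌋ or ⌊n_c/k⌋+1, larger chunks going to the currently
  smallest folds; per-fold class counts are within 1 of proportionality
  and 242 labels (113/129) produce fold sizes {49,49,48,48,48}.
- Hold-out: stratified 159:83 split by largest-remainder allocation
  (74 or 75 RILI cases in training).
- "Test accuracy" in the published table style is interpreted as
  resubstitution on the training partition — the only reading under
  which the kNN row (100%) is attainable — and "validation accuracy" as
  the 5-fold CV mean. Both are always reported together with an honest
  held-out accuracy so the ambiguity is surfaced rather than hidden.
  Whether CV runs inside the 159-row training partition or on the full
  table is a pipeline flag (default: training partition).
- ROC curves sweep unique score values (low-score-positive orientation
  available for HPF); AUC is trapezoidal and equals pair-counting
  concordance with ties at ½, to 1e−12 (tested). CV ROC pools
  out-of-fold scores.
- A fold whose fit degenerates (single-class training half) is excluded
  from the CV mean with a warning instead of aborting the run.
- Report rounding: accuracies to 1 decimal, descriptive statistics and
  effect sizes to 2, p-values to 3.

## Synthetic data: what it emulates and what it does not

`sample_feature_table` draws each feature independently from a truncated
normal per RILI group. Targets are the published group summary
statistics: mean and SD of each feature as the marginal's moments, and
the published group minimum/maximum as hard truncation bounds. Because
truncating a normal shifts its mean toward the interval centre and
shrinks its SD (by up to tens of HU/cm³ for the asymmetric bounds here),
the parent (μ, σ) are solved by moment-matching rather than used
directly — the generator is calibrated so that large samples recover the
published group means and SDs within Monte-Carlo error (tested at
n = 5000/group against 3-standard-error bands). Rows violating
hu_min < hu_mean < hu_max (or positivity) are redrawn wholesale;
resampling rather than clipping avoids probability atoms at the bounds.
Defaults: 113 RILI / 129 no-RILI, seed 20250527, all randomness from one
seeded generator; fixed config ⇒ byte-identical tables.

Only *marginal* summaries are published, so the generator deliberately
models no cross-feature correlation — real lungs correlate volume with
mean density, and a synthetic cohort will understate any classifier
performance that exploits such structure. Green model tests therefore
establish that the algorithms are implemented correctly and behave
sensibly on a cohort with realistic marginals, not that the published
dataset-dependent accuracies (e.g. tree 83.1/54.1) are reproduced; those
require the original cohort.

Phantoms are voxelised ellipsoids (axes rescaled isotropically to the
target volume) filled with Gaussian HU noise around a base level
(default −760 ± 55 HU) plus dense spherical lesions (denser tissue,
offset ≥ 0) emulating opacity/reticulation. The common lesion offset is
tuned by bisection until the masked mean matches the target record's
hu_mean (guaranteed within 2 HU; the mask volume is within one voxel
layer of the target). hu_sd/min/max follow from the texture and are not
matched. No anatomy, airways, or dose distributions are modelled.

## Known limitations

- Independent marginals in the cohort generator (above).
- The HPF cutoff, kernel scale, and kNN standardization are package
  defaults, not published facts.
- The exact Mann–Whitney oracle is limited to N ≤ 16 by enumeration cost.
- Binary labels only; the multiclass machinery of the original modelling
  environment collapses to the binary case here and is not generalised.
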