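# Methods

This note records the model, the numerical conventions, and the design
choices behind `aquagrade`, at the level of detail a maintainer or reviewer
needs to audit a grading.

## Grading model

A well is a vector of indicator concentrations; a grade is one of five
ordered quality classes defined per indicator by four ascending limits
S1 ≤ S2 ≤ S3 ≤ S4 (grade V is the open interval above S4 and has no numeric
upper limit anywhere in the package — it is represented by a flag, never an
invented number). The default factor set is the nine health-relevant
indicators TH, TDS, NO₂⁻, NO₃⁻, NH₄⁺, Mn, Fe, Cl⁻, SO₄²⁻ (all mg/L); pH, EC
and the major ions are characterized by the traditional tools but excluded
from the fuzzy stage. The factor set and the graded-limit table are both
configurable (drop-in CSV with columns `indicator,unit,S1..S4`).

### Membership construction

The generic trapezoid μ(x; α, β, γ, δ) is 0 outside [α, δ], 1 on [β, γ],
and linear on the ramps. The per-grade memberships used in production are
the adjacent-interval special case: between consecutive limits S_j and
S_{j+1}, grade j falls linearly 1 → 0 while grade j+1 rises 0 → 1, so the
two are complementary and every membership row sums to exactly 1 with at
most two nonzero, adjacent entries. Equivalent explicit trapezoids
(`grade_trapezoids`) are exposed for cross-checking: grade I is the left
shoulder (−∞, −∞, S1, S2), interior grades are tents
(S_{j−1}, S_j, S_j, S_{j+1}), grade V is the right step (S4, S4, ∞, ∞).

Conventions at the awkward points:

* **Boundary ties.** A value exactly at a limit belongs to the better
  grade's full-membership side: x = S2 is fully grade II, x = S4 fully
  grade IV. Deterministic and health-conservative one grade later (the
  step to grade V triggers strictly above S4).
* **Grade V step.** With no S5 to ramp toward, grade-V membership is a step
  (0 for x ≤ S4, 1 above). This preserves row sums without inventing an
  upper bound; the cost is a membership discontinuity at S4, visible only
  as the mean-grade jump 4 → 5.
* **Zero-width intervals.** Where consecutive limits coincide (ammonium and
  manganese both print S1 = S2), the empty interval is skipped: the shared
  point carries full membership in the more stringent grade, and
  interpolation proceeds from the shared point upward. Rows still sum to 1.
* Negative concentrations are rejected as input errors; any nonnegative
  real is accepted.

### Weighting

Raw weight Wᵢ = Cᵢ / S̄ᵢ with S̄ᵢ the mean of the five class limits. Because
grade V prints no limit, its limit in the mean is taken equal to S4 (the
shared IV/V boundary); the choice is configurable via the `s5` argument of
`class_mean_limit`. Measured concentrations are not capped at S4: an
extreme exceedance should dominate the weight vector, which is what lets a
single far-out-of-standard indicator drag a well toward grade V. Weights
are normalized to the unit simplex; an all-zero weight vector (every
indicator at zero) is undefined and raises. Full precision is kept
internally; reports round to 3 decimals.

### Composition and classification

B = A × R is the ordinary weighted-sum matrix product, not the max–min
fuzzy operator: only the weighted sum reproduces the published worked
example from its printed inputs, and it conserves mass (Σb = 1 whenever
rows sum to 1, each b_m a convex combination). Classification takes the
grade of the maximum composite degree; exact ties resolve to the worse
grade (logged). Printed-value comparisons in tests use one ulp of the
printed 3-decimal precision (1e-3): composing the *rounded* published
inputs reproduces the published composite only to that precision, since
the original computation evidently rounded after composing.

## Traditional characterization

* Descriptive statistics use the sample (n−1) standard deviation
  (configurable `ddof`).
* Scalar rules, all half-open with the boundary in the lower class:
  hardness soft ≤ 75 < moderately hard ≤ 150 < hard ≤ 300 < very hard
  (mg/L CaCO₃); TDS fresh ≤ 1000 < brackish ≤ 10⁴ < saline ≤ 10⁶ < brine
  (mg/L); EC type I ≤ 1500 < type II ≤ 3000 < type III (µS/cm).
* "Neutral" pH is a band 7 ± 0.2 (configurable): monitoring panels whose
  wells read 6.9–7.1 are reported as neutral water, which exact equality
  to 7 would not capture.
* Compliance is flagged per indicator against WHO 2011 or GB 5749-2006
  single limits; pH is a closed range flagged on either side; indicators a
  scheme does not limit are skipped with a logged notice rather than
  treated as unlimited.
* Pearson correlation uses the two-tailed t transform with n−2 degrees of
  freedom (scipy's `pearsonr`), marked `**`/`*` at the 0.01/0.05 levels;
  at least three wells are required and zero-variance columns are reported
  as undefined rather than propagating NaNs. Strength labels: strong
  |r| > 0.7, moderate 0.5–0.7, weak below (the conventional rubric leaves
  0.3–0.5 unnamed; it is folded into "weak" here).

## Piper construction

Concentrations convert to meq/L by the registered equivalent weights
(Ca 20.04, Mg 12.15, Na 22.99, K 39.10, HCO₃ 61.02, Cl 35.45, SO₄ 48.03
mg/meq). Na and K pool on the cation triangle; carbonate is absent from the
target waters, so HCO₃ alone holds the alkalinity pole. Planar layout,
fixed so plots are bit-reproducible: unit-edge equilateral triangles,
cation triangle x ∈ [0, 1] with Ca at the origin, Na+K at (1, 0), Mg at the
apex; anion triangle x ∈ [1.1, 2.1] with HCO₃ lower-left, Cl lower-right,
SO₄ at the apex. The diamond point is the intersection of the 60°
projection up-right from the cation point and the 120° projection up-left
from the anion point; it depends only on the alkali share p = (Na+K)% and
strong-acid share q = (SO₄+Cl)%, with closed form
x = (p + q + 1.1)/2, y = (√3/2)(1.1 + q − p). The diamond's corners are
Ca+Mg/HCO₃ left, Na+K/SO₄+Cl right, (p,q) = (1,0) bottom, (0,1) top; in
share space (p, q), Ca-HCO₃ water sits at the origin. Facies labels list
every cation and anion holding ≥ 20 meq% of its triangle (the conventional
dominance cutoff; configurable), ordered by descending share.

## Synthetic panels

The generator emulates the only published statistical description of the
study panel: per-indicator min/max/mean/SD over six wells. Defaults: each
indicator is an independent truncated normal with the published mean and SD,
hard-truncated at the published min/max; four replicates per well — the
quarterly seasonal sampling design — are averaged; six wells; the seed is
recorded in every CSV header. A uniform-on-[min, max] mode is offered
because n = 6 makes the normality assumption weak.

What the generator does **not** emulate: the strong inter-ion correlations
of real groundwater (indicators are drawn independently) and any spatial
structure (wells are exchangeable). Consequently, synthetic panels
under-produce the jointly-extreme wells that real contamination creates; a
passing grade-distribution check on synthetic panels shows the pipeline's
behavior under the published marginals, not a field validation. Replicate
averaging halves the per-well spread, which is also why default panels sit
firmly in the grade II–III band that single draws would occasionally leave.

Planted-grade scenarios draw each indicator uniformly from the part of its
target grade's class interval where that grade's membership strictly
exceeds ½ — (0, S1) for grade I, the upper half (midpoint, S_j) of the
class interval for interior grades, (S4, 2·S4) for grade V — so the planted
grade is the modal grade of every fuzzified row and recovery by the full
pipeline is exact by construction, making the recovery experiment a sharp
correctness check rather than a statistical one. Targets whose class
interval has zero width (ammonium or manganese grade II) are unplantable
and raise.

## Problem sizes and tolerances

Dense-grid membership checks use ~600–1000 points per indicator; the
trapezoid cross-check uses 1000 random concentrations per indicator; the
recovery experiment uses 200 planted wells (50 per plantable grade);
generator calibration is checked on 10,000 single-replicate draws against
the truncated-normal mean obtained by numeric integration (3-standard-error
band). Row sums are asserted to 1e-12, composite sums to 1e-9,
printed-value comparisons to 1e-3 as explained above.

## Known limitations

* The published worked example's relation matrix could not be re-derived
  from published raw data (none exists); it is carried as a fixture, and
  its row order is the canonical nine-indicator order, which does not
  reconcile every row with the published per-indicator ranges.
* The NO₂⁻ graded limits (1.0–10 mg/L) sit orders of magnitude above both
  the measured range and the GB 5749-2006 drinking limit (0.02 mg/L); they
  are stored exactly as printed, without reconciliation, so NO₂⁻ in
  practice always fuzzifies to grade I with a tiny weight.
* Only trapezoidal memberships are implemented; no Gaussian or sigmoidal
  alternatives, no defuzzification beyond maximum membership, and no
  expert-judgment or entropy weighting.
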