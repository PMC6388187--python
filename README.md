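# aquagrade

Fuzzy comprehensive evaluation of groundwater quality for drinking use,
with the traditional hydrochemical toolkit alongside it.

## Who this is for

Hydrogeologists and environmental-health analysts who monitor well panels
and need to grade each well against the five-grade Chinese groundwater
standard **GB/T 14848-93** (I excellent … V very poor). Crisp comparisons
against class limits are brittle near boundaries — a well at 449 mg/L total
hardness is "moderate" and one at 451 mg/L "poor" — so this package grades by
fuzzy membership instead, while also providing the descriptive statistics,
drinking-limit compliance checks, Pearson correlation, and Piper trilinear
facies typing that a conventional hydrochemical study reports.

## The method

For one well with indicators *u₁…uₙ* (defaults: TH, TDS, NO₂⁻, NO₃⁻, NH₄⁺,
Mn, Fe, Cl⁻, SO₄²⁻) and grade set *v₁…v₅*:

1. **Fuzzification.** Each measured concentration *x* is mapped to a
   membership row *rᵢ·* over the five grades by trapezoidal membership
   functions built from the class limits S1–S4: grade I holds full
   membership up to S1 and ramps to 0 at S2; grades II–IV are tents peaking
   at their own limit; grade V is a step above S4. Rows sum to 1 and have at
   most two nonzero, adjacent entries. Stacking rows gives the relation
   matrix **R** (n × 5).
2. **Over-standard weighting.** Each indicator's raw weight is
   *Wᵢ = Cᵢ / S̄ᵢ*, its concentration over the mean of its five class
   limits, then normalized: *aᵢ = Wᵢ / Σ Wᵢ*. Indicators running at or past
   their standards dominate the verdict.
3. **Composition and grading.** **B = A × R** (weighted sum,
   *b_m = Σᵢ aᵢ rᵢm*), and the well receives the grade with the maximum
   composite membership; exact ties resolve to the worse grade.

No per-well raw chemistry is published for the study panel this package is
calibrated against, so a seeded generator draws synthetic panels from
truncated normals matching the published per-indicator min/max/mean/SD,
averaging four seasonal replicates per well, and a planted-grade scenario
builder supports exact recovery experiments.

## Worked example

The published single-well worked example ships with the package
(`examples/worked_example.py`):

```python
import aquagrade as aq

fixtures = aq.load_fixtures()
b = aq.compose(fixtures.q6_weights, fixtures.q6_relation)
print([round(float(v), 3) for v in b], aq.grade_label(aq.classify(b)))
```

prints

```
[0.443, 0.557, 0.0, 0.0, 0.0] II (good)
```

i.e. the well belongs 44% to grade I and 56% to grade II and is graded
**II — good, suitable for drinking**: its composite membership in grades
III–V is zero, so boundary uncertainty is confined to the excellent/good
distinction. `examples/` holds similar short scripts for panel evaluation,
characterization, Piper facies, and the grade-recovery experiment; the
`aquagrade` CLI (`simulate`, `characterize`, `evaluate`, `piper`, `run`)
wraps the same calls for CSV-in/CSV+JSON-out batch use.

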