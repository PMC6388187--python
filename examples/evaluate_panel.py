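"""Fuzzy-evaluate a synthetic well panel.

Draws a six-well panel calibrated to the published per-indicator statistics
(truncated normals, four seasonal replicates averaged per well), fuzzifies
each well against the five-grade groundwater standard, weights indicators
by how close they run to their standards, and grades each well by maximum
composite membership.
"""

import aquagrade as aq

standards = aq.builtin_graded_standard()
panel = aq.generate_panel(aq.default_config(n_wells=6, seed=0))

evaluations = [aq.evaluate_well(sample, standards) for sample in panel]
for ev in evaluations:
    degrees = [round(float(v), 3) for v in ev.degrees]
    print(f"{ev.well_id}: B = {degrees} -> grade {ev.label}")

dist = aq.grade_distribution(evaluations)
print("grade distribution (%):",
      {aq.standards.ROMAN[g]: round(p, 2) for g, p in dist.items() if p > 0})
print("(each B row sums to 1; the well belongs most strongly to the grade")
print(" holding the largest composite membership)")
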