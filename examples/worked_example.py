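"""Reproduce the published single-well worked example.

Composes the published well-Q6 weight vector with its published fuzzy
relation matrix and grades the result by maximum membership.  The two
leading composite degrees are the well's membership in quality grades I
(excellent) and II (good); the grade with the larger degree wins.
"""

import aquagrade as aq

fixtures = aq.load_fixtures()
b = aq.compose(fixtures.q6_weights, fixtures.q6_relation)
grade = aq.classify(b)

print("composite membership B =", [round(float(v), 3) for v in b])
print("assigned grade:", aq.grade_label(grade))
print("(grade II wins because", round(float(b[1]), 3), "is the largest degree:")
print(" the well is good-quality drinking water, with substantial")
print(" grade-I character but no membership in grades III-V)")
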