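"""Piper trilinear coordinates and hydrochemical facies for a panel.

Converts each well's major ions to meq/L, computes the cation/anion
triangle percentages and the diamond projection, and names the water type
from the ions holding at least 20% of their triangle's milliequivalents.
"""

import aquagrade as aq

panel = aq.generate_panel(aq.default_config(n_wells=6, seed=0))

labels = []
for sample in panel:
    shares = aq.ion_percentages(sample)
    coords = aq.piper_coordinates(shares)
    label = aq.classify_facies(shares)
    labels.append(label)
    c = {k: round(v, 1) for k, v in shares.cation_pct.items()}
    a = {k: round(v, 1) for k, v in shares.anion_pct.items()}
    print(f"{sample.well_id}: cations {c} anions {a} -> {label}")

print("facies distribution (%):",
      {k: round(v, 2) for k, v in aq.facies_distribution(labels).items()})
print("(Ca-HCO3 water is the classic shallow carbonate-dissolution signature;")
print(" a second token appears when another ion passes the 20 meq% cutoff)")
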