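"""Traditional hydrochemical characterization of a panel.

Prints descriptive statistics in the standard Min/Max/Mean/SD layout,
applies the scalar pH / conductivity / hardness / salinity rules to the
panel means, flags each well against the WHO 2011 drinking limits, and
shows the strongest Pearson correlations.
"""

import aquagrade as aq

panel = aq.generate_panel(aq.default_config(n_wells=6, seed=0))

stats = aq.summary_stats(panel)
print(stats.round(2).to_string())

mean = stats["Mean"]
print("\npanel means classify as:",
      aq.classify_ph(mean["pH"]), "pH,",
      aq.classify_ec(mean["EC"]), "salt enrichment,",
      aq.classify_hardness(mean["TH"]) + ",",
      aq.classify_tds(mean["TDS"]), "water")

who = aq.builtin_drinking_limits("WHO2011")
for sample in panel[:2]:
    flags = aq.compliance_flags(sample, who)
    exceeded = [c for c, f in flags.items() if f == "exceeds"]
    print(f"{sample.well_id}: exceeds WHO 2011 limits for {exceeded or 'nothing'}")

corr = aq.pearson_matrix(panel)
r = corr.r.loc["TDS", "EC"]
print(f"\nPearson r(TDS, EC) = {r:.3f} ({aq.CorrelationMatrix.strength(r)};"
      " the synthetic generator draws indicators independently, so real-world"
      " ion correlations are not reproduced)")
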