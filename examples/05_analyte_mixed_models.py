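"""Plasma analyte preprocessing and mixed-model differential abundance.

Out-of-range wells are imputed with the per-plate min/max of in-range
calculated concentrations, duplicate wells averaged, and noisy analytes
(>10% out of range) flagged.  Each analyte's log2 concentration is then
modelled with a linear mixed model: karyotype + age + sex as fixed effects
and sample source as a random intercept, BH-corrected across analytes.
"""

from dsimmune import markers, synth

config = synth.default_config(seed=1)
parts = synth.generate_participants(config)
raw = synth.generate_analyte_table(parts, config)

collapsed, report = markers.preprocess_analytes(raw)
flagged = report[report["flagged"]]["analyte"].tolist()
print(f"analytes flagged for >10% out-of-range values: {flagged or 'none'}")

da = markers.differential_abundance(collapsed, parts)
cols = ["analyte", "log2fc", "p", "q", "significant"]
print(da.sort_values("q")[cols].round(4).to_string(index=False))

effects = markers.age_karyotype_effects(collapsed, parts)
print("\nkaryotype-vs-age decomposition:")
print(effects[["analyte", "log2fc", "age_slope", "classification"]]
      .round(4).to_string(index=False))
# log2fc is the T21-vs-D21 effect on log2 pg/mL after age/sex adjustment;
# 'T21 only' marks analytes elevated by trisomy without an age trend.
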