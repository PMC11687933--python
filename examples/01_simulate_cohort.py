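"""Generate a synthetic T21/D21 cohort and inspect its structure.

The generator emulates a trisomy-21 research cohort with euploid controls:
participant metadata with condition prevalences, a bead-array MFI matrix
with ground-truth positivity, censored plasma analytes, ISG expression,
cell-cluster compositions, and a small treatment trial.
"""

from dsimmune import synth

config = synth.default_config(seed=1)
bundle = synth.generate_cohort(config)

parts = bundle.participants
print(f"participants: {len(parts)} "
      f"({(parts.karyotype == 'T21').sum()} T21, "
      f"{(parts.karyotype == 'D21').sum()} D21)")
print(f"AITD prevalence in T21: "
      f"{parts.loc[parts.karyotype == 'T21', 'AITD'].mean():.1%}")
print(f"antigen array: {bundle.antigen_array.mfi.shape[0]} samples x "
      f"{bundle.antigen_array.mfi.shape[1]} antigens")
print(f"analyte wells: {len(bundle.analytes)} rows "
      f"({bundle.analytes['flag'].ne('in').mean():.1%} out of range)")
print(f"trial: {bundle.trial['participant_id'].nunique()} participants x "
      f"weeks {sorted(map(int, bundle.trial['week'].unique()))}")
# Every table is deterministic given the seed; each draws from its own
# random substream, so regenerating one never changes the others.
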