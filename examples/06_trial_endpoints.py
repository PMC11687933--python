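"""Longitudinal trial endpoints: score decreases and ULN-based response.

The synthetic trial follows 10 participants at weeks 0/2/8/16 under a
treatment that lowers IFN scores, cytokine scores and thyroid autoantibody
titers, with two immune-trigger spikes (a vaccination before the week-8
draw, an infection before week 16) that transiently elevate the scores.
"""

import pandas as pd

from dsimmune import scores, synth, trial

config = synth.default_config(seed=1)
series = synth.generate_trial_series(config)

for week in (2, 8, 16):
    n_dec, n_eval = trial.count_decreasing(series, "IFN_score", week)
    print(f"week {week:>2}: {n_dec} of {n_eval} participants decreased "
          f"their IFN score from baseline")

tpo = trial.uln_response(series, trial.ThresholdRule("anti_TPO", 60.0))
print(f"\nanti-TPO: {tpo['n_above_at_baseline']} of 10 above the "
      f"60 U/mL ULN at baseline; "
      f"{len(tpo['decreased_all_weeks'])} decreased at both weeks 8 and 16; "
      f"{len(tpo['crossed_below_uln'])} crossed below the ULN on treatment")

# paired Wilcoxon tests across endpoints, BH-corrected
pairs = {}
for meas in sorted(series["measurement"].unique()):
    wide = series[series.measurement == meas].pivot(
        index="participant_id", columns="week", values="value")
    pairs[meas] = (wide[0].to_numpy(), wide[8].to_numpy())
paired = scores.compare_paired(pairs)
print("\nbaseline vs week 8 (paired Wilcoxon, BH across endpoints):")
print(paired.round(4).to_string(index=False))

log = pd.DataFrame({
    "participant_id": ["P01", "P04"], "event": ["URI", "URI"],
    "grade": [1, 1], "attribution": ["possibly", "possibly"],
    "serious": [False, False]})
safety = trial.evaluate_safety_rule(log, n_participants=10)
print(f"\nsafety rule (<=2 definitely-attributable SAEs): "
      f"{'PASS' if safety['pass'] else 'FAIL'} "
      f"({safety['n_definite_saes']} definite SAEs)")
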