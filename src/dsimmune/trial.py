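"""Longitudinal trial endpoint evaluation.

Operates on a long-format time-series of (participant, week, measurement,
value): change from baseline per participant, counts of participants with
strictly decreased values, autoantibody response against an upper limit of
normal (ULN, e.g. 60 U/mL anti-TPO, 4 IU/mL anti-TG), and the protocol
safety rule tolerating at most two serious adverse events definitely
attributable to treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ThresholdRule",
    "change_from_baseline",
    "count_decreasing",
    "uln_response",
    "evaluate_safety_rule",
]

ATTRIBUTIONS = ("unrelated", "possibly", "probably", "definitely")


@dataclass(frozen=True)
class ThresholdRule:
    """Upper limit of normal for a measurement; values strictly above are
    abnormal."""

    measurement: str
    uln: float


def _series_for(series: pd.DataFrame, measurement: str) -> pd.DataFrame:
    sub = series[series["measurement"] == measurement]
    if sub.empty:
        known = sorted(series["measurement"].unique())
        raise ConfigurationError(
            f"unknown measurement {measurement!r}; available: {known}"
        )
    return sub


def change_from_baseline(series: pd.DataFrame, measurement: str, week: int
                         ) -> tuple[pd.Series, list]:
    """Per-participant delta = value(week) - value(0).

    Participants missing either visit are excluded from the deltas and
    returned in the missing report.
    """
    sub = _series_for(series, measurement)
    wide = sub.pivot_table(index="participant_id", columns="week",
                           values="value", aggfunc="first")
    missing = []
    if 0 not in wide.columns:
        missing = list(wide.index)
        return pd.Series(dtype=float), missing
    if week not in wide.columns:
        return pd.Series(dtype=float), list(wide.index)
    ok = wide[0].notna() & wide[week].notna()
    missing = list(wide.index[~ok])
    deltas = (wide.loc[ok, week] - wide.loc[ok, 0]).rename("delta")
    return deltas, missing


def count_decreasing(series: pd.DataFrame, measurement: str, week: int
                     ) -> tuple[int, int]:
    """(n with strictly negative delta, n evaluable) at the given week.

    Ties (delta exactly 0) count as not decreased.
    """
    deltas, _ = change_from_baseline(series, measurement, week)
    if len(deltas) == 0:
        raise ConfigurationError(
            f"no evaluable participants for {measurement!r} at week {week}"
        )
    return int((deltas < 0).sum()), int(len(deltas))


def uln_response(series: pd.DataFrame, rule: ThresholdRule,
                 weeks: Sequence[int] = (8, 16)) -> dict:
    """Autoantibody response against an upper limit of normal.

    Reports the participants strictly above the ULN at baseline; of those,
    how many show a strict decrease at each requested week (and at all
    requested weeks jointly, requiring every visit to be present); and how
    many crossed below the ULN at any on-treatment visit.
    """
    sub = _series_for(series, rule.measurement)
    wide = sub.pivot_table(index="participant_id", columns="week",
                           values="value", aggfunc="first")
    if 0 not in wide.columns:
        raise ConfigurationError("series has no baseline (week 0) values")
    above = wide.index[wide[0] > rule.uln]
    decreased_by_week = {}
    for w in weeks:
        if w not in wide.columns:
            decreased_by_week[w] = []
            continue
        d = wide.loc[above, w] - wide.loc[above, 0]
        decreased_by_week[w] = list(d.index[d < 0])
    all_weeks = set(above)
    for w in weeks:
        all_weeks &= set(decreased_by_week[w])
    on_treatment = [w for w in wide.columns if w > 0]
    crossed = [
        pid for pid in above
        if (wide.loc[pid, on_treatment] < rule.uln).any()
    ]
    return {
        "measurement": rule.measurement,
        "uln": rule.uln,
        "above_at_baseline": list(above),
        "n_above_at_baseline": len(above),
        "decreased_by_week": decreased_by_week,
        "decreased_all_weeks": sorted(all_weeks),
        "crossed_below_uln": crossed,
    }


def evaluate_safety_rule(log: pd.DataFrame, n_participants: int,
                         max_definite_saes: int = 2) -> dict:
    """Protocol safety rule: pass iff at most ``max_definite_saes`` serious
    adverse events are definitely attributable to treatment.

    ``log`` columns: participant_id, event, grade (1-5), attribution
    (unrelated/possibly/probably/definitely), serious (bool).  Also returns
    an attribution x seriousness tabulation.
    """
    if len(log) == 0:
        return {"pass": True, "n_definite_saes": 0,
                "n_participants": n_participants,
                "tabulation": pd.DataFrame()}
    bad_attr = set(log["attribution"]) - set(ATTRIBUTIONS)
    if bad_attr:
        raise ConfigurationError(f"unknown attribution values: {sorted(bad_attr)}")
    if not log["grade"].between(1, 5).all():
        raise ConfigurationError("adverse-event grades must be within 1-5")
    serious = log["serious"].astype(bool)
    definite_saes = int((serious & (log["attribution"] == "definitely")).sum())
    tab = (
        log.assign(serious=serious)
        .groupby(["attribution", "serious"]).size().rename("n_events")
        .reset_index()
    )
    return {
        "pass": definite_saes <= max_definite_saes,
        "n_definite_saes": definite_saes,
        "n_participants": n_participants,
        "tabulation": tab,
    }
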