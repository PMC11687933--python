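"""Bead-array autoantibody analysis.

Raw bead-array MFI carries a strong sample-specific background (total IgG,
plasma quality, bead coupling).  The pipeline removes it by standardizing
each sample (reaction) to median-absolute-deviation units:

    MADs = (MFI - median_sample(MFI)) / MAD_sample(MFI)

Positivity for each antigen is then called against the empirical 90th
percentile of the euploid (D21) control samples, antigens detected in too
few samples are excluded, and over-representation of positivity in the T21
group (or within-T21 condition subgroups) is tested with Fisher's exact
test under Benjamini-Hochberg FDR control.

Two scalar assays complete the module: the anti-TPO index (signal normalized
between negative and positive controls, positive above the 95th percentile
of healthy controls) and the ANA OD ratio (positive at >= 2.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayInvalidError, ConfigurationError, DegenerateSampleError
from ._stats import bh_adjust, quantile

__all__ = [
    "MadMatrix",
    "PositivityTable",
    "EnrichmentResult",
    "ScalarAssayResult",
    "qc_bead_counts",
    "mad_transform",
    "call_positivity",
    "filter_detected",
    "fisher_enrichment",
    "condition_association",
    "positivity_burden",
    "tpo_index",
    "ana_call",
]


@dataclass(frozen=True)
class MadMatrix:
    """Per-sample MAD-standardized array values (unitless)."""

    values: pd.DataFrame  # samples x antigens
    sample_median: pd.Series
    sample_mad: pd.Series
    mad_constant: float = 1.0


@dataclass(frozen=True)
class PositivityTable:
    """Boolean positivity calls with the control-percentile thresholds used."""

    calls: pd.DataFrame  # samples x antigens, bool
    thresholds: pd.Series  # per-antigen threshold in MAD units
    percentile: float = 0.90
    removed_antigens: tuple = ()


@dataclass(frozen=True)
class EnrichmentResult:
    """One antigen's 2x2 Fisher test: a,b = positive/negative in the index
    group, c,d = positive/negative in the reference group."""

    antigen: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = np.nan
    condition: Optional[str] = None


@dataclass(frozen=True)
class ScalarAssayResult:
    sample_id: str
    assay: str  # "TPO" or "ANA"
    index: float
    call: bool
    threshold: float


def qc_bead_counts(mfi: pd.DataFrame, bead_count: pd.DataFrame,
                   min_beads: int = 20) -> pd.DataFrame:
    """Mask MFI wells whose bead count falls below the QC minimum."""
    return mfi.where(bead_count >= min_beads)


def mad_transform(mfi: pd.DataFrame, mad_constant: float = 1.0) -> MadMatrix:
    """Standardize each sample's MFI values to MAD units.

    ``mad_constant`` rescales the raw median absolute deviation (1.0 keeps
    the raw MAD; 1.4826 would make it a consistent sigma estimator under
    normality).  Samples with fewer than 3 finite values or zero spread are
    rejected, because their scale is undefined.
    """
    finite = mfi.notna().sum(axis=1)
    too_few = finite[finite < 3]
    if len(too_few):
        raise DegenerateSampleError(
            f"samples with <3 finite MFI values: {list(too_few.index)}"
        )
    med = mfi.median(axis=1, skipna=True)
    mad = (mfi.sub(med, axis=0)).abs().median(axis=1, skipna=True) * mad_constant
    zero = mad[mad == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"zero MAD (constant MFI) for samples: {list(zero.index)}"
        )
    values = mfi.sub(med, axis=0).div(mad, axis=0)
    return MadMatrix(values=values, sample_median=med, sample_mad=mad,
                     mad_constant=mad_constant)


def call_positivity(mad: MadMatrix, control_ids: Sequence[str],
                    percentile: float = 0.90,
                    quantile_method: str = "linear") -> PositivityTable:
    """Call positivity as strictly exceeding the control percentile.

    Per antigen, the threshold is the empirical ``percentile`` of the control
    (euploid) samples' MAD values; a sample is positive only when its value
    is strictly greater than the threshold.
    """
    control_ids = list(control_ids)
    missing = set(control_ids) - set(mad.values.index)
    if missing:
        raise ConfigurationError(f"unknown control samples: {sorted(missing)}")
    if len(control_ids) < 5:
        raise ConfigurationError(
            f"need >=5 control samples to set thresholds, got {len(control_ids)}"
        )
    ctrl = mad.values.loc[control_ids]
    thresholds = ctrl.apply(
        lambda col: quantile(col, percentile, method=quantile_method)
    )
    calls = mad.values.gt(thresholds, axis=1)
    return PositivityTable(calls=calls, thresholds=thresholds,
                           percentile=percentile)


def filter_detected(table: PositivityTable, min_samples: int = 18) -> PositivityTable:
    """Drop antigens called positive in fewer than ``min_samples`` samples."""
    counts = table.calls.sum(axis=0)
    keep = counts[counts >= min_samples].index
    removed = tuple(c for c in table.calls.columns if c not in set(keep))
    return PositivityTable(
        calls=table.calls[list(keep)],
        thresholds=table.thresholds[list(keep)],
        percentile=table.percentile,
        removed_antigens=table.removed_antigens + removed,
    )


def _fisher_or(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with Haldane 0.5 correction at zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_test(a: int, b: int, c: int, d: int,
                alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on one 2x2 table: (odds_ratio, p).

    The odds ratio is the cross-product with Haldane correction at zero
    cells; the p-value conditions on both margins (hypergeometric).
    """
    p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue
    return _fisher_or(a, b, c, d), float(p)


def fisher_enrichment(table: PositivityTable, groups: pd.Series,
                      index_group: str = "T21", reference_group: str = "D21",
                      alternative: str = "two-sided") -> pd.DataFrame:
    """Per-antigen Fisher's exact test of positivity, index vs reference group.

    Returns a DataFrame (antigen, a, b, c, d, odds_ratio, p, q) with BH
    q-values across the tested antigens.
    """
    groups = groups.reindex(table.calls.index)
    in_idx = groups == index_group
    in_ref = groups == reference_group
    if in_idx.sum() == 0 or in_ref.sum() == 0:
        raise ConfigurationError(
            f"both groups must be non-empty (index={int(in_idx.sum())}, "
            f"reference={int(in_ref.sum())})"
        )
    rows = []
    for antigen in table.calls.columns:
        pos = table.calls[antigen]
        a = int((pos & in_idx).sum())
        b = int((~pos & in_idx).sum())
        c = int((pos & in_ref).sum())
        d = int((~pos & in_ref).sum())
        orr, p = fisher_test(a, b, c, d, alternative=alternative)
        rows.append((antigen, a, b, c, d, orr, p))
    out = pd.DataFrame(
        rows, columns=["antigen", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    out["q"] = bh_adjust(out["p"])
    return out


def condition_association(table: PositivityTable, participants: pd.DataFrame,
                          conditions: Sequence[str], karyotype: str = "T21",
                          min_cases: int = 5,
                          alternative: str = "two-sided") -> tuple[pd.DataFrame, list]:
    """Within one karyotype, test antigen positivity against condition status.

    Conditions with fewer than ``min_cases`` cases among the analyzed samples
    are skipped and reported.  BH correction is applied across all tested
    (antigen, condition) pairs.
    """
    meta = participants.set_index("sample_id").reindex(table.calls.index)
    in_k = meta["karyotype"] == karyotype
    calls = table.calls.loc[in_k]
    meta = meta.loc[in_k]
    rows, skipped = [], []
    for cond in conditions:
        cases = meta[cond].astype(bool)
        if int(cases.sum()) < min_cases:
            skipped.append((cond, int(cases.sum())))
            continue
        for antigen in calls.columns:
            pos = calls[antigen]
            a = int((pos & cases).sum())
            b = int((~pos & cases).sum())
            c = int((pos & ~cases).sum())
            d = int((~pos & ~cases).sum())
            orr, p = fisher_test(a, b, c, d, alternative=alternative)
            rows.append((antigen, cond, a, b, c, d, orr, p))
    out = pd.DataFrame(
        rows,
        columns=["antigen", "condition", "a", "b", "c", "d", "odds_ratio", "p"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out, skipped


def positivity_burden(table: PositivityTable,
                      antigen_subset: Optional[Sequence[str]] = None
                      ) -> tuple[pd.Series, pd.Series]:
    """Per-sample count of positive antigens, plus the >=k fraction curve.

    Returns ``(burden, at_least)`` where ``burden[sample]`` is the number of
    positive antigens in the subset and ``at_least[k]`` the fraction of
    samples positive for at least k antigens (k = 1..max burden).
    """
    if antigen_subset is None:
        antigen_subset = list(table.calls.columns)
    unknown = set(antigen_subset) - set(table.calls.columns)
    if unknown:
        raise ConfigurationError(f"unknown antigens: {sorted(unknown)}")
    burden = table.calls[list(antigen_subset)].sum(axis=1)
    kmax = int(burden.max()) if len(burden) else 0
    at_least = pd.Series(
        {k: float((burden >= k).mean()) for k in range(1, kmax + 1)}, dtype=float
    )
    return burden, at_least


def tpo_index(sample_signal: float, neg_signal: float, pos_signal: float,
              control_values: Sequence[float],
              percentile: float = 0.95,
              sample_id: str = "") -> ScalarAssayResult:
    """Anti-TPO index: (sample - negative) / (positive - negative) control
    signals, called positive above the control percentile (default 95th)."""
    if not pos_signal > neg_signal:
        raise AssayInvalidError(
            "positive control signal must exceed negative control signal"
        )
    index = (sample_signal - neg_signal) / (pos_signal - neg_signal)
    threshold = quantile(np.asarray(control_values, dtype=float), percentile)
    return ScalarAssayResult(sample_id=sample_id, assay="TPO", index=index,
                             call=index > threshold, threshold=threshold)


def ana_call(od_sample: float, od_negative: float, cutoff: float = 2.1,
             sample_id: str = "") -> ScalarAssayResult:
    """ANA status from the OD ratio: positive at ratio >= cutoff (2.1)."""
    if od_negative <= 0:
        raise AssayInvalidError("negative-control OD must be positive")
    ratio = od_sample / od_negative
    return ScalarAssayResult(sample_id=sample_id, assay="ANA", index=ratio,
                             call=ratio >= cutoff, threshold=cutoff)
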