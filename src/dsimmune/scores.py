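"""Composite interferon and cytokine scores against a reference cohort.

The scoring pipeline is: (1) residualize each feature (gene expression or
log2 analyte concentration) on nuisance covariates — age, sex, batch/sample
source — while keeping the group term of interest in the fit so group
differences are preserved; (2) standardize each feature to Z-scores against
the euploid reference group's mean and standard deviation ("reference" mode)
or across the compared sample set itself ("internal" mode); (3) sum Z-scores
over a feature panel.  The interferon score uses a panel of
interferon-stimulated genes selected from a differential-expression table
(fold-change >= 1.5, q < 0.1, excluding the chromosome-21-encoded IFNAR2,
MX1 and MX2); the cytokine score sums TNF-a, IL-6, CRP and IP-10.

Group comparisons are reported as median differences with Mann-Whitney U
p-values, and longitudinal paired comparisons as two-sided Wilcoxon
signed-rank tests with Benjamini-Hochberg correction across endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from ._stats import bh_adjust

__all__ = [
    "AdjustmentModel",
    "ReferenceStats",
    "ISGPanel",
    "CompositeScoreTable",
    "CYTOKINE_PANEL",
    "CHR21_ISGS",
    "fit_covariate_adjustment",
    "apply_adjustment",
    "reference_zscores",
    "internal_zscores",
    "select_isg_panel",
    "composite_score",
    "compare_groups",
    "paired_wilcoxon",
    "compare_paired",
]

CYTOKINE_PANEL = ("TNF-a", "IL-6", "CRP", "IP-10")
CHR21_ISGS = ("IFNAR2", "MX1", "MX2")


def _nuisance_design(covariates: pd.DataFrame,
                     levels: Optional[dict] = None) -> tuple[pd.DataFrame, dict]:
    """Numeric columns pass through; categoricals become treatment dummies.

    ``levels`` pins the category ordering so a model fitted on one cohort can
    be applied to another with the same encoding.
    """
    cols, out_levels = [], {}
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols.append(col.astype(float).rename(name))
        else:
            lv = (levels or {}).get(name) or sorted(col.astype(str).unique())
            out_levels[name] = list(lv)
            for level in lv[1:]:  # first level is the reference
                cols.append(
                    (col.astype(str) == level).astype(float).rename(f"{name}[{level}]")
                )
    design = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=covariates.index)
    return design, out_levels


@dataclass(frozen=True)
class AdjustmentModel:
    """Per-feature nuisance coefficients with centering reference values."""

    coefficients: pd.DataFrame  # features x nuisance design columns
    reference: pd.Series  # nuisance design column means at fit time
    covariate_columns: tuple
    levels: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReferenceStats:
    """Reference-group mean/sd per feature; zero-variance features rejected."""

    mean: pd.Series
    sd: pd.Series
    rejected: tuple = ()


@dataclass(frozen=True)
class ISGPanel:
    genes: tuple
    min_fc: float = 1.5
    q_max: float = 0.1
    excluded_chr21: tuple = CHR21_ISGS


@dataclass(frozen=True)
class CompositeScoreTable:
    """Per-sample composite score with its per-feature Z breakdown."""

    values: pd.Series
    breakdown: pd.DataFrame
    score_type: str = "IFN"
    mode: str = "reference"


def fit_covariate_adjustment(values: pd.DataFrame, covariates: pd.DataFrame,
                             keep: Optional[pd.Series] = None) -> AdjustmentModel:
    """Fit per-feature least squares on nuisance covariates + the kept term.

    ``values`` is samples x features.  The kept grouping term (e.g. karyotype)
    is included in the design so that nuisance coefficients are estimated
    within groups, but only nuisance coefficients are stored for subtraction:
    applying the model never removes group differences.
    """
    covariates = covariates.reindex(values.index)
    if covariates.isna().any().any():
        bad = list(covariates.index[covariates.isna().any(axis=1)])
        raise ConfigurationError(f"missing covariates for samples: {bad}")
    nuisance, levels = _nuisance_design(covariates)
    parts = [pd.Series(1.0, index=values.index, name="Intercept"), nuisance]
    if keep is not None:
        keep_design, _ = _nuisance_design(keep.to_frame(keep.name or "group"))
        parts.append(keep_design)
    design = pd.concat(parts, axis=1)
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by greedy removal
        bad = []
        kept_idx: list[int] = []
        for j in range(x.shape[1]):
            trial = kept_idx + [j]
            if np.linalg.matrix_rank(x[:, trial]) == len(trial):
                kept_idx.append(j)
            else:
                bad.append(design.columns[j])
        raise ConfigurationError(f"design matrix rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, values.to_numpy(float), rcond=None)
    coef = pd.DataFrame(beta.T, index=values.columns, columns=design.columns)
    return AdjustmentModel(
        coefficients=coef[nuisance.columns],
        reference=nuisance.mean(axis=0),
        covariate_columns=tuple(covariates.columns),
        levels=levels,
    )


def apply_adjustment(model: AdjustmentModel, values: pd.DataFrame,
                     covariates: pd.DataFrame) -> pd.DataFrame:
    """Subtract nuisance effects: adjusted = y - B (x - x_ref).

    Samples whose covariates sit at the reference values pass through
    unchanged; group contrasts are preserved because the group term was in
    the fit but is not subtracted.
    """
    covariates = covariates.reindex(values.index)
    missing_cols = set(model.covariate_columns) - set(covariates.columns)
    if missing_cols:
        raise ConfigurationError(f"missing covariate columns: {sorted(missing_cols)}")
    covariates = covariates[list(model.covariate_columns)]
    if covariates.isna().any().any():
        bad = list(covariates.index[covariates.isna().any(axis=1)])
        raise ConfigurationError(f"missing covariates for samples: {bad}")
    nuisance, _ = _nuisance_design(covariates, levels=model.levels)
    nuisance = nuisance.reindex(columns=model.reference.index, fill_value=0.0)
    centered = nuisance - model.reference
    removal = centered.to_numpy(float) @ model.coefficients.T.to_numpy(float)
    return values - pd.DataFrame(removal, index=values.index, columns=model.coefficients.index)


def reference_zscores(adjusted: pd.DataFrame, reference_ids: Sequence[str]
                      ) -> tuple[pd.DataFrame, ReferenceStats]:
    """Z-scores against the reference (euploid control) group's mean and sd."""
    reference_ids = list(reference_ids)
    missing = set(reference_ids) - set(adjusted.index)
    if missing:
        raise ConfigurationError(f"unknown reference samples: {sorted(missing)}")
    if len(reference_ids) < 3:
        raise ConfigurationError("need >=3 reference samples")
    ref = adjusted.loc[reference_ids]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    rejected = tuple(sd.index[(sd == 0) | sd.isna()])
    keep = [c for c in adjusted.columns if c not in set(rejected)]
    z = (adjusted[keep] - mu[keep]) / sd[keep]
    return z, ReferenceStats(mean=mu[keep], sd=sd[keep], rejected=rejected)


def internal_zscores(values: pd.DataFrame) -> pd.DataFrame:
    """Z-scores computed across the supplied sample set itself."""
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ConfigurationError(
            f"zero variance features: {list(sd.index[sd == 0])}"
        )
    return (values - values.mean(axis=0)) / sd


def select_isg_panel(de: pd.DataFrame, candidates: Sequence[str],
                     chr21_genes: Sequence[str] = CHR21_ISGS,
                     min_fc: float = 1.5, q_max: float = 0.1) -> ISGPanel:
    """Panel = candidates with fold-change >= min_fc, q < q_max, not chr21.

    ``de`` must carry ``gene`` plus either ``fold_change`` or ``log2fc``
    (converted as 2**log2fc) and ``q`` columns.
    """
    de = de.set_index("gene") if "gene" in de.columns else de
    missing = [g for g in candidates if g not in de.index]
    if missing:
        raise ConfigurationError(f"candidates absent from DE table: {missing}")
    if "fold_change" in de.columns:
        fc = de["fold_change"]
    elif "log2fc" in de.columns:
        fc = 2.0 ** de["log2fc"]
    else:
        raise ConfigurationError("DE table needs a fold_change or log2fc column")
    chr21 = set(chr21_genes)
    genes = tuple(
        g for g in candidates
        if g not in chr21 and fc[g] >= min_fc and de.loc[g, "q"] < q_max
    )
    return ISGPanel(genes=genes, min_fc=min_fc, q_max=q_max,
                    excluded_chr21=tuple(chr21_genes))


def composite_score(z: pd.DataFrame, features: Sequence[str],
                    score_type: str = "IFN",
                    mode: str = "reference") -> CompositeScoreTable:
    """Per-sample sum of Z-scores over the panel features."""
    features = list(features)
    missing = set(features) - set(z.columns)
    if missing:
        raise ConfigurationError(f"panel features missing from Z matrix: {sorted(missing)}")
    breakdown = z[features]
    return CompositeScoreTable(values=breakdown.sum(axis=1),
                               breakdown=breakdown,
                               score_type=score_type, mode=mode)


def compare_groups(group1, group2, alternative: str = "two-sided",
                   exact_max_n: int = 12) -> dict:
    """Median difference (group2 - group1) with a Mann-Whitney U p-value.

    ``alternative`` states the hypothesis for group1 relative to group2
    ("less" means group1 tends below group2).
    The exact U distribution is used when both groups have at most
    ``exact_max_n`` observations and no ties straddle the groups; otherwise
    the normal approximation with midrank tie correction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n
                         and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return {
        "median_difference": float(np.median(y) - np.median(x)),
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
    }


def paired_wilcoxon(before, after, alternative: str = "two-sided",
                    exact_max_n: int = 15) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired values, zeros dropped.

    Exact null distribution for up to ``exact_max_n`` non-zero differences
    (when untied); all-zero differences give p = 1 with a warning.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ConfigurationError("paired series must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p set to 1")
        return {"n": 0, "statistic": np.nan, "p": 1.0, "method": "degenerate"}
    ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= exact_max_n and not ties) else "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox",
                         alternative=alternative, method=method)
    return {"n": int(nonzero.size), "statistic": float(res.statistic),
            "p": float(res.pvalue), "method": method}


def compare_paired(pairs: dict, alternative: str = "two-sided") -> pd.DataFrame:
    """Paired Wilcoxon tests across a family of endpoints, BH-corrected.

    ``pairs`` maps endpoint name -> (baseline values, follow-up values),
    aligned per participant.
    """
    rows = []
    for name, (before, after) in pairs.items():
        res = paired_wilcoxon(before, after, alternative=alternative)
        rows.append((name, res["n"], res["statistic"], res["p"]))
    out = pd.DataFrame(rows, columns=["endpoint", "n", "statistic", "p"])
    out["q"] = bh_adjust(out["p"])
    return out
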