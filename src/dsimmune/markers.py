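"""Plasma analyte preprocessing and mixed-model differential abundance.

Multiplex immunoassay concentrations arrive per well with plate/batch ids
and detection-range flags.  Preprocessing replaces out-of-range wells with
the per-plate minimum (below range) or maximum (above range) of the in-range
calculated concentrations for that analyte, averages duplicate wells, and
flags analytes with more than 10% of values out of range.

Differential abundance is a linear mixed model per analyte: log2
concentration on group (karyotype or clinical subgroup) with age and sex as
fixed covariates and sample source as a random intercept (REML).  Wald tests
on the fixed effects are BH-corrected across analytes at q < 0.1.  A
companion decomposition contrasts, per analyte, the karyotype effect with
the within-T21 age effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError
from ._stats import bh_adjust
from .composition import mask_outliers

__all__ = [
    "LMMFit",
    "preprocess_analytes",
    "mask_outliers_markers",
    "fit_mixed_model",
    "differential_abundance",
    "age_karyotype_effects",
]


@dataclass(frozen=True)
class LMMFit:
    """Random-intercept linear mixed model fit on the log2 pg/mL scale."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2_u: float  # random-intercept (source) variance
    sigma2_e: float  # residual variance
    loglike: float
    n: int
    method: str  # "reml" or "ols" (single-source fallback)


def preprocess_analytes(raw: pd.DataFrame, flag_threshold: float = 0.10
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute out-of-range wells, collapse duplicates, flag noisy analytes.

    ``raw`` is long format with columns sample_id, analyte, plate, source,
    well, value (NaN when out of range) and flag in {in, below, above}.
    Below-range wells take the per-(plate, analyte) minimum of in-range
    values, above-range wells the maximum.  Zero or negative calculated
    concentrations are treated as below range so log2 stays defined.
    Returns ``(collapsed, analyte_report)``: one row per sample-analyte with
    the replicate-mean concentration, and a per-analyte report with the
    out-of-range fraction and flag.
    """
    df = raw.copy()
    required = {"sample_id", "analyte", "plate", "well", "value", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"analyte table missing columns: {sorted(missing)}")
    bad = df["flag"].eq("in") & (df["value"] <= 0)
    df.loc[bad, "flag"] = "below"
    df.loc[bad, "value"] = np.nan

    dropped = []
    out_frames = []
    for (analyte, plate), sub in df.groupby(["analyte", "plate"]):
        in_range = sub.loc[sub["flag"] == "in", "value"]
        if in_range.empty:
            dropped.append((analyte, plate, len(sub)))
            continue
        lo, hi = float(in_range.min()), float(in_range.max())
        sub = sub.copy()
        sub.loc[sub["flag"] == "below", "value"] = lo
        sub.loc[sub["flag"] == "above", "value"] = hi
        out_frames.append(sub)
    if not out_frames:
        raise ConfigurationError("no analyte has any in-range values")
    imputed = pd.concat(out_frames, ignore_index=True)

    group_cols = ["analyte", "sample_id", "plate"]
    if "source" in imputed.columns:
        group_cols.append("source")
    collapsed = (
        imputed.groupby(group_cols, as_index=False)
        .agg(value=("value", "mean"), n_wells=("well", "nunique"),
             n_out_of_range=("flag", lambda f: int((f != "in").sum())))
    )

    oor = df.assign(out=df["flag"] != "in").groupby("analyte")["out"].mean()
    report = pd.DataFrame({
        "analyte": oor.index,
        "fraction_out_of_range": oor.to_numpy(),
        "flagged": (oor > flag_threshold).to_numpy(),
    }).reset_index(drop=True)
    report.attrs["dropped_plates"] = dropped
    return collapsed, report


def mask_outliers_markers(values, karyotype, k: float = 3.0):
    """3x-IQR fencing per karyotype group (shared rule with composition)."""
    return mask_outliers(values, karyotype, k=k)


def fit_mixed_model(y, design: pd.DataFrame, groups,
                    reml: bool = True) -> LMMFit:
    """Random-intercept mixed model of log2 concentration.

    ``design`` must contain an intercept column; ``groups`` is the sample
    source.  With a single source the model is unidentifiable, so the fit
    falls back to OLS with a warning.  At a zero variance-component estimate
    the fixed effects coincide with OLS.
    """
    y = np.asarray(y, dtype=float)
    x = design.to_numpy(float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ConfigurationError("design matrix is rank deficient")
    groups = np.asarray(groups)
    n_sources = len(np.unique(groups))
    names = list(design.columns)
    if n_sources < 2:
        warnings.warn("single sample source; falling back to fixed-effects OLS")
        res = sm.OLS(y, x).fit()
        return LMMFit(
            params=pd.Series(res.params, index=names),
            bse=pd.Series(res.bse, index=names),
            pvalues=pd.Series(res.pvalues, index=names),
            sigma2_u=0.0, sigma2_e=float(res.scale),
            loglike=float(res.llf), n=len(y), method="ols",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        model = sm.MixedLM(y, x, groups=groups)
        res = model.fit(reml=reml)
        bse = np.asarray(res.bse_fe, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)[: len(names)]
        sigma2_u = float(np.asarray(res.cov_re)[0, 0])
    if not np.all(np.isfinite(bse)):
        # at the sigma2_u = 0 boundary the mixed-model information matrix
        # can be singular; the model degenerates to OLS, so use its inference
        ols = sm.OLS(y, x).fit()
        return LMMFit(
            params=pd.Series(ols.params, index=names),
            bse=pd.Series(ols.bse, index=names),
            pvalues=pd.Series(ols.pvalues, index=names),
            sigma2_u=0.0, sigma2_e=float(ols.scale),
            loglike=float(ols.llf), n=len(y), method="ols",
        )
    return LMMFit(
        params=pd.Series(res.fe_params, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_u=sigma2_u,
        sigma2_e=float(res.scale),
        loglike=float(res.llf),
        n=len(y),
        method="reml" if reml else "ml",
    )


def _analyte_design(meta: pd.DataFrame, group_col: str, index_group: str,
                    covariates: Sequence[str]) -> pd.DataFrame:
    design = pd.DataFrame({"Intercept": 1.0}, index=meta.index)
    design["group"] = (meta[group_col] == index_group).astype(float)
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            design[cov] = col.astype(float)
        else:
            for level in sorted(col.astype(str).unique())[1:]:
                design[f"{cov}[{level}]"] = (col.astype(str) == level).astype(float)
    return design


def differential_abundance(collapsed: pd.DataFrame, participants: pd.DataFrame,
                           group_col: str = "karyotype",
                           index_group: str = "T21",
                           covariates: Sequence[str] = ("age", "sex"),
                           random_effect_col: str = "source",
                           fdr: float = 0.1,
                           fence_outliers: bool = True) -> pd.DataFrame:
    """Per-analyte mixed-model differential abundance with BH correction.

    ``collapsed`` is the preprocessed table (one row per sample-analyte);
    outliers are fenced per karyotype before fitting.
    """
    meta = participants.set_index("sample_id")
    rows = []
    for analyte, sub in collapsed.groupby("analyte"):
        sub = sub.set_index("sample_id")
        m = meta.reindex(sub.index)
        y = np.log2(sub["value"].to_numpy(float))
        keep = np.ones(len(y), dtype=bool)
        if fence_outliers:
            mask, _ = mask_outliers(y, m[group_col].to_numpy())
            keep = mask.to_numpy()
        design = _analyte_design(m.loc[sub.index[keep]], group_col,
                                 index_group, covariates)
        fit = fit_mixed_model(y[keep], design,
                              sub[random_effect_col].to_numpy()[keep])
        rows.append({
            "analyte": analyte,
            "log2fc": float(fit.params["group"]),
            "se": float(fit.bse["group"]),
            "p": float(fit.pvalues["group"]),
            "sigma2_source": fit.sigma2_u,
            "n": fit.n,
            "method": fit.method,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < fdr
    return out


def age_karyotype_effects(collapsed: pd.DataFrame, participants: pd.DataFrame,
                          covariates: Sequence[str] = ("age", "sex"),
                          random_effect_col: str = "source",
                          fdr: float = 0.1) -> pd.DataFrame:
    """Contrast the karyotype effect with the within-T21 age effect.

    The karyotype effect comes from the mixed model (T21 vs D21, age/sex
    adjusted); the age effect is a linear regression of log2 concentration
    on age within the T21 cohort.  Each family is BH-corrected separately
    and analytes are classified as T21 only / age only / both / ns.
    """
    meta = participants.set_index("sample_id")
    t21_ids = meta.index[meta["karyotype"] == "T21"]
    if len(t21_ids) == 0 or (meta["karyotype"] == "D21").sum() == 0:
        raise ConfigurationError("both karyotype groups must be present")
    if meta.loc[t21_ids, "age"].nunique() < 3:
        raise ConfigurationError("degenerate age distribution in the T21 group")
    da = differential_abundance(collapsed, participants, covariates=covariates,
                                random_effect_col=random_effect_col, fdr=fdr)
    rows = []
    for analyte, sub in collapsed.groupby("analyte"):
        sub = sub.set_index("sample_id")
        in_t21 = sub.index.intersection(t21_ids)
        y = np.log2(sub.loc[in_t21, "value"].to_numpy(float))
        age = meta.loc[in_t21, "age"].to_numpy(float)
        x = np.column_stack([np.ones_like(age), age])
        res = sm.OLS(y, x).fit()
        rows.append({"analyte": analyte, "age_slope": float(res.params[1]),
                     "age_p": float(res.pvalues[1])})
    age_df = pd.DataFrame(rows)
    age_df["age_q"] = bh_adjust(age_df["age_p"])
    out = da.merge(age_df, on="analyte")
    t21_sig = out["q"] < fdr
    age_sig = out["age_q"] < fdr
    out["classification"] = np.select(
        [t21_sig & age_sig, t21_sig, age_sig],
        ["both", "T21 only", "age only"], default="ns",
    )
    return out
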