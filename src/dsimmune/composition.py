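"""Compositional immunophenotyping via beta regression.

Immune-cell cluster relative frequencies live in (0, 1), are heteroskedastic
and skewed, so group effects are modelled with beta regression: the outcome
follows a Beta(mu*phi, (1-mu)*phi) law with a logit link for the mean
mu and a single constant precision phi.  Under the logit link,
exp(beta_group) is an odds-scale fold-change — for rare clusters it is close
to the ratio of frequencies, for common clusters it is not, so the results
table also reports the implied ratio of fitted means at reference
covariates.

Extreme outliers are fenced per group and per cluster before fitting
(beyond 3x the interquartile range outside the quartiles), proportions are
squeezed off the boundary with the standard (y*(n-1)+0.5)/n transform, and
Benjamini-Hochberg correction is applied across clusters within a gating
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

from .errors import ConfigurationError
from ._stats import bh_adjust, quantile

__all__ = [
    "BetaRegFit",
    "mask_outliers",
    "squeeze_proportions",
    "fit_beta_regression",
    "summarize_fold_changes",
    "adjust_for_display",
    "run_composition_analysis",
]


@dataclass(frozen=True)
class BetaRegFit:
    """Maximum-likelihood beta regression fit (logit mean link, constant phi)."""

    params: pd.Series  # mean-submodel coefficients on the logit scale
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    phi: float
    loglike: float
    converged: bool
    n: int
    group_term: Optional[str] = None

    @property
    def fold_change(self) -> float:
        """exp(beta_group): the odds-scale fold-change of the group effect."""
        if self.group_term is None:
            raise ConfigurationError("fit has no group term")
        return float(np.exp(self.params[self.group_term]))


def mask_outliers(values, groups=None, k: float = 3.0,
                  min_group: int = 4,
                  quantile_method: str = "linear") -> tuple[pd.Series, pd.DataFrame]:
    """Fence extreme outliers within each group: keep Q1-k*IQR <= x <= Q3+k*IQR.

    Returns ``(mask, report)`` where ``mask`` is True for retained values.
    Equality with a fence is retained (only values strictly *more than*
    k*IQR beyond a quartile are excluded).  Groups with fewer than
    ``min_group`` finite values are skipped (nothing masked) and reported.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(["all"] * len(v)) if groups is None else pd.Series(
        np.asarray(groups)).reset_index(drop=True)
    mask = pd.Series(True, index=v.index)
    rows = []
    for name, idx in v.groupby(g).groups.items():
        x = v.loc[idx]
        finite = x.dropna()
        if len(finite) < min_group:
            rows.append((name, len(finite), np.nan, np.nan, 0, "skipped"))
            continue
        q1 = quantile(finite, 0.25, method=quantile_method)
        q3 = quantile(finite, 0.75, method=quantile_method)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        bad = (x < lo) | (x > hi)
        mask.loc[idx] = ~bad.fillna(False)
        rows.append((name, len(finite), lo, hi, int(bad.sum()), "fenced"))
    report = pd.DataFrame(
        rows, columns=["group", "n", "lower_fence", "upper_fence",
                       "n_masked", "status"],
    )
    return mask, report


def squeeze_proportions(y, n_samples: Optional[int] = None) -> np.ndarray:
    """Map [0,1] proportions into the open interval: (y*(n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    if np.nanmin(y) < 0 or np.nanmax(y) > 1:
        raise ConfigurationError("proportions must lie in [0, 1]")
    n = len(y) if n_samples is None else n_samples
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(y, design: pd.DataFrame,
                        group_term: Optional[str] = None) -> BetaRegFit:
    """Fit a beta regression (logit mean link, constant precision) by ML.

    ``design`` must contain an intercept column.  Standard errors come from
    the inverse observed information; p-values are two-sided Wald tests.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ConfigurationError(
            "proportions must lie strictly in (0, 1); apply squeeze_proportions"
        )
    x = design.to_numpy(float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ConfigurationError("design matrix is rank deficient")
    if len(y) <= x.shape[1] + 1:
        raise ConfigurationError("need n > p + 1 observations")
    if group_term is not None and group_term not in design.columns:
        raise ConfigurationError(f"group term {group_term!r} not in design")
    model = BetaModel(y, x, exog_precision=np.ones((len(y), 1)))
    # start values: logit-scale least squares for the mean submodel and a
    # method-of-moments precision
    logit_y = np.log(y / (1.0 - y))
    beta0, *_ = np.linalg.lstsq(x, logit_y, rcond=None)
    mu0 = 1.0 / (1.0 + np.exp(-(x @ beta0)))
    resid_var = float(np.var(y - mu0)) or 1e-6
    phi0 = max(float(np.mean(mu0 * (1 - mu0))) / resid_var - 1.0, 1.0)
    start = np.append(beta0, np.log(phi0))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # convergence is verified below via the score norm
        _warnings.simplefilter("ignore")
        res = model.fit(start_params=start, method="bfgs", maxiter=500,
                        disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            # BFGS can stop on precision loss at a stationary point; accept
            # a small gradient, otherwise polish with Nelder-Mead
            grad = np.max(np.abs(model.score(res.params)))
            if grad > 1e-3:
                res = model.fit(start_params=res.params, method="nm",
                                maxiter=2000, disp=False)
                grad = np.max(np.abs(model.score(res.params)))
            if grad > 1e-2:
                raise ConfigurationError(
                    f"beta regression did not converge (max |score| = {grad:.3g})"
                )
            converged = True
    names = list(design.columns)
    k = len(names)
    return BetaRegFit(
        params=pd.Series(res.params[:k], index=names),
        bse=pd.Series(res.bse[:k], index=names),
        zvalues=pd.Series(res.tvalues[:k], index=names),
        pvalues=pd.Series(res.pvalues[:k], index=names),
        phi=float(np.exp(res.params[k])),  # precision uses a log link
        loglike=float(res.llf),
        converged=converged,
        n=len(y),
        group_term=group_term,
    )


def _implied_mean_ratio(fit: BetaRegFit, design_reference: pd.Series) -> float:
    """Ratio of fitted means with/without the group effect at reference
    covariates (the frequency-scale companion to the odds-scale exp(beta))."""
    eta0 = float(design_reference @ fit.params)
    eta1 = eta0 + float(fit.params[fit.group_term])
    inv = lambda e: 1.0 / (1.0 + np.exp(-e))
    return inv(eta1) / inv(eta0)


def summarize_fold_changes(fits: dict, design_reference: Optional[pd.Series] = None,
                           fdr: float = 0.1) -> pd.DataFrame:
    """Collect per-cluster fits into a results table with BH q-values.

    ``fits`` maps cluster id -> BetaRegFit (all with the same group term).
    """
    if not fits:
        raise ConfigurationError("no fits supplied")
    rows = []
    for cluster, fit in fits.items():
        beta = float(fit.params[fit.group_term])
        row = {
            "cluster": cluster,
            "beta_group": beta,
            "se": float(fit.bse[fit.group_term]),
            "p": float(fit.pvalues[fit.group_term]),
            "fold_change": float(np.exp(beta)),
            "phi": fit.phi,
            "n": fit.n,
        }
        if design_reference is not None:
            row["mean_ratio"] = _implied_mean_ratio(fit, design_reference)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < fdr
    return out


def adjust_for_display(proportions, age, sex) -> np.ndarray:
    """Age/sex-residualized proportions for plotting only.

    Residualizes logit proportions on age and sex, re-centers to the grand
    mean, and maps back through the inverse logit.  Inference never uses
    these values.
    """
    y = np.asarray(proportions, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = pd.Series(np.asarray(sex))
    if np.isnan(age).any() or sex.isna().any():
        raise ConfigurationError("age and sex must be complete for display adjustment")
    if np.any((y <= 0) | (y >= 1)):
        y = squeeze_proportions(y)
    logit = np.log(y / (1 - y))
    sex_num = (sex.astype(str) == sorted(sex.astype(str).unique())[-1]).astype(float)
    x = np.column_stack([np.ones_like(age), age, sex_num.to_numpy()])
    beta, *_ = np.linalg.lstsq(x, logit, rcond=None)
    resid = logit - x @ beta + logit.mean()
    return 1.0 / (1.0 + np.exp(-resid))


def run_composition_analysis(frequencies: pd.DataFrame,
                             participants: pd.DataFrame,
                             level: str = "live",
                             group_col: str = "karyotype",
                             index_group: str = "T21",
                             covariates: Sequence[str] = ("age", "sex"),
                             fdr: float = 0.1) -> pd.DataFrame:
    """Full per-cluster analysis at one gating level.

    For each cluster: fence outliers per group, squeeze proportions, fit a
    beta regression of proportion on group + covariates (logit link), then
    BH-correct the group-effect p-values across clusters.
    """
    freq = frequencies[frequencies["level"] == level]
    if freq.empty:
        raise ConfigurationError(f"no rows at level {level!r}")
    meta = participants.set_index("sample_id")
    fits = {}
    ref = None
    for cluster, sub in freq.groupby("cluster"):
        sub = sub.set_index("sample_id")
        m = meta.reindex(sub.index)
        y = sub["proportion"]
        mask, _ = mask_outliers(y.to_numpy(), m[group_col].to_numpy())
        keep = mask.to_numpy()
        y_kept = squeeze_proportions(y.to_numpy()[keep])
        design = pd.DataFrame({"Intercept": 1.0}, index=sub.index[keep])
        design["group"] = (m.loc[sub.index[keep], group_col] == index_group).astype(float).to_numpy()
        for cov in covariates:
            col = m.loc[sub.index[keep], cov]
            if pd.api.types.is_numeric_dtype(col):
                design[cov] = col.astype(float).to_numpy()
            else:
                lv = sorted(col.astype(str).unique())
                for level_name in lv[1:]:
                    design[f"{cov}[{level_name}]"] = (
                        col.astype(str) == level_name
                    ).astype(float).to_numpy()
        fits[cluster] = fit_beta_regression(y_kept, design, group_term="group")
        if ref is None:
            ref = pd.Series(0.0, index=design.columns)
            ref["Intercept"] = 1.0
            num = [c for c in covariates
                   if c in design.columns and pd.api.types.is_numeric_dtype(meta[c])]
            for c in num:
                ref[c] = float(meta[c].mean())
    out = summarize_fold_changes(fits, design_reference=ref, fdr=fdr)
    out.insert(1, "level", level)
    return out
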