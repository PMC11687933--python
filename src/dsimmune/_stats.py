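"""Small shared statistical utilities used across the pipeline."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "quantile"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def quantile(values, q: float, method: str = "linear") -> float:
    """Empirical quantile with an explicit interpolation convention.

    ``method="linear"`` is the type-7 convention (the default of most
    statistical software); other numpy conventions can be requested.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("quantile of empty data")
    return float(np.quantile(v, q, method=method))
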