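"""Kolmogorov-Smirnov goodness of fit of the skew-normal model, per gene.

The test compares the empirical CDF of a gene's CLR values with the fitted
skew-normal CDF, with the estimated parameters plugged in (no correction for
estimation: p-values are computed from the asymptotic Kolmogorov
distribution exactly as a practitioner applies a one-sample KS test after
fitting).  Plug-in KS p-values are conservative in the usual direction for
this use, which is acceptable because the cohort summary only counts genes
whose fit is *not* rejected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .preprocess import clr_transform, filter_genes
from .sn import CenteredParams, cp_to_dp, sn_cdf
from .dv import _fit_gene

__all__ = ["ks_stat", "gof_table", "gof_summary"]


def ks_stat(values, cp: CenteredParams) -> tuple[float, float]:
    """One-sample KS statistic and asymptotic p against a fitted skew-normal.

    ``cp`` are the (estimated) centered parameters; the statistic is
    sup_x |ECDF(x) - F(x; cp)|.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError(f"need at least 20 observations, got {x.size}")
    dp = cp_to_dp(cp)
    res = kstest(x, lambda t: sn_cdf(t, dp), method="asymp")
    return float(res.statistic), float(res.pvalue)


def gof_table(
    counts: pd.DataFrame,
    apply_filter: bool = True,
    pseudo_value: float = 0.5,
) -> pd.DataFrame:
    """Per-gene skew-normal fit + KS test on CLR-transformed counts.

    Returns a DataFrame with columns gene_id, ks_D, ks_p, fit_ok.  Genes
    whose skew-normal fit fails are reported with fit_ok False and NaN
    statistics.
    """
    if apply_filter:
        counts, _ = filter_genes(counts)
    clr = clr_transform(counts, pseudo_value)
    values = clr.to_numpy()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, gene in enumerate(counts.index):
            fit = _fit_gene(values[idx])
            if fit is None:
                rows.append((gene, np.nan, np.nan, False))
                continue
            d, p = ks_stat(values[idx], fit.cp)
            rows.append((gene, d, p, True))
    return pd.DataFrame(rows, columns=["gene_id", "ks_D", "ks_p", "fit_ok"])


def gof_summary(records: pd.DataFrame, threshold: float = 0.05) -> float:
    """Proportion of successfully fitted genes whose KS p exceeds ``threshold``."""
    if len(records) == 0:
        raise ValueError("empty goodness-of-fit table")
    ok = records["fit_ok"].to_numpy(dtype=bool)
    if ok.sum() == 0:
        raise ValueError("no successful fits in table")
    return float((records.loc[ok, "ks_p"] > threshold).mean())
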