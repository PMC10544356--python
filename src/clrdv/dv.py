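"""The differential-variability test: per-group skew-normal fits and Wald test.

For each gene g the CLR-transformed values of the two groups are fitted
separately by skew-normal maximum likelihood, and equality of the standard
deviations is tested with

    Z_g = (sigma_hat_{g,2} - sigma_hat_{g,1})
          / sqrt(Var(sigma_hat_{g,2}) + Var(sigma_hat_{g,1})),

asymptotically standard normal under the null, giving a two-sided p-value.
The family of p-values is adjusted with the Benjamini-Yekutieli step-up
procedure, which controls the FDR under arbitrary dependence between genes
(CLR values are correlated across genes by construction, so the BY guarantee
matters here).  Effect size is reported as the SD ratio sigma_2/sigma_1 and
its log2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import clr_transform, filter_genes
from .sn import SNFit, fit_sn_cp

__all__ = [
    "GroupDesign",
    "wald_z",
    "by_adjust",
    "run_clrdv",
    "volcano_frame",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id",
    "sigma_control",
    "sigma_treatment",
    "se_control",
    "se_treatment",
    "z",
    "p_value",
    "q_value",
    "sd_ratio",
    "log2_sd_ratio",
    "status",
]


@dataclass
class GroupDesign:
    """Two-group sample assignment.

    ``labels`` is a pandas Series indexed by sample id with exactly two
    distinct values; ``reference_group`` is treated as group 1 (control),
    the other level as group 2 (treatment).
    """

    labels: pd.Series
    reference_group: str

    def __post_init__(self):
        levels = pd.unique(self.labels)
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, got {list(levels)}")
        if self.reference_group not in levels:
            raise ValueError(
                f"reference group {self.reference_group!r} not among {list(levels)}"
            )
        self.test_group = [g for g in levels if g != self.reference_group][0]
        for name, n in self.group_sizes().items():
            if n < 20:
                raise ValueError(f"group {name!r} has {n} samples; need >= 20")
            if n < 50:
                warnings.warn(
                    f"group {name!r} has {n} < 50 samples; "
                    "scale estimation may be unreliable",
                    stacklevel=2,
                )

    def group_sizes(self) -> dict:
        return self.labels.value_counts().to_dict()

    def samples(self, group) -> pd.Index:
        return self.labels.index[self.labels == group]


def wald_z(fit1: SNFit, fit2: SNFit) -> float:
    """Wald statistic for equality of the two groups' sigma parameters."""
    if not (fit1.converged and fit2.converged):
        raise ValueError("both fits must have converged")
    denom = fit1.var_sigma + fit2.var_sigma
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("non-finite or non-positive variance of sigma-hat")
    return (fit2.cp.sigma - fit1.cp.sigma) / np.sqrt(denom)


def by_adjust(p) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order.

    NaN entries are excluded from the family size m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    # harmonic constant c(m); fsum so the value is independent of summation order
    c_m = math.fsum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(pm, kind="stable")
    ranks = np.arange(1, m + 1)
    scaled = np.minimum(1.0, (m * c_m) * pm[order] / ranks)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]  # step-up: min over j >= i
    q = np.empty(m)
    q[order] = q_sorted
    out[mask] = q
    return out


def volcano_frame(result: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates (log2 SD ratio vs -log10 q) from a result table."""
    ok = result[result["status"] == "ok"]
    return pd.DataFrame(
        {
            "gene_id": ok["gene_id"],
            "log2_sd_ratio": ok["log2_sd_ratio"],
            "neg_log10_q": -np.log10(ok["q_value"].clip(lower=np.finfo(float).tiny)),
        }
    )


def _fit_gene(values) -> SNFit | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_sn_cp(values)
    except ValueError:
        return None
    if not fit.converged or not np.isfinite(fit.var_sigma) or fit.var_sigma <= 0:
        return None
    return fit


def run_clrdv(
    counts: pd.DataFrame,
    design: GroupDesign,
    alpha: float = 0.05,
    cpm_threshold: float = 0.5,
    zero_proportion: float = 0.85,
    pseudo_value: float = 0.5,
) -> pd.DataFrame:
    """Full differential-variability pipeline on a raw count matrix.

    Filters genes on the pooled samples, CLR-transforms the pooled matrix,
    fits each gene's CLR values per group, tests sigma equality with the
    Wald statistic and BY-adjusts the p-values.  Genes whose fit fails in
    either group get status ``fit_failed`` (p and q NaN) and are excluded
    from the BY family rather than silently dropped.

    Returns a DataFrame with columns ``RESULT_COLUMNS``; the flagged DV set
    is ``q_value < alpha``.
    """
    missing = design.labels.index.difference(counts.columns)
    if len(missing):
        raise ValueError(f"labelled samples absent from counts: {list(missing)[:5]}")
    counts = counts[design.labels.index]

    kept, report = filter_genes(counts, cpm_threshold, zero_proportion)
    clr = clr_transform(kept, pseudo_value)
    ctrl = clr[design.samples(design.reference_group)].to_numpy()
    treat = clr[design.samples(design.test_group)].to_numpy()

    rows = []
    n_failed = 0
    for idx, gene in enumerate(kept.index):
        fit1 = _fit_gene(ctrl[idx])
        fit2 = _fit_gene(treat[idx]) if fit1 is not None else None
        if fit1 is None or fit2 is None:
            n_failed += 1
            rows.append(
                (gene, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                 np.nan, np.nan, "fit_failed")
            )
            continue
        z = wald_z(fit1, fit2)
        p = 2.0 * norm.sf(abs(z))
        s1, s2 = fit1.cp.sigma, fit2.cp.sigma
        rows.append(
            (gene, s1, s2, fit1.se[1], fit2.se[1], z, p, np.nan,
             s2 / s1, np.log2(s2 / s1), "ok")
        )

    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    result["q_value"] = by_adjust(result["p_value"].to_numpy())

    n_flagged = int((result["q_value"] < alpha).sum())
    logger.info(
        "clrDV run: %d genes in, %d filtered out, %d tested, %d fit failures, "
        "%d flagged at q < %g",
        counts.shape[0], len(report.removed_gene_ids),
        len(result) - n_failed, n_failed, n_flagged, alpha,
    )
    return result
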