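"""Gene filtering and the centered log-ratio (CLR) transform for count matrices.

RNA-seq counts are treated as compositional: each sample carries only
relative information about gene abundance.  The CLR transform maps each
sample's composition from the simplex into Euclidean space,

    CLR(x_gi) = log(x_gi) - (1/G) * sum_g' log(x_g'i),

so that every transformed sample column sums to zero.  Before the transform,
genes with negligible expression are removed: a gene is dropped when its
mean counts-per-million across all samples falls below ``cpm_threshold``
(default 0.5) or when it is zero in at least ``zero_proportion`` (default
85%) of the samples.  Zero cells are replaced by a pseudo-value (default
0.5) so the logarithm is defined; non-zero counts are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "validate_counts",
    "compute_cpm",
    "filter_genes",
    "clr_transform",
]


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_genes`.

    Attributes
    ----------
    kept_gene_ids : list of str
    removed_gene_ids : list of str
    reason_per_removed : dict mapping removed gene id to one of
        ``"low_cpm"``, ``"high_zero_proportion"``, ``"both"``.
    """

    kept_gene_ids: list = field(default_factory=list)
    removed_gene_ids: list = field(default_factory=list)
    reason_per_removed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, False, "") for g in self.kept_gene_ids]
        rows += [(g, True, self.reason_per_removed[g]) for g in self.removed_gene_ids]
        return pd.DataFrame(rows, columns=["gene_id", "removed", "reason"])


def validate_counts(counts: pd.DataFrame, min_genes: int = 2) -> None:
    """Check a genes x samples count matrix.

    Entries must be non-negative integers, gene and sample identifiers
    unique, and at least ``min_genes`` genes present (the CLR transform is
    undefined for a one-part composition).
    """
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    if counts.shape[0] < min_genes:
        raise ValueError(f"need at least {min_genes} genes, got {counts.shape[0]}")
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled by its library size times 1e6.

    Raises if any sample has zero library size (all-zero column).
    """
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero library size")
    return counts / libsize * 1e6


def filter_genes(
    counts: pd.DataFrame,
    cpm_threshold: float = 0.5,
    zero_proportion: float = 0.85,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove weakly expressed genes before the CLR transform.

    A gene is removed when its mean CPM over all samples (pooled, computed
    from pre-filtering library sizes) is strictly below ``cpm_threshold``,
    or when the fraction of samples with a zero count is at least
    ``zero_proportion``.

    Returns the retained sub-matrix and a :class:`FilterReport`.
    """
    if not 0 < zero_proportion <= 1:
        raise ValueError("zero_proportion must be in (0, 1]")
    if cpm_threshold < 0:
        raise ValueError("cpm_threshold must be >= 0")
    validate_counts(counts)

    mean_cpm = compute_cpm(counts).mean(axis=1)
    zero_frac = (counts == 0).mean(axis=1)
    low_cpm = mean_cpm < cpm_threshold
    high_zero = zero_frac >= zero_proportion
    removed = low_cpm | high_zero

    report = FilterReport(
        kept_gene_ids=list(counts.index[~removed]),
        removed_gene_ids=list(counts.index[removed]),
    )
    for g in report.removed_gene_ids:
        if low_cpm[g] and high_zero[g]:
            report.reason_per_removed[g] = "both"
        elif low_cpm[g]:
            report.reason_per_removed[g] = "low_cpm"
        else:
            report.reason_per_removed[g] = "high_zero_proportion"

    kept = counts.loc[~removed]
    if kept.shape[0] < 2:
        raise ValueError(
            f"only {kept.shape[0]} genes survive filtering; CLR needs at least 2"
        )
    return kept, report


def clr_transform(counts: pd.DataFrame, pseudo_value: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of a (filtered) count matrix.

    Zero cells are replaced by ``pseudo_value``; non-zero counts are left
    unchanged.  Natural logarithms; the geometric mean runs over the G
    retained genes of each sample, so every output column sums to zero.
    """
    if pseudo_value <= 0:
        raise ValueError("pseudo_value must be > 0")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    values = np.where(values == 0, pseudo_value, values)
    log_values = np.log(values)
    clr = log_values - log_values.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)
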