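"""NB2 count simulation for benchmarking the differential-variability test.

Counts are drawn from the NB2 negative binomial, in which variance and mean
are related quadratically, var = mu + phi * mu^2 (size = 1/phi).  A two-group
benchmark instance gives both groups identical per-gene (mu, phi) except for
a fraction of genes spiked as true DV genes: their size parameter in one
group is multiplied by a random fold x drawn from (0.25, 0.5) U (2, 4)
(equivalently phi -> phi / x), so the groups differ in variability only,
never in mean.

Per-gene NB2 parameters can be estimated from a real count matrix
(:func:`estimate_nb2`) or produced by a seeded synthetic generator
(:func:`synth_nb2_params`) emulating bulk RNA-seq: log-normal means spanning
roughly 1-1000 expected counts and a dispersion trend decreasing with the
mean (phi ~ (0.1 + 2/mu) x log-normal noise), the classic mean-BCV
relationship of bulk data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .dv import GroupDesign

__all__ = [
    "NB2Params",
    "SimDesign",
    "ConfusionSummary",
    "estimate_nb2",
    "synth_nb2_params",
    "sample_dv_fold",
    "simulate_two_groups",
    "score_calls",
    "benchmark",
]

PHI_FLOOR = 1e-8

#: support of the DV spike fold applied to the size parameter
DEFAULT_FOLD_SUPPORT = ((0.25, 0.5), (2.0, 4.0))


@dataclass(frozen=True)
class NB2Params:
    """NB2 parameters: mean mu > 0 and dispersion phi >= 0 (var = mu + phi mu^2)."""

    mu: float
    phi: float

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")

    @property
    def size(self) -> float:
        return 1.0 / max(self.phi, PHI_FLOOR)

    @property
    def variance(self) -> float:
        return self.mu + self.phi * self.mu**2


@dataclass
class SimDesign:
    """Design of one benchmark experiment."""

    G: int = 2000
    prop_dv: float = 0.1
    n_per_group: int = 100
    n_instances: int = 1
    seed: int = 0
    fold_support: tuple = DEFAULT_FOLD_SUPPORT
    spiked_group: int = 2

    def __post_init__(self):
        if not 0 <= self.prop_dv <= 1:
            raise ValueError("prop_dv must be in [0, 1]")
        for lo, hi in self.fold_support:
            if not (0 < lo < hi) or lo <= 1 <= hi:
                raise ValueError("fold intervals must be positive and exclude 1")
        if self.spiked_group not in (1, 2):
            raise ValueError("spiked_group must be 1 or 2")


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    fdr: float = field(init=False)
    type2: float = field(init=False)

    def __post_init__(self):
        self.fdr = self.fp / (self.fp + self.tp) if (self.fp + self.tp) else 0.0
        self.type2 = self.fn / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def _nb2_nll_phi(log_phi, x, mu):
    """NB2 negative log-likelihood profiled in phi (mu fixed at its MLE)."""
    phi = np.exp(log_phi)
    r = 1.0 / phi
    return -np.sum(
        gammaln(x + r) - gammaln(r) - gammaln(x + 1)
        + r * np.log(r / (r + mu))
        + x * np.log(mu / (r + mu))
    )


def estimate_nb2(gene_counts) -> NB2Params:
    """Maximum-likelihood NB2 fit to one gene's counts.

    The NB2 mean MLE is the sample mean; the dispersion is profiled
    numerically.  Falls back to the method of moments,
    phi = max(0, (s^2 - xbar) / xbar^2), if the likelihood step fails, and
    floors phi at 1e-8.
    """
    x = np.asarray(gene_counts, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if np.all(x == 0):
        raise ValueError("all-zero gene: NB2 mean undefined")
    mu = float(np.mean(x))
    s2 = float(np.var(x, ddof=1))
    phi_mom = max((s2 - mu) / mu**2, PHI_FLOOR)
    if s2 <= mu:  # under-dispersed: boundary
        return NB2Params(mu, PHI_FLOOR)
    try:
        res = minimize_scalar(
            _nb2_nll_phi,
            bracket=(np.log(phi_mom) - 1.0, np.log(phi_mom) + 1.0),
            args=(x, mu),
            options={"xtol": 1e-8},
        )
        if res.success and np.isfinite(res.x):
            return NB2Params(mu, max(float(np.exp(res.x)), PHI_FLOOR))
    except (ValueError, FloatingPointError):
        pass
    return NB2Params(mu, phi_mom)


#: nominal sequencing depth the synthetic generator assumes (reads/sample),
#: typical of bulk RNA-seq libraries
NOMINAL_LIBSIZE = 2e7


def synth_nb2_params(G: int, seed: int) -> list[NB2Params]:
    """Seeded synthetic per-gene NB2 parameters emulating filtered bulk RNA-seq.

    Expression: log2 CPM ~ Normal(5, 1.7) clipped to CPM in [1, 1000], scaled
    to expected counts at a nominal 20M-read library (so mu spans roughly
    20-20,000, as in expression-filtered bulk data).  Dispersion follows the
    decreasing mean-dispersion trend phi = (0.1 + 2/mu) * LogNormal(0, 0.4),
    i.e. a biological CV of ~0.32 for well-expressed genes with extra shot
    noise at the low end.  Deterministic given (G, seed).
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    rng = np.random.default_rng(seed)
    cpm = np.clip(2.0 ** rng.normal(5.0, 1.7, size=G), 1.0, 1000.0)
    mu = cpm * (NOMINAL_LIBSIZE / 1e6)
    phi = (0.1 + 2.0 / mu) * np.exp(rng.normal(0.0, 0.4, size=G))
    return [NB2Params(float(m), float(p)) for m, p in zip(mu, phi)]


def sample_dv_fold(rng: np.random.Generator, fold_support=DEFAULT_FOLD_SUPPORT) -> float:
    """Draw a DV spike fold: pick an interval with probability 1/2, then uniform."""
    lo, hi = fold_support[rng.integers(len(fold_support))]
    return float(rng.uniform(lo, hi))


def _draw_counts(rng, mu, phi, size):
    phi = max(phi, PHI_FLOOR)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def simulate_two_groups(
    params: list[NB2Params], design: SimDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroupDesign]:
    """Simulate one two-group instance from per-gene NB2 parameters.

    The first ``floor(prop_dv * G)`` genes (after a seeded shuffle of the
    spike assignment) have their size parameter multiplied by a random fold
    in the spiked group.  Returns (counts, truth, design): counts is a genes
    x samples integer DataFrame; truth has columns gene_id, is_dv, fold,
    spiked_group.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    G = len(params)
    n = design.n_per_group
    n_dv = int(np.floor(design.prop_dv * G))
    dv_genes = rng.choice(G, size=n_dv, replace=False)
    is_dv = np.zeros(G, dtype=bool)
    is_dv[dv_genes] = True
    folds = np.ones(G)
    for g in dv_genes:
        folds[g] = sample_dv_fold(rng, design.fold_support)

    gene_ids = [f"gene_{g + 1}" for g in range(G)]
    sample_ids = [f"ctrl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    counts = np.empty((G, 2 * n), dtype=np.int64)
    for g, p in enumerate(params):
        phi1, phi2 = p.phi, p.phi
        if is_dv[g]:
            # size' = x * size  <=>  phi' = phi / x
            if design.spiked_group == 2:
                phi2 = p.phi / folds[g]
            else:
                phi1 = p.phi / folds[g]
        counts[g, :n] = _draw_counts(rng, p.mu, phi1, n)
        counts[g, n:] = _draw_counts(rng, p.mu, phi2, n)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_dv": is_dv,
            "fold": folds,
            "spiked_group": design.spiked_group,
        }
    )
    labels = pd.Series(
        ["control"] * n + ["treatment"] * n, index=sample_ids, name="group"
    )
    return counts_df, truth, GroupDesign(labels=labels, reference_group="control")


def score_calls(truth: pd.DataFrame, called) -> ConfusionSummary:
    """Confusion summary of DV calls against the simulation truth table.

    ``called`` is a boolean vector aligned with ``truth`` rows.  FDR is the
    sample proportion of false discoveries (0 when nothing is called);
    type2 is the proportion of true DV genes missed.
    """
    called = np.asarray(called, dtype=bool)
    if len(called) != len(truth):
        raise ValueError(
            f"length mismatch: {len(called)} calls vs {len(truth)} truth rows"
        )
    is_dv = truth["is_dv"].to_numpy(dtype=bool)
    tp = int(np.sum(called & is_dv))
    fp = int(np.sum(called & ~is_dv))
    fn = int(np.sum(~called & is_dv))
    tn = int(np.sum(~called & ~is_dv))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def benchmark(
    design: SimDesign,
    params: list[NB2Params] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate -> test -> score over ``design.n_instances`` instances.

    One NB2 parameter set (synthetic by default) is shared across instances;
    counts and spike assignments are redrawn each instance from a single
    seeded stream.  Returns a per-instance summary DataFrame with columns
    instance, fdr, type2, n_called, n_tested.
    """
    from .dv import run_clrdv

    if params is None:
        params = synth_nb2_params(design.G, design.seed)
    rng = np.random.default_rng(design.seed)
    records = []
    for inst in range(design.n_instances):
        counts, truth, gdesign = simulate_two_groups(params, design, rng=rng)
        result = run_clrdv(counts, gdesign, alpha=alpha)
        merged = truth.merge(result, on="gene_id", how="inner")
        called = (merged["q_value"] < alpha).fillna(False).to_numpy()
        summary = score_calls(merged[["gene_id", "is_dv", "fold"]], called)
        records.append(
            {
                "instance": inst,
                "fdr": summary.fdr,
                "type2": summary.type2,
                "n_called": summary.tp + summary.fp,
                "n_tested": len(merged),
            }
        )
    return pd.DataFrame(records)
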