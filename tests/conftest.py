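import numpy as np
import pandas as pd
import pytest

from clrdv.simulate import SimDesign, simulate_two_groups, synth_nb2_params


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with a known CPM answer."""
    return pd.DataFrame(
        [[10, 0], [0, 10], [90, 90]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture(scope="session")
def spiked_instance():
    """One small spiked two-group instance shared across tests.

    200 genes, 10% DV, 100 samples per group.
    """
    design = SimDesign(G=200, prop_dv=0.1, n_per_group=100, seed=11)
    params = synth_nb2_params(design.G, design.seed)
    return simulate_two_groups(params, design)


@pytest.fixture(scope="session")
def null_instance():
    """Both groups drawn from identical NB2 models (no DV genes)."""
    design = SimDesign(G=300, prop_dv=0.0, n_per_group=100, seed=7)
    params = synth_nb2_params(design.G, design.seed)
    return simulate_two_groups(params, design)


def brute_force_by(p):
    """Independent Benjamini-Yekutieli step-up: direct min-over-j scan."""
    import math

    p = np.asarray(p, dtype=float)
    m = p.size
    # fsum is correctly rounded, so summing in the opposite order is exact too
    c_m = math.fsum(1.0 / k for k in range(m, 0, -1))
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(1.0, m * c_m * p[order[j]] / (j + 1)) for j in range(i, m)
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def brute_force_ks(x, cdf):
    """Sup-distance between ECDF and a CDF, scanned over all sample points."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    f = cdf(x)
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - f), np.max(f - (i - 1) / n)))
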