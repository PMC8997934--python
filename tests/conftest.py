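import warnings

import numpy as np
import pytest

import editome as ed

warnings.filterwarnings("ignore", category=UserWarning, module="umap")
warnings.filterwarnings("ignore", message=".*force_all_finite.*")


@pytest.fixture(scope="session")
def fixtures():
    """Hand-constructed filter-cascade fixtures with documented truth."""
    return ed.make_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by read-only tests."""
    cfg = ed.SimConfig(seed=42, n_samples=80, n_sites=300, n_informative_sites=60,
                       n_genes=100, n_regulated=15)
    mat, meta, expr, kd, annot, truth = ed.generate(cfg)
    return {"cfg": cfg, "mat": mat, "meta": meta, "expr": expr, "kd": kd,
            "annot": annot, "truth": truth}


# ---------------------------------------------------------------------------
# independent oracles reused across test modules
# ---------------------------------------------------------------------------

def bh_stepup_oracle(pvals):
    """From-scratch BH step-up adjustment."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def binom_tail_sum_oracle(g, n, p0):
    """Term-by-term summation of the upper binomial tail."""
    from math import comb
    return sum(comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(g, n + 1))
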