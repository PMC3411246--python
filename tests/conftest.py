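"""Shared fixtures: one reduced-size simulation study reused across tests.

The expensive rejection-rate grid is run once per session at 2,000 replicates
per cell (s in {0, 2.5e-7, 1e-6}, SD in {0.24, 1.10, 1.95}, both selection
modes); statistical assertions use 3-binomial-SE tolerances at that replicate
count.  Cheap direction-only studies (the equal-effects test needs no
resampling engine) run at the full 10,000 replicates.
"""

import numpy as np
import pytest

from qtlsign import (
    EffectDistribution,
    GridConfig,
    SelectionRegime,
    qtlst_ee_pvalue,
    run_grid,
    simulate_dataset,
)

ROOT_SEED = 1234
GRID_REPLICATES = 2_000
NEUTRAL_REPLICATES = 10_000


@pytest.fixture(scope="session")
def grid_study():
    """Reduced rejection-rate study shared by the statistical tests."""
    config = GridConfig(
        n_loci=10,
        N=1_000_000,
        s_values=(0.0, 2.5e-7, 1e-6),
        sd_grid=(0.24, 1.10, 1.95),
        modes=("constant", "proportional"),
        replicates=GRID_REPLICATES,
        alpha=0.05,
        seed=ROOT_SEED,
        qtlst_engine="exact",
    )
    return config, run_grid(config)


@pytest.fixture(scope="session")
def neutral_nplus_counts():
    """n_plus of 10,000 oriented neutral datasets at variance 0.06 and 1.0.

    Returns {variance: array of n_plus}.  Used for the equal-effects
    false-positive rate and the folded-binomial goodness-of-fit check.
    """
    regime = SelectionRegime(s=0.0, N=1_000_000)
    out = {}
    for variance in (0.06, 1.0):
        rng = np.random.default_rng(
            np.random.SeedSequence(ROOT_SEED, spawn_key=(9000, int(variance * 100)))
        )
        dist = EffectDistribution(variance=variance)
        out[variance] = np.array(
            [simulate_dataset(10, regime, dist, rng).n_plus for _ in range(NEUTRAL_REPLICATES)]
        )
    return out


def ee_rejection_rate(nplus_values, n=10, alpha=0.05):
    pvals = np.array([qtlst_ee_pvalue(k, n) for k in range(n + 1)])
    return float(np.mean(pvals[nplus_values] < alpha))


def three_se(p, n):
    """Three binomial standard errors for a proportion p estimated from n."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
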