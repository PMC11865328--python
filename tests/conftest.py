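import numpy as np
import pandas as pd
import pytest

from coabnet import CountTable
from coabnet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-region cohort with a planted positive and negative block."""
    cfg = SimulationConfig(
        n_taxa=12,
        n_regions=1,
        samples_per_region_group=(300, 0),
        grade_proportions=(1.0, 0.0, 0.0, 0.0),
        base_blocks=((0, 3, 0.6), (3, 3, -0.45)),
        region_jitter_sd=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        [[10, 5, 0], [3, 7, 2], [8, 1, 4], [2, 2, 2]],
        index=[f"s{i}" for i in range(4)],
        columns=["gA", "gB", "gC"],
    )
    tax = pd.Series(["Firmicutes", "Firmicutes", "Bacteroidetes"],
                    index=["gA", "gB", "gC"])
    return CountTable(counts, tax)


def brute_force_bh(p):
    """Literal step-up definition: q_i = min_{j: p_(j) >= p_(i)} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q
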