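import numpy as np
import pytest

from migselect.datatypes import TriGroupCounts
from migselect.simulate import SimulationScenario, SnpScenario, simulate_cohort


@pytest.fixture
def toy_counts() -> TriGroupCounts:
    """Small three-group table with a with-group excess of minor alleles."""
    return TriGroupCounts(
        k_with=50, n_with=100, k_without=40, n_without=100, k_ctrl=80, n_ctrl=200
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort with one SNP per generating model class."""
    scenario = SimulationScenario(
        n_active=400,
        n_former=80,
        n_never=800,
        seed=2024,
        snps=(
            SnpScenario("rs_subset", "subset", "aura", 0.45, 0.25, 0.25),
            SnpScenario("rs_null", "null", "aura", 0.3, 0.3, 0.3),
            SnpScenario("rs_basic", "basic", "nausea", 0.36, 0.36, 0.27),
        ),
    )
    return simulate_cohort(scenario)


def random_count_tables(rng: np.random.Generator, n_tables: int, max_m: int = 60):
    """Random three-group allele-count tables with non-empty groups."""
    tables = []
    for _ in range(n_tables):
        m = rng.integers(2, max_m, size=3)
        n = 2 * m
        p = rng.uniform(0.05, 0.95, size=3)
        k = rng.binomial(n, p)
        tables.append(
            TriGroupCounts(
                k_with=int(k[0]), n_with=int(n[0]),
                k_without=int(k[1]), n_without=int(n[1]),
                k_ctrl=int(k[2]), n_ctrl=int(n[2]),
            )
        )
    return tables
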