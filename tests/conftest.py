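import numpy as np
import pandas as pd
import pytest

from hatchtraj import Pedigree, SimulationConfig, default_parameters
from hatchtraj import simulate_pedigree, simulate_phenotypes


@pytest.fixture
def trio() -> Pedigree:
    """Unrelated sire and dam with one offspring."""
    return Pedigree(
        ids=np.array([1, 2, 3]),
        sire=np.array([-1, -1, 0]),
        dam=np.array([-1, -1, 1]),
    )


@pytest.fixture
def founders() -> Pedigree:
    return Pedigree(
        ids=np.arange(1, 6), sire=np.full(5, -1), dam=np.full(5, -1)
    )


def random_pedigree(n: int, seed: int = 0, n_founders: int = 20) -> Pedigree:
    """Random discrete pedigree: each non-founder picks two earlier parents."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    return Pedigree(ids=np.arange(1, n + 1), sire=sire, dam=dam)


@pytest.fixture(scope="session")
def small_rr_dataset():
    """A compact simulated breeding program shared by slower model tests."""
    cfg = SimulationConfig(
        n_generations=3,
        n_females_per_gen=60,
        n_males_per_gen=12,
        n_snps=300,
        n_chromosomes=4,
        genotyped_fraction=0.5,
        seed=42,
    )
    ped = simulate_pedigree(cfg)
    data = simulate_phenotypes(ped, default_parameters(), cfg)
    return cfg, ped, data
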