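import numpy as np
import pytest

from parapop.genio import MISSING, GenotypeDataset
from parapop.synth import generate_dataset, mini_template


@pytest.fixture
def toy_dataset():
    """Two species x two populations, 3 loci, handcrafted with missing data."""
    alleles = np.array([
        # pop A1 (species X)
        [[10, 10], [12, 12], [20, 22]],
        [[10, 12], [12, 12], [20, 20]],
        [[10, 10], [MISSING, MISSING], [22, 22]],
        # pop A2 (species X)
        [[10, 12], [12, 14], [20, 22]],
        [[12, 12], [14, 14], [22, 22]],
        # pop B1 (species Y)
        [[14, 14], [16, 16], [30, 30]],
        [[14, 16], [16, 16], [30, 32]],
        [[16, 16], [16, 18], [32, 32]],
    ], dtype=np.int32)
    ids = [f"i{k}" for k in range(len(alleles))]
    pops = np.array(["A1", "A1", "A1", "A2", "A2", "B1", "B1", "B1"], dtype=object)
    return GenotypeDataset(alleles, ids, ["L1", "L2", "L3"], pops,
                           species_of_pop={"A1": "X", "A2": "X", "B1": "Y"})


@pytest.fixture(scope="session")
def mini_study():
    """Small synthetic study dataset with truth table (seeded)."""
    template = mini_template()
    ds, truth = generate_dataset(template, np.random.default_rng(42))
    return ds, truth


def random_dataset(seed: int, n_pops: int = 3, n_per_pop: int = 4, n_loci: int = 4,
                   missing_rate: float = 0.1) -> GenotypeDataset:
    """Arbitrary small valid dataset for round-trip / property tests."""
    rng = np.random.default_rng(seed)
    n = n_pops * n_per_pop
    alleles = rng.integers(1, 999, size=(n, n_loci, 2)).astype(np.int32)
    miss = rng.random((n, n_loci)) < missing_rate
    alleles[miss] = MISSING
    pops = np.array([f"P{i // n_per_pop + 1}" for i in range(n)], dtype=object)
    ids = [f"{pops[i]}_{i}" for i in range(n)]
    species = {f"P{k + 1}": ("X" if k < (n_pops + 1) // 2 else "Y") for k in range(n_pops)}
    return GenotypeDataset(alleles, ids, [f"L{j}" for j in range(n_loci)], pops,
                           species_of_pop=species)
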