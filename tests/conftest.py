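import numpy as np
import pandas as pd
import pytest

from weantime import SimConfig, TraitTable, simulate_dataset, simulate_tree


def toy_frame(n: int = 8, seed: int = 1) -> pd.DataFrame:
    """A small valid raw trait frame with both categories represented."""
    rng = np.random.default_rng(seed)
    brain = 10 ** rng.uniform(0.0, 3.0, n)
    body = brain * 10 ** rng.uniform(1.0, 2.0, n)
    gest = rng.uniform(20.0, 300.0, n)
    wean = rng.uniform(20.0, 900.0, n)
    limbs = ["plantigrade", "non_plantigrade"] * (n // 2) + ["plantigrade"] * (n % 2)
    diets = (["carnivore", "omnivore", "herbivore"] * n)[:n]
    return pd.DataFrame({
        "species": [f"sp{i:02d}" for i in range(n)],
        "order": ["ordA"] * (n // 2) + ["ordB"] * (n - n // 2),
        "brain_mass_g": brain,
        "body_mass_g": body,
        "gestation_d": gest,
        "wean_postnatal_d": wean,
        "limb": limbs,
        "diet": diets,
    })


@pytest.fixture
def toy_table() -> TraitTable:
    return TraitTable(toy_frame(), provenance="toy")


@pytest.fixture(scope="session")
def headline_table() -> TraitTable:
    """One calibrated 67-taxon stand-in table with the human record embedded."""
    table, _ = simulate_dataset(SimConfig(seed=11, include_human=True))
    return table


@pytest.fixture(scope="session")
def fixed_tree():
    """A fixed 67-tip chronogram reused across replicate studies."""
    return simulate_tree(SimConfig(seed=5))
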