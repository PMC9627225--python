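import numpy as np
import pandas as pd
import pytest

from phyloccur.io import AreaTable, OccurrenceMatrix, TraitTable
from phyloccur.simulate import SimConfig, simulate_dataset


@pytest.fixture
def tiny_traits() -> TraitTable:
    rng = np.random.default_rng(0)
    n = 8
    species = [f"Genus{chr(65 + i // 2)}_sp{i}" for i in range(n)]
    genus = [s.split("_")[0] for s in species]
    mid_ll = rng.uniform(3, 15, n)
    mid_lw = rng.uniform(1, 6, n)
    df = pd.DataFrame({
        "genus": genus,
        "height_max": rng.uniform(0.3, 20, n),
        "leaf_length_min": mid_ll * 0.8,
        "leaf_length_max": mid_ll * 1.2,
        "leaf_width_min": mid_lw * 0.8,
        "leaf_width_max": mid_lw * 1.2,
        "fruit_size_max": rng.uniform(0.2, 2, n),
        "calyx_length_max": rng.uniform(0.2, 1.5, n),
        "corolla_length_max": rng.uniform(0.4, 3, n),
    }, index=pd.Index(species, name="species"))
    return TraitTable(data=df)


@pytest.fixture
def tiny_areas() -> AreaTable:
    df = pd.DataFrame({
        "lon": [100.0, 110.0, 120.0, 130.0, 140.0],
        "lat": [2.0, -1.0, 4.0, -3.0, -5.0],
        "ultramafic_pct": [5.0, 15.0, 40.0, 25.0, 8.0],
        "rainfall_min": [150.0, 90.0, 40.0, 70.0, 170.0],
        "lowland_pct": [70.0, 50.0, 25.0, 45.0, 80.0],
    }, index=pd.Index([f"area{i}" for i in range(5)], name="area"))
    return AreaTable(data=df)


@pytest.fixture
def tiny_occurrence(tiny_traits, tiny_areas) -> OccurrenceMatrix:
    rng = np.random.default_rng(1)
    mat = (rng.random((8, 5)) < 0.5).astype(int)
    mat[mat.sum(axis=1) == 0, 0] = 1
    return OccurrenceMatrix(data=pd.DataFrame(
        mat, index=tiny_traits.species, columns=tiny_areas.areas))


@pytest.fixture(scope="session")
def small_sim():
    """A 60-species, 9-area simulated dataset shared across tests."""
    return simulate_dataset(SimConfig(n_species=60, n_areas=9, seed=3))
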