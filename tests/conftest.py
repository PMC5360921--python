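import numpy as np
import pandas as pd
import pytest

import antplant as ap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def census_frame(rows):
    """Build a census table from (elevation, plant, occupied, ant) tuples."""
    records = []
    for i, (elev, plant, occupied, ant) in enumerate(rows, start=1):
        records.append({
            "tree_id": f"T{i:05d}", "elevation_m": float(elev),
            "plant_species": plant, "occupied": int(occupied),
            "ant_species": ant, "height_m": 3.0, "dbh_cm": 5.0,
            "herb_cat1": 10, "herb_cat2": 2, "herb_cat3": 1, "herb_cat4": 0,
        })
    return pd.DataFrame(records)


@pytest.fixture
def tiny_census():
    return census_frame([
        (700, "P1", 1, "A1"),
        (700, "P1", 1, "A1"),
        (700, "P2", 1, "A2"),
        (700, "P3", 0, ""),
        (800, "P1", 1, "A2"),
        (800, "P2", 1, "uncertain"),
    ])


def random_network(rng, max_side=4, max_count=4):
    """A random small pruned network (guaranteed non-empty)."""
    while True:
        n_i = int(rng.integers(2, max_side + 1))
        n_j = int(rng.integers(2, max_side + 1))
        counts = rng.integers(0, max_count, size=(n_i, n_j))
        if counts.sum() == 0:
            continue
        net = ap.BipartiteNetwork.from_counts(counts)
        if not net.is_empty:
            return net
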