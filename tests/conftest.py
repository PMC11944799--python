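import numpy as np
import pandas as pd
import pytest

from rarecycle import SynthConfig, generate_coupled_dataset, generate_otu_table
from rarecycle.network import CooccurrenceNetwork
from rarecycle.tables import NutrientTable, OTUTable


@pytest.fixture
def tiny_otu() -> OTUTable:
    """3 samples x 4 OTUs, handmade."""
    counts = pd.DataFrame(
        [[10, 30, 60, 0], [5, 5, 0, 10], [1, 0, 0, 99]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    crop = pd.Series(["maize", "maize", "cotton"], index=counts.index)
    taxonomy = pd.Series(
        [
            "k__Bacteria;p__Proteobacteria",
            "k__Bacteria;p__Proteobacteria",
            "k__Bacteria;p__Acidobacteriota",
            "k__Bacteria;p__Chloroflexi",
        ],
        index=counts.columns,
    )
    return OTUTable(counts=counts, crop=crop, taxonomy=taxonomy)


@pytest.fixture
def small_nutrients() -> NutrientTable:
    rng = np.random.default_rng(0)
    cols = ["pH", "salt", "BD", "SWC", "NH4_N", "NO3_N", "Olsen_P",
            "Avail_K", "AN", "TP", "TK", "TN", "SOC"]
    data = pd.DataFrame(
        rng.uniform(1, 10, size=(8, len(cols))),
        index=[f"s{i}" for i in range(8)],
        columns=cols,
    )
    crop = pd.Series(["a"] * 4 + ["b"] * 4, index=data.index)
    return NutrientTable(data=data, crop=crop)


@pytest.fixture(scope="session")
def desk_coupled():
    """Coupled dataset at desk scale (small communities, full study design)."""
    cfg = SynthConfig(n_otus_bacteria=1200, n_otus_fungi=500, seed=11)
    return generate_coupled_dataset(cfg)


@pytest.fixture(scope="session")
def default_bacteria() -> OTUTable:
    """A bacterial table at the generator's default (study-scale) settings."""
    return generate_otu_table(SynthConfig(seed=5), "bacteria")


def make_random_network(seed: int, n_max: int = 15, p: float = 0.35) -> CooccurrenceNetwork:
    """Random signed correlation network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                r = float(rng.uniform(0.6, 1.0) * rng.choice([-1, 1]))
                edges.append((nodes[i], nodes[j], r, float(rng.uniform(0, 0.05))))
    connected = sorted({v for a, b, _, _ in edges for v in (a, b)})
    return CooccurrenceNetwork.from_edges(nodes=connected, edges=edges)
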