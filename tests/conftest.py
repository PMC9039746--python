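"""Shared fixtures: small synthetic data sets built once per session."""

import numpy as np
import pandas as pd
import pytest

from salinet import io, simulate
from salinet.datatypes import LINEAGE_RANKS, OtuTable, TaxonomyTable


@pytest.fixture(scope="session")
def small_dataset():
    """12 samples x 40 OTUs under the selection regime."""
    return simulate.fixture_dataset(seed=101, n_samples=12, n_otus=40, depth=2000)


@pytest.fixture(scope="session")
def filtered_small(small_dataset):
    table, metadata, taxonomy, tree = small_dataset
    return io.filter_otus(table, taxonomy), metadata, taxonomy, tree


def make_taxonomy(otu_ids, lineages=None, groups=None):
    """Hand-build a TaxonomyTable from short lineage strings."""
    rows = {}
    for k, otu in enumerate(otu_ids):
        lineage = (lineages or {}).get(otu, "Eukaryota;P;C;O;F;G")
        parts = (lineage.split(";") + ["unclassified"] * 6)[:6]
        rows[otu] = {
            **dict(zip(LINEAGE_RANKS, parts)),
            "functional_group": (groups or {}).get(otu, "algae"),
        }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "otu_id"
    return TaxonomyTable(data)


def planted_three_block(seed, n_per=8, n_otus=60, depth=3000):
    """Selection-regime data with constant salinity within each class.

    Communities within a block are exchangeable (multinomial noise only),
    so a regression tree should recover exactly the three blocks.
    """
    rng = np.random.default_rng(seed)
    tree = simulate.simulate_tree(n_otus, rng)
    optima = simulate.simulate_niche_traits(tree, bm_rate=9.0, seed=rng)
    sal = np.array([11.3] * n_per + [6.2] * n_per + [0.5] * n_per)
    cfg = simulate.SimulationConfig(
        n_samples=3 * n_per, n_otus=n_otus, salinities=sal, depth=depth,
        dispersal=0.05, selection=2.0, seed=int(rng.integers(2**31)),
    )
    niche = simulate.NicheModel(optima, sigma=2.0, s=2.0)
    table, metadata, taxonomy = simulate.simulate_communities(cfg, tree, niche)
    return table, metadata, taxonomy, tree


def make_table(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"OTU{j + 1}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))
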