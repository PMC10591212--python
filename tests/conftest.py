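import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import zoomskit as z
from zoomskit.synthetic_data import (
    SpectrumNoiseModel,
    SyntheticSpeciesConfig,
    make_species,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_chain(mature: str, species: str = "sp", chain_id: str = "COL1a1a",
               pre: str = "", post: str = "") -> z.CollagenChain:
    """Build a chain whose mature region is exactly ``mature``."""
    return z.CollagenChain(
        species_id=species,
        chain_id=chain_id,
        residues=pre + mature + post,
        mature_start=len(pre) + 1,
        mature_end=len(pre) + len(mature),
    )


def make_profile(species: str, matures: dict[str, str]) -> z.SpeciesProfile:
    return z.SpeciesProfile(
        species,
        tuple(
            make_chain(seq, species, cid) for cid, seq in matures.items()
        ),
    )


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree; returns (taxa, distance matrix, splits).

    Built by sequential random edge attachment; pairwise distances are path
    lengths, so the matrix is additive by construction. Splits are the
    non-trivial bipartitions, each given as the side excluding taxon 't0'.
    """
    import itertools

    import networkx as nx

    g = nx.Graph()
    taxa = [f"t{i}" for i in range(n_taxa)]
    g.add_edge(taxa[0], taxa[1], weight=float(rng.uniform(0.05, 0.3)))
    internal = 0
    for leaf in taxa[2:]:
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        w = g[u][v]["weight"]
        node = f"i{internal}"
        internal += 1
        g.remove_edge(u, v)
        split = float(rng.uniform(0.2, 0.8)) * w
        g.add_edge(u, node, weight=split)
        g.add_edge(node, v, weight=w - split)
        g.add_edge(node, leaf, weight=float(rng.uniform(0.05, 0.3)))
    d = np.zeros((n_taxa, n_taxa))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, j in itertools.combinations(range(n_taxa), 2):
        d[i, j] = d[j, i] = paths[taxa[i]][taxa[j]]
    splits = set()
    full = set(taxa)
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        comp = {t for t in nx.node_connected_component(h, u) if t in full}
        side = comp if "t0" not in comp else full - comp
        if 1 < len(side) < n_taxa - 1:
            splits.add(frozenset(side))
    return taxa, d, splits


@pytest.fixture(scope="session")
def synthetic_set():
    """Default 4-species synthetic collagen set with its truth manifest."""
    return make_species(SyntheticSpeciesConfig())


@pytest.fixture(scope="session")
def synthetic_panel(synthetic_set):
    profiles, _ = synthetic_set
    return z.discover(profiles)


@pytest.fixture(scope="session")
def grouper_panel():
    return z.reference_panel()


@pytest.fixture()
def clean_noise():
    return SpectrumNoiseModel.clean()
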