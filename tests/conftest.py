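import sys
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ppi_richclub import nullmodels, richclub, synthetic  # noqa: E402


@pytest.fixture
def k4():
    return nx.complete_graph(4)


@pytest.fixture
def star5():
    """Star with one center and four leaves."""
    return nx.star_graph(4)


@pytest.fixture
def path3():
    return nx.path_graph(3)


@dataclass
class PlantedReplicate:
    seed: int
    graph: nx.Graph
    planted_core: set
    call: richclub.RichClubCall
    degree_sequences_preserved: bool
    members_simple: bool


def _make_replicate(seed: int, n_members: int = 50) -> PlantedReplicate:
    G = synthetic.gen_scale_free(500, m=5, seed=seed, scores=False)
    H, core = synthetic.plant_rich_club(G, 20, 0.8, seed=seed + 1000)
    ens = nullmodels.generate_ensemble(
        H, nullmodels.NullEnsembleConfig(n_networks=n_members, seed=seed + 2000))
    ref = sorted(d for _, d in H.degree())
    deg_ok = all(sorted(d for _, d in M.degree()) == ref for M in ens)
    simple_ok = all(nx.number_of_selfloops(M) == 0 for M in ens)
    call = richclub.call_rich_club(richclub.normalized_rho(H, ens))
    return PlantedReplicate(seed=seed, graph=H, planted_core=set(core),
                            call=call, degree_sequences_preserved=deg_ok,
                            members_simple=simple_ok)


@pytest.fixture(scope="session")
def planted_replicates():
    """Twenty seeded planted-rich-club datasets with their detection calls.

    Shared across the recovery and enrichment acceptance checks; each
    replicate is a 500-node preferential-attachment graph with its top 20
    hubs densified to internal density 0.8, normalized against a 50-member
    degree-preserving ensemble.
    """
    return [_make_replicate(seed) for seed in range(20)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
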