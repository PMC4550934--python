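import networkx as nx
import numpy as np
import pytest

from ppi_richclub import synthetic
from ppi_richclub.richclub import rich_club_phi_dict
from ppi_richclub.graph_metrics import degree_distribution


class TestGenScaleFree:
    def test_interactome_scale_counts(self):
        # preferential attachment at m=20 lands within 5% of the ~17.4k-edge
        # scale of a curated 886-protein interactome
        G = synthetic.gen_scale_free(886, m=20, seed=1)
        assert G.number_of_nodes() == 886
        assert abs(G.number_of_edges() - 17425) / 17425 < 0.05

    def test_same_seed_same_edges(self):
        a = synthetic.gen_scale_free(100, m=3, seed=9)
        b = synthetic.gen_scale_free(100, m=3, seed=9)
        assert set(map(frozenset, a.edges())) == set(map(frozenset, b.edges()))
        assert all(a[u][v]["weight"] == b[u][v]["weight"] for u, v in a.edges())

    def test_exponent_in_scale_free_range(self):
        G = synthetic.gen_scale_free(2000, m=3, seed=4, scores=False)
        assert 2.1 <= degree_distribution(G).fit.gamma <= 3.5

    def test_configuration_model_is_simple(self):
        G = synthetic.gen_scale_free(300, model="configuration", gamma=2.5,
                                     k_min=2, seed=5, scores=False)
        assert nx.number_of_selfloops(G) == 0

    def test_scores_within_string_range(self):
        G = synthetic.gen_scale_free(50, m=2, seed=6)
        ws = [d["weight"] for _, _, d in G.edges(data=True)]
        assert min(ws) >= 0.4 and max(ws) <= 1.0


class TestPlantRichClub:
    def test_full_density_turns_top_hubs_into_clique(self):
        G = synthetic.gen_scale_free(100, m=3, seed=7, scores=False)
        H, core = synthetic.plant_rich_club(G, 10, 1.0, seed=8)
        assert len(core) == 10
        sub = H.subgraph(core)
        assert sub.number_of_edges() == 45  # K10

    def test_planting_creates_high_k_phi_signal(self):
        # on a base graph with no club, the densified core dominates the top
        # degrees, so phi at high thresholds jumps from near 0 to 1
        G = nx.gnp_random_graph(200, 0.05, seed=9)
        G = nx.relabel_nodes(G, {i: f"P{i:04d}" for i in G.nodes()})
        before = rich_club_phi_dict(G)
        H, _ = synthetic.plant_rich_club(G, 10, 1.0, seed=10)
        after = rich_club_phi_dict(H)
        assert max(before.values()) < 0.5
        assert max(after.values()) == pytest.approx(1.0)
        assert all(after[k] == pytest.approx(1.0) for k in sorted(after)[-3:])

    def test_random_placement_control(self):
        G = synthetic.gen_scale_free(200, m=3, seed=11, scores=False)
        _, core = synthetic.plant_rich_club(G, 10, 0.8, seed=12,
                                            placement="random")
        degs = dict(G.degree())
        top10 = sorted(degs.values(), reverse=True)[:10]
        assert sorted((degs[v] for v in core), reverse=True) != top10

    def test_already_dense_core_unchanged(self):
        G = nx.complete_graph(12)
        H, core = synthetic.plant_rich_club(G, 5, 0.5, seed=13)
        assert H.number_of_edges() == G.number_of_edges()


class TestPlantBlocks:
    def test_zero_crosstalk_blocks_are_components(self):
        G, truth = synthetic.plant_blocks(4, 12, 0.6, 0.0, seed=14,
                                          scores=False)
        comps = list(nx.connected_components(G))
        blocks = {}
        for v, b in truth.items():
            blocks.setdefault(b, set()).add(v)
        assert sorted(map(sorted, comps)) == sorted(map(sorted, blocks.values()))

    def test_edge_count_near_binomial_expectation(self):
        nb, bs, p_in, p_out = 6, 30, 0.3, 0.01
        G, _ = synthetic.plant_blocks(nb, bs, p_in, p_out, seed=15,
                                      scores=False)
        n_in_pairs = nb * bs * (bs - 1) / 2
        n_out_pairs = nb * (nb - 1) / 2 * bs * bs
        mean = n_in_pairs * p_in + n_out_pairs * p_out
        sd = np.sqrt(n_in_pairs * p_in * (1 - p_in)
                     + n_out_pairs * p_out * (1 - p_out))
        assert abs(G.number_of_edges() - mean) < 3 * sd

    def test_inverted_densities_rejected(self):
        with pytest.raises(ValueError):
            synthetic.plant_blocks(2, 10, 0.01, 0.3, seed=0)


class TestGenFrequencies:
    def test_flat_model_when_fold_is_one(self):
        G = synthetic.gen_scale_free(300, m=3, seed=16, scores=False)
        recs, truth = synthetic.gen_frequencies(G, base=50, hub_fold=1, seed=17)
        freqs = np.array([r.frequency for r in recs])
        assert truth["hub_nodes"] == []
        assert abs(freqs.mean() - 50) < 3 * np.sqrt(50 / len(freqs))

    def test_counts_are_non_negative_integers(self):
        G = synthetic.gen_scale_free(50, m=2, seed=18, scores=False)
        recs, _ = synthetic.gen_frequencies(G, seed=19)
        assert all(isinstance(r.frequency, int) and r.frequency >= 0
                   for r in recs)

    def test_planted_fold_recovered_on_hub_group(self):
        G = synthetic.gen_scale_free(500, m=5, seed=20, scores=False)
        recs, truth = synthetic.gen_frequencies(G, base=20, hub_fold=4, seed=21)
        freq = {r.accession: r.frequency for r in recs}
        hubs = set(truth["hub_nodes"])
        m_hub = np.mean([freq[v] for v in hubs])
        m_non = np.mean([f for v, f in freq.items() if v not in hubs])
        assert 3.0 <= m_hub / m_non <= 5.0


class TestGenDrugTargets:
    def test_unbiased_drug_matches_network_mean_degree(self):
        G = synthetic.gen_scale_free(500, m=5, seed=22, scores=False)
        degs = dict(G.degree())
        mean_deg = np.mean(list(degs.values()))
        diffs = []
        for s in range(50):
            m, truth = synthetic.gen_drug_targets(G, n_drugs=2,
                                                  targets_per_drug=40,
                                                  hub_bias=2.0, seed=s)
            unif = next(k for k, v in truth["hub_bias"].items() if v == 0)
            diffs.append(np.mean([degs[t] for t in m[unif]]) - mean_deg)
        # unbiased sampling: mean target degree centred on the network mean
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs))

    def test_hub_bias_raises_target_degree(self):
        G = synthetic.gen_scale_free(500, m=5, seed=23, scores=False)
        degs = dict(G.degree())
        mean_deg = np.mean(list(degs.values()))
        wins = 0
        for s in range(50):
            m, truth = synthetic.gen_drug_targets(G, n_drugs=1,
                                                  targets_per_drug=40,
                                                  hub_bias=2.0, seed=s)
            biased = next(iter(m))
            wins += np.mean([degs[t] for t in m[biased]]) > mean_deg
        assert wins >= 48

    def test_same_seed_reproduces_map(self):
        G = synthetic.gen_scale_free(100, m=3, seed=24, scores=False)
        a, _ = synthetic.gen_drug_targets(G, seed=25)
        b, _ = synthetic.gen_drug_targets(G, seed=25)
        assert a == b


def test_generate_dataset_is_pure_function_of_spec():
    spec = synthetic.SyntheticSpec(n_nodes=120, ba_m=3, core_size=8,
                                   targets_per_drug=15, seed=31)
    d1 = synthetic.generate_dataset(spec)
    d2 = synthetic.generate_dataset(spec)
    assert set(map(frozenset, d1["graph"].edges())) \
        == set(map(frozenset, d2["graph"].edges()))
    assert d1["ground_truth"]["planted_core"] == d2["ground_truth"]["planted_core"]
    assert d1["drug_targets"] == d2["drug_targets"]
    assert [r.frequency for r in d1["annotations"]] \
        == [r.frequency for r in d2["annotations"]]
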