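import networkx as nx
import numpy as np
import pytest

from oracles import brute_force_phi
from ppi_richclub import richclub
from ppi_richclub.richclub import (RichClubProfile, call_rich_club,
                                   compare_frequency, normalized_rho,
                                   rich_club_phi, rich_club_phi_dict)


class TestRawPhi:
    def test_clique_is_a_perfect_club(self, k4):
        p = rich_club_phi(k4)
        assert list(p.k) == [0, 1, 2]
        assert np.allclose(p.phi, 1.0)

    def test_star_defined_only_at_zero(self, star5):
        p = rich_club_phi(star5)
        assert p.phi[0] == pytest.approx(0.4)  # 2*4 / (5*4)
        assert np.all(np.isnan(p.phi[1:]))     # only the center has degree > 1

    def test_worked_six_node_example(self):
        G = nx.Graph([("A", "B"), ("A", "C"), ("A", "D"),
                      ("B", "C"), ("B", "E"), ("C", "F")])
        d = rich_club_phi_dict(G)
        assert d[0] == pytest.approx(0.4)          # 2*6 / (6*5)
        assert d[1] == d[2] == pytest.approx(1.0)  # A,B,C form a triangle

    def test_incremental_matches_brute_force_on_random_graphs(self, rng):
        """phi(k) oracle equivalence on 50 seeded random graphs <= 30 nodes."""
        for _ in range(50):
            n = int(rng.integers(4, 31))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.6)),
                                    seed=int(rng.integers(2**31)))
            if G.number_of_edges() == 0:
                continue
            expected = brute_force_phi(G)
            got = rich_club_phi_dict(G)
            assert got == expected

    def test_structural_invariants(self, rng):
        G = nx.barabasi_albert_graph(120, 3, seed=int(rng.integers(2**31)))
        p = rich_club_phi(G)
        assert np.all(np.diff(p.n_gt) <= 0)  # N_>k non-increasing in k
        defined = np.isfinite(p.phi)
        assert np.all(p.phi[defined] >= 0) and np.all(p.phi[defined] <= 1)
        assert np.all(p.e_gt[defined] <= p.n_gt[defined] * (p.n_gt[defined] - 1) / 2)


class TestNormalizedRho:
    def test_identity_ensemble_gives_rho_one(self):
        G = nx.barabasi_albert_graph(40, 3, seed=1)
        prof = normalized_rho(G, [G, G, G])
        defined = np.isfinite(prof.rho)
        assert defined.any()
        assert np.allclose(prof.rho[defined], 1.0)
        assert np.all(prof.empirical_p[defined] == 1.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            normalized_rho(nx.complete_graph(4), [])

    def test_profile_deterministic_given_inputs(self):
        G = nx.barabasi_albert_graph(40, 3, seed=2)
        H = nx.double_edge_swap(G.copy(), nswap=30, seed=3)
        a = normalized_rho(G, [H])
        b = normalized_rho(G, [H])
        assert np.array_equal(a.rho, b.rho, equal_nan=True)


def profile_from_rho(rho_values, degrees=None):
    """Build a minimal normalized profile for call-logic tests."""
    rho = np.asarray(rho_values, dtype=float)
    n = rho.size
    phi = np.where(np.isfinite(rho), 0.5, np.nan)
    return RichClubProfile(k=np.arange(n), n_gt=np.arange(n, 0, -1),
                           e_gt=np.zeros(n, int), phi=phi,
                           phi_rand_mean=np.ones(n), phi_rand_sd=np.zeros(n),
                           rho=rho, empirical_p=np.zeros(n),
                           degrees=degrees or {})


class TestCallRichClub:
    def test_no_club_anywhere_sets_flag(self):
        call = call_rich_club(profile_from_rho([0.5, 0.8, 0.9]))
        assert not call.detected
        assert call.flag == "no rich-club detected"
        assert call.core_nodes == set()

    def test_range_and_peak_follow_definition(self):
        call = call_rich_club(profile_from_rho([0.5, 0.9, 1.2, 1.5, 1.4, 0.8]))
        assert call.significant_range == (2, 4)
        assert call.peak_k == 3 and call.peak_rho == pytest.approx(1.5)

    def test_core_rules(self):
        degrees = {f"v{d}": d for d in range(8)}
        prof = profile_from_rho([1.1, 1.4, 1.5, 1.1, np.nan], degrees=degrees)
        by_min = call_rich_club(prof, core_threshold=1.3, core_rule="min")
        assert by_min.core_range == (1, 2)
        assert by_min.core_nodes == {f"v{d}" for d in range(1, 8)}
        by_range = call_rich_club(prof, core_threshold=1.3, core_rule="range")
        assert by_range.core_nodes == {"v1", "v2"}

    def test_peak_tie_takes_smallest_k(self):
        call = call_rich_club(profile_from_rho([0.9, 1.5, 1.5, 1.2]))
        assert call.peak_k == 1

    def test_unnormalized_profile_rejected(self, k4):
        with pytest.raises(ValueError):
            call_rich_club(rich_club_phi(k4))

    def test_strongest_component_from_phi_plateau(self):
        degrees = {f"v{d}": d for d in range(6)}
        prof = profile_from_rho([1.2, 1.2, 1.2, 1.2], degrees=degrees)
        prof.phi = np.array([0.3, 0.7, 0.96, 0.99])
        call = call_rich_club(prof, plateau_threshold=0.95)
        # k* = 2: phi >= 0.95 from k = 2 onward -> nodes of degree > 2
        assert call.strongest_component_nodes == {"v3", "v4", "v5"}


class TestCompareFrequency:
    def test_identical_groups_no_contrast(self):
        freq = {"a": 5, "b": 5, "c": 5, "d": 5}
        fold, p = compare_frequency({"a", "b"}, freq)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_tenfold_zero_variance_contrast(self):
        freq = {"a": 10, "b": 10, "c": 10, "x": 1, "y": 1, "z": 1}
        fold, p = compare_frequency({"a", "b", "c"}, freq)
        assert fold == pytest.approx(10.0)
        assert p == 0.0  # degenerate zero-variance case with distinct means

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_frequency({"a"}, {"a": 1, "b": 2, "c": 3})
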