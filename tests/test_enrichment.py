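import networkx as nx
import numpy as np
import pytest
from scipy import stats

from oracles import fisher_two_sided_oracle
from ppi_richclub.enrichment import (benjamini_hochberg, drug_enrichment,
                                     fisher_exact, target_degree_comparison)


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((1, 1, 1, 1), 1.0),
        ((2, 0, 0, 2), 2 / 6),       # 3 tables with margins (2,2)/(2,2)
        ((5, 0, 0, 5), 2 / 252),     # enumeration over a = 0..5
    ])
    def test_enumerated_small_tables(self, table, expected):
        p, _ = fisher_exact(*table)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_transpose_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact(a, b, c, d)[0] == pytest.approx(
                fisher_exact(a, c, b, d)[0], abs=1e-12)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact(a, b, c, d)
            _, p_ref = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(p_ref, rel=1e-7, abs=1e-12)

    def test_agrees_with_integer_enumeration(self, rng):
        for _ in range(60):
            r1 = int(rng.integers(1, 25))
            r2 = int(rng.integers(0, 25))
            c1 = int(rng.integers(0, r1 + r2 + 1))
            oracle = fisher_two_sided_oracle(r1, r2, c1)
            for a, p_exp in oracle.items():
                p, _ = fisher_exact(a, r1 - a, c1 - a, r2 - c1 + a)
                assert p == pytest.approx(p_exp, abs=1e-10)

    def test_odds_ratio_continuity_correction(self):
        _, odds = fisher_exact(3, 0, 1, 4)
        assert odds == pytest.approx((3.5 * 4.5) / (0.5 * 1.5))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(0, 0, 0, 0)

    def test_one_sided_upper_tail(self):
        p, _ = fisher_exact(5, 0, 0, 5, alternative="greater")
        assert p == pytest.approx(1 / 252)


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(3)
    p = rng.uniform(size=25).tolist()
    ours = benjamini_hochberg(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(ours, ref)


class TestDrugEnrichment:
    def test_foreground_equal_background_no_contrast(self):
        fg = {"a", "b", "c", "d"}
        recs = drug_enrichment({"d1": {"a", "b"}, "d2": {"c"}}, fg, fg)
        assert all(r.p_value == pytest.approx(1.0) for r in recs)

    def test_perfect_foreground_drug_ranks_first(self):
        fg = {"a", "b"}
        bg = fg | {f"x{i}" for i in range(40)}
        drugs = {"hit": {"a", "b"}, "miss": {"x0", "x1"},
                 "half": {"a", "x2"}}
        recs = drug_enrichment(drugs, fg, bg)
        assert recs[0].set_name == "hit"
        assert recs[0].p_value < recs[-1].p_value

    def test_counts_form_a_partition_of_background(self):
        fg = {"a", "b", "c"}
        bg = fg | {f"x{i}" for i in range(10)}
        recs = drug_enrichment({"d": {"a", "x1", "x2"}}, fg, bg)
        r = recs[0]
        assert (r.a, r.b, r.c, r.d) == (1, 2, 2, 8)
        assert r.a + r.b + r.c + r.d == len(bg)

    def test_integer_background_universe(self):
        recs = drug_enrichment({"d": {"a", "b", "zzz"}}, {"a", "b", "c"}, 20000)
        r = recs[0]
        assert (r.a, r.b, r.c) == (2, 1, 1)
        assert r.a + r.b + r.c + r.d == 20000
        assert r.p_value < 1e-4  # 2 of 3 universe hits inside a 3-node foreground

    def test_drug_outside_background_skipped(self):
        fg = {"a", "b"}
        bg = fg | {"c", "d"}
        recs = drug_enrichment({"ghost": {"zzz"}, "ok": {"a"}}, fg, bg)
        assert [r.set_name for r in recs] == ["ok"]

    def test_growing_background_never_weakens_enrichment(self):
        # enrichment of a set in itself: adding background non-targets
        # (growing d) can only sharpen the contrast
        fg = {"t1", "t2", "t3"}
        last = 1.0
        for extra in (5, 20, 80, 320):
            bg = fg | {f"x{i}" for i in range(extra)}
            rec = drug_enrichment({"d": set(fg)}, fg, bg)[0]
            assert rec.p_value <= last + 1e-12
            last = rec.p_value


class TestTargetDegreeComparison:
    def test_identical_degree_multisets(self):
        G = nx.cycle_graph(8)  # all degrees 2
        mt, mn, p = target_degree_comparison(G, {0, 1, 2})
        assert mt == mn == 2.0
        assert p == pytest.approx(1.0)

    def test_double_star_hubs_have_higher_degree(self):
        G = nx.Graph()
        G.add_edges_from([("h1", f"a{i}") for i in range(5)])
        G.add_edges_from([("h2", f"b{i}") for i in range(5)])
        G.add_edge("h1", "h2")
        mt, mn, p = target_degree_comparison(G, {"h1", "h2"})
        assert mt > mn
        assert p < 0.05

    def test_tiny_group_rejected(self):
        G = nx.path_graph(5)
        with pytest.raises(ValueError):
            target_degree_comparison(G, {0})
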