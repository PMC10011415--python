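import numpy as np
import pytest

import hypermass as hm
from hypermass.hypergraph import load_hypergraph, write_hypergraph


class TestLoading:
    def test_edge_list_parse(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("# comment\n0 1 2\n1 2\n\n")
        H = load_hypergraph(f)
        assert H.node_count == 3
        assert H.n_hyperedges == 2

    def test_set_deduplication(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("0 1\n1 0\n")
        H = load_hypergraph(f)
        assert H.n_hyperedges == 1

    def test_drops_singletons_and_within_edge_repeats(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("5\n0 1\n2 2\n")
        H = load_hypergraph(f)
        # "2 2" collapses to a singleton set and is dropped too
        assert H.n_hyperedges == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("0 1\nfoo bar\n")
        with pytest.raises(ValueError, match=":2"):
            load_hypergraph(f)

    def test_labels_remapped_in_first_appearance_order(self, tmp_path):
        f = tmp_path / "h.txt"
        f.write_text("10 30\n30 20\n")
        H = load_hypergraph(f)
        assert H.node_labels == [10, 30, 20]
        assert H.node_count == 3

    def test_simplex_pair(self, tmp_path):
        (tmp_path / "x-nverts.txt").write_text("3\n2\n")
        (tmp_path / "x-simplices.txt").write_text("0\n1\n2\n1\n2\n")
        H = load_hypergraph(tmp_path / "x-nverts.txt", format="simplex-pair")
        assert H.node_count == 3
        assert H.n_hyperedges == 2

    def test_simplex_pair_length_mismatch(self, tmp_path):
        (tmp_path / "x-nverts.txt").write_text("3\n3\n")
        (tmp_path / "x-simplices.txt").write_text("0\n1\n2\n1\n2\n")
        with pytest.raises(ValueError, match="mismatch"):
            load_hypergraph(tmp_path / "x-nverts.txt", format="simplex-pair")

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        edges = set()
        while len(edges) < 12:
            c = rng.integers(2, 6)
            edges.add(tuple(sorted(rng.choice(30, size=c, replace=False).tolist())))
        H = hm.Hypergraph(sorted(edges), node_count=30)
        path = tmp_path / "rt.txt"
        write_hypergraph(H, path)
        H2 = load_hypergraph(path)
        # written with canonical 0..N-1 labels that reload identically
        assert H2.edge_key_set() == {
            tuple(sorted(H2.node_labels.index(v) for v in e)) for e in map(tuple, H.hyperedges)
        }


class TestValidation:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hm.Hypergraph([(0, 5)], node_count=3)

    def test_rejects_duplicates_and_repeats(self):
        with pytest.raises(ValueError):
            hm.Hypergraph([(0, 1), (1, 0)])
        with pytest.raises(ValueError):
            hm.Hypergraph([(1, 1)])

    def test_params_domain(self):
        with pytest.raises(ValueError):
            hm.DynamicsParameters(lam=-1, delta=1, theta_star=0.5)
        with pytest.raises(ValueError):
            hm.DynamicsParameters(lam=1, delta=1, theta_star=1.5)


class TestProjection:
    def test_single_triangle(self):
        H = hm.Hypergraph([(0, 1, 2)])
        A = hm.projected_adjacency(H)
        assert A[0, 1] == pytest.approx(0.5)
        assert A[0, 0] == 0.0

    def test_disjoint_nodes_zero(self):
        H = hm.Hypergraph([(0, 1), (2, 3)])
        assert hm.projected_adjacency(H)[0, 2] == 0.0

    def test_accumulation(self):
        H = hm.Hypergraph([(0, 1), (0, 1, 2)])
        assert hm.projected_adjacency(H)[0, 1] == pytest.approx(1.5)

    def test_against_brute_force(self):
        rng = np.random.default_rng(7)
        edges = set()
        while len(edges) < 10:
            c = rng.integers(2, 6)
            edges.add(tuple(sorted(rng.choice(15, size=c, replace=False).tolist())))
        H = hm.Hypergraph(sorted(edges), node_count=15)
        A = hm.projected_adjacency(H)
        B = np.zeros((15, 15))
        for i in range(15):
            for k in range(15):
                if i == k:
                    continue
                for e in H.hyperedges:
                    if i in e and k in e:
                        B[i, k] += 1.0 / (e.size - 1)
        assert np.allclose(A, B)
        assert np.allclose(A, A.T)
        assert np.all(A >= 0)


class TestComponents:
    def test_levels(self, toy_hypergraph):
        full = hm.giant_component(toy_hypergraph, level="full")
        assert full == set(range(7))
        pairwise = hm.giant_component(toy_hypergraph, level="pairwise-only")
        assert pairwise == {0, 1, 2}

    def test_disjoint_sizes(self):
        H = hm.Hypergraph([(0, 1, 2), (3, 4)])
        assert hm.giant_component(H) == {0, 1, 2}

    def test_tie_break_smallest_label(self):
        H = hm.Hypergraph([(3, 4), (0, 1)])
        assert hm.giant_component(H) == {0, 1}

    def test_chain_overlap_spans_all(self):
        # hyperedges overlapping pairwise in a chain connect everything
        edges = [tuple(range(i, i + 3)) for i in range(0, 12, 2)]
        H = hm.Hypergraph(edges)
        assert hm.giant_component(H, level="full") == set(range(13))

    def test_restrict(self, toy_hypergraph):
        sub = toy_hypergraph.restrict({0, 1, 2, 3})
        assert sub.node_count == 4
        assert sub.n_hyperedges == 3  # (3,4,5,6) loses too many members


class TestThresholdAndRate:
    @pytest.mark.parametrize(
        "card,ts,expected",
        [(5, 0.5, 3), (2, 0.5, 1), (83, 0.5, 42), (10, 0.0, 0), (4, 1.0, 4)],
    )
    def test_threshold(self, card, ts, expected):
        assert hm.hyperedge_threshold(card, ts) == expected

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            hm.hyperedge_threshold(5, 1.2)

    def test_rate_log2(self):
        p = hm.DynamicsParameters(lam=0.1, delta=1, theta_star=0.5)
        assert hm.hyperedge_rate(2, p) == pytest.approx(0.1)
        p1 = p.replace(lam=1.0)
        assert hm.hyperedge_rate(4, p1) == pytest.approx(2.0)

    def test_per_member_rate_vanishes_for_large_groups(self):
        p = hm.DynamicsParameters(lam=1.0, delta=1, theta_star=0.5)
        vals = [hm.hyperedge_rate(c, p) / c for c in (4, 16, 64, 256, 1024)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01


class TestThresholdProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(2, 500), st.floats(0.0, 1.0))
    def test_threshold_bounds_and_monotonicity(self, card, ts):
        th = hm.hyperedge_threshold(card, ts)
        assert 0 <= th <= card
        if ts > 0:
            assert th >= 1
        # monotone in the critical-mass fraction
        assert th <= hm.hyperedge_threshold(card, min(1.0, ts + 0.1))
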