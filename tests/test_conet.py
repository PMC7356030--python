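import itertools

import networkx as nx
import numpy as np
import pytest

from beelit.conet import (
    bootstrap_transitivity_ci,
    build_network,
    compute_cooccurrence,
    global_transitivity,
    write_network,
)
from beelit.normalize import SynonymMap, normalize_corpus
from conftest import make_corpus, random_keyword_corpus


def norm(rows):
    return normalize_corpus(make_corpus(rows), SynonymMap())


def brute_force_transitivity(net: nx.Graph) -> float:
    """Independent enumeration: 3 * triangles / connected triplets."""
    nodes = list(net.nodes)
    triangles = 0
    triplets = 0
    for a, b, c in itertools.combinations(nodes, 3):
        edges = net.has_edge(a, b) + net.has_edge(b, c) + net.has_edge(a, c)
        if edges == 3:
            triangles += 1
            triplets += 3  # each triangle contains three length-2 paths
        elif edges == 2:
            triplets += 1
    return 0.0 if triplets == 0 else 3.0 * triangles / triplets


def brute_force_stats(corpus, keywords):
    """Exhaustive contingency counting of per-pair co-membership."""
    sets = [set(r.keywords) for r in corpus.records]
    N = len(sets)
    n = {kw: sum(kw in s for s in sets) for kw in keywords}
    n_pair = {
        frozenset((a, b)): sum(a in s and b in s for s in sets)
        for a, b in itertools.combinations(keywords, 2)
    }
    return N, n, n_pair


class TestCooccurrence:
    def test_counts_and_probabilities(self):
        rows = (
            [(2000, ["i", "j"])] * 3 + [(2000, ["i"])] * 2
            + [(2000, ["j"])] * 1 + [(2000, [])] * 4
        )
        stats = compute_cooccurrence(norm(rows), ["i", "j"])
        assert stats.N == 10
        assert stats.n_i.tolist() == [5, 4]
        assert stats.n_ij[0, 1] == 3
        assert stats.p_i[0] == pytest.approx(0.5)
        assert stats.O[0, 1] == pytest.approx(0.3)
        assert stats.E[0, 1] == pytest.approx(0.2)

    def test_absent_keyword_has_zero_everything(self):
        stats = compute_cooccurrence(norm([(2000, ["x"])]), ["x", "ghost"])
        assert stats.n_i[1] == 0
        assert stats.O[0, 1] == 0 and stats.E[0, 1] == 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        corpus = norm_random(rng, 20, list("abcde"))
        stats = compute_cooccurrence(corpus, list("abcde"))
        assert (stats.n_ij == stats.n_ij.T).all()

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError):
            compute_cooccurrence(norm([(2000, ["x"])]), [])


def norm_random(rng, n, keywords, p=0.4):
    return normalize_corpus(random_keyword_corpus(rng, n, keywords, p), SynonymMap())


class TestBuildNetwork:
    def test_edge_iff_observed_exceeds_expected(self):
        rows = (
            [(2000, ["i", "j"])] * 3 + [(2000, ["i"])] * 2
            + [(2000, ["j"])] * 1 + [(2000, [])] * 4
        )
        net = build_network(compute_cooccurrence(norm(rows), ["i", "j"]))
        assert net.has_edge("i", "j")
        assert net["i"]["j"]["weight"] == pytest.approx(0.1)

    def test_equality_gives_no_edge(self):
        # n_ij/N == p_i p_j exactly: N=4, n_i=n_j=2, n_ij=1 -> O=E=0.25
        rows = [(2000, ["i", "j"]), (2000, ["i"]), (2000, ["j"]), (2000, [])]
        net = build_network(compute_cooccurrence(norm(rows), ["i", "j"]))
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"i", "j"}  # isolated nodes retained

    def test_never_cooccurring_pair_has_no_edge(self):
        rows = [(2000, ["i"]), (2000, ["j"])]
        net = build_network(compute_cooccurrence(norm(rows), ["i", "j"]))
        assert net.number_of_edges() == 0

    def test_all_weights_strictly_positive(self):
        rng = np.random.default_rng(8)
        corpus = norm_random(rng, 40, list("abcdef"))
        net = build_network(compute_cooccurrence(corpus, list("abcdef")))
        assert all(d["weight"] > 0 for _, _, d in net.edges(data=True))

    def test_matches_exhaustive_contingency_counting(self):
        rng = np.random.default_rng(31)
        keywords = list("abcdefgh")
        for _ in range(20):
            corpus = norm_random(rng, int(rng.integers(5, 31)), keywords,
                                 p=float(rng.uniform(0.2, 0.6)))
            stats = compute_cooccurrence(corpus, keywords)
            N, n, n_pair = brute_force_stats(corpus, keywords)
            assert stats.N == N
            for i, a in enumerate(keywords):
                assert stats.n_i[i] == n[a]
                for j in range(i + 1, len(keywords)):
                    b = keywords[j]
                    assert stats.n_ij[i, j] == n_pair[frozenset((a, b))]
            net = build_network(stats)
            for i, a in enumerate(keywords):
                for j in range(i + 1, len(keywords)):
                    b = keywords[j]
                    O = n_pair[frozenset((a, b))] / N
                    E = (n[a] / N) * (n[b] / N)
                    assert net.has_edge(a, b) == (O > E)


class TestTransitivity:
    def test_triangle(self):
        net = nx.complete_graph(3)
        assert global_transitivity(net) == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        assert global_transitivity(nx.path_graph(3)) == pytest.approx(0.0)

    def test_triangle_plus_pendant(self):
        net = nx.complete_graph(3)
        net.add_edge(0, 3)
        assert global_transitivity(net) == pytest.approx(0.6)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            net = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)),
                                      seed=int(rng.integers(0, 2**31)))
            assert global_transitivity(net) == pytest.approx(
                brute_force_transitivity(net), abs=1e-12
            )


class TestBootstrapCI:
    def test_degenerate_corpus_gives_point_interval(self):
        # a, b, c co-occur perfectly in half the records: every resample
        # (short of an all-or-nothing draw) yields the same triangle
        rows = [(2000, ["a", "b", "c"])] * 20 + [(2000, [])] * 20
        corpus = norm(rows)
        lo, hi = bootstrap_transitivity_ci(corpus, ["a", "b", "c"],
                                           n_boot=100, seed=0)
        assert (lo, hi) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        corpus = norm_random(rng, 50, list("abcdef"))
        a = bootstrap_transitivity_ci(corpus, list("abcdef"), n_boot=150, seed=5)
        b = bootstrap_transitivity_ci(corpus, list("abcdef"), n_boot=150, seed=5)
        assert a == b

    def test_interval_ordered_and_bounded(self):
        rng = np.random.default_rng(4)
        corpus = norm_random(rng, 50, list("abcdef"))
        lo, hi = bootstrap_transitivity_ci(corpus, list("abcdef"), n_boot=150, seed=5)
        assert 0.0 <= lo <= hi <= 1.0


class TestIndependenceNull:
    def test_mean_excess_shrinks_with_sample_size(self):
        # under independent keyword sampling |O - E| contracts as N grows
        rng = np.random.default_rng(77)
        keywords = list("abcdef")
        means = []
        for n in (50, 400, 3200):
            corpus = norm_random(rng, n, keywords, p=0.3)
            stats = compute_cooccurrence(corpus, keywords)
            iu = np.triu_indices(len(keywords), k=1)
            means.append(np.abs(stats.O - stats.E)[iu].mean())
        assert means[2] < means[1] < means[0]


class TestExport:
    def test_edge_list_tsv(self, tmp_path):
        rows = [(2000, ["a", "b"])] * 3 + [(2000, [])] * 3
        net = build_network(compute_cooccurrence(norm(rows), ["a", "b"]))
        path = tmp_path / "net.tsv"
        write_network(net, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["source", "target", "O", "E", "weight"]
        assert len(lines) == 2

    def test_graphml_round_trip(self, tmp_path):
        rows = [(2000, ["a", "b"])] * 3 + [(2000, [])] * 3
        net = build_network(compute_cooccurrence(norm(rows), ["a", "b"]))
        path = tmp_path / "net.graphml"
        write_network(net, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert back["a"]["b"]["weight"] == pytest.approx(net["a"]["b"]["weight"])
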