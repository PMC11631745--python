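import math

import networkx as nx
import numpy as np
import pytest

from comutnet import (
    absolute_or,
    bh_adjust,
    build_network,
    conditional_mle_or,
    cooc_proportion,
    detect_modules,
    eligible_genes,
    fisher_exact_2x2,
    label_modules,
    map_equation_score,
)
from comutnet import test_all_pairs as compute_all_pairs
from comutnet.io_model import GeneAlterationMatrix
from comutnet.network import CoocPair, haldane_anscombe_or

from _oracles import (
    brute_force_min_partition,
    cmle_or_enumeration,
    fisher_p_enumeration,
)


class TestFisherExact:
    def test_worked_example(self):
        or_hat, p = fisher_exact_2x2((3, 1, 1, 3))
        assert p == pytest.approx(0.485714285714, rel=1e-9)

    def test_complete_exclusivity(self):
        or_hat, p = fisher_exact_2x2((0, 10, 10, 0))
        assert or_hat == 0.0
        assert p == pytest.approx(1.0825e-5, rel=1e-3)

    def test_perfect_cooccurrence(self):
        or_hat, p = fisher_exact_2x2((10, 0, 0, 10))
        assert or_hat == math.inf
        assert p == pytest.approx(1.0825e-5, rel=1e-3)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            cells = rng.integers(0, 12, size=4)
            if cells.sum() == 0:
                continue
            n11, n10, n01, n00 = map(int, cells)
            _, p = fisher_exact_2x2((n11, n10, n01, n00))
            oracle = fisher_p_enumeration(n11, n10, n01, n00)
            assert p == pytest.approx(oracle, rel=1e-7, abs=1e-12)


class TestConditionalMle:
    def test_worked_example(self):
        assert conditional_mle_or(5, 3, 2, 8) == pytest.approx(5.899, abs=5e-4)

    def test_boundary_and_degenerate(self):
        assert conditional_mle_or(0, 5, 5, 5) == 0.0
        assert conditional_mle_or(5, 0, 0, 5) == math.inf
        assert math.isnan(conditional_mle_or(0, 0, 3, 4))  # empty first row

    def test_matches_scipy_root_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 25:
            cells = rng.integers(0, 10, size=4)
            n11, n10, n01, n00 = map(int, cells)
            oracle = cmle_or_enumeration(n11, n10, n01, n00)
            got = conditional_mle_or(n11, n10, n01, n00)
            if math.isnan(oracle):
                assert math.isnan(got)
            elif math.isinf(oracle) or oracle == 0.0:
                assert got == oracle
            else:
                assert got == pytest.approx(oracle, rel=1e-6)
                checked += 1

    def test_conditioning_defines_psi(self):
        # for interior tables the fitted psi reproduces the observed
        # count as the noncentral hypergeometric expectation
        from scipy.stats import nchypergeom_fisher

        psi = conditional_mle_or(4, 6, 3, 7)
        mean = nchypergeom_fisher.mean(20, 10, 7, psi)
        assert mean == pytest.approx(4.0, abs=1e-8)


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_q_at_least_p_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestDescriptiveStats:
    def test_cooc_proportion(self):
        assert cooc_proportion(5, 10, 5) == pytest.approx(25.0)
        assert cooc_proportion(0, 0, 0) == 0.0

    def test_haldane_anscombe(self):
        # all-cell +1/2 correction of (0,10,10,0)
        assert haldane_anscombe_or(0, 10, 10, 0) == pytest.approx(0.25 / 110.25)

    def test_absolute_or(self):
        assert absolute_or(4.0) == 4.0
        assert absolute_or(0.25) == 4.0


def _matrix_from_columns(cols: dict[str, list[int]]) -> GeneAlterationMatrix:
    genes = sorted(cols)
    n = len(next(iter(cols.values())))
    altered = np.array([[bool(cols[g][i]) for g in genes] for i in range(n)])
    return GeneAlterationMatrix(
        [f"S{i}" for i in range(n)], genes, altered, np.ones_like(altered)
    )


class TestPairTesting:
    def test_counts_and_bh_across_pairs(self):
        m = _matrix_from_columns(
            {
                "A": [1, 1, 1, 0, 0, 0, 0, 0],
                "B": [1, 1, 0, 0, 0, 0, 0, 0],
                "C": [0, 0, 0, 1, 1, 0, 0, 0],
            }
        )
        pairs = compute_all_pairs(m, min_prevalence=1.0)
        assert len(pairs) == 3
        ab = next(p for p in pairs if (p.gene_a, p.gene_b) == ("A", "B"))
        assert (ab.n11, ab.n10, ab.n01, ab.n00) == (2, 1, 0, 5)
        expected_q = bh_adjust([p.p_two_sided for p in pairs])
        assert np.allclose([p.q_bh for p in pairs], expected_q)

    def test_pair_denominator_requires_both_assayable(self):
        altered = np.array([[True, False], [False, True], [False, False]])
        assayable = np.array([[True, True], [True, True], [True, False]])
        m = GeneAlterationMatrix(["S0", "S1", "S2"], ["A", "B"], altered, assayable)
        pairs = compute_all_pairs(m, min_prevalence=0.0)
        assert pairs[0].n_eligible == 2  # S2 not assayable for B

    def test_eligibility_threshold(self, study_matrix):
        for g in eligible_genes(study_matrix, 1.0):
            assert study_matrix.prevalence(g) >= 1.0


def _two_triangles() -> nx.Graph:
    g = nx.Graph()
    for a, b in [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f")]:
        g.add_edge(a, b, or_raw=1.0, weight=1.0)
    return g


class TestMapEquation:
    def test_two_triangles_worked_example(self):
        g = _two_triangles()
        part2 = {u: 0 if u in "abc" else 1 for u in g.nodes}
        part1 = {u: 0 for u in g.nodes}
        assert map_equation_score(g, part2) == pytest.approx(math.log2(3), abs=1e-9)
        assert map_equation_score(g, part1) == pytest.approx(
            math.log2(6), abs=1e-9
        )

    def test_all_singletons_penalized(self):
        g = _two_triangles()
        singles = {u: i for i, u in enumerate(sorted(g.nodes))}
        part2 = {u: 0 if u in "abc" else 1 for u in g.nodes}
        assert map_equation_score(g, singles) > map_equation_score(g, part2)

    def test_invalid_partition_rejected(self):
        g = _two_triangles()
        with pytest.raises(ValueError):
            map_equation_score(g, {"a": 0})  # incomplete cover


class TestDetectModules:
    def test_recovers_two_triangles(self):
        part, L = detect_modules(_two_triangles())
        assert len(set(part.values())) == 2
        assert {frozenset(u for u in part if part[u] == m)
                for m in set(part.values())} == {
            frozenset("abc"), frozenset("def")
        }
        assert L == pytest.approx(math.log2(3), abs=1e-9)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for trial in range(12):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, 0.55, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                w = float(rng.uniform(0.2, 6.0))
                g[u][v]["or_raw"] = w
                g[u][v]["weight"] = w
            _, greedy_L = detect_modules(g)
            _, oracle_L = brute_force_min_partition(
                g, lambda gg, pp: map_equation_score(gg, pp)
            )
            assert greedy_L == pytest.approx(oracle_L, abs=1e-9)

    def test_deterministic(self):
        g = _two_triangles()
        assert detect_modules(g, seed=0) == detect_modules(g, seed=99)

    def test_agrees_with_igraph_infomap_qualitatively(self):
        # independent implementation of the same objective family:
        # igraph's infomap should find the same two communities
        import igraph

        g = _two_triangles()
        nodes = sorted(g.nodes)
        ig = igraph.Graph(
            n=len(nodes),
            edges=[(nodes.index(u), nodes.index(v)) for u, v in g.edges],
        )
        communities = ig.community_infomap()
        igraph_parts = {
            frozenset(nodes[i] for i in block) for block in communities
        }
        part, _ = detect_modules(g)
        our_parts = {
            frozenset(u for u in part if part[u] == m)
            for m in set(part.values())
        }
        assert igraph_parts == our_parts


class TestBuildNetwork:
    def _pairs(self):
        return [
            CoocPair("A", "B", 8, 2, 2, 88, or_hat=16.0, p_two_sided=1e-6,
                     q_bh=1e-5, cooc_proportion=66.7),
            CoocPair("A", "C", 0, 10, 10, 80, or_hat=0.0, p_two_sided=1e-4,
                     q_bh=1e-3, cooc_proportion=0.0),
            CoocPair("B", "C", 3, 7, 7, 83, or_hat=4.0, p_two_sided=0.2,
                     q_bh=0.4, cooc_proportion=17.6),
        ]

    def test_threshold_and_attributes(self):
        net = build_network(self._pairs(), q_threshold=0.05)
        assert set(net.graph.edges) == {("A", "B"), ("A", "C")}
        assert net.graph["A"]["B"]["sign"] == "co-occurring"
        assert net.graph["A"]["C"]["sign"] == "exclusive"

    def test_zero_or_replaced_by_corrected_or(self):
        net = build_network(self._pairs(), q_threshold=0.05)
        e = net.graph["A"]["C"]
        expected = haldane_anscombe_or(0, 10, 10, 80)
        assert e["or_raw"] == pytest.approx(expected)
        assert e["weight"] == pytest.approx(1.0 / expected)

    def test_strength_sums_absolute_ors(self):
        net = build_network(self._pairs(), q_threshold=0.05)
        expected = 16.0 + 1.0 / haldane_anscombe_or(0, 10, 10, 80)
        assert net.strength("A") == pytest.approx(expected)
        assert net.degree("A") == 2


class TestLabelModules:
    def test_label_is_top_combination(self):
        m = _matrix_from_columns(
            {
                "X": [1, 1, 1, 0, 0],
                "Y": [1, 0, 0, 1, 0],
            }
        )
        mods = label_modules({"X": 0, "Y": 0}, m)
        assert len(mods) == 1
        # combinations: X alone twice, X+Y once, Y alone once -> label X
        assert mods[0].label == "X"
        assert mods[0].combination_counts == {"X": 2, "X+Y": 1, "Y": 1}

    def test_empty_module_labeled_none(self):
        m = _matrix_from_columns({"X": [0, 0], "Y": [0, 0]})
        mods = label_modules({"X": 0, "Y": 0}, m)
        assert mods[0].label == "(none)"
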