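"""Causal graph machinery checked against independent brute-force oracles.

The d-separation oracle enumerates every undirected path and applies the
blocking rules directly; the backdoor oracle enumerates subsets.  Both
are deliberately naive and independent of the networkx-based
implementation they check.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from screencausal.dag import (CausalDAG, backdoor_adjustment_sets,
                              build_screening_dag, d_separated, format_dag,
                              implied_independences, is_valid_adjustment_set,
                              parse_dag)


# ---------------------------------------------------------------------------
# brute-force oracles


def _all_paths(g: nx.DiGraph, x: str, y: str):
    """All simple undirected paths between x and y with edge directions."""
    ug = g.to_undirected()
    for path in nx.all_simple_paths(ug, x, y):
        yield path


def _path_blocked(g: nx.DiGraph, path, z: set) -> bool:
    """Apply the d-separation blocking rules along one path."""
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        into_left = g.has_edge(prev, node)
        into_right = g.has_edge(nxt, node)
        if into_left and into_right:  # collider
            desc = nx.descendants(g, node) | {node}
            if not (desc & z):
                return True
        else:  # chain or fork
            if node in z:
                return True
    return False


def oracle_d_separated(g: nx.DiGraph, x: str, y: str, z: set) -> bool:
    return all(_path_blocked(g, p, z) for p in _all_paths(g, x, y))


def oracle_backdoor_valid(g: nx.DiGraph, exposure, outcome, z: set) -> bool:
    if z & (nx.descendants(g, exposure) | {exposure, outcome}):
        return False
    g2 = g.copy()
    g2.remove_edges_from(list(g2.out_edges(exposure)))
    return oracle_d_separated(g2, exposure, outcome, z)


def random_dags(n_graphs: int, max_nodes: int = 7, seed: int = 0):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(3, max_nodes + 1))
        p = rng.uniform(0.15, 0.5)
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):  # topological order: i -> j only
                if rng.random() < p:
                    g.add_edge(i, j)
        yield g


# ---------------------------------------------------------------------------


class TestDSeparation:
    def test_blocked_chain(self):
        dag = CausalDAG(nx.DiGraph([("A", "B"), ("B", "C")]))
        assert d_separated(dag, "A", "C", {"B"})
        assert not d_separated(dag, "A", "C", set())

    def test_conditioning_opens_collider(self):
        dag = CausalDAG(nx.DiGraph([("A", "B"), ("C", "B")]))
        assert d_separated(dag, "A", "C", set())
        assert not d_separated(dag, "A", "C", {"B"})

    def test_unknown_node_rejected(self):
        dag = CausalDAG(nx.DiGraph([("A", "B")]))
        with pytest.raises(KeyError):
            d_separated(dag, "A", "Q", set())

    def test_agrees_with_path_enumeration_oracle(self):
        """Exhaustive agreement on random DAGs up to 7 nodes, all (X, Y, Z)."""
        checked = 0
        for g in random_dags(40, max_nodes=7, seed=42):
            dag = CausalDAG(g)
            nodes = list(g.nodes)
            for x, y in itertools.combinations(nodes, 2):
                rest = [n for n in nodes if n not in (x, y)]
                for r in range(len(rest) + 1):
                    for z in itertools.combinations(rest, r):
                        assert d_separated(dag, x, y, set(z)) == \
                            oracle_d_separated(g, x, y, set(z))
                        checked += 1
        assert checked > 5_000


class TestBackdoor:
    def test_screening_dag_minimal_set(self):
        dag = build_screening_dag()
        sets = backdoor_adjustment_sets(dag)
        assert frozenset({"reader_set", "ai_prediction"}) in sets

    def test_screening_dag_extended_set_validates(self):
        dag = build_screening_dag()
        assert is_valid_adjustment_set(
            dag, {"reader_set", "ai_prediction", "age", "round", "density",
                  "supervision"})

    def test_no_backdoor_path_empty_set_qualifies(self):
        dag = CausalDAG(nx.DiGraph([("X", "Y")]), exposure="X", outcome="Y")
        assert backdoor_adjustment_sets(dag) == [frozenset()]

    def test_returned_sets_minimal_and_valid_on_random_dags(self):
        """Every returned set passes the independent backdoor oracle and no
        proper subset does."""
        n_sets = 0
        for g in random_dags(40, max_nodes=6, seed=7):
            nodes = list(g.nodes)
            if len(nodes) < 3:
                continue
            exposure, outcome = nodes[0], nodes[-1]
            dag = CausalDAG(g, exposure=exposure, outcome=outcome)
            for z in backdoor_adjustment_sets(dag):
                assert oracle_backdoor_valid(g, exposure, outcome, set(z))
                for drop in z:
                    assert not any(
                        oracle_backdoor_valid(g, exposure, outcome, set(sub))
                        for sub in [z - {drop}])
                n_sets += 1
        assert n_sets > 10

    def test_latent_nodes_excluded_from_candidates(self):
        dag = build_screening_dag()
        for z in backdoor_adjustment_sets(dag):
            assert not (z & dag.latent)


class TestImpliedIndependences:
    def test_empty_graph_pairwise_marginals(self):
        g = nx.DiGraph()
        g.add_nodes_from(["A", "B", "C"])
        claims = implied_independences(CausalDAG(g))
        assert len(claims) == 3
        assert all(c.z == () for c in claims)

    def test_complete_dag_no_claims(self):
        g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "C")])
        assert implied_independences(CausalDAG(g)) == []

    def test_screening_dag_claims_self_consistent(self):
        dag = build_screening_dag()
        claims = implied_independences(dag)
        for c in claims:
            assert d_separated(dag, c.x, c.y, set(c.z)), c.label()
            assert not ({c.x, c.y} | set(c.z)) & dag.latent

    def test_screening_dag_implies_twelve_independences(self):
        # the transcribed graph yields exactly the count the study reports
        assert len(implied_independences(build_screening_dag())) == 12

    def test_deterministic_order(self):
        a = [c.label() for c in implied_independences(build_screening_dag())]
        b = [c.label() for c in implied_independences(build_screening_dag())]
        assert a == b == sorted(a)


class TestStructure:
    def test_screening_dag_acyclic_with_expected_edges(self):
        dag = build_screening_dag()
        g = dag.graph
        assert nx.is_directed_acyclic_graph(g)
        assert g.has_edge("ai_prediction", "ai_use")
        assert g.has_edge("reader_set", "ai_use")
        assert g.has_edge("reader_set", "outcome")
        assert g.has_edge("cancer", "ai_prediction")
        assert g.has_edge("ai_use", "outcome")
        assert dag.latent == frozenset({"cancer", "unknown_risk"})

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            CausalDAG(nx.DiGraph([("A", "B"), ("B", "A")]))

    def test_serialization_round_trip(self):
        dag = build_screening_dag()
        again = parse_dag(format_dag(dag), exposure="ai_use", outcome="outcome")
        assert set(again.graph.edges) == set(dag.graph.edges)
        assert again.latent == dag.latent
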