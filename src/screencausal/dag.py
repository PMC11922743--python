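"""Causal graph for viewer self-selection in AI-supported screening.

Encodes the study's directed acyclic graph — covariates, latent cancer
status, AI prediction, reader set, viewer adoption (the exposure) and
the screening outcome — and provides d-separation queries, backdoor
adjustment-set search, and enumeration of the testable conditional
independences the graph implies among observed variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "CausalDAG",
    "IndependenceClaim",
    "build_screening_dag",
    "d_separated",
    "backdoor_adjustment_sets",
    "implied_independences",
    "parse_dag",
    "format_dag",
]


@dataclass
class CausalDAG:
    """A DAG with observability flags and designated exposure/outcome."""

    graph: nx.DiGraph
    latent: frozenset = frozenset()
    exposure: str | None = None
    outcome: str | None = None

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("graph contains a directed cycle")
        for node in self.latent:
            if node not in self.graph:
                raise ValueError(f"latent node {node!r} not in graph")
        for role, node in (("exposure", self.exposure), ("outcome", self.outcome)):
            if node is not None and node not in self.graph:
                raise ValueError(f"{role} node {node!r} not in graph")

    @property
    def observed(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n not in self.latent)

    def check_nodes(self, *names) -> None:
        for n in names:
            if n not in self.graph:
                raise KeyError(f"unknown node {n!r}")


@dataclass
class IndependenceClaim:
    """An implied (conditional) independence X _||_ Y | Z, optionally tested."""

    x: str
    y: str
    z: tuple = ()
    implied: bool = True
    statistic: float | None = None
    p_value: float | None = None
    n_permutations: int = 0
    holds: bool | None = None

    def label(self) -> str:
        cond = f" | {', '.join(self.z)}" if self.z else ""
        return f"{self.x} _||_ {self.y}{cond}"


def build_screening_dag() -> CausalDAG:
    """The study DAG, transcribed edge by edge from domain knowledge.

    Nodes: age, screening round, breast density, breast cancer (latent),
    unknown risk factors (latent), AI prediction (normal vs not normal),
    reader set, supervision, AI use (exposure), outcome (detection /
    recall endpoint).

    Edges: density decreases with age; round participation increases
    with age; cancer risk increases with age, density and first round;
    reader sets vary in how they classify density; AI predictions track
    cancer status; the visible AI prediction influences viewer choice
    (reading behavior); reader sets differ in adoption and in reading
    performance; supervision adds a third reader affecting the outcome;
    unknown risk factors drive cancer; AI use affects the outcome (the
    effect under study).
    """
    edges = [
        ("age", "density"),
        ("age", "round"),
        ("age", "cancer"),
        ("density", "cancer"),
        ("round", "cancer"),
        ("reader_set", "density"),
        ("unknown_risk", "cancer"),
        ("cancer", "ai_prediction"),
        ("ai_prediction", "ai_use"),
        ("reader_set", "ai_use"),
        ("reader_set", "outcome"),
        ("supervision", "outcome"),
        ("cancer", "outcome"),
        ("ai_use", "outcome"),
    ]
    g = nx.DiGraph(edges)
    return CausalDAG(graph=g, latent=frozenset({"cancer", "unknown_risk"}),
                     exposure="ai_use", outcome="outcome")


def d_separated(dag: CausalDAG, x: str, y: str, z=()) -> bool:
    """True iff every path between x and y is blocked by Z (d-separation)."""
    z = frozenset(z)
    dag.check_nodes(x, y, *z)
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")
    return nx.is_d_separator(dag.graph, {x}, {y}, set(z))


def _proper_backdoor(dag: CausalDAG, exposure: str, outcome: str, z: frozenset) -> bool:
    """Backdoor criterion: Z has no descendant of exposure and blocks all
    backdoor paths (checked by d-separation with exposure's outgoing
    edges removed)."""
    desc = nx.descendants(dag.graph, exposure)
    if z & desc:
        return False
    g = dag.graph.copy()
    g.remove_edges_from(list(g.out_edges(exposure)))
    return nx.is_d_separator(g, {exposure}, {outcome}, set(z))


def backdoor_adjustment_sets(dag: CausalDAG, exposure: str | None = None,
                             outcome: str | None = None,
                             max_size: int | None = None) -> list[frozenset]:
    """All subset-minimal observed adjustment sets for the backdoor criterion.

    Candidates are observed nodes that are neither the exposure/outcome
    nor descendants of the exposure.  Returns minimal sets sorted by
    size then lexicographically; the empty list means no observed set
    is valid.
    """
    exposure = exposure or dag.exposure
    outcome = outcome or dag.outcome
    if exposure is None or outcome is None:
        raise ValueError("exposure and outcome must be given")
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    dag.check_nodes(exposure, outcome)
    desc = nx.descendants(dag.graph, exposure)
    candidates = sorted(set(dag.observed) - {exposure, outcome} - desc)
    limit = len(candidates) if max_size is None else min(max_size, len(candidates))
    minimal: list[frozenset] = []
    for size in range(limit + 1):
        for combo in itertools.combinations(candidates, size):
            z = frozenset(combo)
            if any(m <= z for m in minimal):
                continue
            if _proper_backdoor(dag, exposure, outcome, z):
                minimal.append(z)
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))


def is_valid_adjustment_set(dag: CausalDAG, z, exposure: str | None = None,
                            outcome: str | None = None) -> bool:
    """Backdoor-criterion check for an arbitrary (not necessarily minimal) set."""
    exposure = exposure or dag.exposure
    outcome = outcome or dag.outcome
    z = frozenset(z)
    dag.check_nodes(exposure, outcome, *z)
    return _proper_backdoor(dag, exposure, outcome, z)


def implied_independences(dag: CausalDAG) -> list[IndependenceClaim]:
    """Testable independences among observed nodes (pairwise-Markov basis).

    For every pair of non-adjacent observed nodes the candidate
    separator is the union of the pair's observed parents; the claim is
    kept only if it actually d-separates the pair.  The list is
    canonically ordered and deterministic.
    """
    g = dag.graph
    obs = dag.observed
    claims = []
    for x, y in itertools.combinations(obs, 2):
        if g.has_edge(x, y) or g.has_edge(y, x):
            continue
        parents = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
        if parents & dag.latent:
            # latent parent: fall back to the observed subset; keep only if
            # it still separates
            parents = parents - dag.latent
        z = tuple(sorted(parents))
        if nx.is_d_separator(g, {x}, {y}, set(z)):
            claims.append(IndependenceClaim(x=x, y=y, z=z))
    return claims


# ---------------------------------------------------------------------------
# edge-list serialization: "parent -> child" lines plus "latent: a, b"


def parse_dag(text: str, exposure: str | None = None,
              outcome: str | None = None) -> CausalDAG:
    g = nx.DiGraph()
    latent: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("latent:"):
            latent |= {t.strip() for t in line[len("latent:"):].split(",") if t.strip()}
        elif "->" in line:
            a, b = (t.strip() for t in line.split("->", 1))
            g.add_edge(a, b)
        else:
            g.add_node(line)
    return CausalDAG(graph=g, latent=frozenset(latent),
                     exposure=exposure, outcome=outcome)


def format_dag(dag: CausalDAG) -> str:
    lines = [f"{a} -> {b}" for a, b in sorted(dag.graph.edges)]
    if dag.latent:
        lines.append("latent: " + ", ".join(sorted(dag.latent)))
    return "\n".join(lines) + "\n"
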