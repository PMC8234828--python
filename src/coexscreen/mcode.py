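"""Molecular-complex detection on undirected gene networks (MCODE).

Stage 1 weights every vertex by the density of the densest k-core of
its closed neighborhood times that core's k.  Stage 2 grows complexes
outward from high-weight seeds, admitting neighbors whose weight is
within a percentage (``vwp``) of the seed's, then post-processes with a
haircut (iterative removal of degree<=1 members) and optional fluff.
A complex's score is its loopless density times its size.

Nodes belong to at most one complex; a node rejected from one expansion
stays available as a later seed.  All tie-breaks are lexicographic on
node id so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass
class MCODEParams:
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_threshold: float = 0.2
    min_complex_size: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must be in [0, 1)")
        if not 0.0 <= self.fluff_density_threshold <= 1.0:
            raise ValueError("fluff_density_threshold must be in [0, 1]")
        if self.min_complex_size < 1:
            raise ValueError("min_complex_size must be >= 1")


@dataclass
class MCODEComplex:
    nodes: list[str]
    seed: str
    score: float
    rank: int


def _density(graph: nx.Graph, nodes) -> float:
    nodes = list(nodes)
    v = len(nodes)
    if v < 2:
        return 0.0
    e = graph.subgraph(nodes).number_of_edges()
    return 2.0 * e / (v * (v - 1))


def vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """Per-node weight: k_max of the closed neighborhood's densest core
    times that core's density; isolated nodes weigh 0."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        closed = [v, *graph.neighbors(v)]
        if len(closed) == 1:
            weights[v] = 0.0
            continue
        sub = graph.subgraph(closed)
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        core_nodes = [n for n, c in core_numbers.items() if c >= k_max]
        weights[v] = k_max * _density(sub, core_nodes)
    return weights


def score_complex(graph: nx.Graph, node_set) -> float:
    """Density x size; singletons score 0."""
    nodes = list(node_set)
    if not nodes:
        raise ValueError("empty node set")
    missing = [n for n in nodes if n not in graph]
    if missing:
        raise KeyError(f"nodes not in graph: {missing[:5]}")
    return _density(graph, nodes) * len(nodes)


def _haircut(graph: nx.Graph, nodes: set[str]) -> set[str]:
    nodes = set(nodes)
    while True:
        sub = graph.subgraph(nodes)
        trim = {n for n in nodes if sub.degree(n) <= 1}
        if not trim or trim == nodes:
            return nodes - trim if trim != nodes else set()
        nodes -= trim


def _fluff(graph: nx.Graph, nodes: set[str], assigned: set[str], threshold: float) -> set[str]:
    boundary = set()
    for n in nodes:
        for nb in graph.neighbors(n):
            if nb in nodes or nb in assigned:
                continue
            closed = [nb, *graph.neighbors(nb)]
            if _density(graph, closed) > threshold:
                boundary.add(nb)
    return nodes | boundary


def predict_complexes(
    graph: nx.Graph, params: MCODEParams | None = None
) -> list[MCODEComplex]:
    """Detect node-disjoint dense complexes, ranked by score descending
    (ties: larger size first, then seed id)."""
    if params is None:
        params = MCODEParams()
    if graph.number_of_nodes() == 0:
        return []
    weights = vertex_weights(graph)
    # stable seed order: weight descending, then node id
    seed_order = sorted(graph.nodes, key=lambda n: (-weights[n], str(n)))
    assigned: set[str] = set()
    raw: list[tuple[set[str], str]] = []
    for seed in seed_order:
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - params.vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            current = frontier.pop(0)
            for nb in sorted(graph.neighbors(current), key=str):
                if nb in members or nb in assigned:
                    continue
                if weights[nb] >= threshold:
                    members.add(nb)
                    frontier.append(nb)
        if params.fluff:
            members = _fluff(graph, members, assigned, params.fluff_density_threshold)
        if params.haircut:
            members = _haircut(graph, members)
        if len(members) >= params.min_complex_size:
            assigned |= members
            raw.append((members, seed))
    complexes = [
        MCODEComplex(sorted(m, key=str), seed, score_complex(graph, m), rank=0)
        for m, seed in raw
    ]
    complexes.sort(key=lambda c: (-c.score, -len(c.nodes), str(c.seed)))
    for i, c in enumerate(complexes, 1):
        c.rank = i
    return complexes
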