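"""Community detection by modularity maximization.

Three routes are provided:

* :func:`girvan_newman` — the classic divisive algorithm: repeatedly remove a
  highest edge-betweenness edge, recomputing betweenness after every removal,
  and return the intermediate component structure of maximal modularity Q.
* :func:`greedy_modularity` — the fast agglomerative (CNM) alternative for
  larger graphs.
* :func:`brute_force_best_partition` — exhaustive search over all set
  partitions, feasible up to 10 nodes; the exact oracle the heuristics are
  validated against.

Modularity of a partition {c} of a simple undirected graph with m edges is

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

where e_c counts intra-module edges of module c and d_c is the sum of degrees
of its nodes. Q is 0 for the single-module partition and bounded in [-1/2, 1].

Determinism: ties among equally central edges are broken lexicographically on
the canonical (min, max) edge name, and the best-Q scan prefers fewer
removals, so repeated runs on the same graph give identical partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import networkx as nx

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

BRUTE_FORCE_MAX_NODES = 10


@dataclass
class Partition:
    """A disjoint cover of the graph's nodes with its modularity score.

    ``modularity_q`` is None for an edgeless graph, where Q is undefined.
    """

    assignment: dict[Hashable, int]
    modularity_q: float | None
    method: str
    n_modules: int

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[Hashable]],
                         modularity_q: float | None, method: str) -> "Partition":
        comms = [sorted(c, key=str) for c in communities]
        comms.sort(key=lambda c: str(c[0]))
        assignment = {n: i for i, c in enumerate(comms) for n in c}
        return cls(assignment=assignment, modularity_q=modularity_q,
                   method=method, n_modules=len(comms))

    def modules(self) -> dict[int, set[Hashable]]:
        out: dict[int, set[Hashable]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out

    def module_sizes(self) -> list[int]:
        return sorted(len(m) for m in self.modules().values())


def modularity(graph: nx.Graph, assignment: Mapping[Hashable, int]) -> float:
    """Newman's modularity Q of a node->module assignment."""
    m = graph.number_of_edges()
    if m == 0:
        raise InvalidParameterError("modularity undefined for an edgeless graph")
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise InvalidParameterError(f"assignment does not cover node(s) {missing}")
    intra: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in graph.edges:
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    for node, deg in graph.degree:
        c = assignment[node]
        degsum[c] = degsum.get(c, 0) + deg
    q = 0.0
    for c, d_c in degsum.items():
        q += intra.get(c, 0) / m - (d_c / (2 * m)) ** 2
    return q


def edge_betweenness(graph: nx.Graph) -> dict[tuple[Hashable, Hashable], float]:
    """Shortest-path betweenness per edge, unnormalized.

    Each unordered node pair contributes 1, split equally among the equally
    short paths joining it; edge keys are canonical (min, max) tuples.
    """
    raw = nx.edge_betweenness_centrality(graph, normalized=False)
    return {_canon(u, v): s for (u, v), s in raw.items()}


def _canon(u: Hashable, v: Hashable) -> tuple[Hashable, Hashable]:
    return (u, v) if str(u) <= str(v) else (v, u)


def _components_partition(graph: nx.Graph) -> list[set[Hashable]]:
    return [set(c) for c in nx.connected_components(graph)]


def girvan_newman(graph: nx.Graph) -> Partition:
    """Divisive edge-betweenness community detection, best-Q partition.

    Scans every component structure in the removal sequence, including the
    initial one; betweenness is recomputed after each single-edge removal.
    Isolated nodes end up as singleton modules.
    """
    _check_simple(graph)
    if graph.number_of_edges() == 0:
        logger.warning("edgeless graph: every node is its own module; Q undefined")
        return Partition.from_communities([{n} for n in graph.nodes], None,
                                          "girvan_newman")
    work = graph.copy()
    best = _components_partition(work)
    best_q = modularity(graph, _assign(best))
    while work.number_of_edges() > 0:
        scores = edge_betweenness(work)
        max_score = max(scores.values())
        target = min((e for e, s in scores.items() if s == max_score),
                     key=lambda e: (str(e[0]), str(e[1])))
        work.remove_edge(*target)
        comms = _components_partition(work)
        q = modularity(graph, _assign(comms))
        if q > best_q:  # ties resolve toward fewer removals
            best, best_q = comms, q
    return Partition.from_communities(best, best_q, "girvan_newman")


def greedy_modularity(graph: nx.Graph) -> Partition:
    """Agglomerative (CNM) modularity maximization; heuristic but fast."""
    _check_simple(graph)
    if graph.number_of_edges() == 0:
        logger.warning("edgeless graph: every node is its own module; Q undefined")
        return Partition.from_communities([{n} for n in graph.nodes], None, "greedy")
    comms = [set(c) for c in
             nx.algorithms.community.greedy_modularity_communities(graph)]
    q = modularity(graph, _assign(comms))
    return Partition.from_communities(comms, q, "greedy")


def brute_force_best_partition(graph: nx.Graph) -> Partition:
    """Globally optimal-Q partition by exhaustive search (<= 10 nodes).

    Deterministic tie-break: among equal-Q optima, the partition whose
    canonical label sequence over sorted nodes is lexicographically smallest.
    """
    _check_simple(graph)
    n = graph.number_of_nodes()
    if n > BRUTE_FORCE_MAX_NODES:
        raise InvalidParameterError(
            f"brute force limited to {BRUTE_FORCE_MAX_NODES} nodes, got {n}")
    if graph.number_of_edges() == 0:
        return Partition.from_communities([{v} for v in graph.nodes], None,
                                          "brute_force")
    nodes = sorted(graph.nodes, key=str)
    m = graph.number_of_edges()
    edges = list(graph.edges)
    degree = dict(graph.degree)
    best_q, best_canon, best_part = None, None, None
    for part in _set_partitions(nodes):
        label = {node: i for i, block in enumerate(part) for node in block}
        intra = [0] * len(part)
        for u, v in edges:
            if label[u] == label[v]:
                intra[label[u]] += 1
        q = 0.0
        for i, block in enumerate(part):
            d = sum(degree[node] for node in block)
            q += intra[i] / m - (d / (2 * m)) ** 2
        canon = _canonical_labels(nodes, label)
        if best_q is None or q > best_q + 1e-15 or (
                abs(q - best_q) <= 1e-15 and canon < best_canon):
            best_q, best_canon, best_part = q, canon, part
    return Partition.from_communities(best_part, best_q, "brute_force")


def _assign(communities: list[set[Hashable]]) -> dict[Hashable, int]:
    return {n: i for i, c in enumerate(communities) for n in c}


def _canonical_labels(sorted_nodes, label: Mapping[Hashable, int]) -> tuple[int, ...]:
    remap: dict[int, int] = {}
    out = []
    for node in sorted_nodes:
        out.append(remap.setdefault(label[node], len(remap)))
    return tuple(out)


def _set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise InvalidParameterError("graph must be simple and undirected")
    if any(u == v for u, v in graph.edges):
        raise InvalidParameterError("graph must not contain self-loops")
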