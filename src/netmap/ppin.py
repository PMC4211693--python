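"""Seed-expanded protein-protein interaction network construction.

Starting from a list of seed proteins (here, MALDI-identified CSF proteins)
and a background interactome, the network is the induced subgraph on the seeds
plus all of their first interaction partners: nodes = seeds and direct
neighbours, edges = every interactome pair with both endpoints in that node
set. The expansion is one hop only. Seeds whose symbol has no listed partner
in the interactome are dropped (not kept as isolates) and reported; an alias
map lets a seed symbol be replaced by one or more database symbols before
expansion (e.g. the classical complement symbol CO4 standing for C4A and C4B).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import InvalidParameterError
from .io_formats import Interactome

logger = logging.getLogger(__name__)

AliasMap = Mapping[str, Sequence[str]]


@dataclass
class SeedResolution:
    retained: list[str]
    dropped: list[tuple[str, str]]  # (symbol, reason)
    alias_log: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)


@dataclass
class PPIN:
    """Seed-expanded interaction network with per-node seed flags."""

    graph: nx.Graph
    dropped_seeds: list[tuple[str, str]] = field(default_factory=list)
    alias_log: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def seeds(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d.get("seed"))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def resolve_seeds(seeds: Iterable[str], interactome: Interactome,
                  alias_map: AliasMap | None = None) -> SeedResolution:
    """Apply alias replacements, then drop seeds with no listed partners.

    Alias expansion happens first, so an alias target is itself checked
    against the interactome. An empty post-resolution seed set is an error.
    """
    seeds = [s.strip().upper() for s in seeds]
    if not seeds:
        raise InvalidParameterError("seed list is empty")
    alias_map = {k.upper(): [v.upper() for v in vs]
                 for k, vs in (alias_map or {}).items()}
    for key, repl in alias_map.items():
        if not repl or key in repl:
            raise InvalidParameterError(
                f"alias for {key!r} must be non-empty and distinct from the key")

    expanded: list[str] = []
    alias_log: list[tuple[str, tuple[str, ...]]] = []
    for s in seeds:
        if s in alias_map:
            repl = tuple(alias_map[s])
            alias_log.append((s, repl))
            expanded.extend(r for r in repl if r not in expanded)
        elif s not in expanded:
            expanded.append(s)

    retained, dropped = [], []
    for s in expanded:
        if interactome.partners(s):
            retained.append(s)
        else:
            dropped.append((s, "no listed partners"))
            logger.info("seed %s dropped: no listed partners", s)
    if not retained:
        raise InvalidParameterError(
            "no seed has any listed partner in the interactome")
    return SeedResolution(retained=retained, dropped=dropped, alias_log=alias_log)


def build_ppin(resolution: SeedResolution | Sequence[str],
               interactome: Interactome) -> PPIN:
    """Induced subgraph on the retained seeds and their first neighbours."""
    if isinstance(resolution, SeedResolution):
        seeds = resolution.retained
        dropped, alias_log = resolution.dropped, resolution.alias_log
    else:
        seeds = [s.upper() for s in resolution]
        dropped, alias_log = [], []
    seed_set = set(seeds)
    for s in seed_set:
        if not interactome.partners(s):
            raise InvalidParameterError(f"seed {s} has no listed partners")
    nodes = set(seed_set)
    for s in seed_set:
        nodes |= interactome.partners(s)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b in interactome.pairs
                     if a in nodes and b in nodes)
    nx.set_node_attributes(g, {n: (n in seed_set) for n in g.nodes}, "seed")
    return PPIN(graph=g, dropped_seeds=list(dropped), alias_log=list(alias_log))


def network_stats(ppin: PPIN) -> dict[str, float]:
    """Basic descriptive statistics of a PPIN."""
    g = ppin.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    density = m / math.comb(n, 2) if n >= 2 else 0.0
    return {
        "n_nodes": n,
        "n_edges": m,
        "density": density,
        "n_seeds": len(ppin.seeds),
        "n_components": nx.number_connected_components(g) if n else 0,
    }
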