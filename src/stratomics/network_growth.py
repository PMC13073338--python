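"""Iterative shortest-path signaling-network inference over a background
interactome.

Starting from root nodes R0 (the highest-degree differentially-expressed
genes in the background graph), the network grows one candidate at a time:
at each step the remaining candidate with the smallest unweighted
shortest-path distance to any current network node is added, together with
every intermediate (connector) node and the path's edges.  Growth stops
when all candidates are placed; candidates in components unreachable from
the roots are reported separately.

Ties are resolved reproducibly: among equally close candidates the
lexicographically smallest gene symbol wins, and among its shortest paths
the lexicographically smallest node sequence is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .datatypes import StratomicsError

logger = logging.getLogger(__name__)


@dataclass
class GrownNetwork:
    graph: nx.Graph
    roles: dict[str, str]                  # node -> root | dep | connector
    unreachable: list[str]
    addition_order: list[str] = field(default_factory=list)


def select_roots(dep_genes: set[str], background: nx.Graph,
                 k: int = 5) -> list[str]:
    """The k dep genes with the highest background degree (ties broken
    lexicographically); dep genes absent from the background are excluded
    with a warning."""
    if k < 1:
        raise StratomicsError("k must be >= 1")
    present = sorted(g for g in dep_genes if g in background)
    absent = sorted(set(dep_genes) - set(present))
    if absent:
        logger.warning("%d dep genes absent from background: %s%s",
                       len(absent), absent[:5], "..." if len(absent) > 5 else "")
    if not present:
        raise StratomicsError("no dep gene present in the background network")
    ranked = sorted(present, key=lambda g: (-background.degree(g), g))
    return ranked[:min(k, len(ranked))]


def _smallest_shortest_path(background: nx.Graph, sources: set[str],
                            target: str, dist_to_target: dict[str, int]
                            ) -> list[str]:
    """Lexicographically smallest shortest path from any source to target.

    ``dist_to_target`` holds BFS distances from the target.  The path is
    built greedily from the source side: the smallest source on a shortest
    path first, then at each hop the smallest neighbor one step closer to
    the target.
    """
    d = min(dist_to_target[s] for s in sources if s in dist_to_target)
    start = min(s for s in sources if dist_to_target.get(s, -1) == d)
    path = [start]
    current = start
    remaining = d
    while remaining > 0:
        nxt = min(v for v in background.neighbors(current)
                  if dist_to_target.get(v) == remaining - 1)
        path.append(nxt)
        current = nxt
        remaining -= 1
    return path


def grow_network(dep_genes: set[str], background: nx.Graph,
                 roots: list[str] | None = None, k: int = 5) -> GrownNetwork:
    """Grow the subnetwork from the roots until every reachable candidate
    is placed (see module docstring).

    ``roots`` defaults to :func:`select_roots` with the given ``k``.  Every
    output edge exists in the background; every dep gene ends up either in
    the network or on the unreachable list.
    """
    in_bg = {g for g in dep_genes if g in background}
    absent = sorted(set(dep_genes) - in_bg)
    if roots is None:
        roots = select_roots(dep_genes, background, k=k)
    if not set(roots) <= in_bg:
        raise StratomicsError("roots must be dep genes present in background")

    grown = nx.Graph()
    grown.add_nodes_from(roots)
    roles = {r: "root" for r in roots}
    candidates = sorted(in_bg - set(roots))

    # reachability is fixed: growth never leaves the components of the roots
    reachable_comp: set[str] = set()
    for r in roots:
        if r not in reachable_comp:
            reachable_comp |= nx.node_connected_component(background, r)
    unreachable = sorted([c for c in candidates if c not in reachable_comp]
                         + absent)
    candidates = [c for c in candidates if c in reachable_comp]

    order: list[str] = []
    while candidates:
        current = set(grown.nodes)
        best: tuple[int, str] | None = None
        dists: dict[str, dict[str, int]] = {}
        for cand in candidates:
            dist = nx.single_source_shortest_path_length(background, cand)
            d = min((dist[v] for v in current if v in dist), default=None)
            if d is None:
                continue
            dists[cand] = dist
            if best is None or (d, cand) < best:
                best = (d, cand)
        assert best is not None  # candidates are in reachable components
        d, chosen = best
        path = _smallest_shortest_path(background, current, chosen,
                                       dists[chosen])
        for node in path[1:]:
            roles.setdefault(node, "connector")
        roles[chosen] = "dep"
        grown.add_nodes_from(path)
        grown.add_edges_from(zip(path[:-1], path[1:]))
        order.append(chosen)
        candidates.remove(chosen)

    logger.info("network growth: %d nodes (%d roots, %d dep, %d connectors), "
                "%d unreachable",
                grown.number_of_nodes(), len(roots),
                sum(1 for r in roles.values() if r == "dep"),
                sum(1 for r in roles.values() if r == "connector"),
                len(unreachable))
    return GrownNetwork(graph=grown, roles=roles, unreachable=unreachable,
                        addition_order=order)
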