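"""Hierarchical abstraction of a learned CSCG.

The learned transition tensor, action-marginalized, is a directed weighted
graph over clones.  Because clones live in the latent space, this graph
exposes modularity (rooms, hyper-rooms) that is invisible in the aliased
observations; flow-based community detection (the map equation / InfoMap)
partitions it, collapsing each community to a node yields the next level, and
repeating the procedure builds a multi-level map.  Planning then proceeds
top-down — a shortest path over communities restricts the search at the level
below — which expands far fewer nodes than searching the flat clone graph.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import CSCGModel
from .plan import InfeasibleGoalError

__all__ = [
    "TransitionGraph",
    "CommunityPartition",
    "HierarchicalMap",
    "HierarchicalPlanResult",
    "to_graph",
    "detect_communities",
    "collapse",
    "build_hierarchy",
    "hierarchical_plan",
    "flat_shortest_path",
    "surrogate_partition",
]


@dataclass
class TransitionGraph:
    """Directed weighted graph over used clones (or, at higher levels, communities).

    ``node_ids`` are the original clone ids (or community ids); ``symbols``
    annotates each node with its emitted observation (-1 above level 0).
    Edges are stored positionally: ``src``/``dst`` index into ``node_ids``.
    """

    node_ids: np.ndarray
    symbols: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for s, d in zip(self.src, self.dst):
            adj[int(s)].append(int(d))
        return adj

    def index_of(self, node_id: int) -> int:
        idx = np.searchsorted(self.node_ids, node_id)
        if idx >= self.node_ids.size or self.node_ids[idx] != node_id:
            raise KeyError(f"node id {node_id} not in graph")
        return int(idx)

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph(
            n=self.n_nodes,
            edges=list(zip(self.src.tolist(), self.dst.tolist())),
            directed=True,
        )
        g.es["weight"] = self.weights.tolist()
        g.vs["node_id"] = self.node_ids.tolist()
        g.vs["symbol"] = self.symbols.tolist()
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, (nid, sym) in enumerate(zip(self.node_ids, self.symbols)):
            g.add_node(i, node_id=int(nid), symbol=int(sym))
        for s, d, w in zip(self.src, self.dst, self.weights):
            g.add_edge(int(s), int(d), weight=float(w))
        return g

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("src\tdst\tweight\n")
            for s, d, w in zip(self.src, self.dst, self.weights):
                fh.write(f"{self.node_ids[s]}\t{self.node_ids[d]}\t{w:.12g}\n")

    def to_graphml(self, path) -> None:
        self.to_igraph().write_graphml(str(path))


@dataclass
class CommunityPartition:
    """Node -> community assignment plus the partition objective's score."""

    membership: np.ndarray
    quality: float = 0.0

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.membership).size)

    def communities(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.membership == c) for c in np.unique(self.membership)]


@dataclass
class HierarchicalMap:
    """Level-0 clone graph, per-level partitions, and collapsed graphs above."""

    graphs: list          # graphs[l] is the level-l TransitionGraph
    partitions: list      # partitions[l] maps level-l nodes to level-(l+1) nodes

    @property
    def n_levels(self) -> int:
        return len(self.graphs)


def to_graph(
    model: CSCGModel,
    floor: float | None = None,
    sequences=None,
    threshold_scale: float = 10.0,
) -> TransitionGraph:
    """Action-marginalized transition graph over the clones actually in use.

    When ``sequences`` is given, nodes are the states appearing in their
    Viterbi decode; otherwise every state with a surviving outgoing edge is
    kept.  With ``floor=None`` edges are stripped at pseudocount scale (an
    entry survives if it exceeds ``threshold_scale`` times its row's minimum,
    as in planning); an explicit ``floor`` keeps action-marginal weights above
    that value instead.
    """
    H = model.n_states
    W = model.action_marginal()
    if floor is None:
        T = model.transitions
        row_min = T.reshape(H, -1).min(axis=1)
        keep = (T > (threshold_scale * row_min)[:, None, None]).any(axis=1)
    else:
        keep = W > floor
    W = np.where(keep, W, 0.0)
    if sequences is not None:
        from .learn import used_states

        nodes = used_states(model, sequences)
    else:
        nodes = np.flatnonzero(keep.any(axis=1) | keep.any(axis=0))
    if nodes.size == 0 or not keep[np.ix_(nodes, nodes)].any():
        warnings.warn("degenerate graph: model appears untrained (no edges)", stacklevel=2)
    sub = W[np.ix_(nodes, nodes)]
    src, dst = np.nonzero(sub)
    symbols = model.allocation.symbol_of_state()[nodes]
    return TransitionGraph(
        node_ids=nodes.astype(np.int64),
        symbols=symbols.astype(np.int64),
        src=src.astype(np.int64),
        dst=dst.astype(np.int64),
        weights=sub[src, dst],
    )


def detect_communities(
    graph: TransitionGraph,
    seed: int = 0,
    trials: int = 10,
    method: str = "infomap",
) -> CommunityPartition:
    """Partition the graph into communities.

    ``infomap`` (default) minimizes the map equation — the flow-based
    objective used on the clone-level graph.  ``modularity`` (Leiden) is used
    on collapsed community graphs, where the few contracted nodes leave too
    little flow structure for the map equation's granularity to settle on the
    coarse modules.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot partition an empty graph")
    import igraph as ig

    ig.set_random_number_generator(random.Random(seed))
    g = graph.to_igraph()
    if method == "infomap":
        clustering = g.community_infomap(edge_weights="weight", trials=trials)
    elif method == "modularity":
        clustering = g.as_undirected(combine_edges="sum").community_leiden(
            objective_function="modularity", weights="weight", n_iterations=10
        )
    else:
        raise ValueError(f"unknown community method {method!r}")
    quality = getattr(clustering, "codelength", None)
    if quality is None:
        quality = clustering.modularity
    return CommunityPartition(np.asarray(clustering.membership), float(quality))


def collapse(graph: TransitionGraph, partition: CommunityPartition) -> TransitionGraph:
    """Contract each community to a node, summing edge weights.

    Within-community mass is kept as a self-loop: it carries the dwell time of
    the underlying walk inside the community, which the map equation needs to
    judge module granularity at the next level.
    """
    mem = partition.membership
    labels = np.unique(mem)
    relabel = {int(c): i for i, c in enumerate(labels)}
    n = labels.size
    W = np.zeros((n, n))
    for s, d, w in zip(graph.src, graph.dst, graph.weights):
        W[relabel[int(mem[s])], relabel[int(mem[d])]] += w
    src, dst = np.nonzero(W)
    return TransitionGraph(
        node_ids=np.arange(n, dtype=np.int64),
        symbols=np.full(n, -1, dtype=np.int64),
        src=src.astype(np.int64),
        dst=dst.astype(np.int64),
        weights=W[src, dst],
    )


def build_hierarchy(
    source, levels: int = 3, seed: int = 0, sequences=None
) -> HierarchicalMap:
    """Alternate community detection and collapsing up to ``levels`` levels.

    ``source`` is a trained model (converted with :func:`to_graph`, optionally
    restricted to the Viterbi-used states of ``sequences``) or an existing
    level-0 :class:`TransitionGraph`.  If the graph collapses to a single node
    early, higher levels are single nodes.
    """
    if levels < 2:
        raise ValueError("a hierarchy needs at least 2 levels")
    graph = source if isinstance(source, TransitionGraph) else to_graph(
        source, sequences=sequences
    )
    graphs = [graph]
    partitions: list[CommunityPartition] = []
    for level in range(levels - 1):
        method = "infomap" if level == 0 else "modularity"
        part = detect_communities(graphs[-1], seed=seed, method=method)
        partitions.append(part)
        graphs.append(collapse(graphs[-1], part))
    return HierarchicalMap(graphs, partitions)


def _dijkstra(adj, source: int, target: int, allowed=None):
    """Unit-weight shortest path with a node-expansion counter.

    Returns ``(path or None, expansions)``; ``allowed`` optionally restricts
    the search to a subset of nodes.
    """
    import heapq

    n = len(adj)
    ok = np.ones(n, dtype=bool) if allowed is None else np.zeros(n, dtype=bool)
    if allowed is not None:
        ok[list(allowed)] = True
    if not (ok[source] and ok[target]):
        return None, 0
    dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    heap = [(0, source)]
    expansions = 0
    done = np.zeros(n, dtype=bool)
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        expansions += 1
        if u == target:
            path = [u]
            while parent[path[-1]] != -1:
                path.append(int(parent[path[-1]]))
            path.reverse()
            return path, expansions
        for v in adj[u]:
            if ok[v] and not done[v] and d + 1 < dist[v]:
                dist[v] = d + 1
                parent[v] = u
                heapq.heappush(heap, (d + 1, v))
    return None, expansions


def _reverse_adjacency(adj):
    rev: list[list[int]] = [[] for _ in range(len(adj))]
    for u, nbrs in enumerate(adj):
        for v in nbrs:
            rev[v].append(u)
    return rev


def _dijkstra_all(adj, source: int):
    """Unit-weight distances from ``source`` to every node, with expansions."""
    import heapq

    n = len(adj)
    dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    dist[source] = 0
    heap = [(0, source)]
    done = np.zeros(n, dtype=bool)
    expansions = 0
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        expansions += 1
        for v in adj[u]:
            if not done[v] and d + 1 < dist[v]:
                dist[v] = d + 1
                heapq.heappush(heap, (d + 1, v))
    return dist, expansions


def flat_shortest_path(graph: TransitionGraph, start_clone: int, goal_clone: int):
    """Shortest clone path on the flat level-0 graph; returns (path, expansions)."""
    s, t = graph.index_of(start_clone), graph.index_of(goal_clone)
    path, expansions = _dijkstra(graph.adjacency(), s, t)
    if path is None:
        raise InfeasibleGoalError("goal unreachable on the flat graph", graph.n_nodes)
    return graph.node_ids[np.asarray(path)], expansions


@dataclass
class HierarchicalPlanResult:
    path: np.ndarray              # clone ids, start to goal
    expansions: int               # total node expansions over all levels
    level_paths: list = field(default_factory=list)


def hierarchical_plan(
    hier: HierarchicalMap, start_clone: int, goal_clone: int
) -> HierarchicalPlanResult:
    """Top-down refinement: route over communities, then within them.

    The shortest community path at the highest level restricts which nodes may
    be searched one level down, and so on until a concrete clone path is
    produced at level 0.  The result's path is a valid walk in the level-0
    graph; ``expansions`` counts Dijkstra node expansions summed over levels,
    the quantity that makes hierarchical search cheaper than flat search.
    """
    g0 = hier.graphs[0]
    s0, t0 = g0.index_of(start_clone), g0.index_of(goal_clone)
    # lift the endpoints through the partitions
    s_lift, t_lift = [s0], [t0]
    for part in hier.partitions:
        s_lift.append(int(part.membership[s_lift[-1]]))
        t_lift.append(int(part.membership[t_lift[-1]]))
    # relabeled community ids used by the collapsed graphs
    for lvl, part in enumerate(hier.partitions):
        labels = np.unique(part.membership)
        relabel = {int(c): i for i, c in enumerate(labels)}
        s_lift[lvl + 1] = relabel[int(part.membership[s_lift[lvl]])]
        t_lift[lvl + 1] = relabel[int(part.membership[t_lift[lvl]])]

    # ancestor community of every level-l node at the top level
    def top_ancestors(lvl: int) -> np.ndarray:
        anc = np.arange(hier.graphs[lvl].n_nodes)
        for part in hier.partitions[lvl:]:
            labels = np.unique(part.membership)
            relabel = {int(c): i for i, c in enumerate(labels)}
            anc = np.asarray([relabel[int(part.membership[a])] for a in anc])
        return anc

    total_expansions = 0
    level_paths: list[np.ndarray] = []
    top_corridor: set[int] | None = None
    for lvl in range(hier.n_levels - 1, -1, -1):
        g = hier.graphs[lvl]
        if top_corridor is None:
            # corridor = every community on ANY shortest top-level route; a
            # single route would break hop-count ties arbitrarily, which at
            # this coarse scale can pick the long way around
            ds, e1 = _dijkstra_all(g.adjacency(), s_lift[lvl])
            dt, e2 = _dijkstra_all(_reverse_adjacency(g.adjacency()), t_lift[lvl])
            total_expansions += e1 + e2
            total_dist = ds[t_lift[lvl]]
            if total_dist >= np.iinfo(np.int64).max:
                raise InfeasibleGoalError(
                    "goal community unreachable at the top level", g.n_nodes
                )
            top_corridor = {
                int(v) for v in range(g.n_nodes) if ds[v] + dt[v] == total_dist
            }
            path, exp = _dijkstra(g.adjacency(), s_lift[lvl], t_lift[lvl])
            total_expansions += exp
        else:
            anc = top_ancestors(lvl)
            allowed = np.flatnonzero(np.isin(anc, list(top_corridor))).tolist()
            path, exp = _dijkstra(
                g.adjacency(), s_lift[lvl], t_lift[lvl], allowed=allowed
            )
            total_expansions += exp
        if path is None:
            raise InfeasibleGoalError(
                f"goal community unreachable at level {lvl}", g.n_nodes
            )
        level_paths.append(np.asarray(path))
    level_paths.reverse()
    return HierarchicalPlanResult(
        path=g0.node_ids[level_paths[0]],
        expansions=total_expansions,
        level_paths=level_paths,
    )


def surrogate_partition(partition: CommunityPartition, seed: int = 0) -> CommunityPartition:
    """Permute community labels over nodes, preserving every community's size.

    Destroys the spatial coherence of the communities while keeping their size
    profile — the control against which the benefit of true room structure is
    measured.
    """
    rng = np.random.default_rng(seed)
    return CommunityPartition(rng.permutation(partition.membership), partition.quality)
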