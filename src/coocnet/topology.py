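"""Per-network topology measures, hub scoring and signed-neighbor queries.

All measures except edge signs operate on the unsigned, unweighted
skeleton of the network.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import SignedNetwork, TopologyRecord

HUB_THRESHOLD = 0.5


def _skeleton(net) -> nx.Graph:
    if isinstance(net, SignedNetwork):
        return net.to_networkx()
    return net


def edge_counts(net: SignedNetwork):
    """(total, positive, negative, pos:neg ratio); the ratio is ``None``
    when there are no negative edges."""
    pos = sum(1 for w in net.edges.values() if w > 0)
    neg = sum(1 for w in net.edges.values() if w < 0)
    ratio = pos / neg if neg > 0 else None
    return pos + neg, pos, neg, ratio


def average_path_length(net) -> float | None:
    """Mean shortest-path length over mutually reachable unordered pairs.

    Pairs in different components are excluded; a network with no
    reachable pairs returns ``None``.
    """
    g = _skeleton(net)
    total = 0
    n_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            n_pairs += len(dists) - 1
    if n_pairs == 0:
        return None
    # each unordered pair was counted twice
    return total / n_pairs


def heterogeneity(net) -> float:
    """Coefficient of variation of the degree sequence (population sd)."""
    g = _skeleton(net)
    if g.number_of_nodes() == 0:
        raise ValueError("heterogeneity needs at least one node")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean = degrees.mean()
    if mean == 0:
        return 0.0
    return float(degrees.std() / mean)


def _louvain_one_level(neighbors: dict, degrees: dict, two_m: float, rng) -> dict:
    """One local-moving pass sequence: move nodes greedily until no move
    with strictly positive modularity gain exists.  Strict positivity
    guarantees termination (Q increases by a bounded-below step)."""
    node2com = {v: v for v in neighbors}
    com_tot = {v: degrees[v] for v in neighbors}  # sum of degrees per community
    order = list(neighbors)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for v in order:
            com_v = node2com[v]
            k_v = degrees[v]
            # edge weight from v into each neighboring community
            links = {}
            for u, w in neighbors[v].items():
                links[node2com[u]] = links.get(node2com[u], 0.0) + w
            com_tot[com_v] -= k_v
            base = links.get(com_v, 0.0) - k_v * com_tot[com_v] / two_m
            best_com, best_gain = com_v, 0.0
            for com, k_in in links.items():
                if com == com_v:
                    continue
                gain = (k_in - k_v * com_tot[com] / two_m) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_com = gain, com
            com_tot[best_com] += k_v
            if best_com != com_v:
                node2com[v] = best_com
                improved = True
    return node2com


def _louvain_partition(g: nx.Graph, rng) -> list:
    """Full Louvain hierarchy on the unweighted skeleton of ``g``."""
    nodes = list(g.nodes)
    # current aggregated graph: community-level weighted adjacency
    neighbors = {v: {u: 1.0 for u in g.neighbors(v) if u != v} for v in nodes}
    self_loops = {v: 0.0 for v in nodes}
    membership = {v: v for v in nodes}
    two_m = float(sum(sum(nb.values()) for nb in neighbors.values()))
    if two_m == 0:
        return [set(nodes)] if nodes else []
    while True:
        degrees = {
            v: sum(neighbors[v].values()) + 2.0 * self_loops[v] for v in neighbors
        }
        node2com = _louvain_one_level(neighbors, degrees, two_m, rng)
        coms = set(node2com.values())
        if len(coms) == len(neighbors):
            break
        # aggregate: one super-node per community
        new_neighbors = {c: {} for c in coms}
        new_loops = {c: 0.0 for c in coms}
        for v, nb in neighbors.items():
            cv = node2com[v]
            new_loops[cv] += self_loops[v]
            for u, w in nb.items():
                cu = node2com[u]
                if cu == cv:
                    new_loops[cv] += 0.5 * w
                else:
                    new_neighbors[cv][cu] = new_neighbors[cv].get(cu, 0.0) + w
        membership = {v: node2com[membership[v]] for v in membership}
        neighbors, self_loops = new_neighbors, new_loops
    out: dict = {}
    for v, c in membership.items():
        out.setdefault(c, set()).add(v)
    return list(out.values())


#: node count at or below which modularity is maximized exactly by
#: partition enumeration instead of the Louvain heuristic
EXACT_MODULARITY_NODES = 8


def _exact_max_modularity(g: nx.Graph):
    """Exhaustive max-modularity partition for tiny graphs (<= 8 nodes)."""
    nodes = list(g.nodes)
    n = len(nodes)
    best_q, best_part = 0.0, [set(nodes)]

    def grow(assignment, next_block):
        nonlocal best_q, best_part
        i = len(assignment)
        if i == n:
            part = {}
            for v, b in zip(nodes, assignment):
                part.setdefault(b, set()).add(v)
            q = nx.community.modularity(g, list(part.values()), weight=None)
            if q > best_q:
                best_q, best_part = q, list(part.values())
            return
        for b in range(next_block + 1):
            grow(assignment + [b], max(next_block, b + 1))

    grow([], 0)
    return best_part, float(best_q)


def modularity_louvain(net, n_restarts: int = 10, seed: int = 0):
    """Maximized Newman modularity and its partition.

    Graphs with at most :data:`EXACT_MODULARITY_NODES` nodes are solved
    exactly by partition enumeration; larger graphs use the Louvain
    heuristic with ``n_restarts`` seeded restarts, reporting the best Q
    found.  The trivial one-community partition (Q = 0 for any graph with
    edges) is always included, so the reported Q is never below 0.
    Edgeless graphs return Q = 0 by convention.
    """
    g = _skeleton(net)
    if g.number_of_edges() == 0:
        return [set(g.nodes)] if g.number_of_nodes() else [], 0.0
    if g.number_of_nodes() <= EXACT_MODULARITY_NODES:
        return _exact_max_modularity(g)
    best_q = 0.0
    best_part = [set(g.nodes)]
    for r in range(n_restarts):
        rng = random.Random(seed * 1_000_003 + r)
        part = _louvain_partition(g, rng)
        q = nx.community.modularity(g, part, weight=None)
        if q > best_q:
            best_q, best_part = q, part
    return best_part, float(best_q)


def clustering_coefficient(net) -> float:
    """Global transitivity: 3 * triangles / connected triples."""
    g = _skeleton(net)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.transitivity(g))


@dataclass
class HubReport:
    """Per-taxon hub scores in [0, 1] with max exactly 1 on non-empty graphs."""

    scores: dict
    threshold: float = HUB_THRESHOLD

    def flags(self) -> dict:
        return {t: s >= self.threshold for t, s in self.scores.items()}


def hub_scores(net, tol: float = 1e-9) -> HubReport:
    """Kleinberg-style centrality on the unsigned binary adjacency.

    For an undirected graph the hub and authority scores coincide: both
    are the principal eigenvector of ``A @ A.T = A^2``, i.e. the top
    eigenspace of ``A`` itself.  Bipartite components make that eigenspace
    degenerate (``A^2`` cannot separate +/- eigenvalues), so the
    deterministic score is the projection of the all-ones starting vector
    onto the top eigenspace of ``A`` — exactly what shifted power
    iteration from a uniform start converges to.  It is computed here by
    dense eigendecomposition, taken in absolute value and normalized so
    the maximum score is 1.  Isolated nodes score 0.
    """
    g = _skeleton(net)
    nodes = list(g.nodes)
    if not nodes:
        return HubReport(scores={})
    if g.number_of_edges() == 0:
        return HubReport(scores={t: 0.0 for t in nodes})
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    w, v = np.linalg.eigh(a)
    lam = w[-1]
    top = v[:, np.abs(w - lam) < tol * max(1.0, abs(lam))]
    x = np.abs(top @ (top.T @ np.ones(len(nodes))))
    x /= x.max()
    x[x < 1e-9] = 0.0
    return HubReport(scores={t: float(s) for t, s in zip(nodes, x)})


def hub_taxa(report: HubReport, threshold: float = HUB_THRESHOLD) -> list:
    """Taxa scoring at or above the threshold, by descending score then ID."""
    qualifying = [(t, s) for t, s in report.scores.items() if s >= threshold]
    qualifying.sort(key=lambda ts: (-ts[1], str(ts[0])))
    return [t for t, _ in qualifying]


def signed_neighbors(net: SignedNetwork, taxon):
    """Partition a taxon's neighbors by edge sign -> (positive, negative)."""
    if taxon not in set(net.nodes):
        raise KeyError(f"unknown taxon {taxon!r}")
    pos, neg = [], []
    for (u, v), w in net.edges.items():
        if taxon == u:
            (pos if w > 0 else neg).append(v)
        elif taxon == v:
            (pos if w > 0 else neg).append(u)
    return sorted(pos, key=str), sorted(neg, key=str)


def topology_record(
    net: SignedNetwork,
    replicate_id: int | None = None,
    group: str | None = None,
    seed: int | None = None,
    n_restarts: int = 10,
    louvain_seed: int = 0,
) -> TopologyRecord:
    """Compute the full per-replicate measure set for one network."""
    total, pos, neg, ratio = edge_counts(net)
    n_nodes = len(net.nodes)
    _, q = modularity_louvain(net, n_restarts=n_restarts, seed=louvain_seed)
    return TopologyRecord(
        total_nodes=n_nodes,
        total_edges=total,
        positive_edges=pos,
        negative_edges=neg,
        pos_neg_ratio=ratio,
        average_path_length=average_path_length(net),
        heterogeneity=heterogeneity(net) if n_nodes else 0.0,
        modularity=q,
        average_degree=(2.0 * total / n_nodes) if n_nodes else 0.0,
        clustering_coefficient=clustering_coefficient(net),
        replicate_id=replicate_id,
        group=group,
        seed=seed,
    )
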