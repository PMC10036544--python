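"""Community detection on the active module and hub classification.

Two partitioning routes mirror the dual clustering of the adhesome
active module:

* Louvain maximisation of the Girvan-Newman modularity
  Q = sum_c [ w_c/m - (d_c/2m)^2 ] on edges weighted by Spearman rank
  correlation + 1;
* Louvain-style maximisation of the constant Potts model quality
  H(gamma) = sum_c [ w_c - gamma * n_c (n_c - 1)/2 ] on edges weighted
  by (clamped non-negative) Spearman correlation, with the resolution
  gamma chosen by scanning a grid and maximising the Surprise of the
  resulting partition on the binary topology.

Surprise is the negative log upper-tail hypergeometric probability of
drawing at least the realised number of intra-community edges when the
graph's m edges are placed uniformly among all node pairs.

Hubs are classified by the within-module degree z-score and the
participation coefficient P = 1 - sum_s (k_is/k_i)^2: connector hubs
spread their edges across modules (moderate P), kinless hubs almost
uniformly (high P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np

from .stats_core import log_hypergeom_tail, spearman_rho
from .synthio import AbundanceMatrix

__all__ = [
    "Partition",
    "HubRecord",
    "abundance_edge_weights",
    "louvain_modularity",
    "cpm_partition",
    "modularity_quality",
    "cpm_quality",
    "surprise",
    "scan_gamma",
    "classify_hubs",
]


class QualityKind(str, Enum):
    MODULARITY = "modularity_Q"
    CPM = "cpm_H"
    SURPRISE = "surprise_S"


@dataclass
class Partition:
    community_of_node: dict
    quality: float
    quality_kind: QualityKind
    gamma: float | None = None

    def communities(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for n, c in self.community_of_node.items():
            out.setdefault(c, []).append(n)
        for members in out.values():
            members.sort()
        return out


@dataclass(frozen=True)
class HubRecord:
    node: str
    within_module_z: float
    participation_P: float
    label: str  # none | connector_hub | kinless_hub


# ---------------------------------------------------------------------------
# edge weighting from abundance profiles

def abundance_edge_weights(
    m: AbundanceMatrix, edges, mode: str = "modularity"
) -> list[tuple[str, str, float]]:
    """Weight interaction edges by the Spearman correlation of node profiles.

    ``modularity`` mode uses rho + 1 (range [0, 2]); ``cpm`` mode uses
    max(rho, 0). Edges with an endpoint lacking an abundance profile (or
    an undefined correlation) get the neutral weight 1 (modularity) or 0
    (cpm).
    """
    if mode not in ("modularity", "cpm"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = m.values
    weighted = []
    for u, v in edges:
        rho = float("nan")
        if u in vals.index and v in vals.index:
            x = vals.loc[u].to_numpy(dtype=float)
            y = vals.loc[v].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 3:
                rho = spearman_rho(x[ok], y[ok])
        if mode == "modularity":
            w = rho + 1.0 if math.isfinite(rho) else 1.0
        else:
            w = max(rho, 0.0) if math.isfinite(rho) else 0.0
        weighted.append((u, v, w))
    return weighted


# ---------------------------------------------------------------------------
# quality functions evaluated on the original graph

def _edge_weight(d: dict) -> float:
    return float(d.get("weight", 1.0))


def modularity_quality(g: nx.Graph, community_of_node: dict) -> float:
    """Girvan-Newman modularity Q of a partition on a weighted graph."""
    m = sum(_edge_weight(d) for _, _, d in g.edges(data=True))
    if m <= 0:
        raise ValueError("graph needs positive total weight")
    w_c: dict = {}
    d_c: dict = {}
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d)
        if community_of_node[u] == community_of_node[v]:
            w_c[community_of_node[u]] = w_c.get(community_of_node[u], 0.0) + w
        d_c[community_of_node[u]] = d_c.get(community_of_node[u], 0.0) + w
        d_c[community_of_node[v]] = d_c.get(community_of_node[v], 0.0) + w
    return sum(
        w_c.get(c, 0.0) / m - (d_c.get(c, 0.0) / (2.0 * m)) ** 2
        for c in set(community_of_node.values())
    )


def cpm_quality(g: nx.Graph, community_of_node: dict, gamma: float) -> float:
    """Constant Potts model quality H(gamma)."""
    w_c: dict = {}
    n_c: dict = {}
    for n, c in community_of_node.items():
        n_c[c] = n_c.get(c, 0) + 1
    for u, v, d in g.edges(data=True):
        if community_of_node[u] == community_of_node[v]:
            c = community_of_node[u]
            w_c[c] = w_c.get(c, 0.0) + _edge_weight(d)
    return sum(
        w_c.get(c, 0.0) - gamma * n * (n - 1) / 2.0 for c, n in n_c.items()
    )


# ---------------------------------------------------------------------------
# Louvain engine (shared by modularity and CPM objectives)

def _louvain_engine(g: nx.Graph, objective: str, gamma: float, seed: int | None):
    """Two-phase Louvain: local moves to exhaustion, then aggregation.

    Sweeps nodes in ascending id order (shuffled once per level when a
    seed is given); a node moves to the neighbouring community with the
    best positive gain, ties breaking toward the smallest community id.
    Deterministic for a fixed seed and input.
    """
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    # level state: adjacency among super-nodes, original-degree, size
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for u, v, d in g.edges(data=True):
        if u == v:
            continue
        w = _edge_weight(d)
        if w < 0:
            raise ValueError("negative edge weights are not supported")
        iu, iv = index[u], index[v]
        adj[iu][iv] = adj[iu].get(iv, 0.0) + w
        adj[iv][iu] = adj[iv].get(iu, 0.0) + w
    deg = [sum(a.values()) for a in adj]
    size = [1] * len(nodes)
    inner = [0.0] * len(nodes)  # internal weight of each super-node
    current_of_orig = list(range(len(nodes)))  # original node -> super-node
    two_m = sum(deg)
    m_tot = two_m / 2.0 if two_m > 0 else 1.0
    rng = np.random.default_rng(seed) if seed is not None else None

    while True:
        n_level = len(adj)
        comm = list(range(n_level))
        comm_deg = deg.copy()
        comm_size = size.copy()
        order = list(range(n_level))
        if rng is not None:
            rng.shuffle(order)
        improved_level = False
        moved = True
        while moved:
            moved = False
            for v in order:
                cv = comm[v]
                # weights to neighbouring communities
                links: dict[int, float] = {}
                for u, w in adj[v].items():
                    links[comm[u]] = links.get(comm[u], 0.0) + w
                # remove v from its community
                comm_deg[cv] -= deg[v]
                comm_size[cv] -= size[v]
                l_own = links.get(cv, 0.0)
                best_c, best_gain = cv, 0.0
                # candidates: neighbouring communities, plus splitting off
                # into an empty community (relevant for high-gamma CPM)
                candidates = dict(links)
                if comm_size[cv] > 0:  # cv still holds others; isolation differs
                    empty = next(
                        (c for c in range(n_level) if comm_size[c] == 0 and c != cv),
                        None,
                    )
                    if empty is not None:
                        candidates.setdefault(empty, 0.0)
                for c in sorted(candidates):
                    l_c = candidates[c]
                    if objective == "modularity":
                        gain = (l_c - l_own) / m_tot - (
                            deg[v] * (comm_deg[c] - comm_deg[cv]) / (2.0 * m_tot * m_tot)
                        )
                    else:
                        gain = (l_c - l_own) - gamma * size[v] * (
                            comm_size[c] - comm_size[cv]
                        )
                    if gain > best_gain + 1e-12 or (
                        abs(gain - best_gain) <= 1e-12 and gain > 1e-12 and c < best_c
                    ):
                        best_gain, best_c = gain, c
                comm_deg[best_c] += deg[v]
                comm_size[best_c] += size[v]
                if best_c != cv:
                    comm[v] = best_c
                    moved = True
                    improved_level = True
        if not improved_level:
            break
        # aggregate communities into super-nodes
        labels = sorted(set(comm))
        relabel = {c: i for i, c in enumerate(labels)}
        comm = [relabel[c] for c in comm]
        new_n = len(labels)
        new_adj: list[dict[int, float]] = [dict() for _ in range(new_n)]
        new_inner = [0.0] * new_n
        new_size = [0] * new_n
        new_deg = [0.0] * new_n
        for v in range(n_level):
            c = comm[v]
            new_size[c] += size[v]
            new_deg[c] += deg[v]
            new_inner[c] += inner[v]
        for v in range(n_level):
            cv = comm[v]
            for u, w in adj[v].items():
                cu = comm[u]
                if cu == cv:
                    if u > v:
                        new_inner[cv] += w
                else:
                    new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
        for i_orig in range(len(nodes)):
            current_of_orig[i_orig] = comm[current_of_orig[i_orig]]
        adj, deg, size, inner = new_adj, new_deg, new_size, new_inner
        if len(adj) == 1:
            break

    return {nodes[i]: current_of_orig[i] for i in range(len(nodes))}


def louvain_modularity(g: nx.Graph, seed: int | None = 0) -> Partition:
    """Louvain modularity maximisation on a non-negatively weighted graph."""
    if g.number_of_edges() < 1:
        raise ValueError("graph needs at least one edge")
    membership = _louvain_engine(g, "modularity", 0.0, seed)
    q = modularity_quality(g, membership)
    return Partition(membership, q, QualityKind.MODULARITY)


def cpm_partition(g: nx.Graph, gamma: float, seed: int | None = 0) -> Partition:
    """Constant Potts model ground-state search at resolution gamma."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    membership = _louvain_engine(g, "cpm", gamma, seed)
    h = cpm_quality(g, membership, gamma)
    return Partition(membership, h, QualityKind.CPM, gamma=gamma)


# ---------------------------------------------------------------------------
# Surprise

def surprise(g: nx.Graph, part: Partition | dict) -> float:
    """Surprise S of a partition: -ln P(X >= m_int) on the binary topology."""
    membership = part.community_of_node if isinstance(part, Partition) else part
    nodes = list(g.nodes)
    n = len(nodes)
    m = g.number_of_edges()
    M = n * (n - 1) // 2
    sizes: dict = {}
    for v in nodes:
        c = membership[v]
        sizes[c] = sizes.get(c, 0) + 1
    M_int = sum(s * (s - 1) // 2 for s in sizes.values())
    m_int = sum(1 for u, v in g.edges if membership[u] == membership[v])
    if M_int == 0 or m == 0:
        return 0.0
    lt = log_hypergeom_tail(m_int, M_int, m, M)
    return max(0.0, -lt)


def scan_gamma(g: nx.Graph, grid, seed: int | None = 0) -> Partition:
    """CPM partitions over a gamma grid; keep the Surprise-maximising one.

    Surprise is evaluated on the binarised topology. Ties break toward
    the smaller gamma.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty gamma grid")
    binary = nx.Graph()
    binary.add_nodes_from(g.nodes)
    binary.add_edges_from(g.edges)
    best: Partition | None = None
    best_s = -math.inf
    for gamma in grid:
        part = cpm_partition(g, gamma, seed=seed)
        s = surprise(binary, part)
        if s > best_s + 1e-12:
            best, best_s = part, s
    return Partition(best.community_of_node, best_s, QualityKind.SURPRISE, gamma=best.gamma)


# ---------------------------------------------------------------------------
# hub cartography

def classify_hubs(
    g: nx.Graph,
    part: Partition | dict,
    z_thr: float = 2.5,
    p_connector: tuple[float, float] = (0.30, 0.75),
    p_kinless: float = 0.75,
) -> list[HubRecord]:
    """Within-module degree z-score and participation coefficient per node.

    A node with z >= ``z_thr`` is a connector hub when P falls in
    (p_connector[0], p_connector[1]] and a kinless hub when
    P > ``p_kinless``; other nodes are unlabelled.
    """
    membership = part.community_of_node if isinstance(part, Partition) else part
    by_comm: dict = {}
    for v in g.nodes:
        by_comm.setdefault(membership[v], []).append(v)

    k_in = {
        v: sum(1 for u in g.neighbors(v) if membership[u] == membership[v])
        for v in g.nodes
    }
    z: dict = {}
    for c, members in by_comm.items():
        vals = np.array([k_in[v] for v in members], dtype=float)
        mu, sd = vals.mean(), vals.std()
        for v in members:
            z[v] = 0.0 if sd == 0 else (k_in[v] - mu) / sd

    records = []
    for v in sorted(g.nodes):
        k = g.degree(v)
        if k == 0:
            P = 0.0
        else:
            per_mod: dict = {}
            for u in g.neighbors(v):
                c = membership[u]
                per_mod[c] = per_mod.get(c, 0) + 1
            P = 1.0 - sum((kis / k) ** 2 for kis in per_mod.values())
        label = "none"
        if z[v] >= z_thr:
            if P > p_kinless:
                label = "kinless_hub"
            elif p_connector[0] < P <= p_connector[1]:
                label = "connector_hub"
        records.append(HubRecord(v, float(z[v]), float(P), label))
    return records
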