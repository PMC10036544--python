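"""FDR-calibrated node scoring and maximal-scoring subnetwork search.

P-values are modelled as a beta-uniform mixture (BUM),

    f(p) = lam + (1 - lam) * a * p**(a - 1),   0 < a < 1,

whose uniform component absorbs noise and whose Beta(a, 1) component
carries signal. The mixture yields an FDR-controlled p-value threshold
tau and a log-scale node score s(p) = (a - 1) * (ln p - ln tau) that is
zero at tau, positive for stronger p-values and negative otherwise.
Finding the maximum-weight connected subgraph (MWCS) of the scored
interaction graph — the active module — is equivalent, up to a constant
offset per node, to a prize-collecting Steiner tree (PCST) instance with
non-negative node profits and a uniform edge cost. An exact
enumeration solver (small graphs) and a contraction/shortest-path
heuristic (arbitrary graphs) are provided.

The exact integer-linear-programming formulation of the PCST (binary
node/edge indicators, profit-minus-cost objective, connectivity via
subtour-elimination or flow constraints) is documented in the methods
note; at desk scale the exhaustive enumeration below is the oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BumFit",
    "ActiveModule",
    "PcstInstance",
    "fit_bum",
    "bum_tau",
    "score_nodes",
    "build_scored_graph",
    "mwcs_to_pcst",
    "solve_mwcs_exact",
    "solve_mwcs_heuristic",
]


# ---------------------------------------------------------------------------
# beta-uniform mixture calibration

@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood beta-uniform mixture parameters.

    ``pi_upper`` = lam + (1 - lam) * a is the mixture density at p = 1,
    an upper bound on the noise fraction.
    """

    lam: float
    a: float
    log_lik: float
    pi_upper: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi_upper", self.lam + (1.0 - self.lam) * self.a)


def fit_bum(p, n_starts: int = 6) -> BumFit:
    """Fit the BUM model by multi-start bounded maximum likelihood."""
    p = np.asarray(p, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable fit")
    if np.any(p > 1):
        raise ValueError("p-values above 1")
    if np.any(p <= 0):
        warnings.warn("p-values <= 0 clamped to smallest positive value")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    lp = np.log(p)

    def nll(theta):
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * lp)
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    eps = 1e-6
    bounds = [(0.0, 1.0), (eps, 1.0 - eps)]
    starts = [
        (0.1, 0.1), (0.3, 0.3), (0.5, 0.5), (0.7, 0.3), (0.9, 0.5), (0.99, 0.8),
    ][: max(5, n_starts)]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lam, a = best.x
    return BumFit(lam=float(lam), a=float(a), log_lik=float(-best.fun))


def bum_tau(fit: BumFit, fdr: float = 0.05) -> float:
    """FDR-controlling p-value threshold implied by the fitted mixture."""
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if fit.lam >= 1.0:
        raise ValueError("no signal component (lam = 1); tau undefined")
    num = fit.pi_upper - fit.lam * fdr
    if num <= 0:
        raise ValueError("fdr too large for the fitted mixture (pi <= lam*fdr)")
    tau = (num / (fdr * (1.0 - fit.lam))) ** (1.0 / (fit.a - 1.0))
    return float(tau)


def score_nodes(
    fit: BumFit,
    p_of_node: dict[str, float],
    fdr: float = 0.05,
    nodes=None,
    default_p: float = 0.5,
) -> dict[str, float]:
    """Log-scale node scores s(p) = (a - 1)(ln p - ln tau); s(tau) = 0.

    Nodes listed in ``nodes`` but absent from ``p_of_node`` receive the
    score of ``default_p``, keeping them available as connectors.
    """
    tau = bum_tau(fit, fdr)
    ltau = math.log(tau)
    coef = fit.a - 1.0

    def s(p: float) -> float:
        p = max(p, np.finfo(float).tiny)
        return coef * (math.log(p) - ltau)

    scores = {node: s(p) for node, p in p_of_node.items()}
    if nodes is not None:
        for node in nodes:
            if node not in scores:
                scores[node] = s(default_p)
    return scores


# ---------------------------------------------------------------------------
# graph containers

def build_scored_graph(edges, scores: dict[str, float]) -> nx.Graph:
    """Simple undirected graph with a ``score`` attribute per node."""
    g = nx.Graph()
    g.add_nodes_from(scores)
    for u, v in edges:
        if u == v:
            continue
        g.add_edge(u, v)
    for n in g.nodes:
        if n not in scores:
            raise ValueError(f"node {n!r} has no score")
        g.nodes[n]["score"] = float(scores[n])
    return g


@dataclass
class ActiveModule:
    """Connected node set maximising (exactly or heuristically) total score."""

    members: tuple
    tree_edges: tuple
    total_score: float


@dataclass(frozen=True)
class PcstInstance:
    """PCST reformulation: profits = score - w_min, uniform edge cost -w_min."""

    profits: dict[str, float]
    edge_cost: float
    offset: float


def mwcs_to_pcst(g: nx.Graph) -> PcstInstance:
    scores = [g.nodes[n]["score"] for n in g.nodes]
    w_min = min(0.0, min(scores)) if scores else 0.0
    profits = {n: g.nodes[n]["score"] - w_min for n in g.nodes}
    return PcstInstance(profits=profits, edge_cost=-w_min, offset=w_min)


# ---------------------------------------------------------------------------
# exact solver (connected induced subgraph enumeration)

def _spanning_tree_edges(g: nx.Graph, members) -> tuple:
    sub = g.subgraph(members)
    tree = nx.minimum_spanning_tree(sub) if sub.number_of_edges() else sub
    return tuple(sorted(tuple(sorted(e)) for e in tree.edges))


def solve_mwcs_exact(g: nx.Graph, max_nodes: int = 20) -> ActiveModule:
    """Exhaustive maximum-weight connected subgraph by border expansion.

    Enumerates every connected induced subgraph exactly once (rooted at
    its smallest node, growing only through permitted neighbours). Ties
    in total score break toward the lexicographically smallest sorted
    node list, making the result deterministic. If every score is
    negative the single best node is returned.
    """
    if g.number_of_nodes() > max_nodes:
        raise ValueError(
            f"{g.number_of_nodes()} nodes exceed max_nodes={max_nodes}; "
            "use solve_mwcs_heuristic"
        )
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    score = {n: g.nodes[n]["score"] for n in nodes}
    best_set: tuple | None = None
    best_score = -math.inf

    def consider(members: frozenset, total: float) -> None:
        nonlocal best_set, best_score
        key = tuple(sorted(members))
        if total > best_score + 1e-12 or (
            abs(total - best_score) <= 1e-12 and (best_set is None or key < best_set)
        ):
            best_set, best_score = key, total

    order = {n: i for i, n in enumerate(nodes)}

    def expand(members: frozenset, total: float, ext: list, forbidden: set) -> None:
        consider(members, total)
        local_forbidden = set(forbidden)
        for i, u in enumerate(ext):
            new_ext = [v for v in ext[i + 1 :]]
            for w in sorted(g.neighbors(u), key=order.get):
                if w not in members and w not in local_forbidden and w != u and w not in new_ext:
                    new_ext.append(w)
            expand(members | {u}, total + score[u], new_ext, local_forbidden)
            local_forbidden.add(u)

    for idx, root in enumerate(nodes):
        allowed_forbidden = set(nodes[:idx])  # roots already covered
        ext = [v for v in sorted(g.neighbors(root), key=order.get) if v not in allowed_forbidden]
        expand(frozenset([root]), score[root], ext, allowed_forbidden)

    return ActiveModule(
        members=best_set,
        tree_edges=_spanning_tree_edges(g, best_set),
        total_score=best_score,
    )


# ---------------------------------------------------------------------------
# heuristic solver

def _best_single_node(g: nx.Graph) -> ActiveModule:
    best = min(sorted(g.nodes), key=lambda n: (-g.nodes[n]["score"], n))
    return ActiveModule((best,), (), g.nodes[best]["score"])


def _heuristic_component(g: nx.Graph) -> ActiveModule:
    score = {n: g.nodes[n]["score"] for n in g.nodes}
    cost = {n: max(0.0, -s) for n, s in score.items()}
    positives = [n for n in g.nodes if score[n] > 0]
    if not positives:
        return _best_single_node(g)

    # 1. contract adjacent positive nodes into super-nodes
    pos_sub = g.subgraph(positives)
    supers = [tuple(sorted(c)) for c in nx.connected_components(pos_sub)]
    supers.sort(key=lambda c: (-sum(score[n] for n in c), c))
    super_of = {n: i for i, c in enumerate(supers) for n in c}
    super_score = [sum(score[n] for n in c) for c in supers]

    # 2./3. grow a module from a seed super-node, attaching further
    # super-nodes via cheapest connector paths while net gain stays >= 0.
    # Paths are re-priced after every attachment (absorbed connectors
    # become free), so shared connectors are paid only once; seeding from
    # every super-node and keeping the best result captures optima that
    # are unprofitable one attachment at a time from the best seed.
    def grow(seed: int) -> set:
        module: set = set(supers[seed])
        attached = {seed}
        while len(attached) < len(supers):
            dist, paths = nx.multi_source_dijkstra(
                g, module, weight=lambda u, v, d: cost[v] if v not in module else 0.0
            )
            best_gain, best_super, best_path = -math.inf, None, None
            for i, comp in enumerate(supers):
                if i in attached:
                    continue
                for entry in comp:
                    if entry not in dist:
                        continue
                    gain = super_score[i] - dist[entry]
                    if gain > best_gain + 1e-12 or (
                        abs(gain - best_gain) <= 1e-12
                        and best_super is not None
                        and i < best_super
                    ):
                        best_gain, best_super, best_path = gain, i, paths[entry]
            if best_super is None or best_gain < 0:
                break
            module.update(supers[best_super])
            module.update(best_path)
            attached.add(best_super)
            for n in best_path:
                if n in super_of:
                    attached.add(super_of[n])
        return module

    def finalise(module: set) -> ActiveModule:
        # prune negative leaves of a spanning tree of the module
        tree = nx.minimum_spanning_tree(g.subgraph(module).copy())
        changed = True
        while changed and tree.number_of_nodes() > 1:
            changed = False
            for leaf in sorted([n for n in tree.nodes if tree.degree(n) == 1]):
                if score[leaf] < 0 and tree.number_of_nodes() > 1:
                    tree.remove_node(leaf)
                    changed = True
        members = tuple(sorted(tree.nodes))
        total = sum(score[n] for n in members)
        return ActiveModule(members, _spanning_tree_edges(g, members), total)

    best = _best_single_node(g)
    for seed in range(min(len(supers), 25)):
        cand = finalise(grow(seed))
        if cand.total_score > best.total_score + 1e-12 or (
            abs(cand.total_score - best.total_score) <= 1e-12
            and cand.members < best.members
        ):
            best = cand
    return best


def solve_mwcs_heuristic(g: nx.Graph) -> ActiveModule:
    """Contraction / cheapest-path heuristic for the active module.

    Adjacent positive-score nodes are contracted into super-nodes; the
    module grows greedily from the highest-scoring super-node, attaching
    further super-nodes through cheapest connector paths (path cost = sum
    of the negative scores traversed) while the net gain stays
    non-negative; negative dangling leaves are pruned. Disconnected
    inputs are solved per component and the best component result wins.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    best: ActiveModule | None = None
    for comp in nx.connected_components(g):
        cand = _heuristic_component(g.subgraph(comp))
        if best is None or cand.total_score > best.total_score:
            best = cand
    return best
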