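"""Community detection on weighted undirected graphs.

Implemented here from the primary algorithm descriptions rather than wrapped
from a graph library, because the detection step is the analytic core of the
package:

* ``modularity`` — Newman–Girvan weighted modularity with a resolution
  parameter:  Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j).
* ``louvain`` — greedy two-phase modularity optimization (local node moves
  until no move improves Q, then community aggregation, repeated).
* ``girvan_newman`` — divisive detection by iterative removal of the
  maximum-edge-betweenness edge; betweenness uses shortest paths with
  distance = 1/weight (heavier co-occurrence means closer).  The returned
  partition is the point along the dendrogram maximizing modularity on the
  ORIGINAL graph.
* ``walktrap`` — agglomerative detection from t-step random-walk probability
  profiles, merging adjacent communities by the minimum Ward-style increase
  in walk-distance variance and cutting the merge tree at maximum
  modularity.

All functions take a dense symmetric weight matrix with zero diagonal
(graphs here have at most a few dozen nodes) and return integer community
labels per node.
"""

from __future__ import annotations

import heapq

import numpy as np
from sklearn.metrics import adjusted_rand_score


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal must be zero (no self-loops)")
    if w.sum() == 0:
        raise ValueError("graph has no edges (total weight is zero)")
    return w


def modularity(weights: np.ndarray, labels, resolution: float = 1.0) -> float:
    """Weighted Newman–Girvan modularity of a labelling; invariant to
    community relabelling and node reordering."""
    w = _check_weights(weights)
    labels = np.asarray(labels)
    if labels.shape[0] != w.shape[0]:
        raise ValueError("labels must cover every node")
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += w[np.ix_(mask, mask)].sum() / two_m
        q -= resolution * (k[mask].sum() / two_m) ** 2
    return float(q)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..k-1 in order of first appearance."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen))
    return out


# ---------------------------------------------------------------------------
# Louvain

def louvain(weights: np.ndarray, resolution: float = 1.0,
            seed: int = 0) -> np.ndarray:
    """Greedy two-phase modularity maximization.

    Node visitation order is shuffled by ``seed``; a tied best move goes to
    the lowest-index community, so results are deterministic given the seed.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    # labels of original nodes in terms of current supernodes
    node_to_super = np.arange(n)
    cur = w.copy()
    while True:
        labels = _one_level(cur, resolution, rng)
        if len(np.unique(labels)) == cur.shape[0]:
            break  # no merge happened at this level
        node_to_super = labels[node_to_super]
        cur = _aggregate(cur, labels)
        if cur.shape[0] == 1:
            break
    return _canonical(node_to_super)


def _one_level(w: np.ndarray, resolution: float,
               rng: np.random.Generator) -> np.ndarray:
    """Local-move phase: move nodes between communities while any move
    strictly increases modularity."""
    n = w.shape[0]
    labels = np.arange(n)
    k = w.sum(axis=1)
    two_m = w.sum()
    comm_tot = k.copy()  # total degree per community label
    order = np.arange(n)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for i in order:
            ci = labels[i]
            comm_tot[ci] -= k[i]
            # weight from i to each community; a self-loop (aggregated
            # internal weight) stays internal wherever i goes, so skip it
            nbr = np.flatnonzero(w[i] > 0)
            nbr = nbr[nbr != i]
            links = np.zeros(n)
            np.add.at(links, labels[nbr], w[i, nbr])
            # gain of joining community c: links[c]/m_half - γ k_i tot_c/(2m²)·...
            # compare via ΔQ ∝ links[c] − γ k_i comm_tot[c] / (2m)
            cand = np.unique(np.append(labels[nbr], ci))
            gains = links[cand] - resolution * k[i] * comm_tot[cand] / two_m
            best = cand[np.argmax(gains)]
            ties = cand[np.isclose(gains, gains.max(), rtol=0, atol=1e-12)]
            best = ties.min()
            if best != ci and gains[np.searchsorted(cand, best)] > \
                    gains[np.searchsorted(cand, ci)] + 1e-12:
                labels[i] = best
                improved = True
            comm_tot[labels[i]] += k[i]
    return _canonical(labels)


def _aggregate(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    ind = np.zeros((k, w.shape[0]))
    ind[labels, np.arange(w.shape[0])] = 1.0
    agg = ind @ w @ ind.T
    np.fill_diagonal(agg, np.diag(agg))  # self-loops carry internal weight
    return agg


# ---------------------------------------------------------------------------
# Girvan-Newman

def edge_betweenness(weights: np.ndarray) -> dict[tuple[int, int], float]:
    """Exact shortest-path edge betweenness (Brandes) on the weighted graph,
    with edge length 1/weight."""
    w = _check_weights(weights)
    n = w.shape[0]
    adj = [np.flatnonzero(w[i] > 0) for i in range(n)]
    between: dict[tuple[int, int], float] = {
        (i, j): 0.0 for i in range(n) for j in range(i + 1, n) if w[i, j] > 0}
    for s in range(n):
        # Dijkstra with path counting
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        visited = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        order = []
        while heap:
            d, u = heapq.heappop(heap)
            if visited[u]:
                continue
            visited[u] = True
            order.append(u)
            for v in adj[u]:
                nd = d + 1.0 / w[u, v]
                if nd < dist[v] - 1e-12:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - dist[v]) <= 1e-12 and not visited[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                share = sigma[p] / sigma[u] * (1.0 + delta[u])
                e = (p, u) if p < u else (u, p)
                between[e] += share
                delta[p] += share
    for e in between:  # each undirected pair counted from both endpoints
        between[e] /= 2.0
    return between


def _components(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    labels = np.full(n, -1)
    nxt = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = nxt
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(w[u] > 0):
                if labels[v] < 0:
                    labels[v] = nxt
                    stack.append(v)
        nxt += 1
    return labels


def girvan_newman(weights: np.ndarray, resolution: float = 1.0) -> np.ndarray:
    """Divisive detection: repeatedly remove the highest-betweenness edge and
    keep the component partition with maximum modularity on the original
    graph. Ties in betweenness break on the lexicographically smallest edge."""
    w = _check_weights(weights)
    work = w.copy()
    best_labels = _components(work)
    best_q = modularity(w, best_labels, resolution)
    while work.sum() > 0:
        bt = edge_betweenness_safe(work)
        top = max(bt.values())
        edge = min(e for e, v in bt.items() if abs(v - top) <= 1e-9)
        work[edge[0], edge[1]] = work[edge[1], edge[0]] = 0.0
        labels = _components(work)
        if work.sum() == 0:
            break
        q = modularity(w, labels, resolution)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels
    return _canonical(best_labels)


def edge_betweenness_safe(work: np.ndarray) -> dict[tuple[int, int], float]:
    """Betweenness on a possibly edge-depleted working copy (skips the
    zero-total-weight check per component by operating on the full matrix)."""
    # _check_weights rejects empty graphs; the caller guarantees work.sum()>0
    return edge_betweenness(work)


# ---------------------------------------------------------------------------
# Walktrap

def walktrap(weights: np.ndarray, t: int = 4,
             resolution: float = 1.0) -> np.ndarray:
    """Agglomerative detection from t-step random-walk profiles.

    Each node starts as its own community; adjacent communities merge in
    order of the minimum Ward-style increase in squared walk distance, and
    the merge tree is cut at the maximum-modularity level.  Isolated nodes
    stay singleton communities.
    """
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    w = _check_weights(weights)
    n = w.shape[0]
    deg = w.sum(axis=1)
    isolated = deg == 0
    # transition matrix on non-isolated nodes; isolated rows stay zero
    p1 = np.zeros_like(w)
    nz = ~isolated
    p1[nz] = w[nz] / deg[nz, None]
    pt = np.linalg.matrix_power(p1, t)

    inv_deg = np.zeros(n)
    inv_deg[nz] = 1.0 / deg[nz]

    # active communities: map label -> (member list, mean profile)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    profile: dict[int, np.ndarray] = {i: pt[i].copy() for i in range(n)}
    adjacent: dict[int, set[int]] = {
        i: set(np.flatnonzero(w[i] > 0)) for i in range(n)}
    labels = np.arange(n)
    merges: list[tuple[int, int]] = []

    def dsq(a: int, b: int) -> float:
        diff = profile[a] - profile[b]
        r2 = float(np.sum(diff * diff * inv_deg))
        na, nb = len(members[a]), len(members[b])
        return na * nb / (na + nb) / n * r2

    snapshots = [labels.copy()]
    active = set(range(n))
    while True:
        best = None
        best_cost = np.inf
        for a in sorted(active):
            for b in sorted(adjacent[a]):
                if b <= a or b not in active:
                    continue
                cost = dsq(a, b)
                if cost < best_cost - 1e-15:
                    best_cost = cost
                    best = (a, b)
        if best is None:
            break
        a, b = best
        na, nb = len(members[a]), len(members[b])
        profile[a] = (na * profile[a] + nb * profile[b]) / (na + nb)
        members[a].extend(members[b])
        adjacent[a] = (adjacent[a] | adjacent[b]) - {a, b}
        for c in adjacent[b]:
            adjacent[c].discard(b)
            if c != a:
                adjacent[c].add(a)
                adjacent[a].add(c)
        active.discard(b)
        labels = labels.copy()
        labels[labels == b] = a
        merges.append((a, b))
        snapshots.append(labels.copy())

    best_labels = snapshots[0]
    best_q = modularity(w, best_labels, resolution)
    for cand in snapshots[1:]:
        q = modularity(w, cand, resolution)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = cand
    return _canonical(best_labels)


# ---------------------------------------------------------------------------

ALGORITHMS = {
    "louvain": louvain,
    "girvan_newman": girvan_newman,
    "walktrap": walktrap,
}


def detect(weights: np.ndarray, algorithm: str = "louvain",
           resolution: float = 1.0, seed: int = 0, t: int = 4) -> np.ndarray:
    """Dispatch to one of the three implemented algorithms by name."""
    if algorithm == "louvain":
        return louvain(weights, resolution=resolution, seed=seed)
    if algorithm in ("girvan_newman", "gn"):
        return girvan_newman(weights, resolution=resolution)
    if algorithm == "walktrap":
        return walktrap(weights, t=t, resolution=resolution)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (1 = identical up to
    relabelling; <= 0 for chance-level agreement)."""
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))
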