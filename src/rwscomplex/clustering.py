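"""Modularity-based community detection: Qcut, HQcut and their null models.

Qcut maximizes Newman-Girvan modularity

    Q = sum_c [ w_in(c) / W  -  (s(c) / 2W)^2 ]

(W = total edge weight, w_in(c) = weight inside community c, s(c) = summed
node strength of c) by alternating two phases: recursive spectral bisection
using the leading eigenvector of the (generalized) modularity matrix, and a
greedy refinement over three operator families — moving a single vertex,
merging two communities, splitting a community — applying the best strictly
Q-increasing change until a local optimum is reached.

Global modularity maximization suffers from the resolution limit: small,
well-defined communities whose mutual connectivity is light but non-zero get
merged once the network is large enough.  HQcut corrects this by re-running
Qcut inside each found community and accepting the subdivision when the
internal structure is both strong (sub-Q above a threshold, default 0.3) and
statistically significant (empirical p-value below alpha, default 0.05,
against degree-preserving rewired null networks), recursing on accepted
subdivisions.

The null model everywhere is Maslov-Sneppen double-edge swapping, which
preserves the degree sequence exactly — important because modularity is
strongly degree-driven and PPI networks are degree-skewed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network_io import Network

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "modularity",
    "qcut",
    "refine",
    "hqcut",
    "community_pvalue",
    "rewire_preserving_degrees",
]

_EPS = 1e-12


@dataclass
class Partition:
    """Disjoint, exhaustive assignment of nodes to communities, with its Q."""

    assignment: dict[str, int]
    q: float

    def communities(self) -> dict[int, list[str]]:
        """Community id -> member list (node insertion order preserved)."""
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def _arrays(net: Network) -> tuple[sp.csr_matrix, np.ndarray, float]:
    A = net.adjacency()
    s = net.strengths()
    W = float(s.sum()) / 2.0
    return A, s, W


def _labels_of(net: Network, partition) -> np.ndarray:
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    try:
        raw = [assignment[v] for v in net.nodes]
    except KeyError as exc:
        raise ValueError(f"partition does not cover node {exc.args[0]!r}") from exc
    _, labels = np.unique(np.asarray(raw, dtype=object), return_inverse=True)
    return labels.astype(np.intp)


def _modularity_arrays(
    A: sp.csr_matrix, s: np.ndarray, W: float, labels: np.ndarray
) -> float:
    n = A.shape[0]
    comms, inv = np.unique(labels, return_inverse=True)
    M = sp.csr_matrix(
        (np.ones(n), (np.arange(n), inv)), shape=(n, len(comms))
    )
    E = (M.T @ (A @ M)).toarray()
    w_in = np.diag(E) / 2.0
    sc = M.T @ s
    return float(w_in.sum() / W - ((sc / (2.0 * W)) ** 2).sum())


def modularity(net: Network, partition) -> float:
    """Exact weighted Newman-Girvan modularity of a partition."""
    A, s, W = _arrays(net)
    if W <= 0:
        raise ValueError("modularity undefined for a network with zero total weight")
    return _modularity_arrays(A, s, W, _labels_of(net, partition))


# ---------------------------------------------------------------------------
# spectral bisection
# ---------------------------------------------------------------------------


def _kl_sweep(Bg: np.ndarray, sgn: np.ndarray, max_passes: int = 8) -> np.ndarray:
    """Kernighan-Lin style fine-tuning of a split vector, maximizing s'Bg s."""
    n = len(sgn)
    best = sgn.copy()
    best_val = float(best @ Bg @ best)
    diag = np.diag(Bg).copy()
    for _ in range(max_passes):
        cur = best.copy()
        val = best_val
        Bs = Bg @ cur
        moved = np.zeros(n, dtype=bool)
        trail_vals = np.empty(n)
        trail_idx = np.empty(n, dtype=np.intp)
        for t in range(n):
            gains = -4.0 * cur * Bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            val += gains[i]
            Bs = Bs - 2.0 * cur[i] * Bg[:, i]
            cur[i] = -cur[i]
            moved[i] = True
            trail_vals[t] = val
            trail_idx[t] = i
        t_best = int(np.argmax(trail_vals))
        if trail_vals[t_best] > best_val + _EPS:
            best_val = float(trail_vals[t_best])
            new = best.copy()
            for t in range(t_best + 1):
                new[trail_idx[t]] = -new[trail_idx[t]]
            best = new
        else:
            break
    return best


def _spectral_split(
    A: sp.csr_matrix, s: np.ndarray, W: float, idx: np.ndarray
) -> tuple[np.ndarray, float] | None:
    """Try to bisect the community ``idx`` via the modularity matrix.

    Returns (boolean side mask over idx, exact global delta-Q) or None when
    the community is indivisible (no strictly positive delta-Q split).
    """
    m = len(idx)
    if m < 2:
        return None
    k = s[idx]
    Asub = A[np.ix_(idx, idx)].toarray()
    B = Asub - np.outer(k, k) / (2.0 * W)
    Bg = B - np.diag(B.sum(axis=1))  # generalized modularity matrix
    vals, vecs = np.linalg.eigh(Bg)
    if vals[-1] < 1e-9:
        return None
    v = vecs[:, -1]
    # deterministic sign: largest-magnitude entry positive
    imax = int(np.argmax(np.abs(v)))
    if v[imax] < 0:
        v = -v
    sgn = np.where(v >= 0.0, 1.0, -1.0)
    sgn = _kl_sweep(Bg, sgn)
    dq = float(sgn @ Bg @ sgn) / (4.0 * W)
    if dq <= _EPS or abs(sgn.sum()) == m:
        return None
    return sgn > 0, dq


def _split_phase(
    A: sp.csr_matrix, s: np.ndarray, W: float, labels: np.ndarray
) -> bool:
    """Recursively bisect every community while Q strictly increases."""
    changed = False
    next_label = int(labels.max()) + 1 if len(labels) else 0
    stack = sorted(set(labels.tolist()))
    while stack:
        cid = stack.pop()
        idx = np.flatnonzero(labels == cid)
        res = _spectral_split(A, s, W, idx)
        if res is None:
            continue
        mask, _ = res
        labels[idx[~mask]] = next_label
        stack.extend([cid, next_label])
        next_label += 1
        changed = True
    return changed


# ---------------------------------------------------------------------------
# greedy refinement (moves + merges); splits handled by the split phase
# ---------------------------------------------------------------------------


def _refine_moves_merges(
    A: sp.csr_matrix, s: np.ndarray, W: float, labels: np.ndarray,
    max_iter: int = 20000,
) -> bool:
    """Apply the best strictly Q-increasing vertex move or community merge,
    repeatedly, until neither family improves Q.  Mutates ``labels``."""
    n = A.shape[0]
    changed = False
    for _ in range(max_iter):
        comms, inv = np.unique(labels, return_inverse=True)
        C = len(comms)
        M = sp.csr_matrix((np.ones(n), (np.arange(n), inv)), shape=(n, C))
        K = (A @ M).toarray()                      # K[v, c] = weight v -> c
        sc = np.asarray(M.T @ s).ravel()
        # vertex moves: dQ(v: a->b) = (K_vb - K_va)/W - s_v (s_b - s_a + s_v)/(2W^2)
        G = K / W - np.outer(s, sc) / (2.0 * W * W)
        own = G[np.arange(n), inv]
        dq_move = G - own[:, None] - (s**2)[:, None] / (2.0 * W * W)
        dq_move[np.arange(n), inv] = -np.inf
        mv_flat = int(np.argmax(dq_move))
        mv_v, mv_c = divmod(mv_flat, C)
        best_move = float(dq_move[mv_v, mv_c])
        # merges: dQ(a+b) = E_ab/W - s_a s_b/(2W^2)
        best_merge = -np.inf
        mg_a = mg_b = -1
        if C > 1:
            E = (M.T @ (A @ M)).toarray()
            dq_merge = E / W - np.outer(sc, sc) / (2.0 * W * W)
            iu = np.triu_indices(C, k=1)
            flat = int(np.argmax(dq_merge[iu]))
            mg_a, mg_b = int(iu[0][flat]), int(iu[1][flat])
            best_merge = float(dq_merge[mg_a, mg_b])
        if best_move <= _EPS and best_merge <= _EPS:
            break
        if best_move >= best_merge:
            labels[mv_v] = comms[mv_c]
        else:
            labels[labels == comms[mg_b]] = comms[mg_a]
        changed = True
    return changed


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities by first occurrence in node order."""
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels.tolist()):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def _finish(net: Network, labels: np.ndarray, W: float,
            A: sp.csr_matrix, s: np.ndarray) -> Partition:
    labels = _canonical(labels)
    q = _modularity_arrays(A, s, W, labels) if W > 0 else 0.0
    return Partition(dict(zip(net.nodes, labels.tolist())), q)


def qcut(net: Network, seed: int = 0) -> Partition:
    """Two-phase modularity maximization: spectral partitioning + refinement.

    Connected components are clustered independently (they are never merged:
    merging disconnected communities cannot increase Q).  Isolated nodes
    become singleton communities.  Fully deterministic for a given network;
    ``seed`` is accepted for interface symmetry with the stochastic stages.
    """
    n = net.n_nodes
    if n == 0:
        return Partition({}, 0.0)
    A, s, W = _arrays(net)
    if W <= 0:
        return Partition({v: i for i, v in enumerate(net.nodes)}, 0.0)
    _, labels = sp.csgraph.connected_components(A, directed=False)
    labels = labels.astype(np.intp)
    for _ in range(100):
        did_split = _split_phase(A, s, W, labels)
        did_refine = _refine_moves_merges(A, s, W, labels)
        if not (did_split or did_refine):
            break
    return _finish(net, labels, W, A, s)


def refine(net: Network, partition, seed: int = 0) -> Partition:
    """Greedy local search over moves, merges and splits from a partition.

    The split operator runs :func:`qcut` on the induced subcommunity and
    accepts its subdivision when that strictly increases the global Q.  The
    returned partition has Q >= the input's and is a local optimum under all
    three operator families.
    """
    A, s, W = _arrays(net)
    if W <= 0:
        return Partition(dict(partition.assignment) if isinstance(partition, Partition)
                         else dict(partition), 0.0)
    labels = _labels_of(net, partition)
    nodes = list(net.nodes)
    for _ in range(1000):
        _refine_moves_merges(A, s, W, labels)
        # moves/merges exhausted: try qcut-based splits
        best_dq = _EPS
        best_apply: tuple[np.ndarray, np.ndarray] | None = None
        q_now = _modularity_arrays(A, s, W, labels)
        for cid in sorted(set(labels.tolist())):
            idx = np.flatnonzero(labels == cid)
            if len(idx) < 2:
                continue
            sub = net.subgraph([nodes[i] for i in idx])
            if sub.n_edges == 0:
                continue
            subp = qcut(sub, seed)
            if subp.n_communities < 2:
                continue
            trial = labels.copy()
            base = int(labels.max()) + 1
            for j, name in enumerate(sub.nodes):
                trial[net.node_index(name)] = base + subp.assignment[name]
            dq = _modularity_arrays(A, s, W, trial) - q_now
            if dq > best_dq:
                best_dq = dq
                best_apply = (idx, trial)
        if best_apply is None:
            break
        labels = best_apply[1]
    return _finish(net, labels, W, A, s)


# ---------------------------------------------------------------------------
# degree-preserving null model
# ---------------------------------------------------------------------------


def rewire_preserving_degrees(
    net: Network, n_swaps: int | None = None, seed: int = 0
) -> Network:
    """Maslov-Sneppen double-edge swap randomization.

    Attempts ``n_swaps`` successful swaps (default 10 x |E|), preserving the
    degree sequence and edge count exactly and never introducing self-loops
    or multi-edges.  Edge weights are shuffled onto the rewired edge set.
    Graphs admitting no legal swap (e.g. a triangle) come back unchanged up
    to weight permutation.
    """
    edges = [(u, v) for u, v, _ in net.edges()]
    weights = [w for _, _, w in net.edges()]
    if len(edges) < 2:
        return net.copy()
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    edge_set = {frozenset(e) for e in edges}
    successes = 0
    attempts = 0
    max_attempts = max(100, 20 * n_swaps)
    n_e = len(edges)
    while successes < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, n_e, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.update((e1, e2))
        edges[i] = (a, d)
        edges[j] = (c, b)
        successes += 1
    perm = rng.permutation(len(weights))
    out = Network(net.nodes)
    for (u, v), pi in zip(edges, perm):
        out.add_edge(u, v, weights[pi], allow_nonpositive=True)
    return out


def community_pvalue(
    subnet: Network, q_obs: float, n_random: int = 30, seed: int = 0
) -> float:
    """Empirical significance of a community's internal modularity.

    p = (1 + #{Q_null >= q_obs}) / (1 + n_random), where each null Q is the
    qcut modularity of a degree-preserving rewiring of the subnetwork.
    Subnetworks with < 4 nodes or < 2 edges are never significant (p = 1).
    """
    if subnet.n_nodes < 4 or subnet.n_edges < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_random):
        null_seed = int(rng.integers(0, 2**31 - 1))
        null_net = rewire_preserving_degrees(subnet, seed=null_seed)
        if qcut(null_net, seed=null_seed).q >= q_obs - _EPS:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_random)


# ---------------------------------------------------------------------------
# HQcut
# ---------------------------------------------------------------------------


def hqcut(
    net: Network,
    q_threshold: float = 0.3,
    alpha: float = 0.05,
    n_random: int = 30,
    seed: int = 0,
) -> Partition:
    """Recursive Qcut: subdivide communities with strong, significant
    internal structure, correcting the resolution limit.

    A community is subdivided when qcut on its induced subnetwork yields
    sub-modularity > ``q_threshold`` AND empirical p-value < ``alpha`` under
    the degree-preserving null; accepted subdivisions are recursed into.
    With ``q_threshold = inf`` this reduces to plain qcut.
    """
    rng = np.random.default_rng(seed)
    top = qcut(net, seed)
    final: list[list[str]] = []
    stack = [members for _, members in sorted(top.communities().items())]
    while stack:
        members = stack.pop(0)
        if len(members) < 4:
            final.append(members)
            continue
        sub = net.subgraph(members)
        if sub.n_edges < 2:
            final.append(members)
            continue
        child_seed = int(rng.integers(0, 2**31 - 1))
        subp = qcut(sub, child_seed)
        if subp.n_communities < 2 or not (subp.q > q_threshold):
            final.append(members)
            continue
        pval_seed = int(rng.integers(0, 2**31 - 1))
        p = community_pvalue(sub, subp.q, n_random=n_random, seed=pval_seed)
        if p < alpha:
            for _, sub_members in sorted(subp.communities().items()):
                stack.append(sub_members)
        else:
            final.append(members)
    assignment = {node: cid for cid, members in enumerate(final) for node in members}
    A, s, W = _arrays(net)
    labels = _canonical(_labels_of(net, assignment))
    q = _modularity_arrays(A, s, W, labels) if W > 0 else 0.0
    return Partition(dict(zip(net.nodes, labels.tolist())), q)
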