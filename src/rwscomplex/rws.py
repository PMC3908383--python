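"""Random Walk with Resistance (RWS) and the PP-TS similarity matrix.

A PPI network is binary, sparse and noisy.  RWS converts it into a dense
protein-protein topological-similarity (PP-TS) matrix in three steps:

1. From every source protein v, propagate a unit of probability mass through
   the network.  Unlike a plain random walk, each traversal of an edge pays a
   toll ``epsilon`` (the flow along (i, j) at step k+1 is
   ``max(0, q_i(k) * P_ij - epsilon)``), and a node that has never held mass
   is entered only if the strongest incoming candidate flow reaches the entry
   threshold ``beta``.  ``epsilon`` makes the walk die out in a
   topology-dependent way; ``beta`` limits walk depth and damps the influence
   of hubs, whose many weak outgoing flows would otherwise smear mass across
   the whole graph.

2. The cumulative visitation vector of the dying walk (sum of the occupancy
   q over all steps) is the *topological profile* of the source.

3. The PP-TS entry for proteins u, v is the Pearson correlation of their
   profiles: two proteins are topologically similar when the walks started
   from them see the rest of the network in the same way, even if the two are
   not directly connected.

The propagation is deterministic flow bookkeeping, not Monte-Carlo sampling,
so this module needs no random seed.  At ``epsilon = beta = 0`` the walk is
the ordinary random walk and the cumulative profile equals the truncated
power sum ``sum_k e_v P^k`` — a useful oracle for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network_io import Network, PPTSMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WalkParams",
    "WalkState",
    "transition_matrix",
    "rws_step",
    "rws_profile",
    "rws_profiles",
    "pp_ts",
    "build_ppts",
]


@dataclass(frozen=True)
class WalkParams:
    """Resistance parameters of the walk.

    epsilon : per-traversal toll subtracted from every candidate edge flow.
    beta    : entry threshold; an unvisited node is entered only when the
              strongest single incoming candidate flow is >= beta.
    max_steps : hard cap on propagation steps.
    tol     : walk stops once the total remaining mass falls to <= tol.
    profile : "cumulative" (default) sums occupancy over all steps;
              "final" keeps the last occupancy vector with positive mass.
    """

    epsilon: float = 0.01
    beta: float = 0.05
    max_steps: int = 100
    tol: float = 1e-6
    profile: str = "cumulative"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.profile not in ("cumulative", "final"):
            raise ValueError("profile must be 'cumulative' or 'final'")


@dataclass
class WalkState:
    """Evolving state of one walk: occupancy q, last flows f, visit flags."""

    q: np.ndarray
    f: np.ndarray | None
    visited: np.ndarray
    cumulative: np.ndarray
    k: int = 0

    @classmethod
    def initial(cls, n: int, source_index: int) -> "WalkState":
        q = np.zeros(n)
        q[source_index] = 1.0
        visited = np.zeros(n, dtype=bool)
        visited[source_index] = True
        return cls(q=q, f=None, visited=visited, cumulative=q.copy(), k=0)


def transition_matrix(net: Network) -> np.ndarray:
    """Row-stochastic move probabilities P[v, u] = w(v, u) / d(v).

    Binary networks give the classic 1/degree rule; weighted networks use
    weight-proportional probabilities.  Rows of isolated nodes are all zero.
    Returned dense: profile propagation touches every entry anyway.
    """
    n = net.n_nodes
    P = net.adjacency().toarray()
    s = P.sum(axis=1)
    nz = s > 0
    P[nz] /= s[nz, None]
    return P


def rws_step(state: WalkState, P: np.ndarray, params: WalkParams) -> WalkState:
    """Advance the walk by one step of the resistance dynamics.

    Candidate flow along each edge (i, j) is ``c = q_i(k) * P_ij``.  A
    visited target pays only the toll: ``f = max(0, c - epsilon)``.  An
    unvisited target additionally requires ``max_i c >= beta``, otherwise all
    its incoming flows are blocked.  New occupancy is the column sum of f.
    """
    C = state.q[:, None] * P
    F = np.maximum(0.0, C - params.epsilon)
    entry_ok = state.visited | (C.max(axis=0) >= params.beta)
    F[:, ~entry_ok] = 0.0
    q_new = F.sum(axis=0)
    visited = state.visited | (q_new > 0)
    return WalkState(
        q=q_new,
        f=F,
        visited=visited,
        cumulative=state.cumulative + q_new,
        k=state.k + 1,
    )


def _run_walk(P: np.ndarray, source_index: int, params: WalkParams) -> WalkState:
    state = WalkState.initial(P.shape[0], source_index)
    last_positive_q = state.q
    for _ in range(params.max_steps):
        state = rws_step(state, P, params)
        total = state.q.sum()
        if total > 0:
            last_positive_q = state.q
        if total <= params.tol:
            break
    state.f = None  # drop the dense flow matrix; callers keep the profile
    if params.profile == "final":
        state.cumulative = last_positive_q.copy()
    return state


def rws_profile(
    net: Network, source: str, params: WalkParams | None = None
) -> np.ndarray:
    """Topological profile of one source node (vector in node order)."""
    params = params or WalkParams()
    P = transition_matrix(net)
    state = _run_walk(P, net.node_index(source), params)
    if params.profile == "final":
        return state.cumulative
    return state.cumulative


def rws_profiles(net: Network, params: WalkParams | None = None) -> np.ndarray:
    """Profile matrix: one walk per source, rows in node order."""
    params = params or WalkParams()
    P = transition_matrix(net)
    n = net.n_nodes
    profiles = np.empty((n, n))
    for i in range(n):
        profiles[i] = _run_walk(P, i, params).cumulative
    return profiles


def pp_ts(profiles: np.ndarray, nodes: list[str] | None = None) -> PPTSMatrix:
    """Pearson-correlate profile rows into the PP-TS matrix.

    Constant rows (zero variance) get correlation 0 with everything,
    including themselves, and are logged; all other diagonal entries are 1.
    """
    profiles = np.asarray(profiles, dtype=float)
    n, m = profiles.shape
    if n < 3 or m < 3:
        raise ValueError("PP-TS needs at least 3 nodes (Pearson needs variance)")
    if nodes is None:
        nodes = [str(i) for i in range(n)]
    X = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.sqrt((X**2).sum(axis=1))
    const = norms < 1e-300
    if const.any():
        logger.warning("%d constant profile row(s); correlations set to 0",
                       int(const.sum()))
        norms = np.where(const, 1.0, norms)
    Xn = X / norms[:, None]
    S = Xn @ Xn.T
    S[const, :] = 0.0
    S[:, const] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    diag = np.ones(n)
    diag[const] = 0.0
    np.fill_diagonal(S, diag)
    return PPTSMatrix(list(nodes), S)


def build_ppts(net: Network, params: WalkParams | None = None) -> PPTSMatrix:
    """Full first stage: walks from every node, then profile correlations."""
    params = params or WalkParams()
    return pp_ts(rws_profiles(net, params), list(net.nodes))
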