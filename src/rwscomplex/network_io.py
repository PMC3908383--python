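"""Containers and file formats for PPI-network analysis.

This module holds the in-memory objects shared by the whole pipeline —
:class:`Network` (an undirected weighted protein graph), :class:`PPTSMatrix`
(the dense protein-protein topological-similarity matrix), :class:`ComplexSet`
(possibly overlapping reference complexes) and :class:`PairScoreTable`
(precomputed per-pair functional scores such as GO semantic similarity) —
together with the plain-text readers/writers for each: TSV edge lists, SIF,
complex membership tables, expression matrices, pair-score tables, partition
files and GraphML export.

All formats are tab-separated text; GraphML export goes through networkx so
the output can be opened directly in Cytoscape or Gephi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "PPTSMatrix",
    "ComplexSet",
    "PairScoreTable",
    "threshold_matrix",
    "read_edge_list",
    "read_sif",
    "write_edge_list",
    "read_complexes",
    "write_complexes",
    "read_expression",
    "write_expression",
    "read_scores",
    "write_scores",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_graphml",
]


def _pair(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered key for an edge."""
    return (u, v) if u <= v else (v, u)


class Network:
    """Undirected weighted graph over named proteins.

    Invariants: no self-loops, no duplicate edges, deterministic node order
    (insertion order).  Binary networks are the weight-1.0 special case; the
    degree of a node in a weighted network is its strength (weight sum).
    """

    __slots__ = ("_nodes", "_index", "_edges", "meta")

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple] = (),
    ) -> None:
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._edges: dict[tuple[str, str], float] = {}
        self.meta: dict = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            u, v, *w = e
            self.add_edge(u, v, float(w[0]) if w else 1.0)

    # -- construction -------------------------------------------------

    def add_node(self, name: str) -> int:
        name = str(name)
        if name not in self._index:
            self._index[name] = len(self._nodes)
            self._nodes.append(name)
        return self._index[name]

    def add_edge(
        self,
        u: str,
        v: str,
        weight: float = 1.0,
        combine: str = "max",
        allow_nonpositive: bool = False,
    ) -> None:
        """Add an undirected edge, collapsing duplicates.

        ``combine='max'`` keeps the larger weight when the edge already
        exists.  Self-loops are rejected (the random walk moves only to
        neighbours ``u != v``); callers that must tolerate them drop them
        before calling.  ``allow_nonpositive`` exists solely for similarity
        networks thresholded at cutoffs <= 0.
        """
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop not allowed: {u!r}")
        w = float(weight)
        if not allow_nonpositive and w <= 0:
            raise ValueError(f"edge weight must be > 0, got {w} for ({u}, {v})")
        self.add_node(u)
        self.add_node(v)
        key = _pair(u, v)
        if key in self._edges:
            if combine == "max":
                self._edges[key] = max(self._edges[key], w)
            elif combine == "sum":
                self._edges[key] += w
            else:  # replace
                self._edges[key] = w
        else:
            self._edges[key] = w

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node_index(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def has_edge(self, u: str, v: str) -> bool:
        return _pair(str(u), str(v)) in self._edges

    def weight(self, u: str, v: str) -> float:
        return self._edges[_pair(str(u), str(v))]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges in deterministic (insertion) order."""
        for (u, v), w in self._edges.items():
            yield u, v, w

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency in node order (CSR)."""
        n = self.n_nodes
        if self.n_edges == 0:
            return sp.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for (u, v), w in self._edges.items():
            i, j = self._index[u], self._index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def strengths(self) -> np.ndarray:
        """Weighted degree d(v) per node, in node order."""
        s = np.zeros(self.n_nodes)
        for (u, v), w in self._edges.items():
            s[self._index[u]] += w
            s[self._index[v]] += w
        return s

    def total_weight(self) -> float:
        return float(sum(self._edges.values()))

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """Induced subgraph; node order inherited from this network."""
        keep = set(nodes)
        ordered = [n for n in self._nodes if n in keep]
        sub = Network(ordered)
        for (u, v), w in self._edges.items():
            if u in keep and v in keep:
                sub._edges[_pair(u, v)] = w
        return sub

    def copy(self) -> "Network":
        out = Network(self._nodes)
        out._edges = dict(self._edges)
        return out

    def connected_components(self) -> list[list[str]]:
        """Components as node-name lists, deterministic order."""
        n = self.n_nodes
        if n == 0:
            return []
        _, labels = sp.csgraph.connected_components(self.adjacency(), directed=False)
        comps: dict[int, list[str]] = {}
        for name, lab in zip(self._nodes, labels):
            comps.setdefault(int(lab), []).append(name)
        return [comps[k] for k in sorted(comps)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self._edges.items())
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        # identity up to node order
        return set(self._nodes) == set(other._nodes) and self._edges == other._edges

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class PPTSMatrix:
    """Symmetric node x node topological-similarity matrix (Pearson scale)."""

    nodes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} nodes"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("PP-TS matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class ComplexSet:
    """Reference protein complexes; overlap between complexes is allowed."""

    complexes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} is empty")

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return out

    def co_pairs(self, universe: set[str] | None = None) -> set[frozenset]:
        """Union of unordered co-complex pairs, optionally restricted."""
        pairs: set[frozenset] = set()
        for members in self.complexes.values():
            m = sorted(members if universe is None else members & universe)
            for i in range(len(m)):
                for j in range(i + 1, len(m)):
                    pairs.add(frozenset((m[i], m[j])))
        return pairs

    def __len__(self) -> int:
        return len(self.complexes)


class PairScoreTable:
    """Symmetric map from unordered protein pairs to a real score."""

    def __init__(self, scores: Mapping | None = None) -> None:
        self._scores: dict[tuple[str, str], float] = {}
        if scores:
            for key, val in scores.items():
                u, v = tuple(key)
                self.set(u, v, val)

    def set(self, u: str, v: str, score: float) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-pair not allowed: {u!r}")
        self._scores[_pair(u, v)] = float(score)

    def get(self, u: str, v: str, default: float | None = None) -> float | None:
        return self._scores.get(_pair(str(u), str(v)), default)

    def __contains__(self, pair) -> bool:
        u, v = tuple(pair)
        return _pair(str(u), str(v)) in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._scores.items())

    def mean(self) -> float:
        return float(np.mean(list(self._scores.values())))


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def threshold_matrix(m: PPTSMatrix, cutoff: float) -> Network:
    """Convert a dense similarity matrix into a sparse weighted network.

    An edge (u, v), u != v, is kept iff ``m[u, v] >= cutoff`` (inclusive),
    with the similarity as its weight.  All nodes are retained so downstream
    partitions stay defined over every protein; nodes with no surviving edge
    become singleton communities.
    """
    net = Network(m.nodes)
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    keep = m.values[iu, ju] >= cutoff
    for i, j in zip(iu[keep], ju[keep]):
        net.add_edge(
            m.nodes[i], m.nodes[j], float(m.values[i, j]), allow_nonpositive=True
        )
    return net


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_edge_list(path, weighted: bool | None = None) -> Network:
    """Read a TSV edge list: ``node1<TAB>node2[<TAB>weight]``.

    ``weighted=None`` auto-detects from the column count.  A header row is
    auto-detected when a third column exists and is non-numeric.  Duplicate
    edges collapse to the max weight; self-loops are dropped with a warning.
    Drop counts are recorded in ``Network.meta``.
    """
    net = Network()
    n_self = n_dup = 0
    n_records = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if lineno == 1 and len(parts) >= 3 and not _is_number(parts[2]):
                continue  # header row
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if weighted is False:
                w = 1.0
            elif len(parts) >= 3:
                if not _is_number(parts[2]):
                    raise ValueError(
                        f"{path}: non-numeric weight on line {lineno}: {line!r}"
                    )
                w = float(parts[2])
            else:
                if weighted is True:
                    raise ValueError(f"{path}: missing weight on line {lineno}")
                w = 1.0
            n_records += 1
            if u == v:
                n_self += 1
                net.add_node(u)
                continue
            if net.has_edge(u, v):
                n_dup += 1
            net.add_edge(u, v, w, combine="max")
    if n_records == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s) (max weight kept)", path, n_dup)
    net.meta = {"self_loops_dropped": n_self, "duplicates_collapsed": n_dup}
    return net


def read_sif(path) -> Network:
    """Read a SIF file: ``node1<TAB>interaction<TAB>node2 [node4 ...]``.

    The interaction type is ignored; a line with a single token declares an
    isolated node.  All edges get weight 1.0.
    """
    net = Network()
    any_line = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            any_line = True
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 1:
                net.add_node(parts[0])
                continue
            if len(parts) == 2:
                raise ValueError(f"{path}: malformed SIF line {lineno}: {line!r}")
            src = parts[0]
            for tgt in parts[2:]:
                if tgt == src:
                    logger.warning("%s: dropped self-loop on line %d", path, lineno)
                    continue
                net.add_edge(src, tgt, 1.0)
    if not any_line:
        raise ValueError(f"{path}: empty SIF file")
    return net


def write_edge_list(net: Network, path) -> None:
    with open(path, "w") as fh:
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_complexes(path) -> ComplexSet:
    """Read ``complex_id<TAB>protein`` membership lines."""
    complexes: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: complex file needs >= 2 columns, line {lineno}: {line!r}"
                )
            complexes.setdefault(parts[0], set()).add(parts[1])
    if not complexes:
        raise ValueError(f"{path}: empty complex file")
    return ComplexSet(complexes)


def write_complexes(cs: ComplexSet, path) -> None:
    with open(path, "w") as fh:
        for cid in cs.complexes:
            for p in sorted(cs.complexes[cid]):
                fh.write(f"{cid}\t{p}\n")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x conditions TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_scores(path) -> PairScoreTable:
    """Read ``protein1<TAB>protein2<TAB>score`` lines."""
    table = PairScoreTable()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if lineno == 1 and len(parts) >= 3 and not _is_number(parts[2]):
                continue  # header
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed score line {lineno}: {line!r}")
            u, v, s = parts[0], parts[1], parts[2]
            if u == v:
                n_self += 1
                continue
            table.set(u, v, float(s))
    if n_self:
        logger.warning("%s: ignored %d self-pair score(s)", path, n_self)
    return table


def write_scores(table: PairScoreTable, path) -> None:
    with open(path, "w") as fh:
        for (u, v), s in sorted(table.items()):
            fh.write(f"{u}\t{v}\t{s:.8g}\n")


def read_matrix(path) -> PPTSMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    nodes = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != nodes:
        raise ValueError(f"{path}: matrix rows and columns disagree")
    return PPTSMatrix(nodes, df.to_numpy(dtype=float))


def write_matrix(m: PPTSMatrix, path) -> None:
    pd.DataFrame(m.values, index=m.nodes, columns=m.nodes).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_partition(path) -> dict[str, str]:
    """Read ``node<TAB>community`` lines."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed partition line {lineno}")
            out[parts[0]] = parts[1]
    return out


def write_partition(assignment: Mapping[str, object], path) -> None:
    with open(path, "w") as fh:
        for node, comm in assignment.items():
            fh.write(f"{node}\t{comm}\n")


def write_graphml(net: Network, assignment: Mapping[str, object] | None, path) -> None:
    """Export the network (and optionally its partition) as GraphML.

    Every node carries a ``community`` attribute when an assignment is given;
    every edge carries its ``weight``.  The file opens directly in Cytoscape.
    """
    g = net.to_networkx()
    if assignment is not None:
        nx.set_node_attributes(
            g, {n: str(assignment.get(n, "")) for n in g.nodes}, "community"
        )
    nx.write_graphml(g, path)
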