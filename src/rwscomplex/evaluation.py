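"""Pair-based evaluation of predicted complexes and functional-relevance curves.

Complex predictions are disjoint partitions; references (e.g. the MIPS
catalogue) may overlap.  Both are therefore compared on the common currency
of unordered co-membership pairs: A = pairs co-clustered in the prediction,
B = pairs co-complexed in the reference (union over complexes, each pair
counted once).  The accuracy is the Fowlkes-Mallows index

    FM = |A ∩ B| / sqrt(|A| * |B|)

i.e. the geometric mean of pairwise precision and recall.  Before pair
counting, the prediction is restricted to proteins appearing in the
reference so both pair sets live on the same universe.

Functional relevance of a PP-TS matrix is probed by ranking all pairs by
similarity and tracing the running mean of an external per-pair score
(GO semantic similarity supplied as a table, or gene co-expression computed
here as Pearson correlation of expression profiles) over the top-r pairs.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .network_io import ComplexSet, Network, PairScoreTable, PPTSMatrix
from .clustering import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "fowlkes_mallows",
    "per_complex_accuracy",
    "coexpression_scores",
    "rank_pairs",
    "score_curve",
    "matched_cutoff",
    "CurvePoint",
]


def _assignment(pred) -> Mapping[str, object]:
    return pred.assignment if isinstance(pred, Partition) else pred


def _co_clustered_pairs(
    assignment: Mapping[str, object], universe: set[str]
) -> set[frozenset]:
    groups: dict[object, list[str]] = {}
    for node, cid in assignment.items():
        if node in universe:
            groups.setdefault(cid, []).append(node)
    pairs: set[frozenset] = set()
    for members in groups.values():
        for u, v in combinations(sorted(members), 2):
            pairs.add(frozenset((u, v)))
    return pairs


def fowlkes_mallows(pred, known: ComplexSet) -> float:
    """Fowlkes-Mallows accuracy of predicted complexes vs a reference set.

    Returns |A∩B|/sqrt(|A|·|B|) over co-membership pairs restricted to
    proteins shared by the prediction and the reference; 0 (with a warning)
    when either pair set is empty.
    """
    assignment = _assignment(pred)
    universe = known.proteins() & set(assignment)
    A = _co_clustered_pairs(assignment, universe)
    B = known.co_pairs(universe)
    if not A or not B:
        logger.warning("fowlkes_mallows: empty pair set (|A|=%d, |B|=%d)", len(A), len(B))
        return 0.0
    return len(A & B) / float(np.sqrt(len(A) * len(B)))


def per_complex_accuracy(pred, known: ComplexSet) -> dict[str, float]:
    """FM of the prediction against each reference complex separately.

    For each complex, the prediction is restricted to that complex's
    proteins and compared with the single-complex reference (all pairs).
    Complexes with fewer than 2 proteins in the prediction are skipped.
    """
    assignment = _assignment(pred)
    out: dict[str, float] = {}
    for cid, members in known.complexes.items():
        present = members & set(assignment)
        if len(present) < 2:
            logger.warning("complex %s: <2 proteins in prediction, skipped", cid)
            continue
        A = _co_clustered_pairs(assignment, present)
        n_b = len(present) * (len(present) - 1) // 2
        out[cid] = len(A) / float(np.sqrt(len(A) * n_b)) if A else 0.0
    return out


def coexpression_scores(expr: pd.DataFrame) -> PairScoreTable:
    """Pairwise Pearson correlation of expression profiles (genes x cond)."""
    if expr.shape[1] < 3:
        raise ValueError("expression matrix needs >= 3 conditions")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("excluded %d zero-variance gene(s)", int((~keep).sum()))
    genes = [g for g, k in zip(expr.index, keep) if k]
    X = X[keep]
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    S = np.clip(Xn @ Xn.T, -1.0, 1.0)
    table = PairScoreTable()
    for i, j in combinations(range(len(genes)), 2):
        table.set(str(genes[i]), str(genes[j]), float(S[i, j]))
    return table


def rank_pairs(
    m: PPTSMatrix, exclude_known: Network | None = None
) -> list[tuple[tuple[str, str], float, bool]]:
    """All unordered off-diagonal pairs, descending by PP-TS score.

    Ties are broken lexicographically by pair.  Each entry is
    ``((u, v), score, in_reference)`` where the flag marks pairs that are
    edges of ``exclude_known`` (False everywhere when no reference given).
    """
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    entries = []
    for i, j in zip(iu, ju):
        u, v = m.nodes[i], m.nodes[j]
        pair = (u, v) if u <= v else (v, u)
        known = exclude_known.has_edge(u, v) if exclude_known is not None else False
        entries.append((pair, float(m.values[i, j]), known))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries


class CurvePoint(NamedTuple):
    rank: int
    mean_score: float
    n_scored: int


def score_curve(
    pairs: Sequence[tuple],
    table: PairScoreTable,
    ranks: Sequence[int],
) -> list[CurvePoint]:
    """Mean external score of the top-r ranked pairs, for each r in ranks.

    Pairs absent from the score table are skipped; the effective count of
    scored pairs is reported per point.  A point with no scored pair gets
    mean NaN (flagged by n_scored = 0).
    """
    if max(ranks) > len(pairs):
        raise ValueError(f"rank {max(ranks)} exceeds {len(pairs)} available pairs")
    scores = np.full(len(pairs), np.nan)
    for idx, entry in enumerate(pairs):
        (u, v) = entry[0]
        s = table.get(u, v)
        if s is not None:
            scores[idx] = s
    out = []
    for r in sorted(ranks):
        top = scores[:r]
        n_scored = int(np.sum(~np.isnan(top)))
        mean = float(np.nanmean(top)) if n_scored else float("nan")
        if n_scored == 0:
            logger.warning("score_curve: no scored pair in top-%d", r)
        out.append(CurvePoint(r, mean, n_scored))
    return out


def matched_cutoff(
    pairs: Sequence[tuple],
    table: PairScoreTable,
    target_mean: float,
) -> tuple[int, float]:
    """Largest rank whose running mean score still reaches ``target_mean``.

    Mirrors calibrating the predicted network to the same average functional
    score as the original PPI network: returns (rank, PP-TS score at that
    rank).  Raises when the target is never attained, reporting the best
    running mean reached.
    """
    running_sum = 0.0
    n_scored = 0
    best_rank = 0
    best_mean = -np.inf
    cutoff = float("nan")
    for idx, entry in enumerate(pairs):
        (u, v), sim = entry[0], entry[1]
        s = table.get(u, v)
        if s is not None:
            running_sum += s
            n_scored += 1
        if n_scored == 0:
            continue
        mean = running_sum / n_scored
        best_mean = max(best_mean, mean)
        if mean >= target_mean:
            best_rank = idx + 1
            cutoff = sim
    if best_rank == 0:
        raise ValueError(
            f"target mean {target_mean} never attained (max running mean "
            f"{best_mean:.6g})"
        )
    return best_rank, cutoff
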