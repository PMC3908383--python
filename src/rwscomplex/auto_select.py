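"""Auto-HQcut: automated similarity-cutoff selection by modularity difference.

The PP-TS matrix is dense; a cutoff turns it back into a sparse weighted
network.  A good cutoff should produce a network that is *more modular than
chance*: highly structured relative to degree-preserving rewired copies of
itself.  For each candidate cutoff this module clusters the thresholded
network with HQcut, clusters ``n_random`` rewired nulls the same way, and
scores the cutoff by the modularity difference

    Q_diff = Q_obs - mean(Q_null).

The cutoff with the largest Q_diff wins (ties go to the smaller cutoff, i.e.
the denser network, which discards less evidence), and its partition is the
final complex prediction.  The full scan table is returned for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .network_io import Network, PPTSMatrix, threshold_matrix
from .clustering import Partition, hqcut, rewire_preserving_degrees

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "ModularityDifference",
    "ScanRow",
    "CutoffScanResult",
    "modularity_difference",
    "scan_cutoffs",
    "auto_hqcut",
    "select_best",
    "parse_grid",
]

#: Default cutoff grid: 0.30 to 0.95 in steps of 0.05.
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.30, 0.951, 0.05), 2))


def parse_grid(text: str) -> list[float]:
    """Parse ``start:stop:step`` (inclusive) or a comma-separated list."""
    if ":" in text:
        start, stop, step = (float(x) for x in text.split(":"))
        return [round(float(v), 10) for v in np.arange(start, stop + step / 2, step)]
    return [float(x) for x in text.split(",")]


class ModularityDifference(NamedTuple):
    q_obs: float
    q_null_mean: float
    q_diff: float
    q_null_sd: float
    partition: Partition


@dataclass
class ScanRow:
    cutoff: float
    n_edges: int
    valid: bool
    q_obs: float = float("nan")
    q_null_mean: float = float("nan")
    q_null_sd: float = float("nan")
    q_diff: float = float("nan")
    partition: Partition | None = None


@dataclass
class CutoffScanResult:
    rows: list[ScanRow] = field(default_factory=list)

    def valid_rows(self) -> list[ScanRow]:
        return [r for r in self.rows if r.valid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": [r.cutoff for r in self.rows],
                "n_edges": [r.n_edges for r in self.rows],
                "valid": [r.valid for r in self.rows],
                "Q_obs": [r.q_obs for r in self.rows],
                "Q_null_mean": [r.q_null_mean for r in self.rows],
                "Q_null_sd": [r.q_null_sd for r in self.rows],
                "Q_diff": [r.q_diff for r in self.rows],
                "n_communities": [
                    r.partition.n_communities if r.partition else 0 for r in self.rows
                ],
            }
        )


def modularity_difference(
    net: Network,
    n_random: int = 30,
    seed: int = 0,
    q_threshold: float = 0.3,
    alpha: float = 0.05,
    pvalue_n_random: int | None = None,
) -> ModularityDifference:
    """HQcut modularity of a network minus its mean over rewired nulls.

    ``pvalue_n_random`` controls the null count used *inside* HQcut's
    per-community significance test (defaults to ``n_random``).
    """
    if net.n_edges == 0:
        raise ValueError("modularity difference undefined for an empty edge set")
    if pvalue_n_random is None:
        pvalue_n_random = n_random
    rng = np.random.default_rng(seed)
    obs_seed = int(rng.integers(0, 2**31 - 1))
    part = hqcut(net, q_threshold, alpha, pvalue_n_random, seed=obs_seed)
    q_obs = part.q
    q_nulls = np.empty(n_random)
    for r in range(n_random):
        rw_seed = int(rng.integers(0, 2**31 - 1))
        hq_seed = int(rng.integers(0, 2**31 - 1))
        null_net = rewire_preserving_degrees(net, seed=rw_seed)
        q_nulls[r] = hqcut(
            null_net, q_threshold, alpha, pvalue_n_random, seed=hq_seed
        ).q
    mean = float(q_nulls.mean())
    sd = float(q_nulls.std(ddof=1)) if n_random > 1 else 0.0
    return ModularityDifference(q_obs, mean, q_obs - mean, sd, part)


def _row_valid(net: Network) -> bool:
    """A scan row is usable when the network has edges and its largest
    connected component spans at least 4 nodes."""
    if net.n_edges == 0:
        return False
    largest = max(len(c) for c in net.connected_components())
    return largest >= 4


def scan_cutoffs(
    m: PPTSMatrix,
    grid: Sequence[float] = DEFAULT_GRID,
    n_random: int = 30,
    seed: int = 0,
    q_threshold: float = 0.3,
    alpha: float = 0.05,
    pvalue_n_random: int | None = None,
) -> CutoffScanResult:
    """Threshold at every grid cutoff and score each network by Q_diff."""
    if len(grid) == 0:
        raise ValueError("cutoff grid is empty")
    rng = np.random.default_rng(seed)
    result = CutoffScanResult()
    for cutoff in grid:
        net = threshold_matrix(m, float(cutoff))
        row_seed = int(rng.integers(0, 2**31 - 1))
        if not _row_valid(net):
            logger.info("cutoff %.3g: invalid (n_edges=%d)", cutoff, net.n_edges)
            result.rows.append(ScanRow(float(cutoff), net.n_edges, valid=False))
            continue
        md = modularity_difference(
            net, n_random, row_seed, q_threshold, alpha, pvalue_n_random
        )
        logger.info(
            "cutoff %.3g: %d edges, Q_obs=%.4f, Q_null=%.4f, Q_diff=%.4f",
            cutoff, net.n_edges, md.q_obs, md.q_null_mean, md.q_diff,
        )
        result.rows.append(
            ScanRow(
                float(cutoff), net.n_edges, True,
                md.q_obs, md.q_null_mean, md.q_null_sd, md.q_diff, md.partition,
            )
        )
    if not result.valid_rows():
        raise ValueError(
            "every cutoff produced an unusable network; try a lower grid"
        )
    return result


def auto_hqcut(
    m: PPTSMatrix,
    grid: Sequence[float] = DEFAULT_GRID,
    n_random: int = 30,
    seed: int = 0,
    q_threshold: float = 0.3,
    alpha: float = 0.05,
    pvalue_n_random: int | None = None,
) -> tuple[float, Partition, CutoffScanResult]:
    """Scan the grid and return (best cutoff, its partition, full scan).

    The best row maximizes Q_diff; ties resolve to the smaller cutoff.
    """
    scan = scan_cutoffs(
        m, sorted(grid), n_random, seed, q_threshold, alpha, pvalue_n_random
    )
    best = select_best(scan)
    assert best.partition is not None
    logger.info("selected cutoff %.3g (Q_diff=%.4f)", best.cutoff, best.q_diff)
    return best.cutoff, best.partition, scan


def select_best(scan: CutoffScanResult) -> ScanRow:
    """Valid row with the largest Q_diff; ties go to the smaller cutoff."""
    rows = sorted(scan.valid_rows(), key=lambda r: r.cutoff)
    if not rows:
        raise ValueError("no valid scan rows to select from")
    best = rows[0]
    for row in rows[1:]:  # strict > keeps the earlier (smaller) cutoff on ties
        if row.q_diff > best.q_diff:
            best = row
    return best
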