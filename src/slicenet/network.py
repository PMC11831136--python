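"""Distance-delay correlation network.

Two proteins whose expression domains are displaced along the tissue axis
correlate best when one profile is shifted against the other; the shift at
the correlation maximum is the pair's *delay* (in profile grid units, about
one slice each).  All pairs are scanned, pairs with implausibly large delays
discarded, each remaining pair directed so its delay is non-negative, and
redundant edges removed by a data-processing-inequality (DPI) test: a
direct edge is dropped when some two-step path through a common neighbour
explains it with no greater total delay and comparable correlation.

Small overlaps inflate correlations toward 1, so the scan never uses
overlaps below the ``delayt`` floor (default 45% of the profile length).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_DELAY_LIMIT = 20
DEFAULT_DPI_TOLERANCE = 0.1
DEFAULT_DELAYT_FRACTION = 0.45


@dataclass
class DelayCurve:
    """Correlation as a function of delay, indexed -D..+D."""

    delays: np.ndarray
    corr: np.ndarray

    def argmax(self) -> tuple[int, float]:
        """First maximum (most negative delay on ties), NaN-aware."""
        if np.all(np.isnan(self.corr)):
            raise PipelineError("delay curve is entirely undefined")
        masked = np.where(np.isnan(self.corr), -np.inf, self.corr)
        i = int(np.argmax(masked))
        return int(self.delays[i]), float(self.corr[i])


def _segment_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    if method.startswith("s"):
        return float(stats.spearmanr(a, b).statistic)
    return float(np.corrcoef(a, b)[0, 1])


def delay_correlation(
    x, y, delayt: int | None = None, method: str = "spearman"
) -> DelayCurve:
    """Delay-correlation curve between two equal-length complete profiles.

    For every overlap i from ``delayt`` to n the head of one profile is
    correlated with the tail of the other, in both directions; the two
    half-curves are concatenated (second reversed, duplicate zero-delay
    entry removed) into a curve over delays -D..+D with D = n - delayt.
    Positive delays correspond to y's head matching x's tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValidationError("profiles must have equal length")
    if n < 4:
        raise ValidationError("need at least 4 points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise PipelineError("profiles must be complete (post-imputation)")
    if delayt is None:
        delayt = math.floor(n / 10 * 4.5)
    delayt = int(delayt)
    if delayt < 3:
        raise ValidationError("delayt must be >= 3")
    delayt = min(delayt, n)

    cor1 = np.array(
        [_segment_corr(x[:i], y[n - i :], method) for i in range(delayt, n + 1)]
    )
    cor2 = np.array(
        [_segment_corr(y[:i], x[n - i :], method) for i in range(delayt, n + 1)]
    )
    # cor1 spans delays -(n-delayt)..0, reversed cor2 spans 0..+(n-delayt);
    # drop cor1's zero-delay duplicate
    curve = np.concatenate([cor1[:-1], cor2[::-1]])
    d = n - delayt
    delays = np.arange(-d, d + 1)
    return DelayCurve(delays=delays, corr=curve)


def best_delays(
    values: pd.DataFrame,
    delayt: int | None = None,
    method: str = "spearman",
    delayt_fraction: float = DEFAULT_DELAYT_FRACTION,
) -> pd.DataFrame:
    """Best delay and correlation for every unordered protein pair.

    Operates on the finalized matrix whose columns are ordered by
    (replicate, perc2).  Pairs whose curve is entirely undefined are
    dropped with a log entry.  The result does not depend on enumeration
    order.
    """
    n = values.shape[1]
    if delayt is None:
        delayt = math.floor(n * delayt_fraction)
    rows = []
    arr = values.to_numpy(dtype=float)
    ids = list(values.index)
    for i, j in combinations(range(len(ids)), 2):
        try:
            curve = delay_correlation(arr[i], arr[j], delayt=delayt, method=method)
            delay, corr = curve.argmax()
        except PipelineError:
            logger.info("pair (%s, %s): undefined delay curve, dropped", ids[i], ids[j])
            continue
        rows.append((ids[i], ids[j], delay, corr))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "delay", "corr"])


def build_directed_edges(
    pairs: pd.DataFrame, delay_limit: int = DEFAULT_DELAY_LIMIT
) -> pd.DataFrame:
    """Direct each retained pair so its delay is non-negative.

    Pairs with |delay| >= ``delay_limit`` are removed (strict bound on both
    sides); every kept pair contributes the reversed pair with negated
    delay, and only delay >= 0 edges are retained — so zero-delay pairs
    appear in both directions.
    """
    keep = pairs[(pairs["delay"] > -delay_limit) & (pairs["delay"] < delay_limit)]
    fwd = keep.rename(columns={"protein_a": "source", "protein_b": "target"})
    rev = keep.rename(columns={"protein_a": "target", "protein_b": "source"}).assign(
        delay=lambda d: -d["delay"]
    )
    edges = pd.concat([fwd, rev], ignore_index=True)
    edges = edges[edges["delay"] >= 0].copy()
    edges["delay_inv"] = 1.0 / (edges["delay"] + 1.0)
    edges = edges[["source", "target", "delay", "corr", "delay_inv"]]
    return edges.reset_index(drop=True)


def dpi_prune(edges: pd.DataFrame, tolerance: float = DEFAULT_DPI_TOLERANCE) -> pd.DataFrame:
    """Single-pass data-processing-inequality pruning.

    An edge x->y with delay d and correlation c is removed iff some common
    intermediate i (out-neighbour of x and in-neighbour of y in the FULL
    unpruned graph) has both leg delays strictly positive, leg-delay sum
    below d*(1+tolerance), and |mean leg correlation| >= |c| - tolerance.
    All edges are evaluated against the original graph; removals apply
    once.  Nodes are never removed.
    """
    g = nx.DiGraph()
    attr: dict[tuple, tuple[float, float]] = {}
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target)
        attr[(row.source, row.target)] = (float(row.delay), float(row.corr))

    def redundant(x, y) -> bool:
        d, c = attr[(x, y)]
        if d < 0:  # cannot occur after build_directed_edges; keep and log
            logger.warning("edge %s->%s has negative delay; kept", x, y)
            return False
        common = set(g.successors(x)) & set(g.predecessors(y))
        common.discard(x)
        common.discard(y)
        for i in common:
            d1, c1 = attr[(x, i)]
            d2, c2 = attr[(i, y)]
            if (
                d1 > 0
                and d2 > 0
                and d1 + d2 < d * (1.0 + tolerance)
                and abs((c1 + c2) / 2.0) >= abs(c) - tolerance
            ):
                return True
        return False

    keep_mask = [
        not redundant(row.source, row.target) for row in edges.itertuples(index=False)
    ]
    return edges[keep_mask].reset_index(drop=True)


def export(edges: pd.DataFrame, path) -> None:
    """Write the network as a Cytoscape-importable edge-list CSV."""
    io.write_edge_list(edges, path)


def infer_network(
    values: pd.DataFrame,
    delay_limit: int = DEFAULT_DELAY_LIMIT,
    dpi_tolerance: float = DEFAULT_DPI_TOLERANCE,
    method: str = "spearman",
    delayt_fraction: float = DEFAULT_DELAYT_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full network stage: (unpruned directed edges, DPI-pruned edges)."""
    pairs = best_delays(values, method=method, delayt_fraction=delayt_fraction)
    edges = build_directed_edges(pairs, delay_limit=delay_limit)
    pruned = dpi_prune(edges, tolerance=dpi_tolerance)
    return edges, pruned
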