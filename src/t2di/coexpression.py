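"""De novo co-expression network: mutual information, thresholding, DPI.

The estimator discretizes each expression profile into equal-frequency
(rank-based) bins and computes plug-in mutual information in nats.  Pairs
above a stringent MI threshold (default 1.0 nats) are kept, then pruned with
the data processing inequality: in every triangle the strictly weakest edge
is presumed an indirect interaction and removed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .network import COEXPRESSION, Network

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MIEdge:
    """Symmetric gene-pair edge weighted by mutual information in nats."""

    gene_a: str
    gene_b: str
    mi: float

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


def default_bins(n_samples: int) -> int:
    """Default equal-frequency bin count B = max(2, floor(sqrt(n)))."""
    return max(2, int(np.sqrt(n_samples)))


def _rank_discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins.

    Ranks are taken with ties broken by original index (stable argsort), so
    the discretization is deterministic on any input.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Plug-in MI (nats) of the joint equal-frequency discretization.

    A constant vector carries no information: MI = 0 is returned with a
    degenerate-input warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if bins is None:
        bins = default_bins(len(x))
    if bins < 2 or len(x) < bins:
        raise ValueError(f"need |x| >= bins >= 2; got n={len(x)}, bins={bins}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: mutual information degenerate, returning 0", stacklevel=2)
        return 0.0
    bx = _rank_discretize(x, bins)
    by = _rank_discretize(y, bins)
    if bx.tobytes() > by.tobytes():
        bx, by = by, bx  # canonical orientation: MI(x,y) bitwise equals MI(y,x)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def pairwise_mi_matrix(expr: pd.DataFrame, bins: int | None = None, log_transform: bool = True) -> pd.DataFrame:
    """MI for every gene pair of a genes x samples expression matrix.

    Expression is log2(x+1)-transformed by default before rank binning (the
    ranks are invariant to the monotone transform; kept for parity with the
    documented pipeline).  Vectorized: the joint bin counts for all pairs at
    once are indicator-matrix products, one per (bin, bin) cell.  Constant
    genes get MI 0 against every partner.
    """
    values = expr.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    g, n = values.shape
    if bins is None:
        bins = default_bins(n)
    if bins < 2 or n < bins:
        raise ValueError(f"need n_samples >= bins >= 2; got n={n}, bins={bins}")
    constant = np.ptp(values, axis=1) == 0
    disc = np.vstack([_rank_discretize(row, bins) for row in values])
    # indicator[u]: genes x samples, 1 where the sample falls in bin u
    indicator = np.stack([(disc == u).astype(float) for u in range(bins)])
    marginal = indicator.sum(axis=2) / n  # bins x genes
    with np.errstate(divide="ignore"):
        log_marginal = np.log(marginal)
    mi = np.zeros((g, g))
    for u in range(bins):
        for v in range(bins):
            joint = (indicator[u] @ indicator[v].T) / n  # genes x genes
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * (np.log(joint) - log_marginal[u][:, None] - log_marginal[v][None, :])
            mi += np.where(joint > 0, term, 0.0)
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    np.fill_diagonal(mi, 0.0)
    mi = np.maximum(mi, 0.0)  # clip tiny negative rounding
    return pd.DataFrame(mi, index=expr.index, columns=expr.index)


def pairwise_mi(expr: pd.DataFrame, bins: int | None = None, log_transform: bool = True) -> list[MIEdge]:
    """All-pairs MI as a flat edge list (see :func:`pairwise_mi_matrix`)."""
    mat = pairwise_mi_matrix(expr, bins=bins, log_transform=log_transform).to_numpy()
    genes = list(expr.index)
    return [MIEdge(genes[i], genes[j], float(mat[i, j]))
            for i, j in itertools.combinations(range(len(genes)), 2)]


def dpi_prune(mi_edges: list[MIEdge], tolerance: float = 0.0) -> list[MIEdge]:
    """Data-processing-inequality pruning of a weighted MI graph.

    For every triangle (x, y, z) the edge with the strictly smallest MI is
    marked for removal when ``mi_weakest < (1 - tolerance) * min(other two)``.
    Marks are taken against the ORIGINAL edge set and applied simultaneously,
    so the result is independent of edge iteration order.  With all three MI
    equal there is no strict minimum and nothing is removed.
    """
    weight = {e.pair: e.mi for e in mi_edges}
    adjacency: dict[str, set[str]] = {}
    for e in mi_edges:
        adjacency.setdefault(e.gene_a, set()).add(e.gene_b)
        adjacency.setdefault(e.gene_b, set()).add(e.gene_a)
    doomed: set[frozenset[str]] = set()
    for e in mi_edges:
        a, b = e.gene_a, e.gene_b
        for c in adjacency[a] & adjacency[b]:
            w_ab = weight[e.pair]
            w_ac = weight[frozenset((a, c))]
            w_bc = weight[frozenset((b, c))]
            if w_ab < w_ac and w_ab < w_bc and w_ab < (1.0 - tolerance) * min(w_ac, w_bc):
                doomed.add(e.pair)
    return [e for e in mi_edges if e.pair not in doomed]


def build_mi_network(
    expr: pd.DataFrame,
    threshold: float = 1.0,
    bins: int | None = None,
    tolerance: float = 0.0,
    log_transform: bool = True,
) -> Network:
    """Two-step co-expression network: MI threshold, then DPI pruning.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples nonnegative expression (counts or FPKM).
    threshold : float
        Minimum MI in nats (default 1.0).
    """
    if threshold < 0:
        raise InvalidConfigError(f"MI threshold must be >= 0, got {threshold}")
    if expr.index.has_duplicates:
        raise InvalidConfigError("duplicate gene symbols in expression matrix")
    if len(expr) < 2:
        raise InvalidConfigError("need >= 2 genes to build a co-expression network")
    mat = pairwise_mi_matrix(expr, bins=bins, log_transform=log_transform).to_numpy()
    genes = list(expr.index)
    ii, jj = np.nonzero(np.triu(mat >= threshold, k=1))
    edges = [MIEdge(genes[i], genes[j], float(mat[i, j])) for i, j in zip(ii, jj)]
    kept = dpi_prune(edges, tolerance=tolerance)
    logger.info("MI network: %d pairs >= %.3g nats, %d after DPI", len(edges), threshold, len(kept))
    net = Network()
    for g in expr.index:
        net.add_node(g)
    for e in kept:
        net.add_edge(e.gene_a, e.gene_b, sources=(COEXPRESSION,), mi=e.mi)
    return net


def write_mi_edges(edges: list[MIEdge], path) -> None:
    """Write MI edges as TSV ``geneA geneB mi``."""
    with open(path, "w") as fh:
        for e in sorted(edges, key=lambda e: tuple(sorted((e.gene_a, e.gene_b)))):
            a, b = sorted((e.gene_a, e.gene_b))
            fh.write(f"{a}\t{b}\t{e.mi:.6g}\n")
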