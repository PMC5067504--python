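"""Module topology statistics: size z-score, separation, effect size.

Quantifies whether a disease gene set forms a non-random neighborhood of
the interactome: the observed largest-connected-component size S is
compared with its null distribution over uniformly resampled gene sets of
the same size, and the mean nearest-disease-gene distance d_s summarizes
how scattered the set is.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import empirical_p
from .errors import DegenerateInputError
from .network import Network, largest_connected_component

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleTopologyResult:
    """Largest-component statistics of a disease gene set on a network."""

    S: int
    Nd: int
    relative_size: float
    null_mean: float
    null_sd: float
    z: float                 # nan when the null is degenerate
    p_normal: float          # one-sided upper tail; nan when degenerate
    p_empirical: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "S": self.S, "Nd": self.Nd, "relative_size": self.relative_size,
            "null_mean": self.null_mean, "null_sd": self.null_sd, "z": self.z,
            "p_normal": self.p_normal, "p_empirical": self.p_empirical,
            "degenerate": self.degenerate,
        }


def p_from_z(z: float) -> float:
    """One-sided upper normal tail, 1 - Phi(z)."""
    return float(stats.norm.sf(z))


def module_size_zscore(
    network: Network,
    disease_genes,
    n_rand: int = 1000,
    seed: int | np.random.Generator = 0,
    degree_binned: bool = False,
) -> ModuleTopologyResult:
    """Observed vs random largest-component size of a disease gene set.

    The null resamples ``Nd`` genes uniformly from all network nodes
    ``n_rand`` times (``degree_binned=True`` instead resamples within
    log2-degree bins, preserving the degree profile).  z and the normal
    tail p are reported alongside the plus-one empirical p, which never
    reaches 0.  A zero null sd is flagged degenerate; only the empirical p
    is then meaningful.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100")
    genes = {Network._canon(g) for g in disease_genes}
    present = sorted(genes & network.nodes)
    if not present:
        raise ValueError("no disease genes present in the network")
    Nd = len(present)
    S = len(largest_connected_component(network, present))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    edge_u = np.array([index[a] for a, b in network.graph.edges], dtype=np.int64)
    edge_v = np.array([index[b] for a, b in network.graph.edges], dtype=np.int64)
    if degree_binned:
        degs = np.array([max(network.graph.degree[g], 1) for g in nodes])
        bin_id = np.floor(np.log2(degs)).astype(int)
        bins = {b: np.nonzero(bin_id == b)[0] for b in np.unique(bin_id)}
        present_bins = [int(np.floor(np.log2(max(network.graph.degree[g], 1)))) for g in present]

    null = np.empty(n_rand)
    for i in range(n_rand):
        if degree_binned:
            idx = np.unique([bins[b][rng.integers(len(bins[b]))] for b in present_bins])
        else:
            idx = rng.choice(n, size=Nd, replace=False)
        null[i] = _lcc_size_indices(n, edge_u, edge_v, idx)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    p_emp = empirical_p(int((null >= S).sum()), n_rand)
    if null_sd == 0:
        logger.warning("degenerate null (sd = 0); reporting empirical p only")
        return ModuleTopologyResult(S, Nd, S / Nd, null_mean, 0.0, float("nan"),
                                    float("nan"), p_emp, degenerate=True)
    z = (S - null_mean) / null_sd
    return ModuleTopologyResult(S, Nd, S / Nd, null_mean, null_sd, z, p_from_z(z), p_emp)


def _lcc_size_indices(n: int, edge_u: np.ndarray, edge_v: np.ndarray, idx: np.ndarray) -> int:
    """Largest-component size of the subgraph induced by node indices ``idx``.

    Same statistic as :func:`t2di.network.largest_connected_component`,
    computed with sparse connected components for the randomization loop.
    """
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    active = np.zeros(n, dtype=bool)
    active[idx] = True
    mask = active[edge_u] & active[edge_v]
    if not mask.any():
        return 1 if len(idx) else 0
    sub = sparse.coo_matrix(
        (np.ones(mask.sum()), (edge_u[mask], edge_v[mask])), shape=(n, n)
    )
    _, labels = connected_components(sub, directed=False)
    counts = np.bincount(labels[idx])
    return int(counts.max())


def separation_ds(network: Network, disease_genes) -> float:
    """Mean distance from each disease gene to its nearest other disease gene.

    Genes unreachable from every other disease gene are excluded with a
    logged count; fewer than 2 reachable genes is an error.
    """
    genes = sorted({Network._canon(g) for g in disease_genes} & network.nodes)
    if len(genes) < 2:
        raise DegenerateInputError("need >= 2 disease genes in the network")
    gene_set = set(genes)
    distances = []
    n_unreachable = 0
    for g in genes:
        d = _bfs_nearest(network, g, gene_set - {g})
        if d is None:
            n_unreachable += 1
        else:
            distances.append(d)
    if n_unreachable:
        logger.info("excluded %d disease gene(s) unreachable from any other", n_unreachable)
    if len(distances) < 2:
        raise DegenerateInputError("fewer than 2 disease genes reachable from another")
    return float(np.mean(distances))


def _bfs_nearest(network: Network, source: str, targets: set[str]) -> int | None:
    """Breadth-first distance from source to the nearest member of targets."""
    graph = network.graph
    seen = {source}
    queue = deque([(source, 0)])
    while queue:
        node, dist = queue.popleft()
        for nb in graph.neighbors(node):
            if nb in seen:
                continue
            if nb in targets:
                return dist + 1
            seen.add(nb)
            queue.append((nb, dist + 1))
    return None


def glass_delta(treatment_values, control_values) -> float:
    """Glass' Delta: (mean_treat - mean_control) / sd_control (ddof=1)."""
    treat = np.asarray(treatment_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    sd = ctrl.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError("control standard deviation is zero; Glass' Delta undefined")
    return float((treat.mean() - ctrl.mean()) / sd)
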