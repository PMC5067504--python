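"""Interactome data model and topology diagnostics.

A :class:`Network` is an undirected simple graph over upper-cased gene
symbols.  Every edge carries a set of *source tags* recording whether it came
from the curated physical interactome, the de novo co-expression network, or
both after merging.  The model is deliberately unweighted for module
discovery; mutual-information values survive only as optional edge metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import DegenerateInputError, ParseError

logger = logging.getLogger(__name__)

PHYSICAL = "physical"
COEXPRESSION = "coexpression"


@dataclass(frozen=True)
class DegreeFit:
    """Continuous maximum-likelihood power-law fit of a degree distribution.

    Attributes
    ----------
    alpha : float
        Estimated exponent (> 1).
    xmin : int
        Minimum degree included in the fitted tail.
    n_tail : int
        Number of nodes with degree >= xmin.
    """

    alpha: float
    xmin: int
    n_tail: int


class Network:
    """Undirected simple graph of gene symbols with per-edge source tags."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------
    @staticmethod
    def _canon(gene: str) -> str:
        return gene.strip().upper()

    def add_node(self, gene: str) -> None:
        self.graph.add_node(self._canon(gene))

    def add_edge(self, a: str, b: str, sources: Iterable[str] = (), **attrs) -> bool:
        """Add an undirected edge; self-loops are silently rejected.

        Returns True if an edge was added or updated, False for a self-loop.
        Source tags accumulate across repeated additions.
        """
        a, b = self._canon(a), self._canon(b)
        if a == b:
            return False
        tags = set(sources)
        if self.graph.has_edge(a, b):
            tags |= self.graph.edges[a, b].get("sources", set())
        self.graph.add_edge(a, b, sources=tags, **attrs)
        return True

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], source_tag: str | None = None) -> "Network":
        net = cls()
        tags = (source_tag,) if source_tag else ()
        for a, b in edges:
            net.add_edge(a, b, sources=tags)
        return net

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sources(self, a: str, b: str) -> set[str]:
        return set(self.graph.edges[self._canon(a), self._canon(b)].get("sources", set()))

    def degree(self, gene: str) -> int:
        return self.graph.degree[self._canon(gene)]

    def __contains__(self, gene: str) -> bool:
        return self._canon(gene) in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self):  # mutable container
        raise TypeError("Network is unhashable")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, source_tag: str | None = None) -> Network:
    """Read a TSV edge list (``geneA<TAB>geneB[<TAB>source]``) into a Network.

    Symbols are upper-cased and trimmed; duplicate rows collapse; self-loops
    are dropped with a logged count.  A row whose first two fields are not
    both nonempty raises :class:`ParseError` naming the line.  An empty file
    yields a valid empty network with a warning.
    """
    net = Network()
    n_rows = 0
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"{path}: line {lineno}: expected >=2 tab-separated gene symbols, got {line!r}")
            n_rows += 1
            tag = parts[2].strip() if len(parts) >= 3 and parts[2].strip() else source_tag
            tags = tag.split(",") if tag else ([source_tag] if source_tag else [])
            if not net.add_edge(parts[0], parts[1], sources=[t for t in tags if t]):
                n_loops += 1
    if n_rows == 0:
        logger.warning("edge list %s is empty; returning empty network", path)
    if n_loops:
        logger.warning("dropped %d self-loop row(s) reading %s", n_loops, path)
    return net


def write_edge_list(network: Network, path: str | Path) -> None:
    """Write the canonical sorted edge list; round-trips with read_edge_list."""
    rows = []
    for a, b in network.graph.edges:
        a, b = sorted((a, b))
        tags = ",".join(sorted(network.graph.edges[a, b].get("sources", set())))
        rows.append((a, b, tags))
    with open(path, "w") as fh:
        for a, b, tags in sorted(rows):
            fh.write(f"{a}\t{b}\t{tags}\n")


def write_graphml(network: Network, path: str | Path) -> None:
    """GraphML export for visualization tools; source tags joined by commas."""
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for a, b, data in network.graph.edges(data=True):
        g.add_edge(a, b, sources=",".join(sorted(data.get("sources", set()))))
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Merging and topology
# ---------------------------------------------------------------------------

def merge_networks(physical: Network, coexpr: Network) -> Network:
    """Union of two networks; an edge present in both carries both tags.

    ``|E_merged| = |E_phys| + |E_coexpr| - |E_shared|`` by construction.
    """
    merged = Network()
    for net in (physical, coexpr):
        for n in net.graph.nodes:
            merged.add_node(n)
        for a, b, data in net.graph.edges(data=True):
            merged.add_edge(a, b, sources=data.get("sources", set()))
    return merged


def power_law_fit(network: Network, xmin: int = 2) -> DegreeFit:
    """Continuous MLE of the degree-distribution power-law exponent.

    alpha_hat = 1 + n / sum(ln(k_i / (xmin - 0.5))) over degrees k_i >= xmin.
    Raises DegenerateInputError when fewer than 2 nodes reach xmin or when
    every tail degree equals xmin (the log-sum vanishes and the MLE diverges).
    """
    return power_law_fit_degrees([d for _, d in network.graph.degree], xmin)


def power_law_fit_degrees(degrees, xmin: int = 2) -> DegreeFit:
    """Power-law MLE on a raw degree sequence (see :func:`power_law_fit`)."""
    if xmin < 1:
        raise DegenerateInputError("xmin must be >= 1")
    tail = [d for d in degrees if d >= xmin]
    if len(tail) < 2:
        raise DegenerateInputError(f"need >= 2 nodes with degree >= {xmin}; found {len(tail)}")
    if max(tail) == xmin:
        raise DegenerateInputError("all tail degrees equal xmin; power-law exponent undefined")
    log_sum = sum(math.log(k / (xmin - 0.5)) for k in tail)
    if log_sum <= 0:
        raise DegenerateInputError("degenerate degree sequence; power-law exponent undefined")
    return DegreeFit(alpha=1.0 + len(tail) / log_sum, xmin=xmin, n_tail=len(tail))


def largest_connected_component(network: Network, genes: Iterable[str]) -> set[str]:
    """Largest connected component of the subgraph induced by ``genes``.

    Genes absent from the network count as isolated singletons.  Ties break
    toward the component containing the lexicographically smallest member.
    Empty input yields the empty set.
    """
    present = [Network._canon(g) for g in genes]
    present = sorted(set(present))
    if not present:
        return set()
    in_graph = [g for g in present if g in network.graph]
    sub = network.graph.subgraph(in_graph)
    components = [set(c) for c in nx.connected_components(sub)]
    components.extend({g} for g in present if g not in network.graph)
    return min(components, key=lambda c: (-len(c), min(c)))
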