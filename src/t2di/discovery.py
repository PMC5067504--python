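"""Disease-module discovery: diffusion expansion, active subnetworks, signatures.

Two complementary searches run on the merged interactome:

* **Diffusion expansion** (DIAMOnD-style): starting from known disease
  (seed) genes, iteratively add the gene whose links to the current set are
  most significant under a hypergeometric connectivity test.  Scoring by
  connectivity *significance* rather than raw link count penalizes hubs,
  whose many seed links are expected by degree alone.

* **Active-subnetwork search** (jActiveModules-style): map per-gene
  differential-expression p-values to z-scores, and search by simulated
  annealing for connected subgraphs maximizing the size-calibrated
  aggregate z.  The search is run recursively: a second pass inside the
  first-pass subnetworks yields the refined high-scoring network (HSN2).

Genes found by either method must additionally pass the
differential-expression gate to enter the final signature set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateInputError, InvalidConfigError
from .network import Network

logger = logging.getLogger(__name__)

_P_CLAMP = 1e-12


@dataclass(frozen=True)
class DiamondCandidateScore:
    """One gene added by diffusion expansion, with its connectivity evidence."""

    gene: str
    k: int        # degree in the network
    ks: int       # links to the seed/expanded set when added
    p: float      # hypergeometric connectivity p-value
    rank: int     # iteration at which the gene was added (1-based)


@dataclass(frozen=True)
class ActiveModuleScore:
    """A connected active subnetwork and its calibrated aggregate score."""

    genes: frozenset[str]
    zA: float
    sA: float
    k: int
    mu_k: float
    sigma_k: float


@dataclass
class SignatureSet:
    """DE-supported module genes with per-gene method provenance."""

    provenance: dict[str, str] = field(default_factory=dict)  # gene -> diamond|jactivemodules|both

    @property
    def genes(self) -> set[str]:
        return set(self.provenance)

    def counts(self) -> dict[str, int]:
        n_diamond = sum(1 for v in self.provenance.values() if v in ("diamond", "both"))
        n_jam = sum(1 for v in self.provenance.values() if v in ("jactivemodules", "both"))
        n_both = sum(1 for v in self.provenance.values() if v == "both")
        return {"diamond": n_diamond, "jactivemodules": n_jam, "both": n_both, "total": len(self.provenance)}


# ---------------------------------------------------------------------------
# Diffusion expansion
# ---------------------------------------------------------------------------

def diamond_connectivity_p(N: int, s: int, k: int, ks: int) -> float:
    """Hypergeometric tail P(X >= ks) for a degree-k gene with ks seed links.

    p = sum_{i=ks}^{min(k,s)} C(s,i) C(N-s, k-i) / C(N,k).
    """
    if not (0 <= ks <= min(k, s)):
        raise ValueError(f"require 0 <= ks <= min(k, s); got ks={ks}, k={k}, s={s}")
    if not (0 <= s < N):
        raise ValueError(f"require 0 <= s < N; got s={s}, N={N}")
    if not (0 <= k <= N - 1):
        raise ValueError(f"require 0 <= k <= N-1; got k={k}, N={N}")
    # survival function at ks-1 == upper tail including ks; scipy evaluates
    # the sum of log-space pmf terms, stable for large N
    return float(stats.hypergeom.sf(ks - 1, N, s, k))


def diamond_run(network: Network, seeds: set[str], n_iter: int = 200) -> list[DiamondCandidateScore]:
    """Iterative most-significant-connectivity expansion from seed genes.

    At each step every non-member gene with at least one link to the
    current set is scored by :func:`diamond_connectivity_p` with N = all
    network nodes and s = current set size; the smallest p wins, ties going
    to larger ks then lexicographically smaller symbol.  Returns the added
    genes in order, stopping early if the frontier empties.
    """
    if n_iter < 1:
        raise InvalidConfigError("n_iter must be >= 1")
    effective = {g for g in (Network._canon(s) for s in seeds) if g in network.graph}
    dropped = len(set(seeds)) - len(effective)
    if dropped:
        logger.warning("dropped %d seed(s) absent from the network", dropped)
    if not effective:
        raise ValueError("no seed genes present in the network")

    graph = network.graph
    nodes = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    N = len(nodes)
    degree = np.array([graph.degree[g] for g in nodes])
    ks = np.zeros(N, dtype=np.int64)
    member = np.zeros(N, dtype=bool)
    for g in effective:
        member[index[g]] = True
    for g in effective:
        for nb in graph.neighbors(g):
            ks[index[nb]] += 1

    results: list[DiamondCandidateScore] = []
    s = len(effective)
    for rank in range(1, n_iter + 1):
        frontier = np.nonzero(~member & (ks >= 1))[0]
        if frontier.size == 0:
            logger.info("diffusion frontier exhausted after %d additions", len(results))
            break
        k_f = degree[frontier]
        ks_f = ks[frontier]
        p_f = stats.hypergeom.sf(ks_f - 1, N, s, k_f)
        best_p = p_f.min()
        tied = frontier[p_f == best_p]
        best_ks = ks[tied].max()
        tied = tied[ks[tied] == best_ks]
        winner = min(tied, key=lambda i: nodes[i])
        results.append(
            DiamondCandidateScore(
                gene=nodes[winner], k=int(degree[winner]), ks=int(ks[winner]),
                p=float(stats.hypergeom.sf(ks[winner] - 1, N, s, degree[winner])), rank=rank,
            )
        )
        member[winner] = True
        for nb in graph.neighbors(nodes[winner]):
            ks[index[nb]] += 1
        s += 1
    return results


# ---------------------------------------------------------------------------
# Active-subnetwork scoring
# ---------------------------------------------------------------------------

def gene_zscore(p: float) -> float:
    """z = Phi^-1(1 - p), with p clamped to [1e-12, 1 - 1e-12]."""
    if not (0.0 < p < 1.0):
        warnings.warn(f"p={p} outside (0,1); clamping", stacklevel=2)
    clamped = min(max(p, _P_CLAMP), 1.0 - _P_CLAMP)
    if clamped != p and 0.0 < p < 1.0:
        warnings.warn(f"p={p} clamped to {clamped} for z-scoring", stacklevel=2)
    return float(stats.norm.isf(clamped))


def subnetwork_score(zs) -> float:
    """Aggregate z of a subnetwork: zA = sum(z_i) / sqrt(k)."""
    zs = np.asarray(zs, dtype=float)
    if zs.size < 1:
        raise ValueError("need at least one z")
    return float(zs.sum() / np.sqrt(zs.size))


def calibrate_score(
    network: Network,
    gene_p: dict[str, float],
    k: int,
    n_samples: int = 2000,
    seed: int | np.random.Generator = 0,
    method: str = "mc",
) -> tuple[float, float]:
    """Null moments (mu_k, sigma_k) of zA over uniform random k-gene sets.

    ``method='mc'`` samples ``n_samples`` subsets (the reference
    definition); ``method='exact'`` returns the closed-form
    finite-population moments of the same quantity (the n_samples -> inf
    limit), which the annealer uses internally for speed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = sorted(network.nodes)
    if k > len(nodes):
        raise ValueError("k exceeds network size")
    z = np.array([gene_zscore(_lookup_p(gene_p, g)) for g in nodes])
    if method == "exact":
        return _exact_null_moments(z, k)
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.empty(n_samples)
    n = len(nodes)
    for i in range(n_samples):
        idx = rng.choice(n, size=k, replace=False)
        draws[i] = z[idx].sum() / np.sqrt(k)
    mu = float(draws.mean())
    sigma = float(draws.std(ddof=1))
    if sigma == 0:
        raise DegenerateInputError("degenerate calibration: sigma_k = 0")
    return mu, sigma


def _lookup_p(gene_p: dict[str, float], gene: str) -> float:
    p = gene_p.get(gene, 1.0)
    return min(max(p, _P_CLAMP), 1.0 - _P_CLAMP)


def _exact_null_moments(z: np.ndarray, k: int) -> tuple[float, float]:
    """Finite-population mean/sd of sum(z_subset)/sqrt(k) under uniform sampling."""
    n = len(z)
    mu_pop = z.mean()
    var_pop = z.var(ddof=0)
    mu = np.sqrt(k) * mu_pop
    if n == 1 or k == n:
        var = var_pop * (n - k) / max(n - 1, 1)
    else:
        var = var_pop * (n - k) / (n - 1)
    sigma = float(np.sqrt(max(var, 0.0)))
    if sigma == 0:
        raise DegenerateInputError("degenerate calibration: sigma_k = 0")
    return float(mu), sigma


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

class _AnnealState:
    """Vectorized scorer: top-m calibrated component scores of active nodes."""

    def __init__(self, network: Network, gene_p: dict[str, float], n_modules: int):
        self.nodes = sorted(network.graph.nodes)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        self.n = len(self.nodes)
        edges = [(self.index[a], self.index[b]) for a, b in network.graph.edges]
        self.eu = np.array([e[0] for e in edges], dtype=np.int32)
        self.ev = np.array([e[1] for e in edges], dtype=np.int32)
        self.z = np.array([gene_zscore(_lookup_p(gene_p, g)) for g in self.nodes])
        self.n_modules = n_modules
        # closed-form null moments, precomputed for every component size
        mu_pop = self.z.mean()
        var_pop = self.z.var(ddof=0)
        ks = np.arange(self.n + 1, dtype=float)
        self.mu_k = np.sqrt(ks) * mu_pop
        denom = max(self.n - 1, 1)
        var_k = var_pop * (self.n - ks) / denom
        self.sigma_k = np.sqrt(np.clip(var_k, 1e-12, None))

    def component_scores(self, active: np.ndarray):
        """(labels, sizes, sA per active component); empty arrays if none active."""
        act_idx = np.nonzero(active)[0]
        if act_idx.size == 0:
            return None, np.array([]), np.array([])
        mask = active[self.eu] & active[self.ev]
        sub = sparse.coo_matrix(
            (np.ones(mask.sum()), (self.eu[mask], self.ev[mask])), shape=(self.n, self.n)
        )
        n_comp, labels = connected_components(sub, directed=False)
        labels_active = labels[act_idx]
        comp_ids, inverse = np.unique(labels_active, return_inverse=True)
        sizes = np.bincount(inverse)
        zsum = np.bincount(inverse, weights=self.z[act_idx])
        zA = zsum / np.sqrt(sizes)
        sA = (zA - self.mu_k[sizes]) / self.sigma_k[sizes]
        return (labels, act_idx, inverse, comp_ids), sizes, sA

    def score(self, active: np.ndarray) -> float:
        _, _, sA = self.component_scores(active)
        if sA.size == 0:
            return -np.inf
        top = np.sort(sA)[::-1][: self.n_modules]
        return float(top.sum())


def jactivemodules_run(
    network: Network,
    gene_p: dict[str, float],
    start_temp: float = 1.0,
    end_temp: float = 0.01,
    iterations: int = 1_000_000,
    n_modules: int = 5,
    overlap_threshold: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> list[ActiveModuleScore]:
    """Simulated-annealing search for high-scoring active subnetworks.

    Every node starts active with probability 1/2; each iteration toggles
    one uniformly random node, accepting score improvements always and
    worsenings with probability exp(delta/T) under geometric cooling
    T_i = start * (end/start)^(i/iterations).  The state score is the sum
    of the ``n_modules`` highest calibrated component scores sA.  The
    best-seen state's components are returned in descending sA, greedily
    filtered to pairwise Jaccard overlap <= ``overlap_threshold``.
    """
    if iterations < 1:
        raise InvalidConfigError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = _AnnealState(network, gene_p, n_modules)
    if state.n == 0:
        return []
    active = rng.random(state.n) < 0.5
    current = state.score(active)
    best = current
    best_active = active.copy()

    ratio = end_temp / start_temp
    toggles = rng.integers(0, state.n, size=iterations)
    unif = rng.random(iterations)
    for i in range(iterations):
        node = toggles[i]
        active[node] = ~active[node]
        proposal = state.score(active)
        delta = proposal - current
        if delta >= 0:
            current = proposal
        else:
            temp = start_temp * ratio ** (i / iterations)
            if unif[i] < np.exp(delta / temp):
                current = proposal
            else:
                active[node] = ~active[node]  # revert
        if current > best:
            best = current
            best_active = active.copy()

    return _extract_modules(state, best_active, n_modules, overlap_threshold)


def _extract_modules(
    state: _AnnealState, active: np.ndarray, n_modules: int, overlap_threshold: float
) -> list[ActiveModuleScore]:
    info, sizes, sA = state.component_scores(active)
    if info is None:
        return []
    _, act_idx, inverse, _ = info
    order = np.argsort(-sA, kind="stable")
    chosen: list[ActiveModuleScore] = []
    for ci in order:
        genes = frozenset(state.nodes[i] for i in act_idx[inverse == ci])
        ok = True
        for prev in chosen:
            jac = len(genes & prev.genes) / len(genes | prev.genes)
            if jac > overlap_threshold:
                ok = False
                break
        if not ok:
            continue
        k = int(sizes[ci])
        zA = float(sum(state.z[state.index[g]] for g in genes) / np.sqrt(k))
        chosen.append(
            ActiveModuleScore(
                genes=genes, zA=zA, sA=float(sA[ci]), k=k,
                mu_k=float(state.mu_k[k]), sigma_k=float(state.sigma_k[k]),
            )
        )
        if len(chosen) == n_modules:
            break
    return chosen


def recursive_search(
    network: Network,
    gene_p: dict[str, float],
    seed: int | np.random.Generator = 0,
    **params,
) -> tuple[list[ActiveModuleScore], list[ActiveModuleScore]]:
    """Two-pass annealing: HSN1 on the full network, HSN2 inside HSN1.

    The second pass searches the subgraph induced by the union of HSN1
    genes, so HSN2 genes are always a subset of HSN1 genes.
    """
    if not gene_p:
        logger.warning("no scored genes; returning empty HSN1/HSN2")
        return [], []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hsn1 = jactivemodules_run(network, gene_p, seed=rng, **params)
    if not hsn1:
        logger.warning("first-pass search returned no modules; HSN2 empty")
        return [], []
    union = set().union(*(m.genes for m in hsn1))
    sub = Network()
    for g in union:
        sub.add_node(g)
    for a, b in network.graph.edges:
        if a in union and b in union:
            sub.add_edge(a, b)
    hsn2 = jactivemodules_run(sub, {g: p for g, p in gene_p.items() if g in union}, seed=rng, **params)
    return hsn1, hsn2


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

def combine_signatures(diamond: list[str] | set[str], hsn2: set[str], deg: set[str]) -> SignatureSet:
    """DE-supported union of the two discovery methods.

    signatures = (diamond ∪ hsn2) ∩ deg, with per-gene provenance;
    |signatures| = |diamond∩deg| + |hsn2∩deg| − |diamond∩hsn2∩deg|.
    """
    d = set(diamond) & set(deg)
    j = set(hsn2) & set(deg)
    sig = SignatureSet()
    for g in sorted(d | j):
        sig.provenance[g] = "both" if (g in d and g in j) else ("diamond" if g in d else "jactivemodules")
    return sig


def signature_table(sig: SignatureSet, stats_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signature genes with provenance and, when available, their DE stats."""
    df = pd.DataFrame(
        {"gene": sorted(sig.provenance), "provenance": [sig.provenance[g] for g in sorted(sig.provenance)]}
    ).set_index("gene")
    if stats_table is not None:
        df = df.join(stats_table, how="left")
    return df
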