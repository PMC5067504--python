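"""GWAS integration: SNP-to-gene binning, gene-level p, enrichment layers.

Summary statistics are aggregated to the gene level by positional- and
LD-based binning: a SNP belongs to a gene's bin if it lies inside the gene
body, or is in LD (r^2 above threshold, one hop) with a genotyped SNP that
does.  The bin's minimum p is Sidak-corrected for bin size.  On top of the
gene-level p sit the comparison layers: genomic inflation, fraction curves
against size-matched random control gene sets, Fisher 2x2 enrichment,
Monte-Carlo annotation enrichment of SNP sets, perfect-LD expansion, and a
simplified Bayes-factor concordance score between eQTL and GWAS signals
("sherlock-lite").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import empirical_p
from .errors import ValidationError

logger = logging.getLogger(__name__)

GENOME_WIDE_SIGNIFICANCE = 5.00e-8
_CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...
DEFAULT_SHERLOCK_W = 0.04


@dataclass(frozen=True)
class GeneBin:
    """SNPs assigned to one gene by positional- and LD-binning."""

    gene: str
    snps: frozenset[str]
    m: int
    p_min: float


@dataclass(frozen=True)
class McEnrichmentResult:
    """Monte-Carlo annotation enrichment of a SNP set vs random size-matched sets."""

    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_rand: int


@dataclass(frozen=True)
class SherlockGeneScore:
    """Summed log Bayes factor of a gene's eSNPs against GWAS, with permutation p."""

    gene: str
    esnps: tuple[str, ...]
    lbf_per_esnp: tuple[float, ...]
    total_lbf: float
    p: float


# ---------------------------------------------------------------------------
# Binning and gene-level p
# ---------------------------------------------------------------------------

def canonicalize_ld(ld: pd.DataFrame) -> pd.DataFrame:
    """Store each LD pair once with sorted ids; duplicates keep the max r2."""
    a = ld[["snp1", "snp2"]].min(axis=1)
    b = ld[["snp1", "snp2"]].max(axis=1)
    out = ld.assign(snp1=a, snp2=b)
    out = out[out.snp1 != out.snp2]
    return out.sort_values(["snp1", "snp2", "r2"]).drop_duplicates(["snp1", "snp2"], keep="last").reset_index(drop=True)


def bin_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.8,
) -> list[GeneBin]:
    """Positional- and LD-based SNP binning (one LD hop, no chaining).

    SNP s enters bin(g) iff it lies within [start_g, end_g] on g's
    chromosome, or some genotyped SNP t inside g has r^2(s, t) >=
    ``r2_threshold``.  A SNP may belong to several bins.  Genes with empty
    bins are omitted.
    """
    if (genes["start"] > genes["end"]).any():
        bad = genes[genes["start"] > genes["end"]].iloc[0]
        raise ValidationError(f"gene {bad['gene']}: start > end")
    pos = snps.set_index("snp")
    neighbors: dict[str, set[str]] = {}
    if ld is not None and len(ld):
        strong = canonicalize_ld(ld)
        strong = strong[strong["r2"] >= r2_threshold]
        for s1, s2 in zip(strong["snp1"], strong["snp2"]):
            neighbors.setdefault(s1, set()).add(s2)
            neighbors.setdefault(s2, set()).add(s1)

    bins: list[GeneBin] = []
    for row in genes.itertuples():
        inside = snps[
            (snps["chrom"] == row.chrom) & (snps["pos"] >= row.start) & (snps["pos"] <= row.end)
        ]["snp"]
        members = set(inside)
        for t in inside:
            members |= neighbors.get(t, set())
        members &= set(pos.index)
        if not members:
            continue
        p_min = float(pos.loc[sorted(members), "p"].min())
        bins.append(GeneBin(gene=row.gene, snps=frozenset(members), m=len(members), p_min=p_min))
    return bins


def gene_p_sidak(gene_bin: GeneBin) -> float:
    """Sidak-corrected minimum p of a bin: 1 - (1 - p_min)^m."""
    if gene_bin.m < 1:
        raise ValidationError("empty bin has no gene-level p")
    return float(-np.expm1(gene_bin.m * np.log1p(-gene_bin.p_min)))


def gene_p_simes(gene_bin: GeneBin, snp_p: pd.Series) -> float:
    """Simes combination over the bin's SNP p-values (alternative aggregator)."""
    p = np.sort(snp_p.loc[sorted(gene_bin.snps)].to_numpy())
    m = len(p)
    return float(min(1.0, (p * m / np.arange(1, m + 1)).min()))


def aggregate_gene_p(bins: list[GeneBin], snp_p: pd.Series | None = None, method: str = "sidak") -> dict[str, float]:
    """Gene-level p for every bin, by Sidak-corrected min-p or Simes."""
    if method == "sidak":
        return {b.gene: gene_p_sidak(b) for b in bins}
    if method == "simes":
        if snp_p is None:
            raise ValidationError("simes aggregation needs per-SNP p-values")
        return {b.gene: gene_p_simes(b, snp_p) for b in bins}
    raise ValidationError(f"unknown aggregation method {method!r}")


# ---------------------------------------------------------------------------
# Inflation and fraction curves
# ---------------------------------------------------------------------------

def lambda_gc(pvals) -> float:
    """Genomic inflation factor: median chi2_1 quantile over its null median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


def qq_fraction_comparison(
    gene_p: dict[str, float],
    query_sets: dict[str, set[str]],
    n_controls: int = 100,
    seed: int | np.random.Generator = 0,
    grid: np.ndarray | None = None,
) -> dict:
    """Fraction of genes below each p threshold, vs random control gene sets.

    For each query set and threshold t on a log-spaced grid, the fraction
    of member genes with gene-level p <= t is compared with the mean +/- sd
    band over ``n_controls`` uniform size-matched samples from the
    gene-level p domain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if grid is None:
        grid = np.logspace(-6, 0, 25)
    domain = sorted(gene_p)
    values = np.array([gene_p[g] for g in domain])
    result: dict = {"grid": grid.tolist(), "sets": {}, "n_controls": n_controls}
    for name, genes in query_sets.items():
        present = [g for g in genes if g in gene_p]
        missing = len(genes) - len(present)
        if not present:
            raise ValidationError(f"query set {name!r} has no genes with a gene-level p")
        if missing:
            logger.info("query set %s: %d gene(s) without gene-level p dropped", name, missing)
        q = np.array([gene_p[g] for g in present])
        curve = (q[None, :] <= grid[:, None]).mean(axis=1)
        ctrl_curves = np.empty((n_controls, len(grid)))
        for i in range(n_controls):
            idx = rng.choice(len(domain), size=len(present), replace=False)
            ctrl_curves[i] = (values[idx][None, :] <= grid[:, None]).mean(axis=1)
        result["sets"][name] = {
            "n_genes": len(present),
            "n_missing": missing,
            "fraction": curve.tolist(),
            "control_mean": ctrl_curves.mean(axis=0).tolist(),
            "control_sd": ctrl_curves.std(axis=0, ddof=1).tolist(),
        }
    return result


# ---------------------------------------------------------------------------
# Enrichment engines
# ---------------------------------------------------------------------------

def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (greater) Fisher's exact test on the 2x2 table [[a,b],[c,d]].

    Returns (odds_ratio, p).  OR = ad/bc, infinite when bc = 0 with ad > 0.
    """
    cells = (a, b, c, d)
    if any((not isinstance(x, (int, np.integer))) or x < 0 for x in cells):
        raise ValidationError("table cells must be nonnegative integers")
    if sum(cells) < 1:
        raise ValidationError("table must contain at least one observation")
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    p = float(stats.hypergeom.sf(a - 1, n_total, row1, col1))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


def monte_carlo_snp_enrichment(
    query_snps,
    background: pd.DataFrame,
    flags: pd.Series | pd.DataFrame,
    n_rand: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> McEnrichmentResult:
    """Monte-Carlo enrichment of flagged SNPs in a query set.

    The statistic is the number of query SNPs carrying the annotation flag;
    the null redraws a size-matched SNP set from the background ``n_rand``
    times without replacement within each draw.  A without-replacement
    flagged count is a hypergeometric variate, so the null is sampled
    directly from Hypergeometric(N, K, n) — distribution-identical to
    explicit permutation and fast at 10^6 draws.  p uses the plus-one
    convention, so its floor at 10^6 draws is 1.00E-6.
    """
    if n_rand < 100:
        raise ValidationError("n_rand must be >= 100")
    query = sorted(set(query_snps))
    bg_ids = set(background["snp"])
    if not set(query) <= bg_ids:
        raise ValidationError("query SNPs must be a subset of the background")
    if isinstance(flags, pd.DataFrame):
        flag_series = flags.set_index("snp").drop(columns=[], errors="ignore").max(axis=1)
    else:
        flag_series = flags
    flag_series = flag_series.reindex(sorted(bg_ids)).fillna(0).astype(int)
    observed = int(flag_series.loc[query].sum())
    N = len(bg_ids)
    K = int(flag_series.sum())
    n = len(query)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = rng.hypergeometric(K, N - K, n, size=n_rand)
    return McEnrichmentResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p=empirical_p(int((null >= observed).sum()), n_rand),
        n_rand=n_rand,
    )


def perfect_ld_expand(snps, ld: pd.DataFrame) -> set[str]:
    """Transitive closure of a SNP set under perfect LD (r^2 = 1 AND D' = 1).

    Perfect LD is an equivalence relation, so expansion follows connected
    components of the perfect-LD subgraph.
    """
    query = set(snps)
    if ld is None or not len(ld):
        return query
    perfect = canonicalize_ld(ld)
    perfect = perfect[(perfect["r2"] == 1.0) & (perfect["dprime"] == 1.0)]
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s1, s2 in zip(perfect["snp1"], perfect["snp2"]):
        parent[find(s1)] = find(s2)
    roots = {find(q) for q in query if q in parent}
    expanded = set(query)
    for s in parent:
        if find(s) in roots:
            expanded.add(s)
    return expanded


# ---------------------------------------------------------------------------
# Sherlock-lite eQTL/GWAS concordance
# ---------------------------------------------------------------------------

def sherlock_lbf(z: float, V: float, W: float = DEFAULT_SHERLOCK_W) -> float:
    """Approximate log Bayes factor of one eSNP's GWAS association.

    LBF = ln[ sqrt(V/(V+W)) * exp(z^2 W / (2 (V+W))) ], the Wakefield
    asymptotic form: negative near z = 0 (evidence against association),
    positive for large |z|.  eSNPs absent from the GWAS contribute nothing.
    """
    if V <= 0:
        raise ValidationError("V must be > 0")
    if W < 0:
        raise ValidationError("W must be >= 0")
    if W == 0:
        return 0.0
    return float(0.5 * np.log(V / (V + W)) + (z * z * W) / (2.0 * (V + W)))


def sherlock_gene_score(
    gene: str,
    esnps: pd.DataFrame,
    z_pool: np.ndarray,
    W: float = DEFAULT_SHERLOCK_W,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SherlockGeneScore | None:
    """Summed eSNP LBF for a gene with a permutation p-value.

    ``esnps`` columns: snp, z (GWAS z of the eSNP), V.  Each permutation
    redraws the gene's eSNP z-scores uniformly from the full GWAS z pool;
    p = (#{perm >= observed} + 1)/(n_perm + 1).  Genes with no eSNPs are
    skipped (None).
    """
    if len(esnps) == 0:
        logger.info("gene %s has no eSNPs; skipped", gene)
        return None
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lbfs = tuple(sherlock_lbf(row.z, row.V, W) for row in esnps.itertuples())
    total = float(sum(lbfs))
    z_pool = np.asarray(z_pool, dtype=float)
    V = esnps["V"].to_numpy()[None, :]
    z_draw = rng.choice(z_pool, size=(n_perm, len(esnps)), replace=True)
    perm_totals = (0.5 * np.log(V / (V + W)) + (z_draw**2 * W) / (2.0 * (V + W))).sum(axis=1)
    p = empirical_p(int((perm_totals >= total).sum()), n_perm)
    return SherlockGeneScore(gene=gene, esnps=tuple(esnps["snp"]), lbf_per_esnp=lbfs, total_lbf=total, p=p)
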