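"""Synthetic study generator with a planted disease module.

Every downstream stage of the pipeline is exercised offline against data
from this module: a scale-free interactome with a planted connected disease
module, a two-group negative-binomial expression cohort whose fold changes
concentrate in and near the module, GWAS summary statistics with
block-structured LD and association signal in module genes, regulatory
flags and eQTL records enriched at module SNPs, and comorbid-disease gene
sets sharing genes with the module.

All stages draw from independent substreams of one master seed
(:func:`t2di._util.stage_rng`), so regenerating one stage never perturbs
another and identical configs give byte-identical written files.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import stage_rng
from .config import SimConfig
from .errors import InvalidConfigError
from .network import PHYSICAL, Network

_RW_MAX_STEPS_PER_NODE = 200
_RW_MAX_RESTARTS = 25


@dataclass
class GroundTruth:
    """The generator's planted structure, for recovery and calibration tests."""

    module_genes: set[str] = field(default_factory=set)
    seed_genes: set[str] = field(default_factory=set)
    effect_genes: set[str] = field(default_factory=set)
    per_gene_lfc: dict[str, float] = field(default_factory=dict)
    causal_snps: set[str] = field(default_factory=set)

    def validate(self) -> "GroundTruth":
        if not self.seed_genes <= self.module_genes:
            raise ValueError("seed genes must be a subset of module genes")
        return self

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "seed_genes": sorted(self.seed_genes),
            "effect_genes": sorted(self.effect_genes),
            "per_gene_lfc": {g: self.per_gene_lfc[g] for g in sorted(self.per_gene_lfc)},
            "causal_snps": sorted(self.causal_snps),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            module_genes=set(d["module_genes"]),
            seed_genes=set(d["seed_genes"]),
            effect_genes=set(d["effect_genes"]),
            per_gene_lfc=dict(d["per_gene_lfc"]),
            causal_snps=set(d["causal_snps"]),
        )


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _random_walk_module(graph: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Connected module of ``size`` nodes sampled by a random walk.

    Retries from a fresh uniform start when a walk stalls; raises after a
    bounded number of restarts.
    """
    nodes = sorted(graph.nodes)
    for _ in range(_RW_MAX_RESTARTS):
        current = nodes[rng.integers(len(nodes))]
        visited = {current}
        for _ in range(_RW_MAX_STEPS_PER_NODE * size):
            neighbors = sorted(graph.neighbors(current))
            current = neighbors[rng.integers(len(neighbors))]
            visited.add(current)
            if len(visited) == size:
                return visited
    raise RuntimeError(f"random walk failed to collect {size} distinct nodes after {_RW_MAX_RESTARTS} restarts")


def simulate_interactome(config: SimConfig) -> tuple[Network, GroundTruth]:
    """Scale-free interactome with a planted connected disease module.

    Preferential attachment (``attach_m`` edges per new node) over
    ``n_genes`` symbols; the module is a connected induced subgraph of
    ``module_size`` nodes collected by a random walk and densified by extra
    in-module edges (each absent module pair added with probability
    ``module_extra_edge_prob`` — disease modules are by definition locally
    dense neighborhoods).  Seed genes are drawn uniformly from the module;
    planted expression effects cover the module plus each first neighbor
    with probability ``neighbor_effect_prob``.
    """
    config.validate()
    rng = stage_rng(config.seed, "interactome")
    symbols = _gene_symbols(config.n_genes)
    ba_seed = int(rng.integers(2**31))
    graph = nx.barabasi_albert_graph(config.n_genes, config.attach_m, seed=ba_seed)
    graph = nx.relabel_nodes(graph, {i: symbols[i] for i in range(config.n_genes)})

    module = _random_walk_module(graph, config.module_size, rng)
    module_sorted = sorted(module)
    for i, a in enumerate(module_sorted):
        for b in module_sorted[i + 1:]:
            if not graph.has_edge(a, b) and rng.random() < config.module_extra_edge_prob:
                graph.add_edge(a, b)

    seeds = set(rng.choice(module_sorted, size=config.n_seeds, replace=False))

    effect = set(module)
    neighbor_pool = sorted({n for g in module_sorted for n in graph.neighbors(g)} - module)
    for g in neighbor_pool:
        if rng.random() < config.neighbor_effect_prob:
            effect.add(g)
    per_gene_lfc = {g: float(config.lfc_effect) for g in sorted(effect)} if config.lfc_effect != 0 else {}
    if config.lfc_effect == 0:
        effect = set()

    net = Network()
    for g in symbols:
        net.add_node(g)
    for a, b in graph.edges:
        net.add_edge(a, b, sources=(PHYSICAL,))
    truth = GroundTruth(
        module_genes=module,
        seed_genes=seeds,
        effect_genes=effect,
        per_gene_lfc=per_gene_lfc,
    ).validate()
    return net, truth


def simulate_expression(network: Network, truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Two-group negative-binomial count matrix (genes x samples).

    Controls draw NB(mu_g, phi) with mu_g log-normal around ``base_mean``;
    cases multiply mu_g by 2**lfc for planted effect genes.  Module genes
    additionally share one latent log-normal factor across samples
    (strength ``latent_sd``), inducing the positive co-expression that the
    mutual-information network is expected to recover.
    """
    config.validate()
    if config.dispersion <= 0:
        raise InvalidConfigError("dispersion must be > 0")
    if not truth.module_genes <= network.nodes:
        raise ValueError("ground-truth genes must be network nodes")
    rng = stage_rng(config.seed, "expression")
    genes = sorted(network.nodes)
    n_samples = config.n_cases + config.n_controls
    mu = config.base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))

    is_case = np.array([True] * config.n_cases + [False] * config.n_controls)
    lfc = np.array([truth.per_gene_lfc.get(g, 0.0) for g in genes])
    means = np.tile(mu[:, None], (1, n_samples))
    means[:, is_case] *= 2.0 ** lfc[:, None]

    if config.latent_sd > 0 and truth.module_genes:
        factor = rng.normal(0.0, 1.0, size=n_samples)
        in_module = np.array([g in truth.module_genes for g in genes])
        means[in_module] *= np.exp(config.latent_sd * factor)[None, :]

    phi = config.dispersion
    r = 1.0 / phi
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    columns = [f"case_{i + 1:02d}" for i in range(config.n_cases)] + [
        f"ctrl_{i + 1:02d}" for i in range(config.n_controls)
    ]
    return pd.DataFrame(counts, index=genes, columns=columns)


def sample_groups(counts: pd.DataFrame) -> pd.Series:
    """Group labels ('case'/'control') inferred from simulated column names."""
    return pd.Series(
        ["case" if c.startswith("case") else "control" for c in counts.columns],
        index=counts.columns,
    )


def gene_coordinates(genes: list[str], gene_length: int = 2000, gap: int = 2000) -> pd.DataFrame:
    """Non-overlapping 1-based inclusive gene intervals on one synthetic chromosome."""
    starts = 1 + np.arange(len(genes)) * (gene_length + gap)
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + gene_length - 1, "gene": list(genes)}
    )


def simulate_gwas(
    genes: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GWAS summary statistics and a block-structured LD table.

    SNP counts per gene body and per inter-gene gap are Poisson with mean
    ``snps_per_gene_mean``; z ~ Normal(0, 1) with ``gwas_ncp`` added at
    causal SNPs (those inside module genes when the study has any planted
    expression effect); p = 2 * Phi(-|z|).  LD is emitted for every pair
    within blocks of ``ld_block_size`` consecutive SNPs, r^2 drawn high,
    some pairs at exactly r^2 = 1, D' = 1, and nothing across blocks.

    Also records the causal SNP ids on ``truth``.
    """
    config.validate()
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene intervals must satisfy start <= end")
    rng = stage_rng(config.seed, "gwas")
    positions: list[int] = []
    in_module_gene: list[bool] = []
    genes_sorted = genes.sort_values("start").reset_index(drop=True)
    for row in genes_sorted.itertuples():
        n_in = rng.poisson(config.snps_per_gene_mean)
        if n_in:
            pos = np.sort(rng.integers(row.start, row.end + 1, size=n_in))
            positions.extend(int(x) for x in pos)
            in_module_gene.extend([row.gene in truth.module_genes] * n_in)
    gaps = list(zip(genes_sorted["end"][:-1] + 1, genes_sorted["start"][1:] - 1))
    for lo, hi in gaps:
        if hi < lo:
            continue
        n_gap = rng.poisson(config.snps_per_gene_mean)
        if n_gap:
            pos = np.sort(rng.integers(lo, hi + 1, size=n_gap))
            positions.extend(int(x) for x in pos)
            in_module_gene.extend([False] * n_gap)

    order = np.argsort(positions, kind="stable")
    positions_arr = np.asarray(positions)[order]
    causal_mask = np.asarray(in_module_gene)[order]
    n_snps = len(positions_arr)
    ids = [f"rs{i + 1:06d}" for i in range(n_snps)]

    z = rng.normal(0.0, 1.0, size=n_snps)
    planted = causal_mask & (config.gwas_ncp != 0)
    z[planted] += config.gwas_ncp
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    snps = pd.DataFrame({"snp": ids, "chrom": "chr1", "pos": positions_arr, "p": p, "z": z})
    truth.causal_snps = set(np.asarray(ids)[planted])

    ld_rows = []
    for block_start in range(0, n_snps, config.ld_block_size):
        block = ids[block_start: block_start + config.ld_block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                if rng.random() < 0.15:
                    r2, dprime = 1.0, 1.0
                else:
                    r2 = float(rng.uniform(0.7, 1.0))
                    dprime = float(rng.uniform(np.sqrt(r2), 1.0))
                a, b = sorted((block[i], block[j]))
                ld_rows.append((a, b, r2, dprime))
    ld = pd.DataFrame(ld_rows, columns=["snp1", "snp2", "r2", "dprime"])
    return snps, ld


def simulate_annotations(
    snps: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP binary regulatory flags and an eQTL table.

    Flag odds are multiplied by ``annot_enrichment`` at causal SNPs.  eQTL
    records (snp, gene, z, V, tissue) preferentially target module genes:
    module genes draw more eSNPs, from their own (causal) SNPs.
    """
    config.validate()
    if snps.empty:
        raise ValueError("gwas table must be nonempty")
    rng = stage_rng(config.seed, "annotations")
    causal = snps["snp"].isin(truth.causal_snps).to_numpy()
    base_odds = config.annot_base_rate / (1.0 - config.annot_base_rate)
    odds = np.where(causal, base_odds * config.annot_enrichment, base_odds)
    prob = odds / (1.0 + odds)
    flags = pd.DataFrame({"snp": snps["snp"]})
    for cell_type in config.cell_types:
        flags[cell_type] = (rng.random(len(snps)) < prob).astype(int)

    coords = gene_coordinates(_gene_symbols(config.n_genes))
    pos = snps["pos"].to_numpy()
    eqtl_rows = []
    for row in coords.itertuples():
        inside = snps["snp"].to_numpy()[(pos >= row.start) & (pos <= row.end)]
        if len(inside) == 0:
            continue
        is_module = row.gene in truth.module_genes
        n_esnp = min(len(inside), int(rng.poisson(3.0 if is_module else 1.0)) + 1)
        chosen = rng.choice(inside, size=n_esnp, replace=False)
        for snp_id in sorted(chosen):
            eqtl_rows.append((snp_id, row.gene, float(rng.normal(3.0 if is_module else 0.0, 1.0)), 1.0, "synthetic_tissue"))
    eqtl = pd.DataFrame(eqtl_rows, columns=["snp", "gene", "z", "V", "tissue"])
    return flags, eqtl


def simulate_comorbidity(
    genes: list[str], truth: GroundTruth, config: SimConfig
) -> tuple[list, dict[str, Counter]]:
    """Comorbid-disease gene sets with RR metadata, plus a symptom corpus.

    Each disease draws a Binomial(size, shared_gene_rate) share of its
    members from module/effect genes and the rest uniformly from the
    remainder; symptom vectors overlap the focal disease's vector in the
    same proportion.
    """
    from .comorbidity import ComorbidDisease  # local import to avoid cycle

    config.validate()
    if not genes:
        raise ValueError("gene list must be nonempty")
    rng = stage_rng(config.seed, "comorbidity")
    module_pool = sorted((truth.module_genes | truth.effect_genes) & set(genes))
    other_pool = sorted(set(genes) - set(module_pool))
    vocab = [f"SYMPTOM{i:03d}" for i in range(200)]
    focal_terms = list(rng.choice(vocab, size=30, replace=False))

    diseases = []
    corpus: dict[str, Counter] = {"FOCAL": Counter({t: int(rng.integers(1, 4)) for t in focal_terms})}
    for d in range(config.n_comorbid_diseases):
        size = int(rng.poisson(25)) + 5
        n_shared = rng.binomial(size, config.shared_gene_rate) if module_pool else 0
        n_shared = min(n_shared, len(module_pool))
        members = set(rng.choice(module_pool, size=n_shared, replace=False)) if n_shared else set()
        n_other = min(size - n_shared, len(other_pool))
        if n_other:
            members |= set(rng.choice(other_pool, size=n_other, replace=False))
        rr = float(rng.uniform(1.0, 2.5))
        ci_low = max(0.5, rr - float(rng.uniform(0.1, 0.6)))
        name = f"DISEASE{d + 1:02d}"
        diseases.append(ComorbidDisease(name=name, genes=members, rr=rr, rr_ci_low=ci_low))

        n_terms = 15
        n_focal = rng.binomial(n_terms, config.shared_gene_rate)
        terms = list(rng.choice(focal_terms, size=min(n_focal, len(focal_terms)), replace=False))
        terms += list(rng.choice(vocab, size=n_terms - len(terms), replace=False))
        corpus[name] = Counter()
        for t in terms:
            corpus[name][t] += int(rng.integers(1, 4))
    return diseases, corpus


# ---------------------------------------------------------------------------
# File export (TSV / GMT / JSON), used by the CLI `simulate` subcommand
# ---------------------------------------------------------------------------

def write_study(out_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate the full study and write every artifact as plain text."""
    from . import network as netmod
    from ._util import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = simulate_interactome(config)
    counts = simulate_expression(net, truth, config)
    coords = gene_coordinates(sorted(net.nodes))
    snps, ld = simulate_gwas(coords, truth, config)
    flags, eqtl = simulate_annotations(snps, truth, config)
    diseases, corpus = simulate_comorbidity(sorted(net.nodes), truth, config)

    paths = {}
    paths["network"] = out / "interactome.tsv"
    netmod.write_edge_list(net, paths["network"])
    paths["counts"] = out / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    paths["genes"] = out / "genes.tsv"
    coords.to_csv(paths["genes"], sep="\t", index=False)
    paths["gwas"] = out / "gwas.tsv"
    snps[["snp", "chrom", "pos", "p"]].to_csv(paths["gwas"], sep="\t", index=False)
    paths["ld"] = out / "ld.tsv"
    ld.to_csv(paths["ld"], sep="\t", index=False)
    paths["annotations"] = out / "annotations.tsv"
    flags.to_csv(paths["annotations"], sep="\t", index=False)
    paths["eqtl"] = out / "eqtl.tsv"
    eqtl.to_csv(paths["eqtl"], sep="\t", index=False)
    paths["comorbid"] = out / "comorbid.gmt"
    write_gmt(
        {d.name: (f"RR={d.rr:.3f};CI_LOW={d.rr_ci_low:.3f}", sorted(d.genes)) for d in diseases},
        paths["comorbid"],
    )
    paths["symptoms"] = out / "symptoms.tsv"
    with open(paths["symptoms"], "w") as fh:
        for disease in sorted(corpus):
            for term, count in sorted(corpus[disease].items()):
                fh.write(f"{disease}\t{term}\t{count}\n")
    paths["truth"] = out / "ground_truth.json"
    truth.to_json(paths["truth"])
    return paths
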