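"""End-to-end orchestration of the synthetic integrated study.

Stages run in the fixed order of the study design: simulate the physical
interactome and cohort, build the co-expression network and merge, test
differential expression, discover modules by both methods, gate them into
signatures, and evaluate topology, GWAS/eQTL enrichment and comorbidity.
The report echoes every threshold actually applied, all RNG seeds, and
per-stage wall-clock, and is valid JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import stage_rng
from .comorbidity import comorbid_gene_enrichment, filter_comorbid, tfidf_similarity
from .config import DiscoveryParams, SimConfig
from .coexpression import build_mi_network
from .dge import gene_stats_table, select_deg
from .discovery import combine_signatures, diamond_run, recursive_search
from .gwas import (
    GENOME_WIDE_SIGNIFICANCE,
    aggregate_gene_p,
    bin_snps_to_genes,
    lambda_gc,
    monte_carlo_snp_enrichment,
    perfect_ld_expand,
    qq_fraction_comparison,
    sherlock_gene_score,
)
from .network import merge_networks, power_law_fit, write_edge_list
from .synthetic import (
    GroundTruth,
    gene_coordinates,
    sample_groups,
    simulate_annotations,
    simulate_comorbidity,
    simulate_expression,
    simulate_gwas,
    simulate_interactome,
)
from .topology import module_size_zscore, separation_ds

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """In-memory artifacts of a full synthetic-study run."""

    config: SimConfig
    params: DiscoveryParams
    physical: object = None
    coexpr: object = None
    merged: object = None
    truth: GroundTruth | None = None
    counts: pd.DataFrame | None = None
    stats_table: pd.DataFrame | None = None
    deg: set = field(default_factory=set)
    diamond: list = field(default_factory=list)
    hsn1: list = field(default_factory=list)
    hsn2: list = field(default_factory=list)
    signatures: object = None
    report: dict = field(default_factory=dict)


def discover_signatures(result: StudyResult) -> StudyResult:
    """Stages up to the signature set: networks, DGE, both discovery methods."""
    cfg, params = result.config, result.params
    timings = result.report.setdefault("wall_clock_s", {})

    t0 = time.perf_counter()
    result.physical, result.truth = simulate_interactome(cfg)
    timings["simulate_interactome"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    result.counts = simulate_expression(result.physical, result.truth, cfg)
    timings["simulate_expression"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    result.coexpr = build_mi_network(result.counts, threshold=params.mi_threshold)
    result.merged = merge_networks(result.physical, result.coexpr)
    timings["coexpression_and_merge"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    groups = sample_groups(result.counts)
    result.stats_table = gene_stats_table(
        result.counts, groups, alpha=params.dge_alpha, lfc_threshold=params.dge_lfc_threshold
    )
    result.deg, deg_summary = select_deg(
        result.stats_table, alpha=params.dge_alpha, lfc_threshold=params.dge_lfc_threshold
    )
    timings["dge"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    result.diamond = diamond_run(result.merged, result.truth.seed_genes, n_iter=params.diamond_iterations)
    timings["diamond"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    gene_p = dict(zip(result.stats_table.index, result.stats_table["p"]))
    sa_rng = stage_rng(cfg.seed, "discovery")
    result.hsn1, result.hsn2 = recursive_search(
        result.merged,
        gene_p,
        seed=sa_rng,
        start_temp=params.sa_start_temp,
        end_temp=params.sa_end_temp,
        iterations=params.sa_iterations,
        n_modules=params.n_modules,
        overlap_threshold=params.overlap_threshold,
    )
    timings["jactivemodules"] = round(time.perf_counter() - t0, 3)

    hsn2_genes = set().union(*(m.genes for m in result.hsn2)) if result.hsn2 else set()
    result.signatures = combine_signatures([d.gene for d in result.diamond], hsn2_genes, result.deg)

    truth = result.truth
    sig_genes = result.signatures.genes
    tp = len(sig_genes & truth.module_genes)
    precision = tp / len(sig_genes) if sig_genes else 0.0
    recall = tp / len(truth.module_genes)
    result.report.update(
        {
            "software_version": __version__,
            "config": cfg.to_dict(),
            "params": params.to_dict(),
            "thresholds": {
                "dge_alpha": params.dge_alpha,
                "dge_lfc_threshold": params.dge_lfc_threshold,
                "mi_threshold": params.mi_threshold,
                "ld_r2_threshold": 0.8,
                "genome_wide_significance": GENOME_WIDE_SIGNIFICANCE,
                "comorbid_rr_min": 1.5,
            },
            "network": {
                "physical_nodes": result.physical.n_nodes(),
                "physical_edges": result.physical.n_edges(),
                "coexpression_edges": result.coexpr.n_edges(),
                "merged_edges": result.merged.n_edges(),
            },
            "dge": {
                "n_significant": len(result.deg),
                "n_up": deg_summary.n_up,
                "n_down": deg_summary.n_down,
                "median_lfc_up": deg_summary.median_lfc_up,
                "median_lfc_down": deg_summary.median_lfc_down,
            },
            "signatures": {
                **result.signatures.counts(),
                "precision_vs_module": precision,
                "recall_vs_module": recall,
            },
        }
    )
    return result


def run_all(config: SimConfig, params: DiscoveryParams | None = None, out_dir: str | Path | None = None) -> StudyResult:
    """Full study: signatures plus topology, GWAS/eQTL and comorbidity layers."""
    params = params or DiscoveryParams()
    result = StudyResult(config=config.validate(), params=params)
    discover_signatures(result)
    cfg = config
    timings = result.report["wall_clock_s"]
    truth = result.truth
    sig_genes = result.signatures.genes

    # --- topology of the recovered module -------------------------------
    t0 = time.perf_counter()
    module_like = sig_genes | truth.seed_genes
    topo = module_size_zscore(
        result.merged, module_like, n_rand=params.n_rand_topology, seed=stage_rng(cfg.seed, "topology")
    )
    ds = separation_ds(result.merged, module_like) if len(module_like) >= 2 else float("nan")
    timings["topology"] = round(time.perf_counter() - t0, 3)
    result.report["topology"] = {**topo.to_dict(), "ds": ds,
                                 "relative_size_pct": 100.0 * topo.relative_size}

    # --- GWAS layer -----------------------------------------------------
    t0 = time.perf_counter()
    coords = gene_coordinates(sorted(result.physical.nodes))
    snps, ld = simulate_gwas(coords, truth, cfg)
    flags, eqtl = simulate_annotations(snps, truth, cfg)
    lam = lambda_gc(snps["p"])
    bins = bin_snps_to_genes(snps, coords, ld, r2_threshold=0.8)
    gene_p_gwas = aggregate_gene_p(bins)
    qq = qq_fraction_comparison(
        gene_p_gwas,
        {"signatures": sig_genes & set(gene_p_gwas)},
        n_controls=params.n_control_sets,
        seed=stage_rng(cfg.seed, "enrichment"),
    ) if sig_genes & set(gene_p_gwas) else None

    sig_bins = [b for b in bins if b.gene in sig_genes]
    sig_snps = set().union(*(b.snps for b in sig_bins)) if sig_bins else set()
    sig_snps = perfect_ld_expand(sig_snps, ld) & set(snps["snp"])
    mc = (
        monte_carlo_snp_enrichment(
            sig_snps, snps, flags, n_rand=params.n_rand_mc, seed=stage_rng(cfg.seed, "enrichment")
        )
        if sig_snps
        else None
    )
    z_pool = snps["z"].to_numpy()
    gwas_z = snps.set_index("snp")["z"]
    sherlock = {}
    for gene in sorted(sig_genes):
        sub = eqtl[eqtl["gene"] == gene]
        if len(sub) == 0:
            continue
        sub = sub.assign(z=gwas_z.reindex(sub["snp"]).fillna(0.0).to_numpy())
        score = sherlock_gene_score(
            gene, sub, z_pool, n_perm=max(100, min(1000, params.n_rand_mc)),
            seed=stage_rng(cfg.seed, "enrichment"),
        )
        if score is not None:
            sherlock[gene] = {"total_lbf": score.total_lbf, "p": score.p}
    timings["gwas_integration"] = round(time.perf_counter() - t0, 3)
    result.report["gwas"] = {
        "n_snps": len(snps),
        "lambda_gc": lam,
        "n_gene_bins": len(bins),
        "n_signature_snps": len(sig_snps),
        "qq_fraction": qq,
        "monte_carlo": None if mc is None else {
            "observed": mc.observed, "null_mean": mc.null_mean,
            "null_sd": mc.null_sd, "p": mc.p, "n_rand": mc.n_rand,
        },
        "sherlock_n_significant": sum(1 for v in sherlock.values() if v["p"] < 0.05),
        "sherlock_n_scored": len(sherlock),
    }

    # --- comorbidity ----------------------------------------------------
    t0 = time.perf_counter()
    diseases, corpus = simulate_comorbidity(sorted(result.physical.nodes), truth, cfg)
    kept = filter_comorbid(diseases)
    universe = set(result.physical.nodes)
    enrich = {}
    for d in kept:
        overlap, odds, p = comorbid_gene_enrichment(sig_genes & universe, d, universe)
        enrich[d.name] = {"rr": d.rr, "overlap": overlap, "odds_ratio": odds, "p": p}
    sim = tfidf_similarity(corpus)
    timings["comorbidity"] = round(time.perf_counter() - t0, 3)
    result.report["comorbidity"] = {
        "n_diseases": len(diseases),
        "n_pass_rr_filter": len(kept),
        "n_enriched_p05": sum(1 for v in enrich.values() if v["p"] < 0.05),
        "enrichment": enrich,
        "focal_symptom_similarity": {
            d: float(sim.loc["FOCAL", d]) for d in sim.columns if d != "FOCAL"
        },
    }

    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: StudyResult, out: Path) -> None:
    from .discovery import signature_table

    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(result.merged, out / "merged_network.tsv")
    result.stats_table.to_csv(out / "gene_stats.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        [{"gene": d.gene, "rank": d.rank, "k": d.k, "ks": d.ks, "p": d.p} for d in result.diamond]
    ).to_csv(out / "diamond.tsv", sep="\t", index=False)
    signature_table(result.signatures, result.stats_table).to_csv(
        out / "signatures.tsv", sep="\t", index_label="gene"
    )
    result.truth.to_json(out / "ground_truth.json")
    (out / "report.json").write_text(json.dumps(result.report, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
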