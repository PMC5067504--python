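"""SNP binning, gene-level p, inflation, enrichment and sherlock-lite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t2di.errors import ValidationError
from t2di.gwas import (
    GeneBin,
    bin_snps_to_genes,
    canonicalize_ld,
    fisher_enrichment,
    gene_p_sidak,
    lambda_gc,
    monte_carlo_snp_enrichment,
    perfect_ld_expand,
    qq_fraction_comparison,
    sherlock_gene_score,
    sherlock_lbf,
)


def snp_table(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])


class TestBinning:
    @pytest.fixture
    def toy(self):
        snps = snp_table([
            ("rs1", "chr1", 150, 0.5),
            ("rs2", "chr1", 950, 0.01),
            ("rs3", "chr1", 1500, 0.2),
            ("rs4", "chr2", 150, 0.9),
        ])
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [100, 1400], "end": [200, 1600],
            "gene": ["GA", "GB"],
        })
        return snps, genes

    def test_positional_binning(self, toy):
        snps, genes = toy
        bins = {b.gene: b for b in bin_snps_to_genes(snps, genes)}
        assert bins["GA"].snps == frozenset({"rs1"})
        assert bins["GB"].snps == frozenset({"rs3"})

    def test_ld_hop_binning(self, toy):
        snps, genes = toy
        ld = pd.DataFrame({"snp1": ["rs2"], "snp2": ["rs1"], "r2": [1.0], "dprime": [1.0]})
        bins = {b.gene: b for b in bin_snps_to_genes(snps, genes, ld)}
        assert bins["GA"].snps == frozenset({"rs1", "rs2"})
        assert bins["GA"].p_min == 0.01

    def test_below_threshold_not_binned(self, toy):
        snps, genes = toy
        ld = pd.DataFrame({"snp1": ["rs2"], "snp2": ["rs1"], "r2": [0.79], "dprime": [1.0]})
        bins = {b.gene: b for b in bin_snps_to_genes(snps, genes, ld)}
        assert bins["GA"].snps == frozenset({"rs1"})

    def test_invalid_interval(self, toy):
        snps, _ = toy
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [100], "gene": ["BAD"]})
        with pytest.raises(ValidationError):
            bin_snps_to_genes(snps, genes)

    def test_matches_per_pair_rule_oracle(self, rng):
        # synthetic chromosome: 5 genes, 40 SNPs, block LD
        genes = pd.DataFrame({
            "chrom": "chr1",
            "start": 1 + np.arange(5) * 4000,
            "end": 1 + np.arange(5) * 4000 + 1999,
            "gene": [f"G{i}" for i in range(5)],
        })
        pos = np.sort(rng.integers(1, 20_000, size=40))
        snps = snp_table([(f"rs{i}", "chr1", int(p), float(rng.uniform(0.001, 1)))
                          for i, p in enumerate(pos)])
        rows = []
        for b in range(0, 40, 5):
            ids = [f"rs{i}" for i in range(b, min(b + 5, 40))]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    rows.append((ids[i], ids[j], float(rng.uniform(0.5, 1.0)), 1.0))
        ld = pd.DataFrame(rows, columns=["snp1", "snp2", "r2", "dprime"])

        got = {b.gene: set(b.snps) for b in bin_snps_to_genes(snps, genes, ld, r2_threshold=0.8)}

        # oracle: literal rule per SNP x gene pair
        ld_r2 = {}
        for r in ld.itertuples():
            ld_r2[(r.snp1, r.snp2)] = r.r2
            ld_r2[(r.snp2, r.snp1)] = r.r2
        expected: dict[str, set] = {}
        for srow in snps.itertuples():
            for grow in genes.itertuples():
                inside = grow.start <= srow.pos <= grow.end
                via_ld = any(
                    ld_r2.get((srow.snp, t.snp), 0) >= 0.8
                    and grow.start <= t.pos <= grow.end
                    for t in snps.itertuples()
                )
                if inside or via_ld:
                    expected.setdefault(grow.gene, set()).add(srow.snp)
        assert got == expected

    def test_removing_ld_pair_never_adds_snps(self, toy):
        snps, genes = toy
        ld = pd.DataFrame({"snp1": ["rs2", "rs3"], "snp2": ["rs1", "rs2"],
                           "r2": [0.9, 0.85], "dprime": [1.0, 1.0]})
        full = {b.gene: set(b.snps) for b in bin_snps_to_genes(snps, genes, ld)}
        reduced = {b.gene: set(b.snps) for b in bin_snps_to_genes(snps, genes, ld.iloc[:1])}
        for gene, members in reduced.items():
            assert members <= full[gene]


class TestGenePSidak:
    def test_single_snp_identity(self):
        assert gene_p_sidak(GeneBin("G", frozenset({"a"}), 1, 0.03)) == pytest.approx(0.03)

    def test_closed_form(self):
        assert gene_p_sidak(GeneBin("G", frozenset(), 10, 0.01)) == pytest.approx(0.095618, abs=1e-6)

    def test_zero_p(self):
        assert gene_p_sidak(GeneBin("G", frozenset(), 5, 0.0)) == 0.0

    def test_monotone_in_m_and_p(self):
        ps = [gene_p_sidak(GeneBin("G", frozenset(), m, 0.01)) for m in (1, 2, 5, 20)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        qs = [gene_p_sidak(GeneBin("G", frozenset(), 5, p)) for p in (0.001, 0.01, 0.1)]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestLambdaGc:
    def test_all_half_is_one(self):
        assert lambda_gc([0.5] * 101) == pytest.approx(1.0, abs=1e-9)

    def test_doubled_chi2_doubles_lambda(self, rng):
        p = rng.uniform(0.001, 1, size=10_001)
        chi2 = stats.chi2.isf(p, df=1)
        p_doubled = stats.chi2.sf(2 * chi2, df=1)
        assert lambda_gc(p_doubled) == pytest.approx(2 * lambda_gc(p), rel=1e-9)

    def test_uniform_null_near_one(self, rng):
        p = rng.uniform(size=100_000)
        assert 0.98 <= lambda_gc(p) <= 1.02

    def test_rejects_bad_input(self):
        with pytest.raises(ValidationError):
            lambda_gc([])
        with pytest.raises(ValidationError):
            lambda_gc([0.0, 0.5])


class TestQqFraction:
    def test_control_set_count_and_shape(self, rng):
        gene_p = {f"G{i}": float(p) for i, p in enumerate(rng.uniform(size=500))}
        res = qq_fraction_comparison(gene_p, {"q": set(list(gene_p)[:50])}, n_controls=100, seed=1)
        assert res["n_controls"] == 100
        assert len(res["sets"]["q"]["fraction"]) == len(res["grid"])

    def test_top_genes_exceed_control_band(self, rng):
        gene_p = {f"G{i}": float(p) for i, p in enumerate(rng.uniform(size=1000))}
        top = set(sorted(gene_p, key=gene_p.get)[:100])
        res = qq_fraction_comparison(gene_p, {"top": top}, n_controls=100, seed=2)
        grid = np.array(res["grid"])
        i = int(np.argmin(np.abs(grid - 0.05)))
        s = res["sets"]["top"]
        assert s["fraction"][i] > s["control_mean"][i] + s["control_sd"][i]

    def test_empty_query_rejected(self, rng):
        gene_p = {"G1": 0.5}
        with pytest.raises(ValidationError):
            qq_fraction_comparison(gene_p, {"q": {"MISSING"}}, seed=0)


class TestFisher:
    def test_hand_enumeration(self):
        odds, p = fisher_enrichment(4, 1, 1, 4)
        assert p == pytest.approx(26 / 252, rel=1e-9)
        assert odds == pytest.approx(16.0)

    def test_zero_overlap_p_one(self):
        _, p = fisher_enrichment(0, 5, 5, 10)
        assert p == pytest.approx(1.0)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_enrichment(a, b, c, d)[1] == pytest.approx(
                fisher_enrichment(a, c, b, d)[1], rel=1e-9
            )

    def test_matches_scipy(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b + c + d == 0:
                continue
            expected = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert fisher_enrichment(a, b, c, d)[1] == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment(-1, 2, 3, 4)


class TestMonteCarloEnrichment:
    @pytest.fixture
    def background(self, rng):
        snps = snp_table([(f"rs{i}", "chr1", i * 10, 0.5) for i in range(400)])
        flags = pd.Series(0, index=[f"rs{i}" for i in range(400)])
        flags.iloc[:60] = 1
        return snps, flags

    def test_all_flagged_p_one(self):
        snps = snp_table([(f"rs{i}", "chr1", i, 0.5) for i in range(50)])
        flags = pd.Series(1, index=[f"rs{i}" for i in range(50)])
        res = monte_carlo_snp_enrichment([f"rs{i}" for i in range(10)], snps, flags,
                                         n_rand=500, seed=1)
        assert res.observed == 10
        assert res.p == 1.0

    def test_matches_explicit_permutation(self, background, rng):
        snps, flags = background
        query = [f"rs{i}" for i in range(0, 40)]  # all flagged -> observed 40
        res = monte_carlo_snp_enrichment(query, snps, flags, n_rand=20_000, seed=3)
        # explicit permutation oracle
        r = np.random.default_rng(9)
        flag_arr = flags.to_numpy()
        null = np.array([
            flag_arr[r.choice(400, size=40, replace=False)].sum() for _ in range(20_000)
        ])
        assert res.null_mean == pytest.approx(null.mean(), abs=0.05)
        assert res.null_sd == pytest.approx(null.std(ddof=1), rel=0.05)
        assert res.observed == 40

    def test_query_outside_background_rejected(self, background):
        snps, flags = background
        with pytest.raises(ValidationError):
            monte_carlo_snp_enrichment(["nope"], snps, flags, n_rand=200, seed=1)

    def test_plus_one_floor(self, background):
        snps, flags = background
        query = [f"rs{i}" for i in range(0, 60)]  # every flagged SNP
        res = monte_carlo_snp_enrichment(query, snps, flags, n_rand=1000, seed=2)
        assert res.p == pytest.approx(1 / 1001)


class TestPerfectLd:
    def test_chain_transitivity(self):
        ld = pd.DataFrame({"snp1": ["s1", "s2"], "snp2": ["s2", "s3"],
                           "r2": [1.0, 1.0], "dprime": [1.0, 1.0]})
        assert perfect_ld_expand({"s1"}, ld) == {"s1", "s2", "s3"}

    def test_requires_both_conditions(self):
        ld = pd.DataFrame({"snp1": ["s1"], "snp2": ["s2"], "r2": [1.0], "dprime": [0.99]})
        assert perfect_ld_expand({"s1"}, ld) == {"s1"}

    def test_matches_component_oracle(self, rng):
        import networkx as nx

        for seed in range(20):
            r = np.random.default_rng(seed)
            rows = []
            for _ in range(30):
                i, j = r.choice(20, size=2, replace=False)
                perfect = r.random() < 0.5
                rows.append((f"s{i}", f"s{j}", 1.0 if perfect else 0.9, 1.0 if perfect else 1.0))
            ld = pd.DataFrame(rows, columns=["snp1", "snp2", "r2", "dprime"])
            query = {f"s{i}" for i in r.choice(20, size=4, replace=False)}
            got = perfect_ld_expand(query, ld)
            g = nx.Graph()
            g.add_nodes_from(f"s{i}" for i in range(20))
            perfect_rows = ld[(ld.r2 == 1.0) & (ld.dprime == 1.0)]
            g.add_edges_from(zip(perfect_rows.snp1, perfect_rows.snp2))
            expected = set(query)
            for comp in nx.connected_components(g):
                if comp & query:
                    expected |= comp
            assert got == expected


class TestSherlock:
    def test_zero_prior_zero_lbf(self):
        assert sherlock_lbf(3.0, 1.0, W=0.0) == 0.0

    def test_closed_forms(self):
        assert sherlock_lbf(0.0, 1.0, W=1.0) == pytest.approx(-0.34657, abs=1e-5)
        assert sherlock_lbf(5.0, 1.0, W=1.0) == pytest.approx(5.9034, abs=1e-4)

    def test_invalid_variance(self):
        with pytest.raises(ValidationError):
            sherlock_lbf(1.0, 0.0, W=1.0)

    def test_single_esnp_total(self, rng):
        esnps = pd.DataFrame({"snp": ["rs1"], "z": [2.5], "V": [1.0]})
        score = sherlock_gene_score("G", esnps, z_pool=rng.normal(size=1000),
                                    W=0.5, n_perm=200, seed=1)
        assert score.total_lbf == pytest.approx(sherlock_lbf(2.5, 1.0, 0.5))

    def test_empty_esnps_skipped(self, rng):
        empty = pd.DataFrame(columns=["snp", "z", "V"])
        assert sherlock_gene_score("G", empty, z_pool=rng.normal(size=100)) is None

    def test_signal_gene_detected(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            z_pool = np.concatenate([r.normal(size=900), r.normal(5.0, 1.0, size=100)])
            esnps = pd.DataFrame({"snp": [f"rs{i}" for i in range(5)],
                                  "z": r.normal(5.0, 1.0, size=5), "V": 1.0})
            score = sherlock_gene_score("G", esnps, z_pool, W=1.0, n_perm=500, seed=seed)
            hits += score.p < 0.05
        assert hits >= 8


class TestCanonicalizeLd:
    def test_sorted_and_deduplicated(self):
        ld = pd.DataFrame({"snp1": ["b", "a", "a"], "snp2": ["a", "b", "a"],
                           "r2": [0.5, 0.9, 1.0], "dprime": [1.0, 1.0, 1.0]})
        out = canonicalize_ld(ld)
        assert len(out) == 1
        assert out.iloc[0]["snp1"] == "a" and out.iloc[0]["snp2"] == "b"
        assert out.iloc[0]["r2"] == 0.9
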