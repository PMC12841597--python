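import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from conftest import make_assoc_table
from panepiclock import age_stats
from panepiclock.gene_matrix import GeneMatrix


def stratum_matrix(values, ages, species="human", layer="DNAm"):
    values = pd.DataFrame(values)
    n = len(values)
    values.index = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    samples = pd.DataFrame({
        "sample_id": values.index, "donor_id": [f"d{i}" for i in range(n)],
        "species": species, "tissue": "liver", "layer": layer, "dataset": "ds1",
        "age_years": ages, "diet": "standard",
    })
    return GeneMatrix(values, samples)


class TestAgeAssociation:
    def test_perfect_monotone_gene(self):
        ages = np.arange(10, 20, dtype=float)
        m = stratum_matrix({"up": ages * 2, "down": -ages}, ages)
        table = age_stats.age_association(m)
        assert table.loc["up", "rho"] == pytest.approx(1.0)
        assert table.loc["down", "rho"] == pytest.approx(-1.0)
        assert (table["p"] > 0).all()

    def test_t_model_pvalue_matches_quadrature(self):
        """rho=0.5, n=20 -> t=2.4495; two-sided p from numerically
        integrating the t density (independent oracle) ~= 0.0249."""
        p = float(age_stats.spearman_t_pvalue(0.5, 20))
        t_obs = 0.5 * np.sqrt(18 / (1 - 0.25))
        assert t_obs == pytest.approx(2.4495, abs=1e-4)
        density = stats.t(df=18).pdf
        tail, _ = integrate.quad(density, t_obs, np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-8)
        assert p == pytest.approx(0.0249, abs=5e-4)

    def test_constant_gene_flagged(self):
        ages = np.arange(4, 14, dtype=float)
        m = stratum_matrix({"flat": np.ones(10), "ok": ages}, ages)
        table = age_stats.age_association(m)
        assert table.loc["flat", "rho"] == 0.0
        assert table.loc["flat", "p"] == 1.0
        assert bool(table.loc["flat", "constant"])

    def test_minimum_samples_enforced(self):
        ages = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 4"):
            age_stats.age_association(stratum_matrix({"g": ages}, ages))

    def test_permuted_ages_null_calibration(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(100, 200))
        ages = rng.permutation(np.linspace(20, 80, 100))
        table = age_stats.age_association(stratum_matrix(values, ages))
        assert age_stats.significant_fraction(table, 0.05) < 0.02


class TestAssocVectorCorrelation:
    def test_self_and_negated(self):
        rng = np.random.default_rng(1)
        t = make_assoc_table(rng.uniform(-1, 1, 200))
        rho, p = age_stats.assoc_vector_correlation(t, t)
        assert rho == pytest.approx(1.0)
        neg = t.copy()
        neg["rho"] = -neg["rho"]
        rho, _ = age_stats.assoc_vector_correlation(t, neg)
        assert rho == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            a = make_assoc_table(rng.normal(size=1000))
            b = make_assoc_table(rng.normal(size=1000))
            rho, _ = age_stats.assoc_vector_correlation(a, b)
            hits += abs(rho) < 0.1
        assert hits >= 18


class TestTopKOverlap:
    def test_identical_rankings_printed_constants(self):
        # with k=1000 over the G=17,602-gene universe: expected 56.81, fold 17.60
        rng = np.random.default_rng(3)
        rho = rng.normal(size=17602)
        t = make_assoc_table(rho)
        res = age_stats.top_k_overlap_enrichment(t, t, k=1000)
        assert res.observed == 1000
        assert res.expected == pytest.approx(1000**2 / 17602)
        assert res.expected == pytest.approx(56.81, abs=0.01)
        assert res.fold == pytest.approx(res.observed / res.expected)
        assert res.fold == pytest.approx(17.60, abs=0.01)

    def test_disjoint_top_sets(self):
        # first 60 genes strongest in A, a disjoint 60 strongest in B
        rho_a = np.concatenate([np.linspace(0.9, 0.8, 60), np.zeros(240)])
        rho_b = np.concatenate([np.zeros(60), np.linspace(0.9, 0.8, 60), np.zeros(180)])
        a, b = make_assoc_table(rho_a), make_assoc_table(rho_b)
        res = age_stats.top_k_overlap_enrichment(a, b, k=60)
        assert res.observed == 0 and res.fold == 0.0
        expected_p = stats.binomtest(0, 60, 60 / 300, alternative="two-sided").pvalue
        assert res.p == pytest.approx(expected_p)

    def test_universe_must_exceed_k(self):
        t = make_assoc_table(np.arange(10) / 10)
        with pytest.raises(ValueError, match="exceed"):
            age_stats.top_k_overlap_enrichment(t, t, k=10)

    def test_ranking_uses_unsigned_magnitude(self):
        rho_a = np.array([-0.9, 0.1, 0.2, 0.05, -0.5, 0.0])
        rho_b = np.array([0.9, 0.1, 0.2, 0.05, 0.5, 0.0])
        a, b = make_assoc_table(rho_a), make_assoc_table(rho_b)
        res = age_stats.top_k_overlap_enrichment(a, b, k=2)
        assert res.observed == 2  # genes 0 and 4 in both despite opposite signs


class TestExactSmallSampleOracles:
    """Statistical primitives vs brute-force enumeration on small instances."""

    @pytest.mark.parametrize("n1,n2,seed", [(3, 4, 0), (5, 5, 1), (8, 6, 2), (8, 8, 3)])
    def test_mwu_matches_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct -> exact method
        x, y = pooled[:n1], pooled[n1:]
        expected = self._mwu_brute(x, y)
        got = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(expected, rel=1e-10)

    @staticmethod
    def _mwu_brute(x, y):
        pooled = np.concatenate([x, y])
        n1 = len(x)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = np.asarray([ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                         for idx in itertools.combinations(range(len(pooled)), n1)])
        p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
        return min(1.0, p)

    @pytest.mark.parametrize("k,prob", [(5, 0.3), (9, 0.5), (12, 0.08)])
    def test_binomial_two_sided_matches_enumeration(self, k, prob):
        for observed in range(k + 1):
            pmf = np.array([comb(k, i) * prob**i * (1 - prob) ** (k - i)
                            for i in range(k + 1)])
            expected = pmf[pmf <= pmf[observed] * (1 + 1e-12)].sum()
            got = stats.binomtest(observed, k, prob, alternative="two-sided").pvalue
            assert got == pytest.approx(min(1.0, expected), rel=1e-9)

    @pytest.mark.parametrize("G,K,n", [(20, 6, 8), (40, 12, 12), (15, 5, 5)])
    def test_hypergeom_two_sided_matches_enumeration(self, G, K, n):
        for observed in range(max(0, n + K - G), min(n, K) + 1):
            pmf = {i: comb(K, i) * comb(G - K, n - i) / comb(G, n)
                   for i in range(max(0, n + K - G), min(n, K) + 1)}
            expected = sum(v for v in pmf.values() if v <= pmf[observed] * (1 + 1e-12))
            got = age_stats.hypergeom_two_sided(observed, G, K, n)
            assert got == pytest.approx(min(1.0, expected), rel=1e-9)

    def test_bh_matches_step_up_definition(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=37)
        from statsmodels.stats.multitest import multipletests
        q = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        n = len(p)
        expected = np.empty(n)
        running = 1.0
        for rank_from_top in range(n - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * n / (rank_from_top + 1))
            expected[i] = running
        assert q == pytest.approx(expected, rel=1e-12)
        # monotone in p
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCrosstalk:
    def test_self_coupling_positive(self):
        rng = np.random.default_rng(6)
        t = make_assoc_table(rng.normal(size=500))
        res = age_stats.crosstalk(t, t, k=100)
        assert res.median_diff > 0
        assert res.p < 1e-10
        assert res.p_bonf == pytest.approx(min(1.0, res.p * 21))

    def test_sign_flip_negative(self):
        rng = np.random.default_rng(7)
        t = make_assoc_table(rng.normal(size=500))
        neg = t.copy()
        neg["rho"] = -neg["rho"]
        assert age_stats.crosstalk(t, neg, k=100).median_diff < 0

    def test_bonferroni_family_is_21_for_seven_layers(self):
        assert age_stats.N_LAYER_PAIRS == comb(7, 2) == 21


class TestGeneSetOperations:
    def test_significant_fraction_extremes(self):
        t = make_assoc_table(np.linspace(-1, 1, 50))
        t["q"] = 1.0
        assert age_stats.significant_fraction(t) == 0.0
        assert age_stats.significant_fraction(t, q_threshold=1.1) == 1.0

    def test_all_layer_intersection_counts(self):
        base = make_assoc_table(np.linspace(0.5, 0.9, 30))
        sig = base.copy(); sig["q"] = 0.01
        null = base.copy(); null["q"] = 0.99
        counts = age_stats.all_layer_intersection({"a": sig, "b": null})
        assert (counts == 0).all()
        counts = age_stats.all_layer_intersection({"a": sig, "b": sig})
        assert (counts == 30).all()
        rng = np.random.default_rng(8)
        mixed = base.copy(); mixed["q"] = rng.uniform(size=30)
        nested = age_stats.all_layer_intersection({"a": mixed}, fdr_levels=(0.05, 0.1, 0.2))
        assert nested.is_monotonic_increasing

    def test_direction_genesets_shared_ranking(self):
        """All layers sharing one ranking with their canonical signs makes the
        repressed set exactly the top-k of that ranking."""
        rng = np.random.default_rng(9)
        rho = rng.normal(size=300)
        tables = {}
        for layer in ("DNAm", "H3K27me3", "H3K9me3"):
            tables[("human", layer)] = make_assoc_table(rho)
        for layer in ("H3K27ac", "H3K36me3", "H3K4me1", "H3K4me3"):
            tables[("human", layer)] = make_assoc_table(-rho)
        repressed, activated = age_stats.select_direction_genesets(tables, k=50)
        expected_rep = set(make_assoc_table(rho).sort_values("rho", ascending=False).index[:50])
        assert repressed == expected_rep
        assert len(repressed & activated) == 0

    def test_direction_genesets_one_reversed_mark_shrinks(self):
        rng = np.random.default_rng(10)
        rho = rng.normal(size=300)
        tables = {("human", l): make_assoc_table(rho) for l in ("DNAm", "H3K27me3")}
        tables[("human", "H3K9me3")] = make_assoc_table(-rho)  # reversed repressive mark
        repressed, _ = age_stats.select_direction_genesets(tables, k=50)
        assert len(repressed) < 10

    def test_direction_genesets_k_equals_universe(self):
        rho = np.linspace(-1, 1, 40)
        tables = {("human", "DNAm"): make_assoc_table(rho)}
        repressed, activated = age_stats.select_direction_genesets(tables, k=40)
        assert len(repressed) == 40 and len(activated) == 40


class TestGenesetEnrichment:
    def test_exact_hypergeometric_p_for_perfect_overlap(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        table = age_stats.geneset_enrichment(term, {"T": term}, universe)
        assert table.iloc[0]["p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_empty_geneset_gives_empty_table(self):
        universe = {f"g{i}" for i in range(20)}
        table = age_stats.geneset_enrichment(set(), {"T": {"g1", "g2"}}, universe)
        assert len(table) == 0

    def test_single_gene_overlap_excluded(self):
        universe = {f"g{i}" for i in range(50)}
        geneset = {"g0", "g30", "g31"}
        library = {"T1": {"g0", "g40", "g41"},          # overlap 1 -> excluded
                   "T2": {"g30", "g31"}}                 # overlap 2 -> kept if significant
        table = age_stats.geneset_enrichment(geneset, library, universe)
        assert "T1" not in set(table["term"])

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("TermA\tdesc\tg1\tg2\tg3\nTermB\tdesc\tg4\n")
        lib = age_stats.read_gmt(path)
        assert lib["TermA"] == {"g1", "g2", "g3"}
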