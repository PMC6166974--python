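"""TPM, ortholog restriction, TMM normalisation and rank-product
differential expression, each checked against a step-by-step oracle."""

import numpy as np
import pandas as pd
import pytest

import te_regnet as tr


def em(df, tissue=None):
    tissue = tissue or {c: c for c in df.columns}
    return tr.ExpressionMatrix(df, pd.Series(tissue))


class TestTpmFromCounts:
    def test_equal_counts_equal_lengths(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 1000})
        out = tr.tpm_from_counts(counts, lengths)
        np.testing.assert_allclose(out.values["s1"], [5e5, 5e5])

    def test_length_normalisation(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        out = tr.tpm_from_counts(counts, lengths)
        np.testing.assert_allclose(out.values["s1"],
                                   [666666.6667, 333333.3333], rtol=1e-9)

    def test_zero_count_zero_tpm_and_dead_sample(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [0, 0]},
                              index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 500})
        with pytest.raises(ValueError, match="s2"):
            tr.tpm_from_counts(counts, lengths)
        ok = tr.tpm_from_counts(counts[["s1"]], lengths)
        assert ok.values.loc["g1", "s1"] == 0.0


class TestRestrictToOrthologs:
    def test_full_map_only_renormalises(self, toy_expression):
        pairs = [(g, g.replace("g", "m")) for g in toy_expression.gene_ids]
        eb = tr.ExpressionMatrix(
            toy_expression.values.rename(index=dict(pairs)),
            toy_expression.tissue_of_sample)
        ra, rb, kept = tr.restrict_to_orthologs(
            toy_expression, eb, tr.OrthologMap(pairs))
        np.testing.assert_allclose(ra.values, toy_expression.values, rtol=1e-12)
        assert len(kept) == 6

    def test_columns_renormalised_to_tpm(self, toy_expression):
        pairs = [(g, g.replace("g", "m")) for g in list(toy_expression.gene_ids)[:4]]
        eb = tr.ExpressionMatrix(
            toy_expression.values.rename(
                index={a: b for a, b in pairs}).iloc[:4],
            toy_expression.tissue_of_sample)
        ra, rb, _ = tr.restrict_to_orthologs(
            toy_expression, eb, tr.OrthologMap(pairs))
        for mat in (ra, rb):
            np.testing.assert_allclose(mat.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_halving_doubles_retained_tpm(self):
        # symmetric instance: all genes equal, drop half -> each doubles
        df = pd.DataFrame(np.full((8, 2), 100.0),
                          index=[f"g{i}" for i in range(8)],
                          columns=["s1", "s2"])
        df = df / df.sum(axis=0) * 1e6
        ea = em(df)
        pairs = [(f"g{i}", f"m{i}") for i in range(4)]
        eb = em(df.rename(index={f"g{i}": f"m{i}" for i in range(8)}))
        ra, _, _ = tr.restrict_to_orthologs(ea, eb, tr.OrthologMap(pairs))
        np.testing.assert_allclose(ra.values.to_numpy(),
                                   2 * df.iloc[:4].to_numpy(), rtol=1e-12)

    def test_empty_intersection_errors(self, toy_expression):
        with pytest.raises(ValueError, match="no ortholog pair"):
            tr.restrict_to_orthologs(toy_expression, toy_expression,
                                     tr.OrthologMap([("x", "y")]))

    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError, match="1-to-1"):
            tr.OrthologMap([("a", "x"), ("a", "y")])


def manual_tmm(x, ref, trim_m=0.30, trim_a=0.05):
    """Independent scalar re-derivation of the trim-and-weight factor."""
    n_x, n_ref = x.sum(), ref.sum()
    rows = [(np.log2(xi) - np.log2(ri),
             0.5 * (np.log2(xi) + np.log2(ri)),
             (n_x - xi) / (n_x * xi) + (n_ref - ri) / (n_ref * ri))
            for xi, ri in zip(x, ref) if xi > 0 and ri > 0]
    n = len(rows)
    lo_m, lo_a = int(np.floor(n * trim_m)) + 1, int(np.floor(n * trim_a)) + 1
    hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
    ms = sorted(r[0] for r in rows)
    as_ = sorted(r[1] for r in rows)
    num = den = 0.0
    for m, a, v in rows:
        rank_m = ms.index(m) + 1
        rank_a = as_.index(a) + 1
        if lo_m <= rank_m <= hi_m and lo_a <= rank_a <= hi_a:
            num += m / v
            den += 1 / v
    return 2 ** (num / den)


class TestTmmFactors:
    def test_identical_samples_give_unity(self):
        rng = np.random.default_rng(1)
        col = rng.lognormal(3, 1, 200)
        df = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        np.testing.assert_allclose(tr.tmm_factors(df), 1.0, rtol=1e-12)

    def test_pure_scaling_recovered(self):
        rng = np.random.default_rng(2)
        col = rng.lognormal(3, 1, 2000)
        df = pd.DataFrame({"s1": col, "s2": 2 * col})
        f = tr.tmm_factors(df, reference="s1")
        assert f["s2"] / f["s1"] == pytest.approx(2.0, rel=0.01)

    def test_eight_gene_fixture_matches_manual_oracle(self):
        x = np.array([12.0, 55.0, 130.0, 8.0, 300.0, 42.0, 77.0, 260.0])
        ref = np.array([10.0, 50.0, 100.0, 20.0, 310.0, 35.0, 70.0, 150.0])
        df = pd.DataFrame({"ref": ref, "x": x})
        f = tr.tmm_factors(df, reference="ref")
        raw = manual_tmm(x, ref)
        rescaled = np.array([1.0, raw])
        rescaled = rescaled / np.exp(np.mean(np.log(rescaled)))
        np.testing.assert_allclose(f.to_numpy(), rescaled, atol=1e-9)

    def test_gene_order_and_global_scale_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.lognormal(3, 1, (300, 3)),
                          columns=["s1", "s2", "s3"])
        f = tr.tmm_factors(df, reference="s1")
        shuffled = df.sample(frac=1, random_state=0)
        np.testing.assert_allclose(
            tr.tmm_factors(shuffled, reference="s1").to_numpy(),
            f.to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(
            tr.tmm_factors(df * 7.5, reference="s1").to_numpy(),
            f.to_numpy(), rtol=1e-9)

    def test_too_few_surviving_genes_errors(self):
        # only one gene positive in both samples -> nothing to trim against
        df = pd.DataFrame({"s1": [5.0, 2.0, 0.0], "s2": [4.0, 0.0, 3.0]})
        with pytest.raises(ValueError, match="survive trimming"):
            tr.tmm_factors(df, reference="s1")


def rank_table_matrix():
    """5-gene, 3-combination instance with a known per-combination rank
    table {(1,1,1),(2,3,2),(3,2,4),(4,5,3),(5,4,5)} (3 A-samples vs 1 B)."""
    ranks = np.array([[1, 1, 1], [2, 3, 2], [3, 2, 4], [4, 5, 3], [5, 4, 5]])
    a = 2.0 ** (6 - ranks)  # larger value -> better rank
    df = pd.DataFrame(np.column_stack([a, np.ones(5)]),
                      index=[f"g{i}" for i in range(5)],
                      columns=["a1", "a2", "a3", "b1"])
    return df, ranks


class TestRankProduct:
    def test_geometric_mean_of_known_ranks(self):
        df, ranks = rank_table_matrix()
        res = tr.rank_product(df, ["a1", "a2", "a3"], ["b1"], n_perm=10, seed=0)
        expected = np.prod(ranks, axis=1) ** (1 / 3)
        np.testing.assert_allclose(res.table["rank_product"], expected,
                                   rtol=1e-12)

    def test_uniformly_strongest_gene_has_rp_one(self):
        df, _ = rank_table_matrix()
        assert tr.rank_product(df, ["a1", "a2", "a3"], ["b1"],
                               n_perm=10, seed=0).table["rank_product"]["g0"] \
            == pytest.approx(1.0)

    def test_single_combination_pfp_is_analytic(self):
        # with one combination every permutation contributes exactly one
        # gene at each rank, so E[#null <= r] = floor(r) whatever the data:
        # the Monte-Carlo pfp must equal rank/position with cumulative max
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.lognormal(3, 1, 6),
                           "b": rng.lognormal(3, 1, 6)},
                          index=[f"g{i}" for i in range(6)])
        res = tr.rank_product(df, ["a"], ["b"], n_perm=200, seed=1)
        srt = res.table.sort_values("rank_product")
        expected = np.maximum.accumulate(
            np.floor(srt["rank_product"]) / np.arange(1, 7))
        np.testing.assert_allclose(srt["pfp"], expected, rtol=1e-12)

    def test_pfp_monotone_along_rp_order(self, small_bundle):
        expr = small_bundle.expression
        samples = list(expr.sample_ids)
        res = tr.rank_product(expr.values, samples[:1], samples[1:3],
                              n_perm=20, seed=3)
        srt = res.table.sort_values("rank_product")
        assert (np.diff(srt["pfp"]) >= -1e-15).all()

    def test_per_sample_scaling_leaves_ranks_unchanged(self):
        df, _ = rank_table_matrix()
        scaled = df * pd.Series({"a1": 3.0, "a2": 0.5, "a3": 7.0, "b1": 2.0})
        r1 = tr.rank_product(df, ["a1", "a2", "a3"], ["b1"], n_perm=10, seed=0)
        r2 = tr.rank_product(scaled, ["a1", "a2", "a3"], ["b1"], n_perm=10, seed=0)
        np.testing.assert_allclose(r1.table["rank_product"],
                                   r2.table["rank_product"], rtol=1e-12)

    def test_n_perm_floor(self):
        df, _ = rank_table_matrix()
        with pytest.raises(ValueError, match="n_perm"):
            tr.rank_product(df, ["a1"], ["b1"], n_perm=5)


class TestCallEnriched:
    @staticmethod
    def _result(cid, pfps):
        table = pd.DataFrame({
            "rank_product": np.arange(1, len(pfps) + 1, dtype=float),
            "pfp": pfps}, index=[f"g{i}" for i in range(len(pfps))])
        return tr.RankProductResult(cid, "up", table, 100)

    def test_intersection_semantics(self):
        res = {"c1": self._result("c1", [0.01, 0.01, 0.5]),
               "c2": self._result("c2", [0.01, 0.5, 0.01])}
        assert tr.call_enriched(res, 0.15) == {"g0"}

    def test_fdr_zero_boundary(self):
        res = {"c1": self._result("c1", [0.0, 0.1])}
        assert tr.call_enriched(res, 0.0) == {"g0"}

    def test_missing_comparison_is_named(self):
        res = {"c1": self._result("c1", [0.1])}
        with pytest.raises(ValueError, match="c2"):
            tr.call_enriched(res, 0.15, required=["c1", "c2"])

    def test_planted_genes_recovered_on_bundle(self):
        cfg = tr.SimulationConfig(seed=5, n_genes=600, n_tissues=4,
                                  n_samples_per_tissue=8, te_fraction=0.05,
                                  effect_size=2.0)
        b = tr.simulate_bundle(cfg)
        enriched, results, _ = tr.tissue_enriched_genes(
            b.expression, b.expression_b, tr.OrthologMap(b.ortholog_map),
            "placenta", fdr_cutoff=0.15, n_perm=50, seed=6)
        truth = set(b.truth.loc[b.truth.planted_effect, "gene_id"])
        tp = len(enriched & truth)
        assert tp / len(truth) >= 0.6
        assert tp / max(len(enriched), 1) >= 0.8
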