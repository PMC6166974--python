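"""Relative coexpression: transform, correlation, resampling null and
odds-ratio summary, checked against enumeration and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import te_regnet as tr


class TestSqrtTransform:
    def test_values_and_fixed_point(self, toy_expression):
        zeros = tr.ExpressionMatrix(
            toy_expression.values * 0.0, toy_expression.tissue_of_sample)
        assert (tr.sqrt_transform(zeros).values == 0).all().all()
        out = tr.sqrt_transform(toy_expression)
        np.testing.assert_allclose(out.values**2, toy_expression.values,
                                   rtol=1e-12)

    def test_negative_rejected_with_location(self, toy_expression):
        bad = toy_expression.values.copy()
        bad.iloc[2, 1] = -1.0
        with pytest.raises(ValueError, match="g2"):
            tr.ExpressionMatrix(bad, toy_expression.tissue_of_sample)


class TestTissueCorrelation:
    def test_self_correlation_is_one(self, toy_expression):
        r = tr.tissue_correlation(toy_expression, ["g0", "g1", "g2"],
                                  "placenta", "placenta")
        assert r == pytest.approx(1.0)

    def test_perfect_linearity(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]},
                          index=["g0", "g1", "g2"])
        em = tr.ExpressionMatrix(df, pd.Series({"a": "A", "b": "B"}))
        assert tr.tissue_correlation(em, ["g0", "g1", "g2"], "A", "B") == \
            pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.lognormal(2, 1, (20, 2)),
                          index=[f"g{i}" for i in range(20)],
                          columns=["a", "b"])
        em = tr.ExpressionMatrix(df, pd.Series({"a": "A", "b": "B"}))
        got = tr.tissue_correlation(em, list(em.gene_ids), "A", "B")
        x, y = df["a"].to_numpy(), df["b"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        want = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_errors(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]},
                          index=["g0", "g1", "g2"])
        em = tr.ExpressionMatrix(df, pd.Series({"a": "A", "b": "B"}))
        with pytest.raises(ValueError, match="zero-variance"):
            tr.tissue_correlation(em, ["g0", "g1", "g2"], "A", "B")


def enumeration_oracle(expr, te_genes, min_tpm=0.0):
    """Exhaustively enumerate every size-matched numerator subset of the
    TE-absent pool and rank the observed ratio (add-one rule)."""
    work = tr.sqrt_transform(expr)
    tissues = work.tissues
    pa = work.tissue_profile(tissues[0])
    pb = work.tissue_profile(tissues[1])
    plus = [g for g in work.gene_ids if g in te_genes]
    minus = [g for g in work.gene_ids if g not in te_genes]

    def corr(ids):
        x, y = pa.loc[ids].to_numpy(), pb.loc[ids].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        return (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))

    observed = corr(plus) / corr(minus)
    nulls = []
    for subset in itertools.combinations(minus, len(plus)):
        rest = [g for g in minus if g not in subset]
        nulls.append(corr(list(subset)) / corr(rest))
    p = (1 + sum(1 for v in nulls if v <= observed)) / (len(nulls) + 1)
    return observed, nulls, p


@pytest.fixture()
def coexpr_toy():
    rng = np.random.default_rng(123)
    df = pd.DataFrame(rng.lognormal(3, 0.8, (9, 2)),
                      index=[f"g{i}" for i in range(9)], columns=["a", "b"])
    df = df / df.sum(axis=0) * 1e6
    return tr.ExpressionMatrix(df, pd.Series({"a": "A", "b": "B"}))


class TestRelativeCoexprTest:
    def test_exhaustive_equals_enumeration(self, coexpr_toy):
        te_genes = ["g0", "g1", "g2"]
        (res,) = tr.relative_coexpr_test(coexpr_toy, te_genes,
                                         exhaustive=True, expressed_min_tpm=0)
        obs, nulls, p = enumeration_oracle(coexpr_toy, set(te_genes))
        assert res.ratio == pytest.approx(obs, abs=1e-12)
        assert len(res.null_ratios) == len(nulls)
        assert res.p_empirical == pytest.approx(p, abs=1e-15)

    def test_monte_carlo_approaches_exhaustive(self, coexpr_toy):
        te_genes = ["g0", "g1", "g2"]
        (ex,) = tr.relative_coexpr_test(coexpr_toy, te_genes,
                                        exhaustive=True, expressed_min_tpm=0)
        B = 5000
        (mc,) = tr.relative_coexpr_test(coexpr_toy, te_genes,
                                        n_resamples=B, seed=5,
                                        expressed_min_tpm=0)
        # compare the underlying null proportions (undoing the add-one
        # rule, which biases the two modes differently at tiny null sizes)
        q_ex = np.mean(ex.null_ratios <= ex.ratio)
        q_mc = (mc.p_empirical * (B + 1) - 1) / B
        se = math.sqrt(q_ex * (1 - q_ex) / B)
        assert abs(q_mc - q_ex) <= 3 * se + 2 / B

    def test_determinism_and_seed_sensitivity(self, small_bundle):
        expr, te = small_bundle.expression, small_bundle.truth_genes
        r1 = tr.relative_coexpr_test(expr, te, n_resamples=200, seed=9)
        r2 = tr.relative_coexpr_test(expr, te, n_resamples=200, seed=9)
        r3 = tr.relative_coexpr_test(expr, te, n_resamples=200, seed=10)
        assert [r.p_empirical for r in r1] == [r.p_empirical for r in r2]
        assert [r.p_empirical for r in r1] != [r.p_empirical for r in r3]

    def test_gene_row_order_exchangeability(self, small_bundle):
        expr, te = small_bundle.expression, small_bundle.truth_genes
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr.gene_ids))
        shuffled = tr.ExpressionMatrix(expr.values.iloc[perm],
                                       expr.tissue_of_sample)
        r1 = tr.relative_coexpr_test(expr, te, n_resamples=100, seed=4)
        r2 = tr.relative_coexpr_test(shuffled, te, n_resamples=100, seed=4)
        for a, b in zip(r1, r2):
            assert a.ratio == pytest.approx(b.ratio, rel=1e-12)

    def test_planted_effect_detected_in_focal_pairs(self, small_bundle):
        res = tr.relative_coexpr_test(small_bundle.expression,
                                      small_bundle.truth_genes,
                                      n_resamples=300, seed=2)
        focal = [r for r in res
                 if "placenta" in (r.tissue_a, r.tissue_b)]
        others = [r for r in res
                  if "placenta" not in (r.tissue_a, r.tissue_b)]
        lower = sum(r.direction == "lower" for r in focal)
        assert lower >= len(focal) - 1
        assert np.median([r.p_empirical for r in focal]) < \
            np.median([r.p_empirical for r in others])

    def test_bh_adjustment_optional_and_monotone(self, small_bundle):
        res = tr.relative_coexpr_test(small_bundle.expression,
                                      small_bundle.truth_genes,
                                      n_resamples=100, seed=4, bh_adjust=True)
        plain = tr.relative_coexpr_test(small_bundle.expression,
                                        small_bundle.truth_genes,
                                        n_resamples=100, seed=4)
        assert all(r.p_adjusted is None for r in plain)
        for r in res:
            assert r.p_adjusted >= r.p_empirical - 1e-15
            assert r.p_adjusted <= 1.0

    def test_te_genes_must_be_subset(self, toy_expression):
        with pytest.raises(ValueError, match="not in expression"):
            tr.relative_coexpr_test(toy_expression, ["nope"], n_resamples=10)

    def test_degenerate_pair_flagged_not_raised(self):
        df = pd.DataFrame({"a": [1.0] * 9,
                           "b": np.arange(1.0, 10.0)},
                          index=[f"g{i}" for i in range(9)])
        em = tr.ExpressionMatrix(df, pd.Series({"a": "A", "b": "B"}))
        (res,) = tr.relative_coexpr_test(em, ["g0", "g1", "g2"],
                                         n_resamples=10, expressed_min_tpm=0)
        assert not res.valid and res.note


class TestOddsRatioMatrix:
    def test_shape_and_symmetry(self, small_bundle):
        res = tr.relative_coexpr_test(small_bundle.expression,
                                      small_bundle.truth_genes,
                                      n_resamples=50, seed=1)
        m = tr.odds_ratio_matrix(res)
        assert m.shape == (4, 4)
        assert np.isnan(np.diag(m.to_numpy())).all()
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)

    def test_heatmap_rendering_smoke(self, small_bundle, tmp_path):
        from te_regnet.coexpression import plot_odds_ratio_heatmap
        res = tr.relative_coexpr_test(small_bundle.expression,
                                      small_bundle.truth_genes,
                                      n_resamples=20, seed=1)
        out = tmp_path / "heatmap.png"
        plot_odds_ratio_heatmap(tr.odds_ratio_matrix(res), out)
        assert out.stat().st_size > 0

    def test_formula_identity(self, small_bundle):
        res = tr.relative_coexpr_test(small_bundle.expression,
                                      small_bundle.truth_genes,
                                      n_resamples=50, seed=1)
        for r in res:
            assert r.odds_ratio == pytest.approx(
                (1 - r.p_empirical) / r.p_empirical)
        # observed below every null at B=5000 would give (1-p)/p = 5000
        p_min = 1 / 5001
        assert (1 - p_min) / p_min == pytest.approx(5000.0)
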