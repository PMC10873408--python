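"""Filtering, normalization and NB differential-expression testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutrigeom import glm
from nutrigeom.expression import (
    CountMatrix,
    bh_fdr,
    de_results_frame,
    filter_low_genes,
    fit_de,
    fit_nutrient_coefficients,
    normalize,
)
from nutrigeom.simulate import ExpressionTruth, simulate_gene_counts


def _brute_force_filter(counts, min_count, max_low):
    keep = []
    for row in counts:
        n_low = sum(1 for v in row if v < min_count)
        keep.append(not (n_low >= max_low))
    return keep


class TestFilterLowGenes:
    def test_all_zero_gene_removed(self):
        counts = np.zeros((1, 57), dtype=int)
        m = CountMatrix([f"g0"], [f"s{i}" for i in range(57)], counts)
        with pytest.warns(UserWarning):
            out = filter_low_genes(m)
        assert out.n_genes == 0

    def test_borderline_gene_kept(self):
        # >= 10 reads in 5 of 57 samples, i.e. < 10 in exactly 52 -> kept
        counts = np.zeros((1, 57), dtype=int)
        counts[0, :5] = 10
        m = CountMatrix(["g0"], [f"s{i}" for i in range(57)], counts)
        assert filter_low_genes(m).n_genes == 1

    def test_low_in_53_removed(self):
        counts = np.zeros((1, 57), dtype=int)
        counts[0, :4] = 100  # < 10 in exactly 53
        m = CountMatrix(["g0"], [f"s{i}" for i in range(57)], counts)
        assert filter_low_genes(m).n_genes == 0

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(0, 15, size=(6, 12))
        m = CountMatrix([f"g{i}" for i in range(6)], [f"s{j}" for j in range(12)], counts)
        out = filter_low_genes(m, min_count=10, max_low_samples=8)
        expected = _brute_force_filter(counts, 10, 8)
        assert out.gene_ids == [g for g, k in zip(m.gene_ids, expected) if k]

    def test_library_sizes_preserved_from_prefilter(self):
        counts = np.array([[100] * 6, [0] * 6])
        m = CountMatrix(["a", "b"], [f"s{i}" for i in range(6)], counts)
        out = filter_low_genes(m, max_low_samples=2)
        np.testing.assert_array_equal(out.library_sizes, m.library_sizes)


class TestNormalize:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 1000, size=200)
        counts = np.tile(col[:, None], (1, 5))
        m = CountMatrix([f"g{i}" for i in range(200)], [f"s{j}" for j in range(5)], counts)
        out = normalize(m)
        np.testing.assert_allclose(out.norm_factors, 1.0, atol=1e-12)

    def test_doubled_column_doubles_effective_size(self, rng):
        col = rng.integers(1, 1000, size=500)
        counts = np.column_stack([col, col, col, 2 * col])
        m = CountMatrix([f"g{i}" for i in range(500)], list("abcd"), counts)
        out = normalize(m)
        ratio = out.effective_library_sizes[3] / out.effective_library_sizes[0]
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(0, 500, size=(300, 8))
        counts[:, 3] *= 3
        m = CountMatrix([f"g{i}" for i in range(300)], [f"s{j}" for j in range(8)], counts)
        out = normalize(m)
        assert np.exp(np.mean(np.log(out.norm_factors))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_sample_rejected(self):
        counts = np.array([[5, 0], [3, 0]])
        m = CountMatrix(["a", "b"], ["s1", "s2"], counts)
        with pytest.raises(ValueError, match="s2"):
            normalize(m)


class TestBhFdr:
    def test_step_up_formula(self):
        np.testing.assert_allclose(
            bh_fdr([0.002, 0.01, 0.03, 0.04]), [0.008, 0.02, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestFitDe:
    def test_planted_fat_gene_detected(self, design):
        rng = np.random.default_rng(0)
        truths = [
            ExpressionTruth(f"null{i}", float(rng.normal(np.log(300), 0.5)), 0, 0, 0, 0.05)
            for i in range(40)
        ]
        truths.append(ExpressionTruth("hot", np.log(300.0), 0.02, 0.0, 0.0, 0.05))
        m, _ = simulate_gene_counts(design, truths, seed=21)
        m = normalize(filter_low_genes(m))
        res = {r.gene_id: r for r in fit_de(m, design)}
        assert res["hot"].significant
        assert res["hot"].coef_fat > 0

    def test_null_pvalues_uniform(self, design):
        truths = [
            ExpressionTruth(f"g{i}", np.log(200.0), 0, 0, 0, 0.05) for i in range(300)
        ]
        m, _ = simulate_gene_counts(design, truths, seed=8)
        res = fit_de(normalize(filter_low_genes(m)), design)
        p = np.array([r.p_value for r in res])
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_compositional_shift_gives_null(self, design):
        # b_fat = b_carb = b_protein -> constant offset because F+C+P = 100
        truths = [
            ExpressionTruth(f"g{i}", np.log(200.0), 0.01, 0.01, 0.01, 0.05)
            for i in range(150)
        ]
        m, _ = simulate_gene_counts(design, truths, seed=12)
        res = fit_de(normalize(filter_low_genes(m)), design)
        p = np.array([r.p_value for r in res])
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert np.mean([r.significant for r in res]) <= 0.05

    def test_poisson_limit_matches_statsmodels_oracle(self, design):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        truths = [ExpressionTruth(f"g{i}", np.log(150.0), 0.01, -0.005, 0, 0.0) for i in range(5)]
        m, _ = simulate_gene_counts(design, truths, seed=17)
        pct = design.sample_percent_matrix().loc[m.sample_ids].to_numpy()
        X = np.column_stack([np.ones(57), pct[:, 2], pct[:, 1]])
        offset = np.log(m.library_sizes)
        res = fit_de(m, design, dispersion=0.0)
        for i, r in enumerate(res):
            oracle = sm.GLM(
                m.counts[i], X, family=sm.families.Poisson(), offset=offset
            ).fit()
            np.testing.assert_allclose(
                [r.coef_intercept, r.coef_fat, r.coef_carb], oracle.params, atol=1e-6
            )
            null = sm.GLM(
                m.counts[i], X[:, :1], family=sm.families.Poisson(), offset=offset
            ).fit()
            lr_oracle = 2 * (oracle.llf - null.llf)
            assert r.lr_stat == pytest.approx(lr_oracle, abs=1e-6)

    def test_batch_covariate_absorbs_confounded_shift(self, design):
        # batch aligned with high-fat diets inflates counts; including the
        # batch term removes the spurious diet signal
        rng = np.random.default_rng(44)
        fat = design.sample_percent_matrix().loc[design.sample_ids, "fat_pct"]
        batch = (fat > 30).to_numpy().astype(int)
        truths = [
            ExpressionTruth(f"g{i}", np.log(300.0), 0, 0, 0, 0.02) for i in range(60)
        ]
        m, _ = simulate_gene_counts(design, truths, seed=45)
        counts = m.counts.copy()
        counts[:, batch == 1] = rng.poisson(counts[:, batch == 1] * 3.0)
        # keep the pre-shift library sizes so the batch effect is not
        # absorbed by the offset
        m2 = CountMatrix(m.gene_ids, m.sample_ids, counts, library_sizes=m.library_sizes)
        naive = fit_de(m2, design, dispersion=0.05)
        adjusted = fit_de(m2, design, dispersion=0.05, extra_covariate=batch)
        assert np.mean([r.significant for r in naive]) > 0.5
        assert np.mean([r.significant for r in adjusted]) <= 0.05

    def test_order_invariance(self, design):
        truths = [
            ExpressionTruth(f"g{i}", np.log(200.0), 0.01 * (i % 2), 0, 0, 0.05)
            for i in range(20)
        ]
        m, _ = simulate_gene_counts(design, truths, seed=3)
        m = normalize(filter_low_genes(m))
        res = {r.gene_id: r.p_value for r in fit_de(m, design)}
        rev = m.subset_genes(m.gene_ids[::-1])
        res_rev = {r.gene_id: r.p_value for r in fit_de(rev, design)}
        for g in res:
            assert res[g] == pytest.approx(res_rev[g], rel=1e-6)


class TestNutrientCoefficients:
    def test_contrast_recovery(self, design):
        # majority-null background so library sizes do not absorb the signal
        truths = [
            ExpressionTruth(f"null{i}", np.log(500.0), 0, 0, 0, 0.01)
            for i in range(200)
        ]
        truths += [
            ExpressionTruth(f"g{i}", np.log(500.0), 0.02, 0.0, -0.02, 0.01)
            for i in range(30)
        ]
        m, _ = simulate_gene_counts(design, truths, seed=30)
        planted = [f"g{i}" for i in range(30)]
        coeffs = fit_nutrient_coefficients(
            normalize(filter_low_genes(m)), design, features=planted, dispersion=0.01
        )
        fat_contrast = np.mean([c.b_fat - c.b_carb for c in coeffs])
        prot_contrast = np.mean([c.b_protein - c.b_carb for c in coeffs])
        assert fat_contrast == pytest.approx(0.02, rel=0.2)
        assert prot_contrast == pytest.approx(-0.02, rel=0.2)

    def test_common_shift_moves_all_coefficients(self, design):
        # adding delta to all three true coefficients shifts fits, not
        # contrasts; the planted gene sits last so the null background's
        # random stream (and hence the library sizes) is shared
        background = [
            ExpressionTruth(f"null{i}", np.log(500.0), 0, 0, 0, 0.0)
            for i in range(200)
        ]
        base = background + [ExpressionTruth("g", np.log(500.0), 0.01, 0.0, -0.01, 0.0)]
        shift = background + [ExpressionTruth("g", np.log(500.0), 0.02, 0.01, 0.0, 0.0)]
        ma, _ = simulate_gene_counts(design, base, seed=7)
        mb, _ = simulate_gene_counts(design, shift, seed=7)
        ca = fit_nutrient_coefficients(ma, design, features=["g"], dispersion=0.0)[0]
        cb = fit_nutrient_coefficients(mb, design, features=["g"], dispersion=0.0)[0]
        assert cb.b_fat - cb.b_carb == pytest.approx(ca.b_fat - ca.b_carb, abs=1e-3)
        assert cb.b_fat - ca.b_fat == pytest.approx(0.01, abs=2e-3)

    def test_agrees_with_two_covariate_fit(self, design):
        truths = [ExpressionTruth("g", np.log(400.0), 0.015, -0.01, 0.0, 0.05)]
        m, _ = simulate_gene_counts(design, truths, seed=2)
        de = fit_de(m, design, dispersion=0.1)[0]
        c = fit_nutrient_coefficients(m, design, dispersion=0.1)[0]
        assert de.coef_fat == pytest.approx(c.b_fat - c.b_protein, abs=1e-6)
        assert de.coef_carb == pytest.approx(c.b_carb - c.b_protein, abs=1e-6)

    def test_unknown_feature_rejected(self, design):
        truths = [ExpressionTruth("g", np.log(400.0), 0, 0, 0, 0.05)]
        m, _ = simulate_gene_counts(design, truths, seed=2)
        with pytest.raises(ValueError, match="not in matrix"):
            fit_nutrient_coefficients(m, design, features=["nope"])


class TestCountMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 100, size=(5, 4))
        m = CountMatrix([f"g{i}" for i in range(5)], list("abcd"), counts)
        path = tmp_path / "counts.tsv"
        m.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        np.testing.assert_array_equal(back.counts, m.counts)
        assert back.gene_ids == m.gene_ids

    def test_mtx_round_trip(self, tmp_path, rng):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        counts = rng.integers(0, 50, size=(6, 3))
        mmwrite(tmp_path / "c.mtx", csr_matrix(counts))
        (tmp_path / "genes.txt").write_text("\n".join(f"g{i}" for i in range(6)))
        (tmp_path / "samples.txt").write_text("\n".join("abc"))
        m = CountMatrix.from_mtx(
            tmp_path / "c.mtx", tmp_path / "genes.txt", tmp_path / "samples.txt"
        )
        np.testing.assert_array_equal(m.counts, counts)
        assert m.sample_ids == list("abc")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["g"], ["s"], np.array([[-1]]))

    def test_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["g"], ["s"], np.array([[1.5]]))
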