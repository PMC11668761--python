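from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import hat_matrix_residuals, multiple_regression_r2
from locmorph.exceptions import ShapeError, ValidationError
from locmorph.genetics import MISSING
from locmorph.mvgwas import (
    MultivariateGWAS,
    cca_snp,
    gwas_scan,
    manhattan_table,
    residualize,
    select_components,
)
from test_genetics import make_genotypes


def make_covars(n, rng, n_pcs=3):
    return pd.DataFrame({
        "age": rng.uniform(108, 173, n),
        "sex": rng.integers(0, 2, n).astype(float),
        **{f"gpc{i + 1}": rng.standard_normal(n) for i in range(n_pcs)},
    })


class TestResidualize:
    def test_exact_fit_gives_zero_residual(self, rng):
        covars = make_covars(50, rng)
        y = 2.0 * covars["age"].to_numpy() + 3.0
        resid = residualize(y[:, None], covars)
        assert np.abs(resid).max() < 1e-10

    def test_matches_hat_matrix_oracle(self, rng):
        covars = make_covars(40, rng)
        Y = rng.standard_normal((40, 6))
        resid = residualize(Y, covars)
        D = np.column_stack([np.ones(40), covars.to_numpy()])
        np.testing.assert_allclose(resid, hat_matrix_residuals(Y, D), atol=1e-10)

    def test_residuals_uncorrelated_with_covariates(self, rng):
        covars = make_covars(60, rng)
        resid = residualize(rng.standard_normal((60, 4)), covars)
        for col in covars.columns:
            c = covars[col].to_numpy() - covars[col].mean()
            assert np.abs(resid.T @ c).max() < 1e-8

    def test_orthogonal_covariates_leave_trait_centred(self, rng):
        n = 64
        covars = pd.DataFrame({"age": np.tile([1.0, -1.0], n // 2)})
        y = np.repeat([1.0, -1.0], n // 2)  # orthogonal to age by construction
        resid = residualize(y[:, None], covars).ravel()
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-10)

    def test_collinear_design_names_column(self, rng):
        covars = make_covars(30, rng)
        covars["age_copy"] = covars["age"]
        with pytest.raises(ValidationError, match="age_copy"):
            residualize(rng.standard_normal((30, 2)), covars)


class TestCCASnp:
    def test_trait_equal_to_dosage_gives_r_one(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=50)
        assoc = cca_snp(d, d[:, None])
        assert assoc.r == pytest.approx(1.0)
        assert assoc.wilks == pytest.approx(0.0)
        assert assoc.p == 1e-300

    def test_orthogonal_dosage_gives_r_zero(self):
        n = 40
        d = np.tile([0.0, 2.0], n // 2)
        t = np.repeat([1.0, -1.0], n // 2)[:, None]  # centred, orthogonal to d
        assoc = cca_snp(d, t)
        assert assoc.r == pytest.approx(0.0, abs=1e-10)
        assert assoc.F == pytest.approx(0.0, abs=1e-16)
        assert assoc.p == pytest.approx(1.0)

    def test_k1_matches_univariate_regression_f_test(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=80)
        t = (0.3 * d + rng.standard_normal(80))[:, None]
        assoc = cca_snp(d, t)
        lr = stats.linregress(t.ravel(), d)
        assert abs(assoc.p - lr.pvalue) < 1e-12
        assert assoc.r == pytest.approx(abs(lr.rvalue), abs=1e-12)

    def test_k5_matches_normal_equations_r2(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=100)
        T = rng.standard_normal((100, 5))
        assoc = cca_snp(d, T)
        assert abs(assoc.r ** 2 - multiple_regression_r2(d, T)) < 1e-12
        assert assoc.df1 == 5 and assoc.df2 == 100 - 5 - 1
        assert assoc.wilks == pytest.approx(1 - assoc.r ** 2)

    def test_p_invariant_under_trait_mixing(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=90)
        T = rng.standard_normal((90, 4))
        T[:, 0] += 0.4 * d
        base = cca_snp(d, T)
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)  # full rank mixing
        mixed = cca_snp(d, T @ A + rng.standard_normal(4))
        assert abs(base.p - mixed.p) < 1e-9
        assert abs(base.r - mixed.r) < 1e-9

    def test_p_invariant_under_dosage_relabel(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=70)
        T = rng.standard_normal((70, 3))
        a = cca_snp(d, T)
        b = cca_snp(2.0 - d, T)
        assert abs(a.p - b.p) < 1e-12

    def test_missing_dosage_complete_case(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=60)
        T = rng.standard_normal((60, 3))
        d_miss = d.copy()
        d_miss[5:10] = MISSING
        keep = np.ones(60, bool)
        keep[5:10] = False
        a = cca_snp(d_miss, T)
        b = cca_snp(d[keep], T[keep])
        assert a.n_used == 55
        assert abs(a.p - b.p) < 1e-12

    def test_untestable_paths(self, rng):
        T = rng.standard_normal((6, 5))
        too_few = cca_snp(np.array([0, 1, 2, 0, 1, 2.0]), T)
        assert not too_few.testable and np.isnan(too_few.p)
        mono = cca_snp(np.ones(30), rng.standard_normal((30, 2)))
        assert not mono.testable and np.isnan(mono.p)

    def test_loadings_are_structure_correlations(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], size=120)
        T = rng.standard_normal((120, 3))
        T[:, 1] += 0.8 * d
        assoc = cca_snp(d, T)
        # the canonical variate is the fitted value of dosage on traits
        Tc = T - T.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Tc, d - d.mean(), rcond=None)
        variate = Tc @ beta
        expect = [np.corrcoef(T[:, j], variate)[0, 1] for j in range(3)]
        np.testing.assert_allclose(assoc.loadings, expect, atol=1e-10)
        assert np.argmax(np.abs(assoc.loadings)) == 1


class TestGwasScan:
    def test_single_snp_reduces_to_cca(self, rng):
        dosage = rng.choice([0, 1, 2], size=(50, 1)).astype(np.int8)
        g = make_genotypes(dosage)
        T = rng.standard_normal((50, 3))
        table, loadings = gwas_scan(g, T)
        direct = cca_snp(dosage[:, 0].astype(float), T)
        assert table.loc[0, "p"] == pytest.approx(direct.p)
        np.testing.assert_allclose(loadings[0], direct.loadings)

    def test_snp_order_permutation_gives_identical_table(self, rng):
        dosage = rng.choice([0, 1, 2], size=(40, 6)).astype(np.int8)
        g = make_genotypes(dosage)
        T = rng.standard_normal((40, 2))
        table, _ = gwas_scan(g, T)
        perm = [3, 0, 5, 1, 4, 2]
        g2 = g.take_snps(np.array(perm))
        table2, _ = gwas_scan(g2, T)
        pd.testing.assert_frame_equal(table, table2)

    def test_confounded_null_recalibrated_by_residualization(self):
        """Age drives both traits and dosage; residualization removes the
        resulting type-I inflation back to the binomial band."""
        gen = np.random.default_rng(42)
        n, m, k = 300, 150, 3
        age = gen.uniform(108, 173, n)
        z = (age - age.mean()) / age.std()
        freq = np.clip(0.3 + 0.15 * z, 0.05, 0.95)
        dosage = gen.binomial(2, freq[:, None].repeat(m, 1)).astype(np.int8)
        g = make_genotypes(dosage)
        T = np.outer(z, gen.standard_normal(k)) + 0.5 * gen.standard_normal((n, k))
        raw_table, _ = gwas_scan(g, T - T.mean(axis=0))
        covars = pd.DataFrame({"age": age})
        adj_table, _ = gwas_scan(g, residualize(T, covars))
        raw_rate = (raw_table["p"] < 0.05).mean()
        adj_rate = (adj_table["p"] < 0.05).mean()
        assert raw_rate > 0.2
        assert 0.01 <= adj_rate <= 0.10


class TestSelectionAndManhattan:
    def test_primary_threshold(self):
        assert select_components(np.array([0.25, -0.10, 0.30])) == {0, 2}

    def test_fallback_threshold(self):
        assert select_components(np.array([0.18, -0.16, 0.01])) == {0, 1}

    def test_empty_selection(self):
        assert select_components(np.array([0.05, -0.08, 0.01])) == set()

    def test_neglog10_and_reference_line(self, rng):
        dosage = rng.choice([0, 1, 2], size=(30, 1)).astype(np.int8)
        g = make_genotypes(dosage)
        table, _ = gwas_scan(g, rng.standard_normal((30, 2)))
        table.loc[0, "p"] = 1e-4
        t = manhattan_table(table, significance_line=1e-8)
        assert t.loc[0, "neglog10p"] == pytest.approx(4.0)
        assert t.attrs["significance_line"] == 1e-8

    def test_cumulative_coordinates_strictly_increase(self, rng):
        m = 24
        dosage = rng.choice([0, 1, 2], size=(40, m)).astype(np.int8)
        g = make_genotypes(dosage)
        g.snps["chrom"] = [str(1 + j // 6) for j in range(m)]
        g.snps["pos"] = 100 + 10 * (np.arange(m) % 6)
        table, _ = gwas_scan(g, rng.standard_normal((40, 2)))
        t = manhattan_table(table)
        assert (np.diff(t["cum_pos"]) > 0).all()

    def test_untestable_snps_excluded(self, rng):
        dosage = rng.choice([0, 1, 2], size=(30, 3)).astype(np.int8)
        dosage[:, 1] = 1  # monomorphic -> untestable
        g = make_genotypes(dosage)
        table, _ = gwas_scan(g, rng.standard_normal((30, 2)))
        t = manhattan_table(table)
        assert len(t) == 2


class TestModelResultsShape:
    def test_fit_produces_results_with_summary(self, rng):
        dosage = rng.choice([0, 1, 2], size=(60, 8)).astype(np.int8)
        g = make_genotypes(dosage)
        scores = rng.standard_normal((60, 4))
        covars = make_covars(60, rng, n_pcs=2)
        res = MultivariateGWAS(g, scores, covariates=covars).fit()
        assert len(res.table) == 8
        assert res.loadings.shape == (8, 4)
        assert res.rank_of(res.top_snp()["id"]) == 1
        text = res.summary()
        assert "top SNP" in text and str(res.n_testable) in text

    def test_shape_mismatch_rejected(self, rng):
        g = make_genotypes(rng.choice([0, 1, 2], size=(10, 2)).astype(np.int8))
        with pytest.raises(ShapeError):
            MultivariateGWAS(g, rng.standard_normal((9, 3)))
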