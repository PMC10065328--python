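import numpy as np
import pandas as pd
import pytest

from epiblup import (
    PhenotypeRecords,
    RelationshipKernel,
    SimConfig,
    fit_with_protocol,
    gblup_kernel,
    genomic_correlation,
    genomic_heritability,
    predict_blup,
    reml_bivariate,
    reml_univariate,
    simulate_dataset,
)
from epiblup.mixed_models import BivariateFit


def _records(line_ids, y1, y2, years=(2017, 2018)):
    rows = []
    for yr, y in zip(years, (y1, y2)):
        for line, v in y.items():
            rows.append((line, yr, "ENV1", "trait", v))
    return PhenotypeRecords(
        pd.DataFrame(rows, columns=["line_id", "year", "environment", "trait", "value"])
    )


@pytest.fixture(scope="module")
def additive_fit_problem():
    cfg = SimConfig(
        n_lines=150, p_snps=150, n_regions=15, n_add_qtl=60, n_epi_pairs=0,
        epi_var_fraction=0.0, h2_year1=0.7, h2_year2=0.6, r_g_target=0.9, seed=55,
    )
    snp, _, recs, truth = simulate_dataset(cfg)
    return snp, recs.subset(environment="ENV1"), truth, gblup_kernel(snp)


class TestUnivariate:
    def test_noiseless_limit_recovers_centered_phenotype(self):
        cfg = SimConfig(n_lines=60, p_snps=80, n_regions=8, n_add_qtl=40,
                        n_epi_pairs=0, epi_var_fraction=0.0,
                        h2_year1=1.0, h2_year2=1.0, seed=5)
        snp, _, recs, _ = simulate_dataset(cfg)
        k = gblup_kernel(snp)
        y = recs.series(recs.years[0], "ENV1", "trait")
        fit = reml_univariate(y, k)
        obs = k.index_of(y.index)
        np.testing.assert_allclose(
            fit.g_hat.to_numpy()[obs], y.to_numpy() - fit.beta_hat, atol=1e-6
        )

    def test_h2_recovery(self):
        """Genomic heritability recovered within +-0.10 on average."""
        ests = []
        for s in range(20):
            cfg = SimConfig(n_lines=300, p_snps=300, n_regions=25, n_add_qtl=100,
                            n_epi_pairs=0, epi_var_fraction=0.0,
                            h2_year1=0.6, h2_year2=0.6, seed=3000 + s)
            snp, _, recs, _ = simulate_dataset(cfg)
            k = gblup_kernel(snp)
            fit = reml_univariate(recs.series(recs.years[0], "ENV1", "trait"), k)
            ests.append(genomic_heritability(fit.sigma2_g, fit.sigma2_e, k))
        assert np.mean(ests) == pytest.approx(0.6, abs=0.10)

    def test_identity_kernel_warns_but_fits(self, rng):
        n = 30
        k = RelationshipKernel([f"L{i}" for i in range(n)], np.eye(n), "gblup", 1.0, n)
        y = pd.Series(rng.standard_normal(n), index=k.line_ids)
        with pytest.warns(UserWarning, match="identifiable"):
            fit = reml_univariate(y, k)
        assert np.isfinite(fit.logL_reml)

    def test_matches_dense_grid_oracle(self, additive_fit_problem):
        """Eigendecomposition REML equals direct dense restricted logL."""
        snp, recs, truth, k = additive_fit_problem
        y = recs.series(recs.years[0], "ENV1", "trait").iloc[:40]
        obs = k.index_of(y.index)
        k_obs = k.ridged()[np.ix_(obs, obs)]
        yv = y.to_numpy(float)
        n = len(yv)
        x = np.ones((n, 1))

        def dense_restricted_ll(lam):
            # logL up to the same additive constant used by the implementation
            v = lam * k_obs + np.eye(n)
            vinv = np.linalg.inv(v)
            xvx = x.T @ vinv @ x
            beta = np.linalg.solve(xvx, x.T @ vinv @ yv)
            py = vinv @ (yv - x @ beta)
            quad = float(yv @ py)
            se2 = quad / (n - 1)
            _, ld_v = np.linalg.slogdet(v)
            _, ld_xvx = np.linalg.slogdet(xvx)  # V on the unit residual scale
            ld_xx = float(np.log(n))
            return -0.5 * (
                (n - 1) * np.log(2 * np.pi * se2) + ld_v + ld_xvx - ld_xx + quad / se2
            )

        from epiblup.mixed_models import _projected_spectrum

        xi, u = _projected_spectrum(k_obs)
        eta = u.T @ yv

        def eigen_restricted_ll(lam):
            d = lam * xi + 1.0
            r = float(np.sum(eta**2 / d))
            return 0.5 * ((n - 1) * np.log((n - 1) / (2 * np.pi * r))
                          - (n - 1) - float(np.sum(np.log(d))))

        for lam in (0.01, 0.5, 1.0, 3.0, 10.0):
            assert eigen_restricted_ll(lam) == pytest.approx(dense_restricted_ll(lam), abs=1e-8)

    def test_too_few_observations_rejected(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        y = recs.series(recs.years[0], "ENV1", "trait").iloc[:5]
        with pytest.raises(ValueError, match="10"):
            reml_univariate(y, k)


class TestBivariate:
    def test_near_duplicate_trait_limit(self, additive_fit_problem):
        """y2 = y1 + tiny noise on identical lines gives r_g near 1."""
        snp, recs, truth, k = additive_fit_problem
        rng = np.random.default_rng(1)
        y1 = recs.series(recs.years[0], "ENV1", "trait")
        y2 = y1 + 1e-3 * y1.std() * rng.standard_normal(len(y1))
        fit = reml_bivariate(_records(y1.index, y1, y2), k)
        assert genomic_correlation(fit) >= 0.95

    def test_independent_years_near_zero_correlation(self):
        ests = []
        for s in range(10):
            cfg = SimConfig(n_lines=250, p_snps=250, n_regions=25, n_add_qtl=100,
                            n_epi_pairs=0, epi_var_fraction=0.0,
                            h2_year1=0.7, h2_year2=0.6, r_g_target=0.0, seed=7000 + s)
            snp, _, recs, _ = simulate_dataset(cfg)
            k = gblup_kernel(snp)
            fit = reml_bivariate(recs.subset(environment="ENV1"), k)
            ests.append(genomic_correlation(fit))
        assert np.mean(ests) == pytest.approx(0.0, abs=0.10)

    def test_disjoint_years_match_univariate(self, additive_fit_problem):
        """With no common lines the covariance is fixed at 0 and the
        likelihood factorizes: year-1 components equal the univariate fit."""
        snp, recs, truth, k = additive_fit_problem
        df = recs.frame
        yrs = sorted(df["year"].unique())
        lines = sorted(df["line_id"].unique())
        half = len(lines) // 2
        dfd = df[
            ((df["year"] == yrs[0]) & df["line_id"].isin(lines[:half]))
            | ((df["year"] == yrs[1]) & df["line_id"].isin(lines[half:]))
        ]
        with pytest.warns(UserWarning, match="fixed at 0"):
            bi = reml_bivariate(PhenotypeRecords(dfd), k, max_iter=500, tol=1e-12)
        uni = reml_univariate(
            PhenotypeRecords(dfd).series(yrs[0], "ENV1", "trait"), k
        )
        assert bi.G0[0, 1] == 0.0
        assert bi.G0[0, 0] == pytest.approx(uni.sigma2_g, abs=1e-6)
        assert bi.sigma2_e1 == pytest.approx(uni.sigma2_e, abs=1e-6)

    def test_logL_monotone_over_iterations(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        fit = reml_bivariate(recs, k)
        assert np.all(np.diff(fit.logL_path) > -1e-8)

    def test_line_permutation_invariance(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        perm = np.random.default_rng(0).permutation(k.n_lines)
        k_perm = RelationshipKernel(
            [k.line_ids[i] for i in perm], k.matrix[np.ix_(perm, perm)],
            k.kind, k.scale_c, k.n_predictors_or_pairs,
        )
        f1 = reml_bivariate(recs, k)
        f2 = reml_bivariate(recs, k_perm)
        np.testing.assert_allclose(f1.components, f2.components, rtol=1e-5, atol=1e-8)
        g1 = f1.g_hat.sort_index()
        g2 = f2.g_hat.sort_index()
        np.testing.assert_allclose(g1.to_numpy(), g2.to_numpy(), atol=1e-6)


class TestProtocol:
    def test_prefit_then_cv_converges(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        pre = fit_with_protocol(recs, k, stage="prefit")
        assert pre.converged and pre.n_iter < 100
        cv = fit_with_protocol(recs, k, stage="cv_fold", init=pre.components)
        assert cv.converged and cv.n_iter < 50
        assert not cv.fixed_fallback

    def test_fallback_fixes_components_at_init(self, additive_fit_problem):
        """A fold fit capped at one iteration from a bad start must fall
        back to BLUPs at the initial components."""
        snp, recs, truth, k = additive_fit_problem
        bad_init = np.array([10.0, 0.0, 10.0, 10.0, 10.0])
        fit = fit_with_protocol(recs, k, stage="cv_fold", init=bad_init, max_iter=1)
        assert fit.fixed_fallback and not fit.converged
        np.testing.assert_array_equal(fit.components, bad_init)

    def test_cv_fold_requires_init(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        with pytest.raises(ValueError, match="init"):
            fit_with_protocol(recs, k, stage="cv_fold")


class TestGenomicCorrelation:
    def test_simple_value(self):
        fit = _dummy_fit(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert genomic_correlation(fit) == pytest.approx(0.5)

    def test_boundary_clip(self):
        fit = _dummy_fit(np.array([[4.0, -2.0], [-2.0, 1.0]]))
        assert genomic_correlation(fit) == -1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            genomic_correlation(_dummy_fit(np.array([[0.0, 0.0], [0.0, 1.0]])))


def _dummy_fit(g0):
    return BivariateFit(
        years=(2017, 2018), beta_hat=np.zeros(2), G0=g0,
        sigma2_e1=1.0, sigma2_e2=1.0, logL_reml=0.0,
        g_hat=pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=[2017, 2018]),
        converged=True, n_iter=1, init_values=np.zeros(5),
    )


class TestPredictBlup:
    def test_clone_line_identity(self, additive_fit_problem):
        """A line with identical kernel rows gets the same prediction."""
        snp, recs, truth, k = additive_fit_problem
        fit = reml_bivariate(recs, k)
        km = k.matrix
        # construct an explicit clone kernel: append a copy of line 0
        ids = list(k.line_ids) + ["CLONE"]
        big = np.zeros((k.n_lines + 1, k.n_lines + 1))
        big[: k.n_lines, : k.n_lines] = km
        big[-1, : k.n_lines] = km[0]
        big[: k.n_lines, -1] = km[0]
        big[-1, -1] = km[0, 0]
        k2 = RelationshipKernel(ids, big, k.kind, k.scale_c, k.n_predictors_or_pairs)
        fit2 = reml_bivariate(recs, k2, init=fit.components, max_iter=50)
        yr = fit2.years[1]
        pred = predict_blup(fit2, k2, yr, ["CLONE", k.line_ids[0]])
        # the PSD ridge (~1e-8 on the diagonal) bounds achievable agreement
        assert pred.iloc[0] == pytest.approx(pred.iloc[1], abs=1e-6)

    def test_full_shrinkage_at_zero_genetic_variance(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        tiny = np.array([1e-9, 0.0, 1e-9, 1.0, 1.0])
        fit = fit_with_protocol(recs, k, stage="cv_fold", init=tiny, max_iter=1)
        assert np.abs(fit.g_hat.to_numpy()).max() < 1e-5

    def test_absent_line_rejected(self, additive_fit_problem):
        snp, recs, truth, k = additive_fit_problem
        fit = reml_bivariate(recs, k)
        with pytest.raises(KeyError):
            predict_blup(fit, k, fit.years[1], ["NOT_A_LINE"])
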