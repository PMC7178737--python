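"""Tests for the ACE twin-model machinery: expected covariances, FIML
likelihoods against brute-force oracles, liability orthants against
quadrature, estimator recovery, nesting and the correlated-factors view."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from sklearn.base import clone

from twinlat.simulate import SimulationConfig, simulate_binary, simulate_pairs
from twinlat.twin import (
    BivariateCholeskyModel,
    UnivariateTwinModel,
    bivariate_normal_cdf,
    concordance_cell_probs,
    expected_pair_covariance,
    fit_bivariate_ladder,
    fit_model,
    homogeneity_ladder,
    lrt,
    neg2ll_binary_liability,
    neg2ll_continuous,
)

LOG2PI = math.log(2 * math.pi)


class TestExpectedCovariance:
    def test_univariate_mz_dz(self):
        a, c, e = math.sqrt(0.25), 0.0, math.sqrt(0.75)
        mz = expected_pair_covariance(a, c, e, "MZ")
        dz = expected_pair_covariance(a, c, e, "DZ")
        np.testing.assert_allclose(mz, [[1, 0.25], [0.25, 1]], atol=1e-12)
        np.testing.assert_allclose(dz[0, 1], 0.125, atol=1e-12)

    def test_bivariate_no_genetic_cross_path(self):
        A = np.array([[0.5, 0.0], [0.0, 0.4]])  # a21 = 0
        C = np.array([[0.3, 0.0], [0.2, 0.3]])
        E = np.array([[0.6, 0.0], [0.3, 0.5]])
        sig = expected_pair_covariance(A, C, E, "DZ")
        # cross-twin cross-trait covariance = 0.5 (AA')_12 + (CC')_12 = (CC')_12
        assert sig[0, 3] == pytest.approx((C @ C.T)[0, 1], abs=1e-12)
        np.testing.assert_allclose(sig, sig.T, atol=1e-12)

    def test_mz_cross_covariance_dominates_dz(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A, C, E = (np.tril(rng.normal(size=(2, 2))) for _ in range(3))
            mz = expected_pair_covariance(A, C, E, "MZ")
            dz = expected_pair_covariance(A, C, E, "DZ")
            diff = np.diag(mz[:2, 2:] - dz[:2, 2:])  # 0.5 AA' diag, PSD
            assert (diff >= -1e-12).all()

    def test_invalid_zygosity(self):
        with pytest.raises(ValueError, match="zygosity"):
            expected_pair_covariance(1.0, 0.0, 1.0, "OS")


class TestContinuousLikelihood:
    @staticmethod
    def _paths(a2=0.25, c2=0.0):
        return {
            "A": math.sqrt(a2),
            "C": math.sqrt(c2),
            "E": math.sqrt(1 - a2 - c2),
        }

    def test_single_pair_identity_closed_form(self):
        pairs = pd.DataFrame({"zygosity": ["MZ"], "y_t1": [0.0], "y_t2": [0.0]})
        val = neg2ll_continuous(pairs, self._paths(a2=0.0), means=0.0)
        assert val == pytest.approx(2 * LOG2PI, abs=1e-12)

    def test_missing_cotwin_marginalizes(self):
        pairs = pd.DataFrame({"zygosity": ["DZ"], "y_t1": [1.3], "y_t2": [np.nan]})
        val = neg2ll_continuous(pairs, self._paths(), means=0.2)
        expected = -2 * stats.norm.logpdf(1.3, loc=0.2, scale=1.0)
        assert val == pytest.approx(expected, abs=1e-10)

    def test_matches_density_summation_oracle(self):
        cfg = SimulationConfig(a2=(0.3, 0.2), c2=(0.1, 0.0))
        pairs = simulate_pairs(cfg, rng=np.random.default_rng(12), n_mz=25, n_dz=25)
        pairs = pairs.rename(columns={"liab1_t1": "y_t1", "liab1_t2": "y_t2"})
        pairs.loc[pairs.index[:5], "y_t2"] = np.nan  # exercise FIML
        paths = self._paths(a2=0.3, c2=0.1)
        mu = 0.1
        ours = neg2ll_continuous(pairs, paths, means=mu)
        # oracle: per-pair multivariate-normal density summation
        oracle = 0.0
        for row in pairs.itertuples(index=False):
            sigma = expected_pair_covariance(
                paths["A"], paths["C"], paths["E"], row.zygosity
            )
            y = np.array([row.y_t1, row.y_t2])
            obs = ~np.isnan(y)
            oracle += -2 * stats.multivariate_normal.logpdf(
                y[obs], mean=np.full(obs.sum(), mu), cov=sigma[np.ix_(obs, obs)]
            )
        assert ours == pytest.approx(oracle, rel=1e-10)


class TestBinaryLikelihood:
    def test_bvn_cdf_against_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            h, k = rng.normal(scale=1.5, size=2)
            rho = rng.uniform(-0.95, 0.95)
            ref = stats.multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bivariate_normal_cdf(h, k, rho) == pytest.approx(ref, abs=1e-9)
        assert bivariate_normal_cdf(0.0, 0.0, 0.5) == pytest.approx(
            0.25 + math.asin(0.5) / (2 * math.pi), abs=1e-12
        )

    def test_independence_and_symmetry_cells(self):
        p = concordance_cell_probs(stats.norm.ppf(0.92), 0.0)
        marg0 = 0.92
        assert p["p00"] == pytest.approx(marg0**2, abs=1e-12)
        assert p["p11"] == pytest.approx(0.08**2, abs=1e-12)
        p0 = concordance_cell_probs(0.0, 0.0)
        for cell in ("p11", "p10", "p00"):
            assert p0[cell] == pytest.approx(0.25, abs=1e-12)

    def test_orthants_match_2d_quadrature(self):
        tau, r = stats.norm.ppf(0.92), 0.5
        dens = stats.multivariate_normal(cov=[[1, r], [r, 1]]).pdf

        def f(y, x):
            return dens([x, y])

        p00_quad, err = integrate.dblquad(f, -8, tau, -8, tau, epsabs=1e-10)
        p = concordance_cell_probs(tau, r)
        assert p["p00"] == pytest.approx(p00_quad, abs=1e-6)
        assert p["p11"] == pytest.approx(
            integrate.dblquad(f, tau, 8, tau, 8, epsabs=1e-10)[0], abs=1e-6
        )
        assert sum(p.values()) + p["p10"] == pytest.approx(1.0, abs=1e-10)

    def test_neg2ll_counts_form(self):
        pairs = pd.DataFrame(
            {
                "zygosity": ["MZ", "MZ", "DZ", "DZ"],
                "y_t1": [1, 0, 1, 1],
                "y_t2": [1, 1, 0, np.nan],
            }
        )
        tau, a2 = -1.0, 0.3
        val = neg2ll_binary_liability(pairs, a2, 0.0, tau)
        pm = concordance_cell_probs(tau, a2)
        pd_ = concordance_cell_probs(tau, 0.5 * a2)
        expected = -2 * (
            math.log(pm["p11"]) + math.log(pm["p10"])
            + math.log(pd_["p10"]) + math.log(1 - stats.norm.cdf(tau))
        )
        assert val == pytest.approx(expected, rel=1e-12)

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            concordance_cell_probs(0.0, 1.0)


class TestUnivariateEstimator:
    def test_sklearn_protocol(self):
        model = UnivariateTwinModel(components="AE", n_restarts=2)
        params = model.get_params()
        assert params["components"] == "AE"
        clone(model)  # must be cloneable for model selection

    def test_e_only_truth_shrinks_a_and_c(self):
        cfg = SimulationConfig(a2=(0.0, 0.0), c2=(0.0, 0.0))
        pairs = simulate_pairs(cfg, rng=np.random.default_rng(21), n_mz=1500, n_dz=1500)
        pairs = pairs.rename(columns={"liab1_t1": "y_t1", "liab1_t2": "y_t2"})
        fit = fit_model(pairs, components="ACE", n_restarts=2)
        assert fit.a2_ < 0.06 and fit.c2_ < 0.06
        assert fit.e2_ > 0.9

    def test_continuous_recovery_large_n(self, continuous_pairs):
        fit = fit_model(continuous_pairs, components="ACE", n_restarts=3)
        # truth a2=.25, c2=.10; tolerances ~3 sampling SDs at 2k+2k pairs
        assert fit.a2_ == pytest.approx(0.25, abs=0.10)
        assert fit.c2_ == pytest.approx(0.10, abs=0.08)
        assert fit.a2_ + fit.c2_ == pytest.approx(0.35, abs=0.05)
        assert fit.a2_ + fit.c2_ + fit.e2_ == pytest.approx(1.0, abs=1e-8)
        assert fit.converged_

    def test_binary_liability_recovery(self):
        cfg = SimulationConfig(a2=(0.4, 0.2), nrh_prevalence=0.2)
        pairs = simulate_binary(cfg, rng=np.random.default_rng(31), n_mz=4000, n_dz=4000)
        fit = fit_model(pairs, components="AE", trait_kind="binary_liability", n_restarts=2)
        assert fit.a2_ == pytest.approx(0.4, abs=0.1)
        assert fit.tau_ == pytest.approx(stats.norm.ppf(0.2), abs=0.06)

    def test_df_bookkeeping_continuous(self):
        cfg = SimulationConfig()
        pairs = simulate_pairs(cfg, rng=np.random.default_rng(41), n_mz=90, n_dz=102)
        pairs = pairs.rename(columns={"liab1_t1": "y_t1", "liab1_t2": "y_t2"})
        fit = fit_model(pairs, components="ACE", n_restarts=1)
        assert fit.n_obs_ == 384
        assert fit.n_free_params_ == 4
        assert fit.df_ == 380
        assert fit.aic_ == pytest.approx(fit.minus2ll_ - 2 * 380)

    def test_requires_both_zygosities(self):
        pairs = pd.DataFrame(
            {"zygosity": ["MZ"] * 5, "y_t1": np.ones(5), "y_t2": np.ones(5)}
        )
        with pytest.raises(ValueError, match="DZ"):
            fit_model(pairs)


class TestLRT:
    def test_identical_fits(self):
        cfg = SimulationConfig()
        pairs = simulate_pairs(cfg, rng=np.random.default_rng(5), n_mz=50, n_dz=50)
        pairs = pairs.rename(columns={"liab1_t1": "y_t1", "liab1_t2": "y_t2"})
        fit = fit_model(pairs, components="AE", n_restarts=1)
        delta, ddf, p = lrt(fit, fit)
        assert (delta, ddf, p) == (0.0, 0, 1.0)

    def test_p_from_chi2_tail(self):
        class Stub:
            pass

        full, nested = Stub(), Stub()
        full.minus2ll_, full.n_free_params_ = 100.0, 5
        nested.minus2ll_, nested.n_free_params_ = 106.37, 4
        delta, ddf, p = lrt(full, nested)
        assert delta == pytest.approx(6.37)
        assert p == pytest.approx(stats.chi2.sf(6.37, 1))

    def test_negative_delta_raises(self):
        class Stub:
            pass

        full, nested = Stub(), Stub()
        full.minus2ll_, full.n_free_params_ = 100.0, 5
        nested.minus2ll_, nested.n_free_params_ = 99.0, 4
        with pytest.raises(RuntimeError, match="refit"):
            lrt(full, nested)


class TestBivariate:
    def test_ladder_nesting_and_aic_identity(self, bivariate_pairs):
        ladder = fit_bivariate_ladder(bivariate_pairs, n_restarts=2, random_state=0)
        tab = ladder.comparison.set_index("model")
        ace = tab.loc["ACE", "minus2ll"]
        for model in ("AE", "AE1", "AE2", "CE", "E"):
            assert tab.loc[model, "minus2ll"] >= ace - 1e-4
        for model in tab.index:
            assert tab.loc[model, "aic"] == pytest.approx(
                tab.loc[model, "minus2ll"] - 2 * tab.loc[model, "df"]
            )
        # df bookkeeping: 205 pairs x 2 traits x 2 twins = 820 observations
        assert tab.loc["ACE", "df"] == 820 - 11
        assert tab.loc["AE", "df"] == 820 - 8
        assert tab.loc["AE1", "df"] == 820 - 7
        assert ladder.best in tab.index

    def test_dropped_cross_path_gives_zero_genetic_correlation(self, bivariate_pairs):
        fit = BivariateCholeskyModel(components="AE", drop=("a21",), n_restarts=2).fit(
            bivariate_pairs
        )
        view = fit.to_correlated_factors()
        assert view.r_a == pytest.approx(0.0, abs=1e-12) or math.isnan(view.r_a)
        assert abs(view.r_e) <= 1.0

    def test_single_genetic_factor_gives_unit_correlation(self):
        model = BivariateCholeskyModel()
        model.A_ = np.array([[0.5, 0.0], [0.3, 0.0]])  # a22 = 0
        model.C_ = np.zeros((2, 2))
        model.E_ = np.array([[0.7, 0.0], [0.2, 0.6]])
        V = model.A_ @ model.A_.T + model.E_ @ model.E_.T
        model.a2_ = np.diag(model.A_ @ model.A_.T) / np.diag(V)
        model.c2_ = np.zeros(2)
        model.e2_ = 1 - model.a2_
        view = model.to_correlated_factors()
        assert abs(view.r_a) == pytest.approx(1.0, abs=1e-12)
        assert math.isnan(view.r_c)

    def test_correlated_factors_reconstruction_identity(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            model = BivariateCholeskyModel()
            model.A_, model.C_, model.E_ = (
                np.tril(rng.normal(size=(2, 2))) + np.eye(2) * 0.5 for _ in range(3)
            )
            V = sum(m @ m.T for m in (model.A_, model.C_, model.E_))
            model.a2_ = np.diag(model.A_ @ model.A_.T) / np.diag(V)
            model.c2_ = np.diag(model.C_ @ model.C_.T) / np.diag(V)
            model.e2_ = np.diag(model.E_ @ model.E_.T) / np.diag(V)
            view = model.to_correlated_factors()
            for r, mat in ((view.r_a, model.A_), (view.r_c, model.C_), (view.r_e, model.E_)):
                cov = mat @ mat.T
                assert r * math.sqrt(cov[0, 0] * cov[1, 1]) == pytest.approx(
                    cov[0, 1], abs=1e-10
                )
            np.testing.assert_allclose(view.a2 + view.c2 + view.e2, 1.0, atol=1e-12)

    def test_unknown_drop_rejected(self):
        with pytest.raises(ValueError, match="drop"):
            BivariateCholeskyModel(drop=("a31",)).fit(
                pd.DataFrame(
                    {
                        "zygosity": ["MZ", "DZ"],
                        "y1_t1": [0.0, 0.1],
                        "y1_t2": [0.0, 0.1],
                        "y2_t1": [0.0, 0.1],
                        "y2_t2": [0.0, 0.1],
                    }
                )
            )


class TestHomogeneityLadder:
    @staticmethod
    def _pairs(order_shift=0.0, n=250, seed=3):
        cfg = SimulationConfig()
        df = simulate_pairs(cfg, rng=np.random.default_rng(seed), n_mz=n, n_dz=n)
        df = df.rename(columns={"liab1_t1": "y_t1", "liab1_t2": "y_t2"})
        df["y_t2"] = df["y_t2"] + order_shift
        rng = np.random.default_rng(seed + 1)
        sexes = rng.choice(["male", "female"], size=(len(df), 2))
        same_sex = df["zygosity"] == "MZ"
        sexes[same_sex.to_numpy(), 1] = sexes[same_sex.to_numpy(), 0]
        df["sex1"], df["sex2"] = sexes[:, 0], sexes[:, 1]
        return df

    def test_nesting_monotone(self):
        ladder = homogeneity_ladder(self._pairs(), n_restarts=1)
        m2ll = ladder["minus2ll"].to_numpy()
        assert (np.diff(m2ll) >= -1e-4).all()
        assert (ladder["n_free_params"].diff().dropna() < 0).all()

    def test_order_mean_shift_detected(self):
        ladder = homogeneity_ladder(self._pairs(order_shift=0.5), n_restarts=1)
        step = ladder.set_index("step").loc["equal_twin_order"]
        # shift of 0.5 sd at 500 pairs: noncentrality ~ 500*0.25/2 >> crit
        assert step["p"] < 1e-6

    def test_null_not_rejected_wildly(self):
        ladder = homogeneity_ladder(self._pairs(seed=8), n_restarts=1)
        assert (ladder["p"].dropna() > 1e-4).all()

    def test_too_few_pairs_skipped_with_warning(self):
        df = self._pairs().iloc[:3]
        df = df[df["zygosity"] == "MZ"]
        with pytest.warns(UserWarning, match="DZ"):
            out = homogeneity_ladder(df)
        assert out.empty
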