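import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from gcsi.cfa import (
    CfaModelSpec,
    add_second_order,
    baseline_df,
    baseline_loglik,
    chi_square,
    count_df,
    fit_cfa,
    fit_indices,
    fit_summary,
    modify_model,
    residual_correlations,
    saturated_loglik,
    severity_factor_scores,
)
from conftest import make_second_order_data


# ---------------------------------------------------------------------------
# brute-force oracles: direct per-row density evaluation, no shared code with
# the pattern-grouped FIML machinery


def oracle_model_loglik(X, fit):
    mvn = multivariate_normal(mean=fit.means, cov=fit.implied_sigma())
    return float(mvn.logpdf(X).sum())


def oracle_saturated_loglik(X):
    mu = X.mean(axis=0)
    S = (X - mu).T @ (X - mu) / len(X)
    return float(multivariate_normal(mean=mu, cov=S).logpdf(X).sum())


def oracle_baseline_loglik(X):
    ll = 0.0
    for j in range(X.shape[1]):
        col = X[:, j]
        ll += norm(loc=col.mean(), scale=col.std(ddof=0)).logpdf(col).sum()
    return float(ll)


class TestModelSpec:
    def test_indicator_in_two_constructs_rejected(self):
        with pytest.raises(ValueError, match="appears in"):
            CfaModelSpec({"a": ("x", "y"), "b": ("y", "z")})

    def test_cross_construct_residual_covariance_rejected(self):
        with pytest.raises(ValueError, match="spans"):
            CfaModelSpec({"a": ("x", "y"), "b": ("z", "w")}, (("x", "z"),))

    def test_second_order_needs_three_constructs(self):
        with pytest.raises(ValueError, match="3 first-order"):
            add_second_order(CfaModelSpec({"a": ("x", "y"), "b": ("z", "w")}))


class TestDegreesOfFreedom:
    def test_final_reported_topology_has_df_40(self):
        # 11 indicators, 3 unit-variance constructs, 3 correlations, 1 residual
        # covariance: 77 moments - 37 free parameters = 40
        spec = CfaModelSpec(
            {
                "governance": ("g1", "g2", "g3", "g4", "g5"),
                "access": ("a1", "a2", "a3"),
                "impact": ("i1", "i2", "i3"),
            },
            residual_covariances=(("g1", "g2"),),
        )
        assert spec.n_free_parameters() == 37
        assert count_df(spec) == 40
        assert count_df(add_second_order(spec)) == 40  # 3 gammas replace 3 correlations

    def test_just_identified_single_construct_df_0(self):
        spec = CfaModelSpec({"a": ("x", "y", "z")})
        assert count_df(spec) == 0

    def test_baseline_df(self):
        assert baseline_df(11) == 55


@pytest.fixture(scope="module")
def fixture_fit():
    rng = np.random.default_rng(7)
    df, _ = make_second_order_data(
        rng, 300, {"a": (0.8, 0.7, 0.6), "b": (0.75, 0.65)}, (0.7, 0.7)
    )
    spec = CfaModelSpec({"a": ("a_1", "a_2", "a_3"), "b": ("b_1", "b_2")})
    fit = fit_cfa(df, spec)
    return df, spec, fit


class TestOracleEquivalence:
    """Complete-data fixtures, <=5 indicators: every reported quantity agrees
    with direct formula evaluation on the sample moments to 1e-6."""

    def test_loglik_matches_per_row_density_sum(self, fixture_fit):
        df, _, fit = fixture_fit
        assert fit.loglik == pytest.approx(oracle_model_loglik(df.to_numpy(), fit), abs=1e-6)

    def test_chi_square_and_indices_match_oracle(self, fixture_fit):
        df, _, fit = fixture_fit
        X = df.to_numpy()
        ll_sat = saturated_loglik(df)
        assert ll_sat == pytest.approx(oracle_saturated_loglik(X), abs=1e-6)
        chi2, model_df = chi_square(fit, ll_sat)
        chi2_oracle = 2 * (oracle_saturated_loglik(X) - oracle_model_loglik(X, fit))
        assert chi2 == pytest.approx(chi2_oracle, abs=1e-6)

        ll_base = baseline_loglik(df)
        assert ll_base == pytest.approx(oracle_baseline_loglik(X), abs=1e-6)
        chi2_b = 2 * (ll_sat - ll_base)
        df_b = baseline_df(5)
        cfi, tli, rmsea = fit_indices(chi2, model_df, chi2_b, df_b, fit.n)
        # independent closed-form evaluation
        cfi_o = 1 - max(chi2_oracle - model_df, 0) / max(chi2_b - df_b, chi2_oracle - model_df, 0)
        tli_o = (chi2_b / df_b - chi2_oracle / model_df) / (chi2_b / df_b - 1)
        rmsea_o = np.sqrt(max(chi2_oracle - model_df, 0) / (model_df * (fit.n - 1)))
        assert cfi == pytest.approx(cfi_o, abs=1e-6)
        assert tli == pytest.approx(tli_o, abs=1e-6)
        assert rmsea == pytest.approx(rmsea_o, abs=1e-6)


class TestFiml:
    def test_complete_data_equals_complete_ml(self, rng):
        """FIML reduces to complete-data ML: an independently parameterized
        direct optimization of the complete-data likelihood attains the same
        maximum."""
        from scipy.optimize import minimize

        df, _ = make_second_order_data(rng, 400, {"a": (0.8, 0.6), "b": (0.7, 0.75)}, (0.8, 0.8))
        spec = CfaModelSpec({"a": ("a_1", "a_2"), "b": ("b_1", "b_2")})
        fit = fit_cfa(df, spec)

        X = df.to_numpy()
        n, p = X.shape

        def neg_ll(theta):
            lam = theta[:4]
            resv = np.exp(theta[4:8])
            r = np.tanh(theta[8])
            mu = theta[9:13]
            L = np.zeros((4, 2))
            L[0, 0], L[1, 0], L[2, 1], L[3, 1] = lam
            phi = np.array([[1, r], [r, 1]])
            sigma = L @ phi @ L.T + np.diag(resv)
            try:
                return -multivariate_normal(mean=mu, cov=sigma).logpdf(X).sum()
            except np.linalg.LinAlgError:
                return 1e10

        x0 = np.r_[np.full(4, 0.6), np.log(np.full(4, 0.4)), 0.3, X.mean(0)]
        res = minimize(neg_ll, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "fatol": 1e-10, "xatol": 1e-8})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-5)

    def test_fiml_close_to_complete_under_mcar(self, rng):
        cs = {"a": (0.8, 0.7, 0.75), "b": (0.7, 0.8, 0.6), "c": (0.75, 0.65, 0.7)}
        df, _ = make_second_order_data(rng, 1000, cs, (0.8, 0.7, 0.6))
        spec = CfaModelSpec(
            {c: tuple(f"{c}_{j + 1}" for j in range(3)) for c in ("a", "b", "c")}
        )
        complete = fit_cfa(df, spec)
        masked = df.mask(np.random.default_rng(5).random(df.shape) < 0.2)
        partial = fit_cfa(masked, spec)
        assert partial.loadings == pytest.approx(complete.loadings, abs=0.08)
        assert partial.converged

    def test_parameter_recovery_three_constructs(self, rng):
        cs = {"a": (0.8, 0.7, 0.75), "b": (0.7, 0.8, 0.6), "c": (0.75, 0.65, 0.7)}
        df, _ = make_second_order_data(rng, 1000, cs, (0.8, 0.7, 0.6))
        spec = CfaModelSpec(
            {c: tuple(f"{c}_{j + 1}" for j in range(3)) for c in ("a", "b", "c")}
        )
        fit = fit_cfa(df, spec)
        true = np.array([l for lams in cs.values() for l in lams])
        assert fit.standardized_loadings().to_numpy() == pytest.approx(true, abs=0.05)

    def test_chi_square_invariant_to_reordering_and_sign_flips(self, rng):
        df, _ = make_second_order_data(rng, 300, {"a": (0.8, 0.7), "b": (0.7, 0.6)}, (0.8, 0.8))
        spec = CfaModelSpec({"a": ("a_1", "a_2"), "b": ("b_1", "b_2")})
        ll_sat = saturated_loglik(df)
        chi2, _ = chi_square(fit_cfa(df, spec), ll_sat)
        flipped = df.copy()
        flipped["a_1"] = -flipped["a_1"]
        cols = ["b_2", "a_1", "b_1", "a_2"]
        spec2 = CfaModelSpec({"b": ("b_2", "b_1"), "a": ("a_1", "a_2")})
        chi2_f, _ = chi_square(fit_cfa(flipped[cols], spec2), saturated_loglik(flipped[cols]))
        assert chi2_f == pytest.approx(chi2, abs=1e-5)

    def test_just_identified_model_chi_square_zero(self, rng):
        df, _ = make_second_order_data(rng, 200, {"a": (0.8, 0.7, 0.6)}, (0.7,))
        spec = CfaModelSpec({"a": ("a_1", "a_2", "a_3")})
        fit = fit_cfa(df, spec)
        chi2, model_df = chi_square(fit, saturated_loglik(df))
        assert model_df == 0
        assert chi2 == pytest.approx(0.0, abs=1e-5)

    def test_standardized_loadings_bounded(self, rng):
        df, _ = make_second_order_data(rng, 500, {"a": (0.9, 0.8), "b": (0.85, 0.7)}, (0.8, 0.8))
        fit = fit_cfa(df, CfaModelSpec({"a": ("a_1", "a_2"), "b": ("b_1", "b_2")}))
        assert np.all(np.abs(fit.standardized_loadings()) <= 1.0)


class TestFitIndices:
    def test_perfect_fit(self):
        cfi, tli, rmsea = fit_indices(40.0, 40, 500.0, 55, 172)
        assert rmsea == 0.0
        assert cfi == 1.0

    def test_tli_closed_form(self):
        # baseline chi2/df = 5, model chi2/df = 1 -> TLI = 1
        _, tli, _ = fit_indices(40.0, 40, 275.0, 55, 172)
        assert tli == pytest.approx(1.0)

    def test_rmsea_reported_scale(self):
        # chi2 107 on 40 df with 172 crises -> sqrt(67 / (40*171)) = 0.0990
        _, _, rmsea = fit_indices(107.0, 40, 1500.0, 55, 172)
        assert rmsea == pytest.approx(np.sqrt(67 / (40 * 171)))
        assert round(rmsea, 2) == 0.10

    def test_malformed_baseline_warns(self):
        with pytest.warns(UserWarning, match="baseline"):
            fit_indices(10.0, 5, 8.0, 4, 100)


class TestSecondOrder:
    def test_fit_statistics_match_first_order_with_three_constructs(self, rng):
        cs = {"a": (0.8, 0.7, 0.75), "b": (0.7, 0.8, 0.6), "c": (0.75, 0.65, 0.7)}
        df, _ = make_second_order_data(rng, 500, cs, (0.73, 0.56, 0.40))
        spec = CfaModelSpec(
            {c: tuple(f"{c}_{j + 1}" for j in range(3)) for c in ("a", "b", "c")}
        )
        ll_sat = saturated_loglik(df)
        chi1, df1 = chi_square(fit_cfa(df, spec), ll_sat)
        chi2_, df2 = chi_square(fit_cfa(df, add_second_order(spec)), ll_sat)
        assert df1 == df2
        assert chi2_ == pytest.approx(chi1, abs=1e-6)

    def test_gamma_recovery(self, rng):
        cs = {"a": (0.85, 0.8, 0.75, 0.8), "b": (0.8, 0.85, 0.75, 0.8), "c": (0.8, 0.75, 0.85, 0.8)}
        gammas = (0.8, 0.65, 0.5)
        dfs = []
        ests = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            df, _ = make_second_order_data(r, 2000, cs, gammas)
            spec = add_second_order(
                CfaModelSpec({c: tuple(f"{c}_{j + 1}" for j in range(4)) for c in ("a", "b", "c")})
            )
            ests.append(fit_cfa(df, spec).second_order_loadings)
        assert np.mean(ests, axis=0) == pytest.approx(gammas, abs=0.05)


class TestResidualsAndModification:
    def test_no_flags_on_data_from_the_model(self, rng):
        cs = {"a": (0.8, 0.7, 0.75), "b": (0.7, 0.8, 0.6), "c": (0.75, 0.65, 0.7)}
        df, _ = make_second_order_data(rng, 5000, cs, (0.8, 0.7, 0.6))
        spec = CfaModelSpec(
            {c: tuple(f"{c}_{j + 1}" for j in range(3)) for c in ("a", "b", "c")}
        )
        report = residual_correlations(fit_cfa(df, spec), df)
        assert report.cross_construct_flags == ()
        assert report.within_construct_flags == ()
        assert np.abs(np.diag(report.residuals.to_numpy())).max() < 1e-6

    def test_injected_within_construct_covariance_flagged_and_found(self, rng):
        # six indicators anchor the construct so the doublet between a_1 and
        # a_2 cannot be absorbed into the loadings
        cs = {"a": (0.6, 0.6, 0.6, 0.7, 0.65, 0.6), "b": (0.7, 0.65, 0.6),
              "c": (0.7, 0.65, 0.6)}
        df, _ = make_second_order_data(
            rng, 4000, cs, (0.8, 0.7, 0.6), residual_pairs=(("a_1", "a_2", 0.25),)
        )
        spec = CfaModelSpec(
            {"a": tuple(f"a_{j}" for j in range(1, 7)), "b": ("b_1", "b_2", "b_3"),
             "c": ("c_1", "c_2", "c_3")}
        )
        report = residual_correlations(fit_cfa(df, spec), df)
        flagged = {frozenset((a, b)) for a, b, _ in report.within_construct_flags}
        assert frozenset(("a_1", "a_2")) in flagged

        final_spec, final_fit, log = modify_model(df, spec, budget=5)
        assert [e["action"] for e in log] == ["add_residual_covariance"]
        assert tuple(sorted(log[0]["target"])) == ("a_1", "a_2")
        assert final_spec.residual_covariances == (("a_1", "a_2"),)
        # the recovered extra covariance is close to the injected 0.25
        ids = final_spec.indicator_ids
        i, j = ids.index("a_1"), ids.index("a_2")
        assert final_fit.theta[i, j] == pytest.approx(0.25, abs=0.06)

    def test_modification_fixed_point(self, rng):
        cs = {"a": (0.8, 0.7, 0.75), "b": (0.7, 0.8, 0.6), "c": (0.75, 0.65, 0.7)}
        df, _ = make_second_order_data(rng, 5000, cs, (0.8, 0.7, 0.6))
        spec = CfaModelSpec(
            {c: tuple(f"{c}_{j + 1}" for j in range(3)) for c in ("a", "b", "c")}
        )
        final_spec, _, log = modify_model(df, spec, budget=5)
        assert log == []
        assert final_spec.constructs == spec.constructs

    def test_cross_construct_offender_removed(self, rng):
        # a_1 shares extra variance with b_1 across constructs: the engine
        # must remove one of them (the rule forbids cross-construct
        # covariances)
        n = 4000
        sev = rng.standard_normal(n)
        u = rng.standard_normal(n)
        cols = {}
        lams = (0.6, 0.65, 0.6, 0.7, 0.65)  # five anchors per construct
        for c, g in zip("abc", (0.8, 0.7, 0.6)):
            f = g * sev + np.sqrt(1 - g * g) * rng.standard_normal(n)
            for j, lam in enumerate(lams):
                extra = 0.3 if (c in "ab" and j == 0) else 0.0
                y = lam * f + np.sqrt(1 - lam**2 - extra) * rng.standard_normal(n)
                if extra:
                    y = y + np.sqrt(extra) * u
                cols[f"{c}_{j + 1}"] = y
        df = pd.DataFrame(cols)
        spec = CfaModelSpec(
            {c: tuple(f"{c}_{j + 1}" for j in range(5)) for c in ("a", "b", "c")}
        )
        final_spec, _, log = modify_model(df, spec, budget=5)
        removed = {e["target"] for e in log if e["action"] == "remove_indicator"}
        assert removed & {"a_1", "b_1"}


class TestSeverityScores:
    def test_normalization_and_recovery_strong_loadings(self, rng):
        cs = {"a": (0.95, 0.9, 0.9, 0.9), "b": (0.9, 0.95, 0.9, 0.9), "c": (0.9, 0.9, 0.95, 0.9)}
        gammas = (0.95, 0.92, 0.9)
        df, sev = make_second_order_data(rng, 1000, cs, gammas)
        spec = add_second_order(
            CfaModelSpec({c: tuple(f"{c}_{j + 1}" for j in range(4)) for c in ("a", "b", "c")})
        )
        fit = fit_cfa(df, spec)
        scores = severity_factor_scores(fit, df)
        assert np.nanmin(scores.normalized) == 0.0
        assert np.nanmax(scores.normalized) == 1.0
        corr = np.corrcoef(scores.raw, sev)[0, 1]
        assert corr > 0.9
        # and the estimate sits at the model's information ceiling
        lam = fit.lambda_matrix()
        c = lam @ fit.second_order_loadings
        ceiling = np.sqrt(c @ np.linalg.inv(fit.implied_sigma()) @ c)
        assert corr == pytest.approx(ceiling, abs=0.03)

    def test_missing_cells_scored_from_observed_subset(self, rng):
        cs = {"a": (0.9, 0.85, 0.8), "b": (0.85, 0.8, 0.9), "c": (0.8, 0.9, 0.85)}
        df, sev = make_second_order_data(rng, 800, cs, (0.9, 0.85, 0.8), missing_rate=0.2)
        spec = add_second_order(
            CfaModelSpec({c: tuple(f"{c}_{j + 1}" for j in range(3)) for c in ("a", "b", "c")})
        )
        scores = severity_factor_scores(fit_cfa(df, spec), df)
        assert np.isfinite(scores.raw).all()
        assert np.corrcoef(scores.raw, sev)[0, 1] > 0.8

    def test_first_order_fit_has_no_severity_scores(self, rng):
        df, _ = make_second_order_data(rng, 100, {"a": (0.8, 0.7), "b": (0.7, 0.6)}, (0.8, 0.8))
        fit = fit_cfa(df, CfaModelSpec({"a": ("a_1", "a_2"), "b": ("b_1", "b_2")}))
        with pytest.raises(ValueError, match="second-order"):
            severity_factor_scores(fit, df)
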