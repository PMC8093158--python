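"""FIML and moment-based estimation of the structured twin model."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from twinreg import datasets
from twinreg.estimation import (
    ComponentModelSpec,
    ParameterVector,
    fiml_loglik,
    fit_fiml,
    fit_moments,
    parameter_uncertainty,
    profile_interval,
    share_target,
)
from twinreg.exceptions import DataError, NotPositiveDefiniteError
from twinreg.model import (
    DEFAULT_ORDER,
    ComponentEstimates,
    MeanModel,
    TwinDataset,
    expected_twin_covariance,
)
from twinreg.simulate import SimulationConfig, simulate_twins


def brute_force_loglik(data, theta, spec):
    """Per-record oracle: subset the mean and covariance, call scipy's density."""
    comps, means = spec.unpack(theta)
    sigma = {z: expected_twin_covariance(comps, z) for z in ("MZ", "DZ")}
    y = data.phenotype_matrix()
    df = data.df
    ll = 0.0
    for i in range(len(df)):
        obs = np.flatnonzero(~np.isnan(y[i]))
        if obs.size == 0:
            continue
        mu = means.expected_means([df.sex1[i]], [df.sex2[i]], [df.age[i]])[0]
        s = sigma[df.zygosity[i]][np.ix_(obs, obs)]
        ll += multivariate_normal.logpdf(y[i, obs], mu[obs], s)
    return ll


def random_theta(spec, seed):
    rng = np.random.default_rng(seed)
    return np.concatenate(
        [rng.uniform(0.4, 1.2, spec.n_component_params), rng.normal(0, 0.5, 9)]
    )


class TestSpecAndParameterVector:
    def test_children_spec_free_cell_count(self, children_spec):
        # full A (6) + single-factor C (3) + predictors-only D (3) + full E (6)
        assert children_spec.n_component_params == 18
        assert len(children_spec.parameter_names()) == 27

    def test_roundtrip_through_index_map(self, children_spec):
        theta = random_theta(children_spec, 0)
        pv = ParameterVector(children_spec, theta)
        series = pv.as_series()
        assert pv["a11"] == series["a11"]
        comps, means = pv.unpack()
        lam = comps.factors["A"]
        assert lam[0, 0] == pytest.approx(pv["a11"])
        assert means.intercept[0] == pytest.approx(pv["b0_aggression"])
        # factors reproduce the component matrices exactly
        for lab, lamm in comps.factors.items():
            np.testing.assert_allclose(comps.component(lab), lamm @ lamm.T)


class TestFimlLoglik:
    def test_standard_normal_at_origin(self):
        # one complete pair, expected covariance I6, zero means, data at zero
        spec = ComponentModelSpec.ae()
        theta = np.zeros(21)
        theta[[6, 8, 11]] = 1.0  # E = I; A = 0 so the cross-twin block vanishes
        df = {
            "pair_id": ["p1"], "zygosity": ["MZ"], "sex1": [0], "sex2": [0], "age": [0.0],
        }
        import pandas as pd

        for c in TwinDataset.phenotype_columns(DEFAULT_ORDER):
            df[c] = [0.0]
        data = TwinDataset(pd.DataFrame(df))
        ll = fiml_loglik(data, theta, spec)
        assert ll == pytest.approx(-3 * math.log(2 * math.pi), abs=1e-10)

    def test_single_twin_record_equals_trivariate_marginal(self, children_spec):
        cfg = datasets.children_simulation_config(seed=1, n_mz=5, n_dz=5)
        data, _ = simulate_twins(cfg)
        df = data.df.copy()
        for c in ["aggression2", "hyperactivity2", "inattention2"]:
            df[c] = np.nan
        data1 = TwinDataset(df)
        theta = random_theta(children_spec, 3)
        comps, means = children_spec.unpack(theta)
        y = data1.phenotype_matrix()
        expected = 0.0
        for i in range(len(df)):
            mu = means.expected_means([df.sex1[i]], [df.sex2[i]], [df.age[i]])[0][:3]
            s = expected_twin_covariance(comps, df.zygosity[i])[:3, :3]
            expected += multivariate_normal.logpdf(y[i, :3], mu, s)
        assert fiml_loglik(data1, theta, children_spec) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed, children_spec, small_children_data):
        data, _ = small_children_data
        theta = random_theta(children_spec, seed)
        ll = fiml_loglik(data, theta, children_spec)
        assert ll == pytest.approx(brute_force_loglik(data, theta, children_spec), abs=1e-8)

    def test_analytic_gradient_matches_finite_differences(self, children_spec, small_children_data):
        from twinreg.estimation import _FimlEvaluator

        data, _ = small_children_data
        ev = _FimlEvaluator(data, children_spec)
        theta = random_theta(children_spec, 5)
        _, grad = ev.loglik_and_grad(theta)
        for i in [0, 4, 9, 17, 18, 22, 26]:
            h = 1e-6 * max(abs(theta[i]), 1.0)
            e = np.zeros_like(theta)
            e[i] = h
            fd = (ev.loglik(theta + e) - ev.loglik(theta - e)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_non_pd_subcovariance_names_the_record(self, children_spec, small_children_data):
        data, _ = small_children_data
        theta = np.zeros(27)  # all factors zero -> singular covariance
        with pytest.raises(NotPositiveDefiniteError, match="pair"):
            fiml_loglik(data, theta, children_spec)


class TestFitFiml:
    def test_ae_totals_recovered(self):
        comps = ComponentEstimates.from_sigmas(
            DEFAULT_ORDER,
            {
                "A": np.array([[2.0, 0.8, 0.5], [0.8, 1.5, 0.6], [0.5, 0.6, 1.0]]),
                "E": np.array([[1.0, 0.2, 0.1], [0.2, 1.2, 0.3], [0.1, 0.3, 0.9]]),
            },
        )
        cfg = SimulationConfig(components=comps, means=MeanModel.zero(), n_mz=800,
                               n_dz=800, age_mean=0.0, age_sd=0.0, seed=9)
        data, _ = simulate_twins(cfg)
        fit = fit_fiml(data, ComponentModelSpec.ae(), n_starts=1, compute_cov=False)
        assert fit.converged
        np.testing.assert_allclose(fit.components.sigma_ph, comps.sigma_ph, atol=0.15)

    def test_entirely_missing_phenotype_rejected(self, children_spec, small_children_data):
        data, _ = small_children_data
        df = data.df.copy()
        df["inattention1"] = np.nan
        df["inattention2"] = np.nan
        with pytest.raises(DataError, match="inattention"):
            fit_fiml(TwinDataset(df), children_spec)

    def test_too_few_pairs_rejected(self, children_spec):
        cfg = datasets.children_simulation_config(seed=0, n_mz=1, n_dz=5)
        data, _ = simulate_twins(cfg)
        with pytest.raises(DataError, match="at least 2"):
            fit_fiml(data, children_spec)

    def test_refit_from_solution_is_idempotent(self, children_spec, small_children_data):
        data, _ = small_children_data
        fit = fit_fiml(data, children_spec, n_starts=1, compute_cov=False)
        refit = fit_fiml(data, children_spec, start=fit.params, n_starts=1, compute_cov=False)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-4)
        np.testing.assert_allclose(refit.components.sigma_ph, fit.components.sigma_ph, atol=1e-3)

    def test_invariance_to_pair_order_and_mz_twin_swap(self, children_spec, small_children_data):
        data, _ = small_children_data
        theta = random_theta(children_spec, 11)
        base = fiml_loglik(data, theta, children_spec)
        # shuffled pair order
        shuffled = TwinDataset(data.df.sample(frac=1.0, random_state=0), data.order)
        assert fiml_loglik(shuffled, theta, children_spec) == pytest.approx(base, abs=1e-8)
        # swap twin 1 / twin 2 within MZ pairs (phenotypes and sexes together)
        df = data.df.copy()
        mz = df["zygosity"] == "MZ"
        for lab in data.order.labels:
            df.loc[mz, [f"{lab}1", f"{lab}2"]] = df.loc[mz, [f"{lab}2", f"{lab}1"]].to_numpy()
        df.loc[mz, ["sex1", "sex2"]] = df.loc[mz, ["sex2", "sex1"]].to_numpy()
        assert fiml_loglik(TwinDataset(df), theta, children_spec) == pytest.approx(base, abs=1e-8)

    def test_complete_data_fiml_agrees_with_moment_fit(self, children_spec):
        cfg = SimulationConfig(components=datasets.children_components(),
                               means=MeanModel.zero(), n_mz=1500, n_dz=1500,
                               age_mean=0.0, age_sd=0.0, seed=7)
        data, _ = simulate_twins(cfg)
        f1 = fit_fiml(data, children_spec, n_starts=1, compute_cov=False)
        y = data.phenotype_matrix()
        zyg = data.df["zygosity"].to_numpy()
        s_mz = np.cov(y[zyg == "MZ"].T, ddof=0)
        s_dz = np.cov(y[zyg == "DZ"].T, ddof=0)
        f2 = fit_moments(s_mz, s_dz, 1500, 1500, children_spec, n_starts=1, compute_cov=False)
        np.testing.assert_allclose(f1.components.sigma_ph, f2.components.sigma_ph, atol=0.02)
        np.testing.assert_allclose(
            f1.components.component("A"), f2.components.component("A"), atol=0.05
        )


class TestFitMoments:
    def test_saturated_recovery(self, adult_components):
        s_mz = expected_twin_covariance(adult_components, "MZ")
        s_dz = expected_twin_covariance(adult_components, "DZ")
        fit = fit_moments(s_mz, s_dz, 1000, 1000, ComponentModelSpec.adults_ade(),
                          n_starts=2, compute_cov=False)
        assert fit.diagnostics["discrepancy"] == pytest.approx(0.0, abs=1e-3)
        for lab in "ADE":
            np.testing.assert_allclose(
                fit.components.component(lab), adult_components.component(lab), atol=0.02
            )

    def test_children_summary_tables_recover_published_heritability(self, children_spec):
        # fitting the published twin correlation/SD tables lands near the
        # published Agg heritability (the original fit used raw records with
        # covariates, so agreement is approximate)
        mi = datasets.children_summary_moments()
        fit = fit_moments(mi.s_mz, mi.s_dz, mi.n_mz, mi.n_dz, children_spec,
                          n_starts=1, compute_cov=False)
        shares = fit.standardized_shares()
        assert shares.loc["aggression", "h2"] == pytest.approx(0.717, abs=0.05)

    def test_jittered_moments_give_positive_discrepancy(self, adult_components):
        rng = np.random.default_rng(0)
        s_mz = expected_twin_covariance(adult_components, "MZ")
        s_dz = expected_twin_covariance(adult_components, "DZ")
        noise = rng.standard_normal((6, 6)) * 0.01 * np.sqrt(np.outer(np.diag(s_mz), np.diag(s_mz)))
        s_mz_j = s_mz + 0.5 * (noise + noise.T)
        fit = fit_moments(s_mz_j, s_dz, 1000, 1000, ComponentModelSpec.adults_ade(),
                          n_starts=1, compute_cov=False)
        assert fit.diagnostics["discrepancy"] > 0.1

    def test_non_pd_input_rejected(self, children_spec):
        bad = np.eye(6)
        bad[0, 0] = -1.0
        with pytest.raises(NotPositiveDefiniteError):
            fit_moments(bad, np.eye(6), 100, 100, children_spec)


@pytest.fixture(scope="module")
def ae_fitted():
    # a well-identified AE model keeps the information matrix regular
    # (the children pattern's near-rank-1 additive matrix does not)
    comps = ComponentEstimates.from_sigmas(
        DEFAULT_ORDER,
        {
            "A": np.array([[2.0, 0.8, 0.5], [0.8, 1.5, 0.6], [0.5, 0.6, 1.0]]),
            "E": np.array([[1.0, 0.2, 0.1], [0.2, 1.2, 0.3], [0.1, 0.3, 0.9]]),
        },
    )
    mm = MeanModel(DEFAULT_ORDER, (1.0, 2.0, 3.0), (-0.5, 0.2, 0.1), (0.05, -0.1, 0.0))
    cfg = SimulationConfig(components=comps, means=mm, n_mz=400, n_dz=400,
                           age_mean=10.0, age_sd=1.0, seed=21)
    data, _ = simulate_twins(cfg)
    return fit_fiml(data, ComponentModelSpec.ae(), n_starts=1)


class TestUncertainty:
    @pytest.fixture()
    def fitted(self, ae_fitted):
        return ae_fitted

    def test_identity_target_equals_information_se(self, fitted):
        assert fitted.param_cov is not None
        table = parameter_uncertainty(fitted)
        se = fitted.parameter_se()
        for name in ("a11", "e11", "b0_aggression"):
            assert table.loc[name, "se"] == pytest.approx(se[name], rel=1e-4)

    def test_interval_ordering(self, fitted):
        targets = {
            "h2_agg": share_target(fitted.spec, "A", "aggression"),
            "e2_ha": share_target(fitted.spec, "E", "hyperactivity"),
        }
        table = parameter_uncertainty(fitted, targets)
        for _, row in table.iterrows():
            assert row["lower"] < row["estimate"] < row["upper"]
            assert row["se"] > 0

    def test_profile_interval_brackets_estimate(self, adult_components):
        s_mz = expected_twin_covariance(adult_components, "MZ")
        s_dz = expected_twin_covariance(adult_components, "DZ")
        fit = fit_moments(s_mz, s_dz, 300, 300, ComponentModelSpec.adults_ade(), n_starts=1)
        lo, hi = profile_interval(fit, "e11", level=0.95)
        assert lo < fit.params["e11"] < hi
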