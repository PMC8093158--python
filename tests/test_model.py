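"""Covariance algebra of the structured twin model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinreg.exceptions import StructuralViolationError
from twinreg.model import (
    DEFAULT_ORDER,
    TRANSCRIPTION_TOL,
    ComponentEstimates,
    FactorPattern,
    MeanModel,
    PhenotypeOrder,
    TwinDataset,
    build_component_matrix,
    expected_twin_covariance,
    rank_diagnostics,
    standardize_components,
)

lower_tri_values = st.lists(
    st.floats(-5, 5, allow_nan=False), min_size=6, max_size=6
)


def triple_loop_product(lam):
    """Elementwise oracle for Lambda Lambda^t."""
    out = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                out[i, j] += lam[i][k] * lam[j][k]
    return out


class TestFactorPatterns:
    def test_children_c_pattern_reproduces_published_matrix(self):
        # single shared-environment factor: the published loadings give back
        # the published covariance matrix up to printed rounding
        pattern = FactorPattern.single_factor("C")
        sigma = build_component_matrix(pattern, [1.364, 0.323, 0.484])
        expected = np.array([[1.86, 0.44, 0.66], [0.44, 0.104, 0.156], [0.66, 0.156, 0.234]])
        np.testing.assert_allclose(sigma, expected, atol=0.01)

    def test_identity_factor_gives_identity(self):
        sigma = build_component_matrix(FactorPattern.full_cholesky("A"), np.eye(3)[np.tril_indices(3)])
        np.testing.assert_allclose(sigma, np.eye(3))

    @given(vals=lower_tri_values)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_triple_loop_oracle(self, vals):
        pattern = FactorPattern.full_cholesky("E")
        lam = pattern.build_factor(vals)
        np.testing.assert_allclose(build_component_matrix(pattern, vals), triple_loop_product(lam), atol=1e-12)

    @given(vals=lower_tri_values)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_never_meaningfully_indefinite(self, vals):
        sigma = build_component_matrix(FactorPattern.full_cholesky("A"), vals)
        w = np.linalg.eigvalsh(sigma)
        assert w[0] >= -1e-8 * max(w[-1], 1.0)

    def test_value_for_fixed_cell_is_structural_violation(self):
        pattern = FactorPattern.predictors_only("D")
        with pytest.raises(StructuralViolationError):
            pattern.build_factor({(0, 0): 1.0, (1, 1): 1.0, (2, 1): 0.5, (2, 2): 1.0})

    def test_upper_triangle_always_fixed(self):
        with pytest.raises(StructuralViolationError):
            FactorPattern("A", ((False, True, False),) * 3)

    @given(
        c_vals=st.lists(st.floats(-3, 3, allow_nan=False), min_size=3, max_size=3),
        d_vals=st.lists(st.floats(-3, 3, allow_nan=False), min_size=3, max_size=3),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_structured_pattern_rank_bounds(self, c_vals, d_vals):
        # single-factor C is rank <= 1, predictors-only D rank <= 2, at 1e-9
        sigma_c = build_component_matrix(FactorPattern.single_factor("C"), c_vals)
        sigma_d = build_component_matrix(FactorPattern.predictors_only("D"), d_vals)
        assert rank_diagnostics(sigma_c, tol=1e-9).rank <= 1
        assert rank_diagnostics(sigma_d, tol=1e-9).rank <= 2


class TestExpectedTwinCovariance:
    def test_all_zero_components(self):
        comps = ComponentEstimates.from_sigmas(
            DEFAULT_ORDER, {lab: np.zeros((3, 3)) for lab in "ACDE"}
        )
        np.testing.assert_array_equal(expected_twin_covariance(comps, "MZ"), np.zeros((6, 6)))

    def test_dz_additive_weight(self):
        comps = ComponentEstimates.from_sigmas(DEFAULT_ORDER, {"A": np.eye(3)})
        sigma = expected_twin_covariance(comps, "DZ")
        np.testing.assert_allclose(sigma[:3, 3:], 0.5 * np.eye(3))
        np.testing.assert_allclose(sigma[:3, :3], np.eye(3))

    def test_children_within_person_block_matches_component_sums(self, children_components):
        sigma = expected_twin_covariance(children_components, "MZ")
        # Agg phenotypic variance is the sum of the published component variances
        assert sigma[0, 0] == pytest.approx(16.20 + 1.86 + 4.50, abs=1e-10)
        np.testing.assert_allclose(sigma[:3, :3], children_components.sigma_ph)
        np.testing.assert_allclose(sigma, sigma.T)

    def test_mz_dz_cross_block_difference(self, children_components):
        mz = expected_twin_covariance(children_components, "MZ")
        dz = expected_twin_covariance(children_components, "DZ")
        expected = 0.5 * children_components.component("A") + 0.75 * children_components.component("D")
        np.testing.assert_allclose((mz - dz)[:3, 3:], expected, atol=1e-12)

    def test_unknown_zygosity_rejected(self, children_components):
        with pytest.raises(ValueError, match="zygosity"):
            expected_twin_covariance(children_components, "OS")


class TestStandardization:
    def test_children_aggression_shares(self, children_components):
        shares = standardize_components(children_components)
        assert shares.loc["aggression", "h2"] == pytest.approx(16.20 / 22.56, abs=1e-12)
        assert shares.loc["aggression", "h2"] == pytest.approx(0.717, abs=0.002)
        assert shares.loc["aggression", "c2"] == pytest.approx(0.082, abs=0.001)

    def test_adult_aggression_dominance_share(self, adult_components):
        shares = standardize_components(adult_components)
        assert shares.loc["aggression", "d2"] == pytest.approx(2.94 / (2.36 + 2.94 + 5.95), abs=1e-12)
        assert shares.loc["aggression", "d2"] == pytest.approx(0.260, abs=0.002)

    def test_equal_components_give_quarter_shares(self):
        comps = ComponentEstimates.from_sigmas(DEFAULT_ORDER, {lab: np.eye(3) for lab in "ACDE"})
        shares = standardize_components(comps)
        np.testing.assert_allclose(shares.to_numpy(), 0.25)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shares_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        sigmas = {}
        for lab in "ACDE":
            a = rng.standard_normal((3, 3))
            sigmas[lab] = a @ a.T + 0.1 * np.eye(3)
        comps = ComponentEstimates.from_sigmas(DEFAULT_ORDER, sigmas)
        shares = standardize_components(comps)
        np.testing.assert_allclose(shares.sum(axis=1).to_numpy(), 1.0, atol=1e-10)

    def test_zero_total_variance_rejected(self):
        comps = ComponentEstimates.from_sigmas(DEFAULT_ORDER, {"A": np.zeros((3, 3))})
        with pytest.raises(ValueError, match="total variance"):
            standardize_components(comps)


class TestRankDiagnostics:
    def test_identity(self):
        d = rank_diagnostics(np.eye(3))
        assert d.eigenvalues == (1.0, 1.0, 1.0)
        assert d.rank == 3

    def test_outer_product_is_rank_one(self):
        v = np.array([1.2, -0.7, 3.1])
        d = rank_diagnostics(np.outer(v, v))
        assert d.rank == 1
        assert d.leading == pytest.approx(v @ v, rel=1e-12)

    def test_children_additive_matrix_nearly_rank_one(self, children_components):
        d = rank_diagnostics(children_components.component("A"), tol=TRANSCRIPTION_TOL)
        assert d.leading == pytest.approx(21.99, abs=0.05)
        assert d.rank == 1

    def test_asymmetric_input_rejected(self):
        m = np.array([[1.0, 0.5, 0.0], [0.2, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            rank_diagnostics(m)


class TestMeanModelAndDataset:
    def test_mean_model_applies_per_twin_sex(self):
        mm = MeanModel(DEFAULT_ORDER, (1.0, 2.0, 3.0), (-1.0, -0.5, 0.5), (0.1, 0.0, 0.0))
        mu = mm.expected_means([0, 1], [1, 1], [10.0, 20.0])
        assert mu.shape == (2, 6)
        assert mu[0, 0] == pytest.approx(1.0 + 0.1 * 10)        # twin 1, male
        assert mu[0, 3] == pytest.approx(1.0 - 1.0 + 0.1 * 10)  # twin 2, female
        assert mu[1, 1] == pytest.approx(2.0 - 0.5)

    def test_phenotype_order_validation(self):
        with pytest.raises(ValueError):
            PhenotypeOrder(("a", "a", "b"))

    def test_dataset_rejects_duplicate_pair_ids(self, small_children_data):
        data, _ = small_children_data
        df = data.df.copy()
        df.loc[1, "pair_id"] = df.loc[0, "pair_id"]
        with pytest.raises(Exception, match="duplicate"):
            TwinDataset(df, data.order)

    def test_dataset_rejects_unknown_zygosity(self, small_children_data):
        data, _ = small_children_data
        df = data.df.copy()
        df.loc[3, "zygosity"] = "OS"
        with pytest.raises(Exception, match="OS"):
            TwinDataset(df, data.order)
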