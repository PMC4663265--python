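import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import affine_transform_class, random_class, random_coefficients, random_model
from semstd.implied_variance import class_eta_variance
from semstd.mc_oracle import SimulationConfig, empirical_standardize, sample_latent
from semstd.model_params import (
    LatentClassParams,
    MixtureModel,
    StructuralCoefficients,
    pair_indices,
    validate_model,
)
from semstd.standardize import (
    solution_table,
    standardize_pooled,
    standardize_reference,
    standardize_within,
    standardized_mean_difference,
)


def _single(c):
    return validate_model(
        MixtureModel(classes=(LatentClassParams(1.0, c.kappa, c.phi, c.coefficients),))
    )


def test_within_solution_matches_published_direct_estimates(direct_model):
    s = standardize_within(direct_model.classes[0])
    assert s.gamma_lin_std[0] == pytest.approx(0.122, abs=0.002)
    assert s.gamma_quad_std[0, 1] == pytest.approx(-0.079, abs=0.002)
    assert s.gamma_quad_std[0, 0] == pytest.approx(-0.058, abs=0.002)
    assert s.psi_std == pytest.approx(0.942, abs=0.002)
    assert s.r_squared == pytest.approx(1 - s.psi_std, abs=1e-12)
    np.testing.assert_allclose(s.kappa_std, 0.0, atol=1e-14)
    np.testing.assert_allclose(np.diag(s.phi_std), 1.0, atol=1e-12)


def test_pooled_indirect_matches_published_estimates(indirect_model):
    s = standardize_pooled(indirect_model)
    assert s.gamma_lin_std[0] == pytest.approx(0.514, abs=0.002)
    assert s.gamma_quad_std[1, 1] == pytest.approx(-0.085, abs=0.002)
    assert s.frame == "pooled"


def test_pooled_multigroup_matches_published_estimates(gender_model):
    female, male = standardize_pooled(gender_model)
    assert female.gamma_lin_std[0] == pytest.approx(0.474, abs=0.002)
    assert female.gamma_quad_std[1, 1] == pytest.approx(-0.181, abs=0.002)
    assert female.kappa_std[0] == pytest.approx(0.266, abs=0.002)
    assert male.gamma_lin_std[0] == pytest.approx(0.587, abs=0.002)
    # common denominator across groups
    assert female.eta_variance == pytest.approx(male.eta_variance)


def test_within_multigroup_matches_published_estimates(gender_model):
    s = standardize_within(gender_model.classes[0])
    assert s.gamma_lin_std[0] == pytest.approx(0.527, abs=0.002)
    assert s.gamma_quad_std[1, 1] == pytest.approx(-0.141, abs=0.002)


@given(st.integers(0, 10_000))
def test_linear_model_reduces_to_classic_formula_and_ignores_means(seed):
    """Without product terms the classic sqrt-variance-ratio formula applies
    and the result cannot depend on the predictor means."""
    rng = np.random.default_rng(seed)
    co = random_coefficients(rng, 2, linear_only=True)
    c = random_class(rng, 2, coefficients=co)
    s = standardize_within(c)
    v = class_eta_variance(c)
    expected = co.gamma_lin * np.sqrt(np.diag(c.phi)) / np.sqrt(v)
    np.testing.assert_allclose(s.gamma_lin_std, expected, atol=1e-12)
    shifted = LatentClassParams(c.weight, c.kappa + rng.uniform(-3, 3, 2), c.phi, co)
    np.testing.assert_allclose(
        standardize_within(shifted).gamma_lin_std, s.gamma_lin_std, atol=1e-12
    )


@given(st.integers(0, 10_000))
def test_affine_invariance_of_standardized_solution(seed):
    rng = np.random.default_rng(seed)
    c = random_class(rng, 2)
    a = rng.uniform(0.5, 2.0, size=2)
    b = rng.uniform(-1.5, 1.5, size=2)
    s = standardize_within(c)
    st_ = standardize_within(affine_transform_class(c, a, b))
    np.testing.assert_allclose(st_.gamma_lin_std, s.gamma_lin_std, atol=1e-9)
    np.testing.assert_allclose(st_.gamma_quad_std, s.gamma_quad_std, atol=1e-9)
    assert st_.psi_std == pytest.approx(s.psi_std, abs=1e-9)
    assert st_.r_squared == pytest.approx(s.r_squared, abs=1e-9)


def test_single_class_pooled_equals_within(direct_model):
    c = direct_model.classes[0]
    m = _single(c)
    s_within = standardize_within(c)
    s_pooled = standardize_pooled(m)[0]
    np.testing.assert_allclose(s_pooled.gamma_lin_std, s_within.gamma_lin_std, atol=1e-12)
    np.testing.assert_allclose(s_pooled.gamma_quad_std, s_within.gamma_quad_std, atol=1e-12)
    assert s_pooled.psi_std == pytest.approx(s_within.psi_std, abs=1e-12)


def test_reference_frame_reductions(gender_model):
    c = gender_model.classes[0]
    # the only class of a G=1 model is its own reference
    m1 = _single(c)
    ref = standardize_reference(m1, 0)[0]
    w = standardize_within(c)
    np.testing.assert_allclose(ref.gamma_lin_std, w.gamma_lin_std, atol=1e-12)
    # two identical classes: any reference equals within for each
    twin = validate_model(
        MixtureModel(
            classes=(
                LatentClassParams(0.5, c.kappa, c.phi, c.coefficients),
                LatentClassParams(0.5, c.kappa, c.phi, c.coefficients),
            )
        )
    )
    for sol in standardize_reference(twin, 1):
        np.testing.assert_allclose(sol.gamma_lin_std, w.gamma_lin_std, atol=1e-12)
        np.testing.assert_allclose(sol.kappa_std, 0.0, atol=1e-12)
    # distinct group means: reference and pooled frames disagree on linear terms
    ref_sols = standardize_reference(gender_model, 0)
    pooled = standardize_pooled(gender_model)
    assert not np.allclose(ref_sols[1].gamma_lin_std, pooled[1].gamma_lin_std, atol=1e-4)
    with pytest.raises(IndexError):
        standardize_reference(gender_model, 5)


def test_standardized_mean_difference(gender_model):
    d = standardized_mean_difference(gender_model, 0, 0, 1)
    assert d == pytest.approx(0.532, abs=0.002)
    assert standardized_mean_difference(gender_model, 0, 1, 0) == pytest.approx(-d)
    assert standardized_mean_difference(gender_model, 0, 1, 1) == 0.0


def test_zscored_product_regression_is_not_the_correct_standardization():
    """Negative control: replacing products of standardized predictors by
    z-scored product variables yields different interaction coefficients
    whenever the predictor means are nonzero."""
    co = StructuralCoefficients(
        0.2, np.array([0.4, 0.3]), np.array([[0.15, 0.25], [0.25, -0.12]]), 0.5
    )
    c = LatentClassParams(1.0, np.array([2.0, 1.5]), np.array([[1.0, 0.3], [0.3, 0.8]]), co)
    m = _single(c)
    draws = sample_latent(SimulationConfig(model=m, n_draws=300_000, seed=9))
    sol = standardize_within(c)

    z = (draws.xi - c.kappa) / np.sqrt(np.diag(c.phi))
    y = (draws.eta - draws.eta.mean()) / np.sqrt(sol.eta_variance)
    correct_cols = [z[:, j] * z[:, k] for j, k in pair_indices(2)]
    wrong_cols = [(col - col.mean()) / col.std(ddof=1) for col in correct_cols]
    X = np.column_stack([np.ones(len(y)), z, *[c_[:, None] for c_ in wrong_cols]])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    # z-scoring divides each product coefficient by sd(product); for the
    # quadratic terms sd = sqrt(2 + 4 kappa*^2) > 1, so with nonzero means
    # those coefficients land far from the correct standardization
    wrong_quad1, wrong_quad2 = beta[4], beta[5]
    assert abs(wrong_quad1 - sol.gamma_quad_std[0, 0]) > 0.02
    assert abs(wrong_quad2 - sol.gamma_quad_std[1, 1]) > 0.02


@pytest.mark.parametrize("frame", ["within", "pooled"])
def test_population_regression_recovers_standardized_coefficients(gender_model, frame):
    """OLS on simulated standardized draws is the independent oracle for the
    closed-form solution in each frame."""
    draws = sample_latent(SimulationConfig(model=gender_model, n_draws=300_000, seed=21))
    if frame == "within":
        g = 0
        c = gender_model.classes[g]
        sol = standardize_within(c)
        emp = empirical_standardize(
            draws.subset(g),
            kappa_ref=c.kappa,
            phi_diag_ref=np.diag(c.phi),
            eta_scale=np.sqrt(sol.eta_variance),
        )
    else:
        from semstd.mixture_moments import mixture_cov, mixture_mean

        g = 1
        sol = standardize_pooled(gender_model)[g]
        emp = empirical_standardize(
            draws.subset(g),
            kappa_ref=mixture_mean(gender_model),
            phi_diag_ref=np.diag(mixture_cov(gender_model)),
            eta_scale=np.sqrt(sol.eta_variance),
        )
    np.testing.assert_array_less(
        np.abs(emp.gamma_lin_std - sol.gamma_lin_std), 3 * emp.se_lin
    )
    for j, k in pair_indices(2):
        assert abs(emp.gamma_quad_std[j, k] - sol.gamma_quad_std[j, k]) < 3 * emp.se_quad[j, k]


def test_solution_table_layout(gender_model, indirect_model):
    df = solution_table(gender_model)
    assert set(df.columns) == {
        "class",
        "parameter",
        "unstandardized",
        "standardized_within",
        "standardized_pooled",
    }
    row = df[(df["class"] == 1) & (df.parameter == "gamma1")].iloc[0]
    assert row.unstandardized == pytest.approx(-0.037)
    assert row.standardized_within == pytest.approx(0.527, abs=0.002)
    assert row.standardized_pooled == pytest.approx(0.474, abs=0.002)
    psi_row = df[(df["class"] == 2) & (df.parameter == "psi")].iloc[0]
    assert psi_row.standardized_pooled == pytest.approx(0.606, abs=0.002)

    di = solution_table(indirect_model)
    shared = di[di["class"] == 0]
    assert shared[shared.parameter == "gamma1"].standardized_pooled.iloc[0] == pytest.approx(
        0.514, abs=0.002
    )


def test_indirect_target_class_rejected(indirect_model):
    with pytest.raises(IndexError):
        standardize_pooled(indirect_model, target_class=1)


def test_pooled_target_class_selection(gender_model):
    sols = standardize_pooled(gender_model)
    one = standardize_pooled(gender_model, target_class=1)
    np.testing.assert_allclose(one.gamma_lin_std, sols[1].gamma_lin_std)
    with pytest.raises(IndexError):
        standardize_pooled(gender_model, target_class=7)


@given(st.integers(0, 10_000))
def test_centered_single_class_special_case(seed):
    # with zero means the linear corrections vanish: gamma_j* is the plain
    # sqrt-variance ratio even with nonlinear terms present
    rng = np.random.default_rng(seed)
    co = random_coefficients(rng, 2)
    c0 = random_class(rng, 2, coefficients=co)
    c = LatentClassParams(1.0, np.zeros(2), c0.phi, co)
    s = standardize_within(c)
    v = class_eta_variance(c)
    np.testing.assert_allclose(
        s.gamma_lin_std, co.gamma_lin * np.sqrt(np.diag(c.phi)) / np.sqrt(v), atol=1e-12
    )
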