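import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from semstd import datasets
from semstd.model_params import (
    LatentClassParams,
    MixtureModel,
    StructuralCoefficients,
    pair_indices,
    validate_model,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def direct_model():
    return datasets.reading_direct()


@pytest.fixture(scope="session")
def indirect_model():
    return datasets.reading_indirect()


@pytest.fixture(scope="session")
def gender_model():
    return datasets.reading_by_gender()


# ---------------------------------------------------------------- utilities


def random_class(rng, p, weight=1.0, coefficients=None) -> LatentClassParams:
    """A random valid latent class with well-conditioned covariance."""
    kappa = rng.uniform(-2, 2, size=p)
    a = rng.uniform(-0.8, 0.8, size=(p, p))
    phi = a @ a.T + np.eye(p) * rng.uniform(0.4, 1.2)
    if coefficients is None:
        coefficients = random_coefficients(rng, p)
    return LatentClassParams(weight=weight, kappa=kappa, phi=phi, coefficients=coefficients)


def random_coefficients(rng, p, linear_only=False) -> StructuralCoefficients:
    glin = rng.uniform(-0.6, 0.6, size=p)
    gquad = np.zeros((p, p))
    if not linear_only:
        for j, k in pair_indices(p):
            gquad[j, k] = gquad[k, j] = rng.uniform(-0.3, 0.3)
    return StructuralCoefficients(
        alpha=rng.uniform(-1, 1), gamma_lin=glin, gamma_quad=gquad, psi=rng.uniform(0.1, 1.0)
    )


def random_model(rng, p=2, n_classes=2, mode="direct", linear_only=False) -> MixtureModel:
    w = rng.dirichlet(np.ones(n_classes) * 4)
    shared = random_coefficients(rng, p, linear_only=linear_only) if mode == "indirect" else None
    classes = tuple(
        random_class(
            rng,
            p,
            weight=w[g],
            coefficients=shared
            if shared is not None
            else random_coefficients(rng, p, linear_only=linear_only),
        )
        for g in range(n_classes)
    )
    return validate_model(MixtureModel(classes=classes, mode=mode))


def affine_transform_class(c: LatentClassParams, a, b) -> LatentClassParams:
    """Rescale predictors xi -> a*xi + b with compensating coefficients.

    The transformed class generates the identical outcome variable eta, so
    every standardized quantity must be unchanged.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    p = c.p
    co = c.coefficients
    om = co.gamma_quad
    om_new = om / np.outer(a, a)
    glin_new = np.empty(p)
    for j in range(p):
        glin_new[j] = (
            co.gamma_lin[j] / a[j]
            - sum(om_new[j, k] * b[k] for k in range(p) if k != j)
            - 2.0 * om_new[j, j] * b[j]
        )
    alpha_new = (
        co.alpha
        - float(np.sum(co.gamma_lin * b / a))
        + sum(om_new[j, k] * b[j] * b[k] for j, k in pair_indices(p))
    )
    return LatentClassParams(
        weight=c.weight,
        kappa=a * c.kappa + b,
        phi=np.outer(a, a) * c.phi,
        coefficients=StructuralCoefficients(
            alpha=alpha_new, gamma_lin=glin_new, gamma_quad=om_new, psi=co.psi
        ),
    )
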