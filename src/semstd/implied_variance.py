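"""Model-implied means and variances of the latent outcome.

Every standardized coefficient divides by the square root of a model-implied
outcome variance.  Three such variances arise:

``class_eta_variance``
    phi_00,g = b_g' Sigma_g b_g + psi_g within one Gaussian class, where b_g
    stacks the linear and product-term coefficients and Sigma_g is the
    extended regressor covariance from the Gaussian product-moment
    identities.

``mixture_eta_variance``
    phi_00, the marginal Var(eta) over classes via the law of total
    variance; for shared-coefficient (indirect) models this equals the
    quadratic form in the mixture extended covariance exactly.

``pooled_eta_variance``
    The pooled-frame denominator for models whose coefficients differ by
    class (direct / multigroup): each class's coefficients are referred to
    the pooled (mixture) predictor distribution and the resulting implied
    variances are averaged with the class proportions,

        phi_00deg = sum_g pi_g (b_g' Sigma_mix b_g + psi_g).

    This is not the marginal Var(eta) when coefficients differ across
    classes; it is the implied variance in the frame that standardizes every
    class against the pooled predictor moments.  The two coincide for
    shared-coefficient models with a common intercept.
"""

from __future__ import annotations

import numpy as np

from . import gaussian_moments as gm
from . import mixture_moments as mm
from .model_params import LatentClassParams, MixtureModel

__all__ = [
    "conditional_eta_mean",
    "class_eta_variance",
    "mixture_eta_variance",
    "pooled_eta_variance",
]


def conditional_eta_mean(c: LatentClassParams) -> float:
    """Class-conditional outcome mean kappa_0,g.

    kappa_0,g = alpha_g + sum_j gamma_j kappa_j + sum_{j<=k} omega_jk E[xi_j xi_k],
    with the product-term means from the distribution-free identity and the
    residual zeta having zero expectation.
    """
    s = gm.MomentSummary(c.kappa, c.phi, source="class")
    return float(c.coefficients.alpha + c.coefficients.stacked() @ gm.extended_mean(s))


def class_eta_variance(c: LatentClassParams) -> float:
    """Within-class implied outcome variance phi_00,g (> psi_g unless b=0)."""
    s = gm.MomentSummary(c.kappa, c.phi, source="class")
    b = c.coefficients.stacked()
    return float(b @ gm.product_term_cov(s) @ b + c.coefficients.psi)


def mixture_eta_variance(model: MixtureModel) -> float:
    """Marginal Var(eta) over classes by the law of total variance.

    phi_00 = sum_g pi_g (phi_00,g + kappa_0,g^2) - (sum_g pi_g kappa_0,g)^2.
    Valid in every mode; reduces to :func:`class_eta_variance` for G=1.
    """
    w = model.weights
    v = np.array([class_eta_variance(c) for c in model.classes])
    k0 = np.array([conditional_eta_mean(c) for c in model.classes])
    return float(w @ (v + k0**2) - (w @ k0) ** 2)


def _mixture_quadratic_form(model: MixtureModel) -> float:
    """phi_00 as b' Sigma_mix b + psi; requires shared coefficients."""
    c0 = model.classes[0].coefficients
    b = c0.stacked()
    cov = mm.mixture_product_term_cov(model)
    return float(b @ cov @ b + c0.psi)


def pooled_eta_variance(model: MixtureModel) -> float:
    """Pooled-frame implied outcome variance phi_00deg.

    Weighted average over classes of each class's coefficient quadratic form
    in the *mixture* extended covariance, plus the class residual variances:
    sum_g pi_g (b_g' Sigma_mix b_g + psi_g).  Equals
    :func:`mixture_eta_variance` when all classes share coefficients and
    intercept, and :func:`class_eta_variance` for G=1.
    """
    cov = mm.mixture_product_term_cov(model)
    out = 0.0
    for wg, c in zip(model.weights, model.classes):
        b = c.coefficients.stacked()
        out += wg * (b @ cov @ b + c.coefficients.psi)
    return float(out)
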