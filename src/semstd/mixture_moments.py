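"""Marginal moments of the latent predictors under a finite Gaussian mixture.

The mixture marginal of xi is nonnormal in general, so its product-term
covariances cannot come from Gaussian identities applied to the marginal
moments.  Instead every required raw moment is composed exactly from the
component Gaussian moments by the law of total (co)variance:

    E[f]      = sum_g pi_g E_g[f]
    Cov(f, h) = sum_g pi_g (Cov_g(f, h) + E_g[f] E_g[h]) - E[f] E[h]

with the component expectations supplied by :mod:`semstd.gaussian_moments`.
"""

from __future__ import annotations

import numpy as np

from . import gaussian_moments as gm
from .model_params import MixtureModel

__all__ = [
    "mixture_mean",
    "mixture_cov",
    "mixture_summary",
    "mixture_extended_moments",
    "mixture_product_term_cov",
]


def mixture_mean(model: MixtureModel) -> np.ndarray:
    """Marginal predictor mean kappa = sum_g pi_g kappa_g."""
    w = model.weights
    return sum(wg * c.kappa for wg, c in zip(w, model.classes))


def mixture_cov(model: MixtureModel) -> np.ndarray:
    """Marginal predictor covariance, within plus between-class dispersion.

    Phi = sum_g pi_g (Phi_g + kappa_g kappa_g') - kappa kappa'
    """
    kappa = mixture_mean(model)
    acc = np.zeros((model.p, model.p))
    for wg, c in zip(model.weights, model.classes):
        acc += wg * (c.phi + np.outer(c.kappa, c.kappa))
    phi = acc - np.outer(kappa, kappa)
    return (phi + phi.T) / 2.0


def mixture_summary(model: MixtureModel) -> gm.MomentSummary:
    """Marginal first/second moments packaged as a mixture-source summary."""
    return gm.MomentSummary(mixture_mean(model), mixture_cov(model), source="mixture-marginal")


def mixture_extended_moments(model: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of (xi, products) under the mixture marginal."""
    means, covs = [], []
    for c in model.classes:
        s = gm.MomentSummary(c.kappa, c.phi, source="class")
        means.append(gm.extended_mean(s))
        covs.append(gm.product_term_cov(s))
    w = model.weights
    mean = sum(wg * mg for wg, mg in zip(w, means))
    acc = np.zeros_like(covs[0])
    for wg, mg, Sg in zip(w, means, covs):
        acc += wg * (Sg + np.outer(mg, mg))
    cov = acc - np.outer(mean, mean)
    return mean, (cov + cov.T) / 2.0


def mixture_product_term_cov(model: MixtureModel) -> np.ndarray:
    """Covariance matrix of (xi, products) under the nonnormal marginal."""
    return mixture_extended_moments(model)[1]
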