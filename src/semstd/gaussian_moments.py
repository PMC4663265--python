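"""Closed-form moments of products of jointly Gaussian latent predictors.

With xi ~ N(kappa, Phi) the extended regressor vector

    x = (xi_1, ..., xi_p, {xi_j xi_k}_{j<=k})

has first and second moments that follow from the product-moment (Isserlis)
identities for uncentered Gaussian vectors:

    E[xi_j xi_k]              = kappa_j kappa_k + phi_jk
    Cov(xi_a, xi_j xi_k)      = kappa_j phi_ak + kappa_k phi_aj
    Cov(xi_j xi_k, xi_l xi_m) = phi_jl phi_km + phi_jm phi_kl
                                + kappa_j kappa_l phi_km + kappa_j kappa_m phi_kl
                                + kappa_k kappa_l phi_jm + kappa_k kappa_m phi_jl

The mean identity is distribution-free; the covariance identities hold under
within-class normality.  The product-term ordering matches
:func:`semstd.model_params.pair_indices` (interactions first, then quadratics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_params import pair_indices

__all__ = [
    "MomentSummary",
    "product_term_means",
    "extended_mean",
    "product_term_cov",
]


@dataclass(frozen=True)
class MomentSummary:
    """First and second moments of the latent predictors.

    ``source`` records whether the summary describes a single (Gaussian)
    class or the mixture marginal; only class summaries may be fed to the
    Gaussian fourth-moment formulas.
    """

    mean: np.ndarray
    cov: np.ndarray
    source: str = "class"

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        cov = (cov + cov.T) / 2.0
        if cov.shape != (mean.shape[0], mean.shape[0]):
            raise ValueError(f"cov shape {cov.shape} inconsistent with mean length {mean.shape[0]}")
        if np.any(np.diag(cov) < 0):
            raise ValueError("cov has a negative diagonal entry")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def p(self) -> int:
        return self.mean.shape[0]


def product_term_means(m: MomentSummary) -> np.ndarray:
    """E[xi_j xi_k] = kappa_j kappa_k + phi_jk for every pair j <= k.

    Holds for any distribution with the given first and second moments.
    """
    kappa, phi = m.mean, m.cov
    return np.array([kappa[j] * kappa[k] + phi[j, k] for j, k in pair_indices(m.p)])


def extended_mean(m: MomentSummary) -> np.ndarray:
    """Mean of the extended regressor vector (xi, products)."""
    return np.concatenate([m.mean, product_term_means(m)])


def product_term_cov(m: MomentSummary, psd_tol: float = 1e-8) -> np.ndarray:
    """Covariance matrix of (xi, products) under within-class normality.

    Returns the symmetric (p + p(p+1)/2) square matrix; raises ``ValueError``
    if the assembled matrix fails positive semi-definiteness beyond
    ``psd_tol`` (which indicates invalid inputs, e.g. a non-PSD ``cov``).
    """
    if m.source not in ("class", "gaussian"):
        raise ValueError(
            "product_term_cov applies Gaussian fourth-moment identities and "
            f"requires a within-class summary, got source={m.source!r}"
        )
    kappa, phi = m.mean, m.cov
    p = m.p
    P = pair_indices(p)
    q = len(P)
    S = np.zeros((p + q, p + q))
    S[:p, :p] = phi
    for a in range(p):
        for i, (j, k) in enumerate(P):
            S[a, p + i] = S[p + i, a] = kappa[j] * phi[a, k] + kappa[k] * phi[a, j]
    for i, (j, k) in enumerate(P):
        for i2 in range(i, q):
            l, mm = P[i2]
            val = (
                phi[j, l] * phi[k, mm]
                + phi[j, mm] * phi[k, l]
                + kappa[j] * kappa[l] * phi[k, mm]
                + kappa[j] * kappa[mm] * phi[k, l]
                + kappa[k] * kappa[l] * phi[j, mm]
                + kappa[k] * kappa[mm] * phi[j, l]
            )
            S[p + i, p + i2] = S[p + i2, p + i] = val
    S = (S + S.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(S).min())
    scale = max(1.0, float(np.abs(np.diag(S)).max()))
    if min_eig < -psd_tol * scale:
        raise ValueError(
            f"extended covariance is not PSD (min eigenvalue {min_eig:.3e}); "
            "check that the input covariance matrix is valid"
        )
    return S
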