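"""Monte-Carlo generator and brute-force verifier for the closed forms.

Samples the latent generative model — class ~ categorical(pi), xi | class ~
N(kappa_g, Phi_g), eta assembled from the class's structural equation with
zeta ~ N(0, psi_g) — and recomputes every closed-form moment and
standardized coefficient empirically.  Because the standardization formulas
are algebraic identities in the model moments, an ordinary least-squares fit
of the standardized outcome on the standardized predictors and their raw
products must recover the closed-form coefficients up to sampling error,
under *any* frame whose reference moments are used for the z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from . import gaussian_moments as gm
from .model_params import MixtureModel, pair_indices

__all__ = [
    "SimulationConfig",
    "LatentDraws",
    "sample_latent",
    "empirical_standardize",
    "empirical_moments",
    "EmpiricalSolution",
]

MIN_DRAWS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation settings: model, number of draws, RNG seed."""

    model: MixtureModel
    n_draws: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class LatentDraws:
    """Sampled latent data: class labels, predictors, outcome."""

    labels: np.ndarray
    xi: np.ndarray
    eta: np.ndarray

    @property
    def n(self) -> int:
        return self.eta.shape[0]

    def subset(self, g: int) -> "LatentDraws":
        m = self.labels == g
        return LatentDraws(self.labels[m], self.xi[m], self.eta[m])


def _eval_structural(coeffs, xi: np.ndarray) -> np.ndarray:
    out = np.full(xi.shape[0], coeffs.alpha) + xi @ coeffs.gamma_lin
    for j, k in pair_indices(xi.shape[1]):
        out += coeffs.gamma_quad[j, k] * xi[:, j] * xi[:, k]
    return out


def sample_latent(cfg: SimulationConfig) -> LatentDraws:
    """Draw (class, xi, eta) from the generative mixture model.

    Deterministic for a fixed seed: class labels first, then per-class
    Gaussian predictors and residuals in class order.
    """
    model = cfg.model
    rng = np.random.default_rng(cfg.seed)
    labels = rng.choice(model.n_classes, size=cfg.n_draws, p=model.weights)
    xi = np.empty((cfg.n_draws, model.p))
    eta = np.empty(cfg.n_draws)
    for g, c in enumerate(model.classes):
        m = labels == g
        ng = int(m.sum())
        if ng == 0:
            continue
        xig = rng.multivariate_normal(c.kappa, c.phi, size=ng)
        zg = rng.normal(0.0, np.sqrt(c.coefficients.psi), size=ng)
        xi[m] = xig
        eta[m] = _eval_structural(c.coefficients, xig) + zg
    return LatentDraws(labels, xi, eta)


@dataclass(frozen=True)
class EmpiricalSolution:
    """OLS estimate of the standardized solution with standard errors."""

    gamma_lin_std: np.ndarray
    gamma_quad_std: np.ndarray
    psi_std: float
    se_lin: np.ndarray
    se_quad: np.ndarray


def _design(z: np.ndarray) -> np.ndarray:
    cols = [np.ones(z.shape[0])] + [z[:, j] for j in range(z.shape[1])]
    cols += [z[:, j] * z[:, k] for j, k in pair_indices(z.shape[1])]
    return np.column_stack(cols)


def empirical_standardize(
    draws: LatentDraws,
    kappa_ref=None,
    phi_diag_ref=None,
    eta_scale=None,
) -> EmpiricalSolution:
    """Fit the standardized structural equation to sampled draws by OLS.

    Predictors are z-scored with the reference means/variances (empirical
    moments of the supplied draws by default), products are formed from the
    standardized predictors *without* re-standardizing them, and the
    centered outcome is divided by ``eta_scale`` (its empirical SD by
    default).  Passing explicit reference moments reproduces pooled or
    reference-class frames whose denominator is not the sample SD.
    """
    if draws.n < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {draws.n}")
    p = draws.xi.shape[1]
    kappa_ref = draws.xi.mean(axis=0) if kappa_ref is None else np.asarray(kappa_ref, float)
    sd_ref = (
        draws.xi.std(axis=0, ddof=1)
        if phi_diag_ref is None
        else np.sqrt(np.asarray(phi_diag_ref, float))
    )
    scale = float(draws.eta.std(ddof=1)) if eta_scale is None else float(eta_scale)
    z = (draws.xi - kappa_ref) / sd_ref
    y = (draws.eta - draws.eta.mean()) / scale
    fit = sm.OLS(y, _design(z)).fit()
    coefs, ses = fit.params[1:], fit.bse[1:]
    glin, se_lin = coefs[:p], ses[:p]
    gquad = np.zeros((p, p))
    se_quad = np.zeros((p, p))
    for i, (j, k) in enumerate(pair_indices(p)):
        gquad[j, k] = gquad[k, j] = coefs[p + i]
        se_quad[j, k] = se_quad[k, j] = ses[p + i]
    resid_share = float(fit.resid.var(ddof=0))
    return EmpiricalSolution(
        gamma_lin_std=np.asarray(glin),
        gamma_quad_std=gquad,
        psi_std=resid_share,
        se_lin=np.asarray(se_lin),
        se_quad=se_quad,
    )


def empirical_moments(draws: LatentDraws) -> tuple[gm.MomentSummary, np.ndarray]:
    """Sample moments of (xi, products): summary of xi plus extended cov."""
    xi = draws.xi
    prods = np.column_stack([xi[:, j] * xi[:, k] for j, k in pair_indices(xi.shape[1])])
    ext = np.column_stack([xi, prods])
    summary = gm.MomentSummary(
        xi.mean(axis=0), np.cov(xi, rowvar=False), source="empirical"
    )
    return summary, np.cov(ext, rowvar=False)
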