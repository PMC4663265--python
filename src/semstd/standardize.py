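"""Correctly standardized coefficients for nonlinear SEM with latent classes.

Standardizing a structural equation that contains interaction and quadratic
terms is not the same as z-scoring every regressor: the products of
standardized predictors are the correct nonlinear regressors, and they are
*not* themselves standardized variables.  Writing the structural equation in
terms of standardized predictors xi_j* = (xi_j - kappa_j)/sqrt(phi_jj) and a
standardized outcome gives, for reference moments (kappa, Phi) and implied
outcome variance phi_00:

    gamma_j*  = (gamma_j + sum_{k!=j} omega_jk kappa_k + 2 omega_jj kappa_j)
                 * sqrt(phi_jj) / sqrt(phi_00)
    omega_jk* = omega_jk sqrt(phi_jj phi_kk) / sqrt(phi_00)   (j < k)
    omega_jj* = omega_jj phi_jj / sqrt(phi_00)
    psi*      = psi / phi_00,    R^2 = 1 - psi*

The linear coefficients absorb mean-dependent corrections because, with
nonlinear terms present, the size of a linear effect depends on where the
predictor means sit; the standardized linear effect is the effect at the
average of the reference population.  Three reference frames are supported:
the class's own moments (``within``), the pooled mixture moments
(``pooled``), and the moments of a designated reference class
(``reference:g``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import implied_variance as iv
from . import mixture_moments as mm
from .model_params import (
    LatentClassParams,
    MixtureModel,
    StructuralCoefficients,
    coefficient_names,
    pair_indices,
)

__all__ = [
    "StandardizedSolution",
    "standardize_within",
    "standardize_pooled",
    "standardize_reference",
    "standardized_mean_difference",
    "solution_table",
]


@dataclass(frozen=True)
class StandardizedSolution:
    """Standardized structural solution for one class in one reference frame.

    ``kappa_std`` and ``phi_std`` are the class's predictor means and
    covariances expressed in the reference frame: zeros and a correlation
    matrix in the ``within`` frame, and the class moments scaled by the
    pooled (or reference-class) means and standard deviations otherwise.
    ``eta_variance`` is the implied outcome variance the solution divides by.
    """

    gamma_lin_std: np.ndarray
    gamma_quad_std: np.ndarray
    psi_std: float
    r_squared: float
    kappa_std: np.ndarray
    phi_std: np.ndarray
    frame: str
    eta_variance: float

    def __post_init__(self) -> None:
        if not self.eta_variance > 0:
            raise ValueError("eta_variance must be positive")
        if abs(self.r_squared - (1.0 - self.psi_std)) > 1e-9:
            raise ValueError("r_squared must equal 1 - psi_std")


def _scale_cov(phi_class: np.ndarray, ref_diag: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(ref_diag)
    return phi_class * np.outer(d, d)


def _standardize_coeffs(
    co: StructuralCoefficients,
    kappa_ref: np.ndarray,
    phi_ref: np.ndarray,
    eta_variance: float,
) -> tuple[np.ndarray, np.ndarray]:
    p = co.p
    sd = np.sqrt(np.diag(phi_ref))
    root = np.sqrt(eta_variance)
    glin = np.empty(p)
    for j in range(p):
        corr = (
            co.gamma_lin[j]
            + sum(co.gamma_quad[j, k] * kappa_ref[k] for k in range(p) if k != j)
            + 2.0 * co.gamma_quad[j, j] * kappa_ref[j]
        )
        glin[j] = corr * sd[j] / root
    gquad = np.zeros((p, p))
    for j, k in pair_indices(p):
        if j == k:
            gquad[j, j] = co.gamma_quad[j, j] * phi_ref[j, j] / root
        else:
            gquad[j, k] = gquad[k, j] = co.gamma_quad[j, k] * sd[j] * sd[k] / root
    return glin, gquad


def _solution(
    co: StructuralCoefficients,
    kappa_ref: np.ndarray,
    phi_ref: np.ndarray,
    eta_variance: float,
    kappa_class: np.ndarray,
    phi_class: np.ndarray,
    frame: str,
) -> StandardizedSolution:
    glin, gquad = _standardize_coeffs(co, kappa_ref, phi_ref, eta_variance)
    psi_std = co.psi / eta_variance
    ref_diag = np.diag(phi_ref)
    return StandardizedSolution(
        gamma_lin_std=glin,
        gamma_quad_std=gquad,
        psi_std=psi_std,
        r_squared=1.0 - psi_std,
        kappa_std=(kappa_class - kappa_ref) / np.sqrt(ref_diag),
        phi_std=_scale_cov(phi_class, ref_diag),
        frame=frame,
        eta_variance=eta_variance,
    )


def standardize_within(c: LatentClassParams) -> StandardizedSolution:
    """Standardize one class against its own means and variances.

    The frame of reference is the class itself: standardized means are zero,
    standardized predictor variances are one (``phi_std`` is the class
    correlation matrix), and the denominator is the within-class implied
    outcome variance phi_00,g.
    """
    v = iv.class_eta_variance(c)
    return _solution(c.coefficients, c.kappa, c.phi, v, c.kappa, c.phi, "within")


def standardize_pooled(model: MixtureModel, target_class=None):
    """Standardize against the pooled (mixture-marginal) moments.

    For shared-coefficient (``indirect``) models this returns a single
    solution: the marginal predictor moments and the marginal implied
    outcome variance define the frame, so the standardized solution
    describes the whole (nonnormal) population.

    For ``direct``/``multigroup`` models one solution per class is returned
    (or the one requested via ``target_class``, a zero-based index).  All
    classes share the same denominator — the pooled implied outcome variance
    of :func:`semstd.implied_variance.pooled_eta_variance` — and the pooled
    means enter the linear correction terms, so coefficients are comparable
    across classes on one common metric.  ``kappa_std`` then carries the
    standardized class means (kappa_g - kappa) / sqrt(diag(Phi)).
    """
    kappa = mm.mixture_mean(model)
    phi = mm.mixture_cov(model)
    if model.mode == "indirect":
        if target_class not in (None, 0):
            raise IndexError("indirect models have a single shared solution; use target_class=None")
        c0 = model.classes[0]
        v = iv.mixture_eta_variance(model)
        return _solution(c0.coefficients, kappa, phi, v, kappa, phi, "pooled")
    v = iv.pooled_eta_variance(model)
    sols = [
        _solution(c.coefficients, kappa, phi, v, c.kappa, c.phi, "pooled")
        for c in model.classes
    ]
    if target_class is None:
        return sols
    if not 0 <= target_class < model.n_classes:
        raise IndexError(
            f"target_class {target_class} out of range for {model.n_classes} classes"
        )
    return sols[target_class]


def standardize_reference(model: MixtureModel, ref: int):
    """Standardize every class against the moments of one reference class.

    The reference class's means, variances, and within-class implied outcome
    variance define the frame; useful when one group is the natural baseline
    (e.g. a control group).  ``ref`` is a zero-based class index.
    """
    if not 0 <= ref < model.n_classes:
        raise IndexError(f"reference class {ref} out of range for {model.n_classes} classes")
    r = model.classes[ref]
    v = iv.class_eta_variance(r)
    return [
        _solution(c.coefficients, r.kappa, r.phi, v, c.kappa, c.phi, f"reference:{ref}")
        for c in model.classes
    ]


def standardized_mean_difference(model: MixtureModel, predictor: int, a: int, b: int) -> float:
    """Difference of two classes' predictor means in pooled SD units.

    (kappa_j,a - kappa_j,b) / sqrt(Phi_jj) with the pooled variance from the
    mixture marginal; zero when a == b, antisymmetric in (a, b).
    """
    for g in (a, b):
        if not 0 <= g < model.n_classes:
            raise IndexError(f"class index {g} out of range")
    if not 0 <= predictor < model.p:
        raise IndexError(f"predictor index {predictor} out of range")
    phi = mm.mixture_cov(model)
    ka = model.classes[a].kappa[predictor]
    kb = model.classes[b].kappa[predictor]
    return float((ka - kb) / np.sqrt(phi[predictor, predictor]))


# ----------------------------------------------------------------- reporting


def _class_rows(c: LatentClassParams, sol_w, sol_p) -> list[dict]:
    p = c.p
    names = coefficient_names(p)
    pairs = pair_indices(p)
    rows = []
    b = c.coefficients.stacked()

    def pick(sol, kind, idx):
        if sol is None:
            return np.nan
        if kind == "glin":
            return sol.gamma_lin_std[idx]
        if kind == "gquad":
            return sol.gamma_quad_std[idx]
        if kind == "kappa":
            return sol.kappa_std[idx]
        if kind == "phi":
            return sol.phi_std[idx]
        if kind == "psi":
            return sol.psi_std
        return 0.0  # standardized intercept: equations are centered per class

    for i, name in enumerate(names):
        kind, idx = ("glin", i) if i < p else ("gquad", pairs[i - p])
        rows.append((name, float(b[i]), pick(sol_w, kind, idx), pick(sol_p, kind, idx)))
    for j in range(p):
        rows.append((f"kappa{j + 1}", float(c.kappa[j]), pick(sol_w, "kappa", j), pick(sol_p, "kappa", j)))
    rows.append(("alpha", c.coefficients.alpha, pick(sol_w, "alpha", None), pick(sol_p, "alpha", None)))
    for j in range(p):
        for k in range(j, p):
            rows.append(
                (f"phi{j + 1}{k + 1}", float(c.phi[j, k]), pick(sol_w, "phi", (j, k)), pick(sol_p, "phi", (j, k)))
            )
    rows.append(("psi", c.coefficients.psi, pick(sol_w, "psi", None), pick(sol_p, "psi", None)))
    return rows


def solution_table(model: MixtureModel) -> pd.DataFrame:
    """Tabulate unstandardized, within-, and pooled-standardized estimates.

    Mirrors the layout of applied results tables: one row per parameter per
    class with columns ``(class, parameter, unstandardized,
    standardized_within, standardized_pooled)``.  For indirect models the
    shared coefficients appear once under class 0 and the within column is
    left blank (there is no class-specific solution to report).
    """
    records = []
    if model.mode == "indirect":
        sol_p = standardize_pooled(model)
        c0 = model.classes[0]
        for name, unstd, _, std in _class_rows(c0, None, sol_p):
            records.append((0, name, unstd, np.nan, std))
        # class blocks: distribution parameters only
        for g, c in enumerate(model.classes):
            for j in range(model.p):
                records.append((g + 1, f"kappa{j + 1}", float(c.kappa[j]), 0.0, np.nan))
            for j in range(model.p):
                for k in range(j, model.p):
                    rjk = c.phi[j, k] / np.sqrt(c.phi[j, j] * c.phi[k, k])
                    records.append((g + 1, f"phi{j + 1}{k + 1}", float(c.phi[j, k]), float(rjk), np.nan))
    else:
        pooled = standardize_pooled(model)
        if not isinstance(pooled, list):
            pooled = [pooled]
        for g, c in enumerate(model.classes):
            sol_w = standardize_within(c)
            for name, unstd, std_w, std_p in _class_rows(c, sol_w, pooled[g]):
                records.append((g + 1, name, unstd, std_w, std_p))
    return pd.DataFrame(
        records,
        columns=["class", "parameter", "unstandardized", "standardized_within", "standardized_pooled"],
    )
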