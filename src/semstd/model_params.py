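"""Parameter data model for class-specific nonlinear structural equation models.

A model has a single latent outcome eta regressed on p latent predictors
xi_1..xi_p plus their pairwise products::

    eta = alpha + sum_j gamma_j xi_j + sum_{j<=k} omega_jk xi_j xi_k + zeta

with zeta ~ N(0, psi).  Each product term (interaction j<k, quadratic j=k)
carries exactly one coefficient; there is no symmetric halving, so the
coefficients are numerically identical to the single-product-term notation
commonly printed in applied tables (gamma_3 xi_1 xi_2 for p=2).

The mixture layer attaches class weights and class-specific Gaussian
predictor distributions N(kappa_g, Phi_g), optionally with class-specific
structural coefficients:

* ``direct`` mode: latent classes are substantive subpopulations; every
  structural parameter may differ by class.
* ``indirect`` mode: the mixture only approximates a nonnormal predictor
  distribution; all structural coefficients (alpha, gamma, omega, psi) are
  shared across classes.
* ``multigroup`` mode: classes are observed groups (known membership);
  parameters may differ by group, as in ``direct``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MODES",
    "StructuralCoefficients",
    "LatentClassParams",
    "MixtureModel",
    "ModelValidationError",
    "validate_model",
    "pair_indices",
    "coefficient_names",
    "from_flat_table",
    "to_flat_table",
]

MODES = ("direct", "indirect", "multigroup")

#: Tolerance inside which class weights are renormalized rather than rejected.
WEIGHT_TOL = 1e-6
#: Positive-definiteness tolerance for predictor covariance matrices.  Inputs
#: transcribed from 3-decimal tables can have tiny negative eigenvalues after
#: symmetrization; anything <= 0 beyond -1e-10 is rejected.
PD_TOL = -1e-10


class ModelValidationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


def pair_indices(p: int) -> list[tuple[int, int]]:
    """Ordered unordered-pairs (j, k), j <= k, indexing the product terms.

    The ordering is interactions first (j < k, lexicographic), then the
    quadratic terms (j, j).  For p = 2 this yields (0,1), (0,0), (1,1),
    matching the conventional gamma_3 (interaction), gamma_4, gamma_5
    (quadratics) numbering.
    """
    inter = [(j, k) for j in range(p) for k in range(j + 1, p)]
    quad = [(j, j) for j in range(p)]
    return inter + quad


def coefficient_names(p: int) -> list[str]:
    """Names gamma1..gammaK for the stacked (linear, product) coefficients."""
    return [f"gamma{i + 1}" for i in range(p + len(pair_indices(p)))]


def _as_symmetric(m: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ModelValidationError(f"{name} must be a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol, rtol=0.0):
        raise ModelValidationError(f"{name} is not symmetric within tolerance {tol}")
    return (m + m.T) / 2.0


@dataclass(frozen=True)
class StructuralCoefficients:
    """Structural regression parameters for one class.

    Parameters
    ----------
    alpha
        Latent intercept.
    gamma_lin
        Linear coefficients, length p.
    gamma_quad
        Symmetric p x p matrix of product-term coefficients.  Entry (j, j)
        is the quadratic coefficient of xi_j**2; entry (j, k) = (k, j), j<k,
        is the single interaction coefficient of xi_j*xi_k.
    psi
        Residual variance of zeta, strictly positive.
    """

    alpha: float
    gamma_lin: np.ndarray
    gamma_quad: np.ndarray
    psi: float

    def __post_init__(self) -> None:
        glin = np.atleast_1d(np.asarray(self.gamma_lin, dtype=float))
        object.__setattr__(self, "gamma_lin", glin)
        gq = _as_symmetric(np.atleast_2d(self.gamma_quad), "gamma_quad")
        if gq.shape[0] != glin.shape[0]:
            raise ModelValidationError(
                f"gamma_quad shape {gq.shape} inconsistent with p={glin.shape[0]}"
            )
        object.__setattr__(self, "gamma_quad", gq)
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "psi", float(self.psi))
        if not self.psi > 0:
            raise ModelValidationError(f"psi must be > 0, got {self.psi}")

    @property
    def p(self) -> int:
        return self.gamma_lin.shape[0]

    def stacked(self) -> np.ndarray:
        """Coefficients of the extended regressor vector (xi, products)."""
        prods = np.array([self.gamma_quad[j, k] for j, k in pair_indices(self.p)])
        return np.concatenate([self.gamma_lin, prods])

    def is_linear(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.gamma_quad) <= tol))


@dataclass(frozen=True)
class LatentClassParams:
    """One mixture component: weight, predictor distribution, coefficients."""

    weight: float
    kappa: np.ndarray
    phi: np.ndarray
    coefficients: StructuralCoefficients

    def __post_init__(self) -> None:
        object.__setattr__(self, "weight", float(self.weight))
        if not (0.0 < self.weight <= 1.0):
            raise ModelValidationError(f"class weight must be in (0, 1], got {self.weight}")
        kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        object.__setattr__(self, "kappa", kappa)
        phi = _as_symmetric(np.atleast_2d(self.phi), "phi")
        if phi.shape[0] != kappa.shape[0]:
            raise ModelValidationError(
                f"phi shape {phi.shape} inconsistent with kappa length {kappa.shape[0]}"
            )
        eig = np.linalg.eigvalsh(phi)
        if eig.min() <= PD_TOL:
            raise ModelValidationError(
                f"phi is not positive definite (min eigenvalue {eig.min():.3e})"
            )
        object.__setattr__(self, "phi", phi)
        if self.coefficients.p != kappa.shape[0]:
            raise ModelValidationError(
                "coefficient dimension does not match number of predictors"
            )

    @property
    def p(self) -> int:
        return self.kappa.shape[0]


@dataclass(frozen=True)
class MixtureModel:
    """Ordered collection of latent classes with an application mode."""

    classes: tuple[LatentClassParams, ...]
    mode: str = "direct"
    predictor_names: tuple[str, ...] = ()
    outcome_name: str = "eta"

    def __post_init__(self) -> None:
        classes = tuple(self.classes)
        if len(classes) < 1:
            raise ModelValidationError("model needs at least one class")
        object.__setattr__(self, "classes", classes)
        if self.mode not in MODES:
            raise ModelValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        p = classes[0].p
        if any(c.p != p for c in classes):
            raise ModelValidationError("all classes must share the same number of predictors")
        names = tuple(self.predictor_names) or tuple(f"xi{j + 1}" for j in range(p))
        if len(names) != p:
            raise ModelValidationError("predictor_names length does not match p")
        object.__setattr__(self, "predictor_names", names)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def p(self) -> int:
        return self.classes[0].p

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes])

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "predictor_names": list(self.predictor_names),
            "outcome_name": self.outcome_name,
            "classes": [
                {
                    "weight": c.weight,
                    "kappa": c.kappa.tolist(),
                    "phi": c.phi.tolist(),
                    "alpha": c.coefficients.alpha,
                    "gamma_lin": c.coefficients.gamma_lin.tolist(),
                    "gamma_quad": c.coefficients.gamma_quad.tolist(),
                    "psi": c.coefficients.psi,
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        try:
            classes = tuple(
                LatentClassParams(
                    weight=c["weight"],
                    kappa=np.asarray(c["kappa"], dtype=float),
                    phi=np.asarray(c["phi"], dtype=float),
                    coefficients=StructuralCoefficients(
                        alpha=c["alpha"],
                        gamma_lin=np.asarray(c["gamma_lin"], dtype=float),
                        gamma_quad=np.asarray(c["gamma_quad"], dtype=float),
                        psi=c["psi"],
                    ),
                )
                for c in d["classes"]
            )
        except KeyError as exc:
            raise ModelValidationError(f"missing required field {exc}") from exc
        model = cls(
            classes=classes,
            mode=d.get("mode", "direct"),
            predictor_names=tuple(d.get("predictor_names", ())),
            outcome_name=d.get("outcome_name", "eta"),
        )
        return validate_model(model)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MixtureModel":
        """Load a model from a JSON string or a readable path."""
        text = source
        try:
            if hasattr(source, "read"):
                text = source.read()
            elif isinstance(source, str) and not source.lstrip().startswith("{"):
                with open(source) as fh:
                    text = fh.read()
        except OSError as exc:
            raise ModelValidationError(f"cannot read parameter file: {exc}") from exc
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"invalid JSON parameter file: {exc}") from exc
        return cls.from_dict(d)


def validate_model(model: MixtureModel) -> MixtureModel:
    """Check all model invariants, normalizing near-unit weight sums.

    Returns the model unchanged when every invariant holds exactly; if the
    class weights sum to 1 only within ``WEIGHT_TOL`` they are renormalized.
    Raises :class:`ModelValidationError` otherwise.
    """
    total = float(model.weights.sum())
    if abs(total - 1.0) > WEIGHT_TOL:
        raise ModelValidationError(
            f"class weights do not sum to 1 (sum={total!r}); weights must sum to 1"
        )
    out = model
    if total != 1.0:
        out = replace(
            model,
            classes=tuple(replace(c, weight=c.weight / total) for c in model.classes),
        )
    if out.mode == "indirect" and out.n_classes > 1:
        ref = out.classes[0].coefficients
        for i, c in enumerate(out.classes[1:], start=2):
            co = c.coefficients
            same = (
                co.alpha == ref.alpha
                and co.psi == ref.psi
                and np.array_equal(co.gamma_lin, ref.gamma_lin)
                and np.array_equal(co.gamma_quad, ref.gamma_quad)
            )
            if not same:
                raise ModelValidationError(
                    "indirect mode requires identical structural coefficients in "
                    f"every class; class {i} differs from class 1"
                )
    return out


# ---------------------------------------------------------------- flat table

_SCALARS = ("weight", "alpha", "psi")


def _parse_name(name: str, p: int) -> tuple[str, tuple]:
    """Map a flat parameter name to a slot in the model structure."""
    name = name.strip().lower()
    if name in _SCALARS:
        return name, ()
    if name.startswith("kappa"):
        j = int(name[5:]) - 1
        if not 0 <= j < p:
            raise ModelValidationError(f"unknown parameter name {name!r}")
        return "kappa", (j,)
    if name.startswith("phi"):
        digits = name[3:]
        if len(digits) != 2 or not digits.isdigit():
            raise ModelValidationError(f"unknown parameter name {name!r}")
        j, k = int(digits[0]) - 1, int(digits[1]) - 1
        if not (0 <= j < p and 0 <= k < p):
            raise ModelValidationError(f"unknown parameter name {name!r}")
        return "phi", (min(j, k), max(j, k))
    if name.startswith("gamma"):
        idx = int(name[5:]) - 1
        names = coefficient_names(p)
        if not 0 <= idx < len(names):
            raise ModelValidationError(f"unknown parameter name {name!r}")
        if idx < p:
            return "gamma_lin", (idx,)
        j, k = pair_indices(p)[idx - p]
        return "gamma_quad", (j, k)
    raise ModelValidationError(f"unknown parameter name {name!r}")


def _infer_p(names: Iterable[str]) -> int:
    ks = [int(n.strip().lower()[5:]) for n in names if n.strip().lower().startswith("kappa")]
    if not ks:
        raise ModelValidationError("cannot infer the number of predictors: no kappa entries")
    return max(ks)


def from_flat_table(
    rows: Sequence[tuple], mode: str = "direct", predictor_names: Sequence[str] = ()
) -> MixtureModel:
    """Assemble a model from (class label, parameter name, value) records.

    Parameter names follow the usual applied-table scheme: ``weight``,
    ``kappa1..kappaP``, ``phi11``/``phi21``/... (either triangle), ``alpha``,
    ``psi`` and ``gamma1..gammaK`` with the linear coefficients first, then
    interactions (lexicographic), then quadratics.  Symmetric entries are
    mirrored automatically.  Classes are ordered by first appearance.
    """
    labels: list = []
    per_class: dict = {}
    for row in rows:
        label, name, value = row
        if label not in per_class:
            labels.append(label)
            per_class[label] = []
        per_class[label].append((str(name), float(value)))

    p = _infer_p(name for recs in per_class.values() for name, _ in recs)
    classes = []
    for label in labels:
        slots: dict = {"kappa": {}, "phi": {}, "gamma_lin": {}, "gamma_quad": {}}
        scalars: dict = {}
        for name, value in per_class[label]:
            kind, idx = _parse_name(name, p)
            if kind in _SCALARS:
                if kind in scalars:
                    raise ModelValidationError(f"duplicate parameter {name!r} in class {label!r}")
                scalars[kind] = value
            else:
                if idx in slots[kind]:
                    raise ModelValidationError(f"duplicate parameter {name!r} in class {label!r}")
                slots[kind][idx] = value
        for req in ("alpha", "psi"):
            if req not in scalars:
                raise ModelValidationError(f"missing {req} for class {label!r}")
        if len(labels) == 1:
            scalars.setdefault("weight", 1.0)
        elif "weight" not in scalars:
            raise ModelValidationError(f"missing weight for class {label!r}")

        kappa = np.full(p, np.nan)
        for (j,), v in slots["kappa"].items():
            kappa[j] = v
        phi = np.full((p, p), np.nan)
        for (j, k), v in slots["phi"].items():
            phi[j, k] = phi[k, j] = v
        glin = np.full(p, np.nan)
        for (j,), v in slots["gamma_lin"].items():
            glin[j] = v
        gquad = np.zeros((p, p))
        for (j, k), v in slots["gamma_quad"].items():
            gquad[j, k] = gquad[k, j] = v
        for arr, what in ((kappa, "kappa"), (phi, "phi"), (glin, "gamma")):
            if np.isnan(arr).any():
                raise ModelValidationError(f"missing {what} entries for class {label!r}")
        classes.append(
            LatentClassParams(
                weight=scalars["weight"],
                kappa=kappa,
                phi=phi,
                coefficients=StructuralCoefficients(
                    alpha=scalars["alpha"], gamma_lin=glin, gamma_quad=gquad, psi=scalars["psi"]
                ),
            )
        )
    return validate_model(
        MixtureModel(classes=tuple(classes), mode=mode, predictor_names=tuple(predictor_names))
    )


def to_flat_table(model: MixtureModel) -> list[tuple]:
    """Inverse of :func:`from_flat_table`; emits the upper phi triangle."""
    rows: list[tuple] = []
    p = model.p
    cnames = coefficient_names(p)
    for g, c in enumerate(model.classes, start=1):
        rows.append((g, "weight", c.weight))
        for j in range(p):
            rows.append((g, f"kappa{j + 1}", float(c.kappa[j])))
        for j in range(p):
            for k in range(j, p):
                rows.append((g, f"phi{j + 1}{k + 1}", float(c.phi[j, k])))
        rows.append((g, "alpha", c.coefficients.alpha))
        b = c.coefficients.stacked()
        for name, value in zip(cnames, b):
            rows.append((g, name, float(value)))
        rows.append((g, "psi", c.coefficients.psi))
    return rows
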