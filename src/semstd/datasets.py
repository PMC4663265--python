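"""Bundled example parameter sets.

Three estimated nonlinear structural models for the same education-science
setting — reading skills regressed on reading attitude and online reading
activities (one interaction, two quadratic effects) for an N=1092 student
sample — covering the three ways a mixture enters:

* :func:`reading_direct` — two latent classes with class-specific
  coefficients (substantive subpopulations),
* :func:`reading_indirect` — two latent classes approximating a nonnormal
  predictor distribution under shared coefficients,
* :func:`reading_by_gender` — an observed two-group (female/male) model
  with equal group proportions.

All values are 3-decimal published estimates; they double as fixtures for
the desk-scale reproduction tests.
"""

from __future__ import annotations

from .model_params import MixtureModel, validate_model

__all__ = ["reading_direct", "reading_indirect", "reading_by_gender"]

_PREDICTORS = ["attitude", "online"]
_OUTCOME = "reading"


def _model(mode, classes) -> MixtureModel:
    return validate_model(
        MixtureModel.from_dict(
            {
                "mode": mode,
                "predictor_names": _PREDICTORS,
                "outcome_name": _OUTCOME,
                "classes": classes,
            }
        )
    )


def reading_direct() -> MixtureModel:
    """Two-class direct application with class-specific coefficients."""
    return _model(
        "direct",
        [
            {
                "weight": 0.626,
                "kappa": [2.341, 3.272],
                "phi": [[0.344, 0.063], [0.063, 0.302]],
                "alpha": -0.147,
                "gamma_lin": [0.309, 0.305],
                "gamma_quad": [[-0.029, -0.042], [-0.042, -0.026]],
                "psi": 0.028,
            },
            {
                "weight": 0.374,
                "kappa": [3.276, 3.514],
                "phi": [[0.188, 0.016], [0.016, 0.149]],
                "alpha": 1.471,
                "gamma_lin": [-0.045, -0.252],
                "gamma_quad": [[0.009, 0.009], [0.009, 0.036]],
                "psi": 0.002,
            },
        ],
    )


def reading_indirect() -> MixtureModel:
    """Two-class indirect application: shared coefficients, nonnormal xi."""
    shared = {
        "alpha": -0.157,
        "gamma_lin": [0.025, 0.450],
        "gamma_quad": [[0.017, 0.010], [0.010, -0.063]],
        "psi": 0.027,
    }
    return _model(
        "indirect",
        [
            {
                "weight": 0.606,
                "kappa": [2.273, 3.274],
                "phi": [[0.272, 0.063], [0.063, 0.318]],
                **shared,
            },
            {
                "weight": 0.394,
                "kappa": [3.333, 3.498],
                "phi": [[0.140, 0.017], [0.017, 0.177]],
                **shared,
            },
        ],
    )


def reading_by_gender() -> MixtureModel:
    """Observed-group model: female (class 0) and male (class 1) students."""
    return _model(
        "multigroup",
        [
            {
                "weight": 0.5,
                "kappa": [2.875, 3.409],
                "phi": [[0.479, 0.055], [0.055, 0.256]],
                "alpha": -0.525,
                "gamma_lin": [-0.037, 0.721],
                "gamma_quad": [[0.020, 0.021], [0.021, -0.108]],
                "psi": 0.025,
            },
            {
                "weight": 0.5,
                "kappa": [2.505, 3.315],
                "phi": [[0.419, 0.135], [0.135, 0.435]],
                "alpha": -0.207,
                "gamma_lin": [0.078, 0.429],
                "gamma_quad": [[0.023, -0.008], [-0.008, -0.053]],
                "psi": 0.026,
            },
        ],
    )
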