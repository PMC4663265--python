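"""Standardized simple-slope curves at fixed moderator levels.

Fixing the standardized moderator xi_k* at a level m (in SD units) turns the
standardized structural polynomial into a conditional curve in the focal
predictor xi_j*:

    eta* = (gamma_k* m + omega_kk* m^2)            # constant
         + (gamma_j* + omega_jk* m) xi_j*          # conditional linear slope
         + omega_jj* (xi_j*)^2                     # curvature

Low/average/high moderator levels default to -1/0/+1 SD, the usual
convention for probing interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standardize import StandardizedSolution, standardize_pooled, standardize_within

__all__ = ["SimpleSlope", "simple_slope", "slope_table", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class SimpleSlope:
    """Quadratic conditional curve eta* = intercept + linear x + quadratic x^2."""

    intercept: float
    linear: float
    quadratic: float
    focal: int
    moderator: int
    level: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.linear * x + self.quadratic * x**2


def simple_slope(
    sol: StandardizedSolution, focal: int, moderator: int, level: float
) -> SimpleSlope:
    """Conditional curve of the outcome on ``focal`` at a moderator level.

    ``level`` is in standard-deviation units of the solution's reference
    frame.  Other predictors (p > 2) are held at the frame mean (zero).
    """
    if focal == moderator:
        raise ValueError("focal and moderator must differ")
    p = sol.gamma_lin_std.shape[0]
    for idx in (focal, moderator):
        if not 0 <= idx < p:
            raise IndexError(f"predictor index {idx} out of range for p={p}")
    const = sol.gamma_lin_std[moderator] * level + sol.gamma_quad_std[moderator, moderator] * level**2
    lin = sol.gamma_lin_std[focal] + sol.gamma_quad_std[focal, moderator] * level
    return SimpleSlope(
        intercept=float(const),
        linear=float(lin),
        quadratic=float(sol.gamma_quad_std[focal, focal]),
        focal=focal,
        moderator=moderator,
        level=float(level),
    )


def slope_table(
    model,
    frame: str = "pooled",
    focal: int = 1,
    moderator: int = 0,
    levels=DEFAULT_LEVELS,
    grid=None,
) -> pd.DataFrame:
    """Evaluate simple-slope curves for every class over a grid.

    Returns long-format rows ``(class, level, x, y)`` ready for plotting,
    with the focal predictor grid defaulting to [-3, 3] standardized units.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if grid is None:
        grid = np.linspace(-3.0, 3.0, 61)
    grid = np.asarray(grid, dtype=float)

    if frame == "within":
        sols = [standardize_within(c) for c in model.classes]
    elif frame == "pooled":
        sols = standardize_pooled(model)
        if not isinstance(sols, list):
            sols = [sols]
    else:
        raise ValueError(f"frame must be 'within' or 'pooled', got {frame!r}")

    records = []
    for g, sol in enumerate(sols):
        for level in levels:
            curve = simple_slope(sol, focal, moderator, level)
            y = curve(grid)
            for xi, yi in zip(grid, y):
                records.append((g, float(level), float(xi), float(yi)))
    return pd.DataFrame(records, columns=["class", "level", "x", "y"])
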