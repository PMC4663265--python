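"""Within-class standardization of a two-class nonlinear structural model.

Loads the bundled two-class direct-application estimates (reading skills on
reading attitude and online activities, with an interaction and two
quadratic effects) and standardizes each class against its own means and
variances.  The standardized coefficients are effect sizes for an average
member of that class; 1 - psi* is the variance explained within the class.
"""

import numpy as np

from semstd import datasets, standardize_within

model = datasets.reading_direct()
for g, cls in enumerate(model.classes, start=1):
    sol = standardize_within(cls)
    print(f"class {g} (weight {cls.weight:.3f})")
    print(f"  implied outcome variance phi00 = {sol.eta_variance:.5f}")
    for j, name in enumerate(model.predictor_names):
        print(f"  linear  {name:<9} gamma* = {sol.gamma_lin_std[j]: .3f}")
    print(f"  interaction        omega* = {sol.gamma_quad_std[0, 1]: .3f}")
    print(f"  quadratic attitude omega* = {sol.gamma_quad_std[0, 0]: .3f}")
    print(f"  quadratic online   omega* = {sol.gamma_quad_std[1, 1]: .3f}")
    print(f"  residual share psi* = {sol.psi_std:.3f}  ->  R^2 = {sol.r_squared:.1%}")
    print()

print("The linear effects differ strongly between the classes (0.122 vs")
print("0.384 for attitude) even though no nonlinear effect is sizable:")
print("the two classes sit at different points of a curved relationship.")
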