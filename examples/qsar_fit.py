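"""Fit an MLR QSAR on the 4-compound colorectal (HCT) panel - and see why
it cannot be validated.

With four observations and five descriptors the least-squares system is
underdetermined: the minimum-norm fit interpolates exactly (r2 = 1), so
the flag matters more than the score.  Contrast with the synthetic panel
in synthetic_recovery.py, where n >> p and coefficients are genuinely
recoverable.
"""

import thioscreen as ts

orbitals = ts.bundled_fixture("reactivity_inputs")
descriptors = ts.descriptor_table(orbitals, phase="aqueous")
physchem = ts.bundled_fixture("physchem")
activities = ts.bundled_fixture("activities")

spec = ts.ModelSpec(
    response="reciprocal",
    descriptor_names=("e_lumo", "chi", "s_soft", "logp", "n_rotb"),
    phase="aqueous",
)
X, y, compounds = ts.build_design_matrix(
    descriptors, physchem, spec, activities, cell_line="HCT"
)
fit = ts.fit_ols(X, y, names=spec.descriptor_names)
print(f"n = {fit.n}, p = {fit.p}, r2 = {fit.r2:.6f}, "
      f"underdetermined = {fit.underdetermined}")
print(ts.predicted_vs_observed(fit, X, y, compounds).round(4).to_string(index=False))
print("\nan exact interpolation: residuals are zero by construction,"
      "\nso this r2 says nothing about predictive power.")
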