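"""Fit every dietary model family to one simulated dataset and compare.

Simulates one dataset of 1,000 days under the log2 truth mechanism, fits
the eight variable-total families, and prints each family's 100-kcal
carbohydrate-for-protein estimate next to the known true effect.
"""

import codasub as cs
from codasub.truth import SubstitutionQuery

truth = cs.default_truth("log2", "variable")
data = cs.simulate_variable_total(n=1000, seed=42)
fpg = cs.simulate_outcome(data, truth, seed=43)

query = SubstitutionQuery("Carbs", "Protein", 100.0, truth.start)
print(f"true 100-kcal effect under the log2 mechanism: "
      f"{cs.true_effect(truth, query):+.3f} mmol/l\n")

for family in ("2A", "2B", "2Bprime", "2C", "2Cprime", "2D", "2Dprime", "2E"):
    spec = cs.ModelSpec(family)
    if spec.is_gam:
        k = cs.select_gam_basis(spec, data, fpg)
        spec = cs.ModelSpec(family, smooth_k=k)
    fitted = cs.fit(spec, data, fpg)
    estimate = cs.estimate_substitution(fitted, query)
    note = f"(k={spec.smooth_k} by AIC)" if spec.is_gam else ""
    print(f"  {family:>8} {fitted.spec.description:<32} {estimate:+.3f} mmol/l {note}")

print(
    "\nThe all-components log2 model (2C') matches the data-generating "
    "mechanism and sits closest to the truth.  The unadjusted nutrient "
    "density model (2B) and the CoDA model (2E) are structurally "
    "misspecified here and miss badly; the leave-one-out families (2A, 2C, "
    "2D) drift toward the linear approximation of the contrast.  Medians "
    "over many replicates (example 04) make the pattern sharp."
)
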