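"""Average treatment effects in each internal target population.

Draws a three-source synthetic study, estimates the ATE in the population
underlying each source with the doubly robust augmented estimator, and
compares each estimate with the generative truth.
"""

import causalmeta as cm

# a moderate-size study: three sources, five-level effect modifier
dgp = cm.SyntheticDGP(sizes=(1200, 800, 600), n_external=1500, p=5)
data, external, _ = cm.generate(dgp, seed=42)
truth = cm.true_effects_closed_form(dgp).set_index(["target", "subgroup"])["truth"]

spec = cm.AnalysisSpec(target="internal", estimand="ATE",
                       treatment_model_type="separate", seed=42)
cm.validate_inputs(data, None, spec).raise_if_fatal()
fits = cm.fit_nuisances(data, None, spec)

print("ATE per internal target population (truth in brackets):")
for est in cm.effect(data, None, fits, spec):
    t = truth.loc[(est.target_id, "overall")]
    print(f"  source {est.target_id}: {est.diff:6.3f} "
          f"[95% CI {est.ci_low:6.3f}, {est.ci_high:6.3f}]   (truth {t:.3f})")
print("Each row is the mean difference in potential outcomes for the")
print("population underlying that source; the CI is Wald, from the")
print("influence-function standard error.")
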