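"""Generalized concentration addition for low-efficacy (partial agonist)
components.

Three perfluorinated carboxylic acids with slope-1 Hill curves and
sub-maximal asymptotes (0.62-0.75): CA cannot invert effects above the
smallest asymptote, so the report grid truncates automatically at 60%,
while GCA's inverse-function extension stays defined.
"""

from mixtoxpred import case_study_fixture, gca_effect, predict_mixture, predictable_effect_range
from mixtoxpred.io import results_table

spec = case_study_fixture("cs3")
rng = predictable_effect_range(spec.drcs)
print(f"{spec.product_name}")
for c in spec.components:
    print(f"  {c.name}: Hill_three alpha={c.drc.params[0]:g} uM, max effect {c.drc.max_effect:.2f}")
print(f"Auto-determined predictable range: {rng.lo * 100:.0f}-{rng.hi * 100:.0f}%")

results = predict_mixture(spec, ["CA", "IA", "GCA"])
print(results_table(results).to_string(index=False))

e_inf = gca_effect(spec.components, 1e6)
print(f"\nGCA saturating effect at very high dose: {e_inf:.3f}")
print("Below every asymptote CA and GCA solve the same equation and agree;")
print("GCA's advantage is extending the curve toward the mixture's own ceiling,")
print("a potency-weighted mean of the component asymptotes.")
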