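"""Predict a mixture EC50 from safety-data-sheet endpoints alone.

A coating product is known only through its SDS: worst-case composition
percentages and 48-h Daphnia magna EC50s for four solvents, no curves.
Simple CA is the only applicable model; it returns one scalar.
"""

from mixtoxpred import case_study_fixture, simple_ca_ec50

spec = case_study_fixture("cs2")
print(f"{spec.product_name}: {len(spec.components)} components (mg/L basis)")
for c in spec.components:
    print(f"  {c.name:18s} {c.fraction * 100:5.1f}%   EC50 = {c.endpoint_value.value:8.1f} mg/L")

ec = simple_ca_ec50(
    [c.fraction for c in spec.components],
    [c.endpoint_value for c in spec.components],
    "mg/L",
)
print(f"\nSimple CA mixture EC50: {ec.value:.3f} {ec.unit}")
print("Weights enter exactly as listed (they sum to 0.90 in this worst case);")
print("the reciprocal-sum rule makes the most toxic, most abundant solvent dominate.")
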