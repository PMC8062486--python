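"""Bias from aging one subspecies' lenses with another's curve.

Lenses grown under the Oca curve (asymptote 240 mg) are inverted with the
Iberian Occ curve (273 mg): because the assumed asymptote is too high, the
same lens weight maps to a younger age, so Oca rabbits are systematically
under-aged, and the error grows without bound as lenses approach the true
asymptote.  Juvenile aging from body weight is shown alongside.
"""

from lensage import (
    JuvenileGrowthParams,
    OCA_IBERIAN,
    OCC_IBERIAN,
    age_bias_table,
    age_from_weight,
)

table = age_bias_table(OCA_IBERIAN, OCC_IBERIAN, [180, 360, 720])
print("Oca lenses aged with the Occ-Iberia curve:")
print(table.round(1).to_string(index=False))
# bias_days < 0: under-aging; |bias| grows with age.

jp = JuvenileGrowthParams()
for w in (250.0, 493.1):
    est = age_from_weight(jp, w)
    print(f"juvenile at {w:.1f} g -> {est.age_days:.1f} d (estimated age)")
try:
    age_from_weight(jp, 620.0)
except ValueError as exc:
    print(f"juvenile at 620.0 g -> refused: {exc}")
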