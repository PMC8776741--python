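"""Dose-rate sparing: survival at a fixed dose as delivery slows down.

Evaluates 10 Gy delivered at average dose rates from 1.0 down to 0.01
Gy/min.  Rates below the 1.0 Gy/min beam rate are realized as 1-Gy
fractions with equal gaps, mirroring multi-fractionated delivery.  Slower
delivery lets sub-lethal damage repair run during irradiation, so survival
rises; the effect is stronger in the radioresistant line whose progeny
repair faster.
"""

import imksurv as ik
from imksurv.protocols import AcuteDelivery, FractionatedDelivery

ctx = ik.REFERENCE_CONTEXT
parent = ik.SAS_FAMILY.parent_model()
resistant = ik.SAS_FAMILY.resistant_model()

dose = 10.0
rates = [1.0, 0.25, 0.1, 0.05, 0.01]

print(f"{'rate (Gy/min)':>14} {'S (SAS)':>12} {'S (SAS-R)':>12}")
for rate in rates:
    if rate >= 1.0:
        delivery = AcuteDelivery(dose_rate_gy_min=rate)
    else:
        delivery = FractionatedDelivery(
            fraction_size=1.0, beam_rate_gy_min=1.0, average_rate_gy_min=rate
        )
    Sp = ik.survival_curve(parent, ctx, [dose], delivery)["surviving_fraction"][0]
    Sr = ik.survival_curve(resistant, ctx, [dose], delivery)["surviving_fraction"][0]
    print(f"{rate:>14} {Sp:>12.5f} {Sr:>12.5f}")

print(
    "\nSurvival increases monotonically as the average dose rate falls:"
    "\nthe Lea-Catcheside factor suppresses the quadratic lesion-interaction"
    "\nterm once delivery is slow compared with the repair rate (a+c)."
)
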