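"""Acute dose-response of a parental line and its radioresistant sibling.

Builds the two-population IMK models of the SAS family from the reference
parameter set and prints the predicted surviving fraction after acute X-ray
doses.  The resistant line survives more at every dose because its progeny
cells repair faster (w_SLDR = 1.059 scales alpha0/beta0 down) and its
stem-like fraction is ~7x higher.
"""

import imksurv as ik

ctx = ik.REFERENCE_CONTEXT
parent = ik.SAS_FAMILY.parent_model()
resistant = ik.SAS_FAMILY.resistant_model()

doses = [0, 2, 4, 6, 8, 10, 15]
parent_curve = ik.survival_curve(parent, ctx, doses)
resistant_curve = ik.survival_curve(resistant, ctx, doses)

print(f"per-domain dose coefficient gamma = {ik.gamma_coefficient(ctx):.4f} Gy")
print(f"{'dose (Gy)':>10} {'S (SAS)':>12} {'S (SAS-R)':>12}")
for d, sp, sr in zip(
    doses,
    parent_curve["surviving_fraction"],
    resistant_curve["surviving_fraction"],
):
    print(f"{d:>10} {sp:>12.5f} {sr:>12.5f}")

print(
    "\nThe log-survival curves are sigmoid: beyond ~10 Gy both flatten toward"
    "\nthe radioresistant stem-like component, and the resistant line's"
    "\nsurvival advantage grows with dose."
)
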