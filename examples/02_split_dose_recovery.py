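"""Estimating the sub-lethal damage repair rate from a split-dose experiment.

Simulates a 2 Gy + 2 Gy split-dose recovery experiment (intervals 0-24 h,
3 replicates, realistic noise), then recovers the SLDR rate (a+c) from the
curve's initial slope and plateau.  The generating rate is the SAS parental
value, 1.279 h^-1.
"""

import imksurv as ik

gamma = ik.gamma_coefficient(ik.REFERENCE_CONTEXT)
progeny = ik.SAS_FAMILY.parent_model().progeny

curve = ik.simulate_recovery_curve(
    progeny, gamma, D1=2.0, D2=2.0, sigma=0.05, replicates=3, seed=42
)
endpoints = ik.estimate_recovery_endpoints(curve)
rate, rate_sd = ik.bootstrap_sldr_rate(curve, n_boot=1000, seed=42)

print(f"S(0)          = {endpoints.S0:.4f}   (no recovery between fractions)")
print(f"S(inf)        = {endpoints.S_inf:.4f}   (full recovery plateau)")
print(f"dS/dtau at 0  = {endpoints.initial_slope:.4f} h^-1")
print(f"SLDR rate     = {rate:.3f} +/- {rate_sd:.3f} h^-1   (truth: 1.279)")
print(
    "\nThe rate is the initial relative slope divided by ln(S_inf/S0); its"
    "\nuncertainty comes from a replicate-level bootstrap.  On a noiseless"
    "\ncurve the identity returns the generating rate exactly."
)
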