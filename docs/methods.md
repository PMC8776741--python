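# Methods

## Model

The package implements the integrated microdosimetric-kinetic (IMK) account
of clonogenic survival.  The cell nucleus is treated as a set of micron-scale
domains; radiation-induced potentially lethal lesions (PLLs) in a domain
either become lethal directly, interact pairwise to lethality, or are
repaired.  Only two lumped quantities survive into the closed forms: the
linear-quadratic coefficients α₀ (Gy⁻¹) and β₀ (Gy⁻²), and the sub-lethal
damage repair (SLDR) rate (a+c) (h⁻¹), dominated in practice by the fast
(NHEJ) repair component.  The microdosimetric intercept couples α₀ with
γ β₀, where γ = y_D/(ρ π r_d²) is the mean specific energy per event in a
domain; with y_D = 4.68 keV/µm for 150 kVp X rays, water density and
r_d = 0.5 µm, γ = 0.9547 Gy.  The Lea–Catcheside factor
F(x) = 2(x + e⁻ˣ − 1)/x², x = (a+c)·T, scales the quadratic term for a
uniform delivery of length T; it is 1 for acute exposure and behaves as
2/x for very slow delivery, which is why log-survival becomes linear in
dose at low dose rates.

Model assumptions worth keeping in mind: no proliferation/repopulation
during or after delivery, no cell-cycle redistribution, no reoxygenation or
inverse dose-rate effects, and a time-invariant stem-like fraction.  These
restrict validity to in-vitro clonogenic assays over delivery times of
hours.

### Multi-fraction generalization

Only the two-fraction split-dose closed form has a conventional printed
expression.  For arbitrary timed protocols the evaluator sums per-fraction
LQ terms (each with the Lea–Catcheside factor of its own beam-on duration)
and adds the pairwise cross terms

    2 β₀ Σ_{i<j} e^{-(a+c) τ_ij} D_i D_j,

with τ_ij measured from the end of fraction i to the start of fraction j.
This choice reduces exactly to the split-dose form for two instantaneous
fractions and to the continuous single-exposure form for one fraction, and
its many-small-fraction limit converges to the Lea–Catcheside integral
(relative error of -ln S: 0.19% at 100 fractions, 0.019% at 1000, for the
SAS parameters at 10 Gy over 1 h).  Cross-fraction protraction within
fractions of nonzero duration is deliberately not double-counted.

### Two-population mixture

A line's survival is S = (1−f_s) S_p + f_s S_s.  The stem population's
repair rate is structurally tied to the parental progeny rate,
(a+c)_H = w_SLDR · (a+c)_p, and is never stored independently; resistant
lines additionally carry progeny coefficients divided by w_SLDR (α₀ and β₀
are inversely proportional to the repair rate in the underlying kinetics).
w_SLDR is dimensionless (a ratio of two rates).  The mixture makes
log-survival sigmoid in dose: the high-dose tail follows the more resistant
stem component.

## Units and numerics

Rates are h⁻¹, times h, doses Gy; dose rates cross the interface in Gy/min
(the experimental unit) and are converted internally (×60).  keV→J uses the
exact CODATA constant 1.602176634e-16.  F is evaluated with `expm1` to
avoid catastrophic cancellation at small (a+c)·T and by its second-order
series below (a+c)·T = 1e-6, making F(0) = 1 exact.  Degenerate inputs
(negative doses/intervals, overlapping fractions, non-positive
microdosimetric constants) raise typed errors rather than producing NaNs.

## SLDR estimation from split-dose recovery

The recovery curve S(τ) after D₁ + D₂ follows
-ln S(τ) = p + q e^{-kτ} with amplitude q = 2β₀D₁D₂ and k = (a+c).  The
estimator fits this three-parameter form to -ln S by nonlinear least
squares (plateau initialized from the τ ≥ 6 h points, amplitude from the
earliest interval, rate from the literature mid-range 1.5 h⁻¹) and then
applies the slope/plateau identity
(a+c) = [(1/S₀)·dS/dτ|₀] / ln(S_∞/S₀), which collapses algebraically to the
fitted k — so on noiseless model-generated curves the generating rate is
recovered exactly (the test suite verifies 1e-6 over random draws).  The
identity's ratio structure cancels any common rescaling of all survivals,
so plating-efficiency normalization does not bias the rate.  A flat curve
returns zero initial slope; a curve whose plateau lies below S(0) is
rejected as unfittable.

Rate uncertainty comes from a nonparametric bootstrap over replicates
within each interval (default 1000 resamples, seeded).  With the default 3
replicates per interval the naive within-cell resampling understates the
sampling variance by the factor (n−1)/n, so the bootstrap SD is inflated by
sqrt(n/(n−1)); against direct Monte-Carlo replication of the whole
experiment this inflation brings the SE estimate in line with the true
sampling SD (0.28 vs 0.275 at σ = 0.05).

## Bayesian family fitting

The likelihood is Gaussian on the -ln S scale (the same scale on which the
generator places noise); the standard density normalization 1/(σ√(2π)) is
used — any constant convention cancels in the Metropolis ratio.  σ defaults
to the pooled replicate SD of the data, pooled over (line, protocol, dose)
cells with dose > 0: the zero-dose cells are excluded because observed
survival is capped at 1 by plating-efficiency normalization, which
truncates their replicate spread and would bias σ downward.  Optionally σ
can be sampled under a weak half-normal prior (`estimate_sigma=True`).

Priors follow the two-stage experimental workflow: uniform boxes for the LQ
coefficients (α ∈ (0,1) Gy⁻¹, β ∈ (0,0.5) Gy⁻²) and w_SLDR ∈ [1,5] —
generous envelopes around reported estimates, all configurable, with the
lower bound of w exposed rather than hard-coded since enhancement below 1
is conceivable; a normal prior on (a+c)_p carrying over the split-dose
estimate and its SE; truncated normals on [0,1] for the two stem fractions,
taken directly from the flow-cytometry mean ± SD.  Stem coefficients are
constrained below the progeny ones (α₀s < α₀p, β₀s < β₀p); violations get
−∞ log-density, i.e. rejection rather than exceptions.  Families are fit
independently; the parent and resistant lines of one family share
[α₀p, β₀p, (a+c)_p, α₀s, β₀s, w_SLDR] and differ only in f_s and in the
resistant line's derived progeny coefficients — matching the layout in
which published family tables print a single stem column per family.

Sampling is seeded Gaussian random-walk Metropolis: 5×10⁴ iterations, first
20% discarded as burn-in.  During burn-in, proposal scales adapt toward
~30% acceptance in windows of 500 iterations, and from the midpoint of
burn-in the proposal switches to a covariance-shaped step (Cholesky of the
trailing-half sample covariance, scaled by 2.4/√d) re-estimated every
window — the classic adaptive-Metropolis scheme.  All adaptation freezes at
the end of burn-in, so the retained chain satisfies detailed balance.
Parameters with zero-width priors are pinned (never proposed), which makes
degenerate point-mass priors exact.  The summary reports posterior
means/SDs for the eight parameters plus the derived (a+c)_H, α₀p*, β₀p*,
the acceptance rate, per-parameter effective sample sizes (via arviz), and
R² per line on the -ln S scale at the posterior mean.  A post-burn-in
acceptance rate below 1% raises a sampler-stuck error.

## Synthetic data generator

The generator emulates the experimental campaign used to characterize a
parental/resistant pair: acute dose-response at 0–10 Gy (1 Gy/min beam),
split-dose 2 Gy + 2 Gy at intervals {0, 0.5, 1, 2, 3, 6, 12, 24} h,
multi-fractionated 1-Gy fractions realizing average dose rates down to 0.01
Gy/min (e.g. 10 Gy at 0.1 Gy/min = 10 fractions over 100 min with 10-min
gaps), 3 replicates per condition, and flow-cytometry-style stem-fraction
measurements (3 repeats, truncated-normal in [0,1], SDs matching typical
ALDEFLUOR replicate spreads: 0.0068 for a ~1% parent, 0.0365 for a ~10%
resistant line).  Survival noise is Gaussian on -ln S (σ = 0.1 by default),
the exact error model the likelihood assumes, with observed -ln S clipped
at 0 so survival never exceeds 1; the clip only ever binds at zero dose,
where the model prediction is parameter-independent, so it cannot bias the
fit.  Colony-count (Poisson) sampling, ALDEFLUOR gating mechanics and
cytometer artifacts are not modelled: passing recovery tests demonstrate
self-consistency of the estimator with this noise model, not robustness to
count noise or gating bias in real assays.  One seed fans out to
per-experiment substreams via `numpy.random.SeedSequence.spawn`, so
composite runs are reproducible component-wise.

## Problem sizes used in the shipped checks

The parameter-recovery study runs ten synthetic SAS-like families (36
survival records each) with 5×10⁴-iteration chains; it verifies that the
first family's posterior means land within 2 posterior SDs of truth for all
eight parameters and that ≥90% of the 80 truths fall in central 95%
credible intervals.  The oracle equivalences use 1000-fraction protocols;
the SLDR round trip uses 100 random parameter draws.  These sizes keep a
full verification run around a minute on one CPU while leaving the
statistical checks well-powered.

## Known limitations

Identifiability is structural, not numerical: with acute-only survival
data, (a+c)_p is informed solely by its split-dose prior and w_SLDR solely
by the resistant line's curves (the test suite asserts both).  The
two-population mixture is a deliberate simplification — real CSC content is
plastic and assay-dependent — and the stem fractions inherit any bias of
the flow-cytometry priors, which dominate f_s for low-f_s parental lines.
R² values near 1 on synthetic data reflect the matched noise model and
should not be read as evidence about model adequacy on real assays.
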