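# imksurv

Two-population **integrated microdosimetric-kinetic (IMK)** modelling of
clonogenic cell survival after X-ray irradiation, for radiation biologists
and medical physicists studying acquired radioresistance: closed-form
surviving fractions under acute, protracted, split-dose and
multi-fractionated delivery; estimation of the sub-lethal damage repair
(SLDR) rate from split-dose recovery experiments; and Bayesian joint fitting
of parental + radioresistant cell-line families that mixes progeny cells
with a cancer stem-like (CSC) sub-population.

## The model

For a single homogeneous population receiving dose *D* (Gy) over delivery
time *T* (h), the lethal-lesion burden is linear-quadratic with a
microdosimetric intercept and a protraction-dependent quadratic term:

    -ln S = (α₀ + γ β₀) D + F β₀ D²,     γ = y_D / (ρ π r_d²)

where *y_D* is the dose-mean lineal energy (keV/µm), *r_d* the domain
radius (µm), and *F* the Lea–Catcheside time factor

    F = 2 / ((a+c)² T²) · [(a+c) T + e^{-(a+c)T} - 1]

with *(a+c)* the SLDR rate (h⁻¹).  Two acute fractions *D₁*, *D₂* separated
by interval τ add a decaying cross term `2 β₀ e^{-(a+c)τ} D₁ D₂`; the
package generalizes this pairwise pattern to arbitrary timed fraction
sequences.  The split-dose recovery curve yields the SLDR rate through

    (a+c) = [ (1/S) dS/dτ |_{τ→0} ] / ln( S(∞) / S(0) )

A cell line is a mixture `S = (1-f_s) S_p + f_s S_s` of progeny cells and a
more radioresistant stem-like fraction *f_s*.  A radioresistant sub-line
differs from its parent by (i) a higher *f_s* and (ii) an SLDR enhancement
ratio *w_SLDR = (a+c)_H / (a+c)_p* that rescales its progeny coefficients
(`α₀p* = α₀p / w_SLDR`, `β₀p* = β₀p / w_SLDR`).  All eight family parameters
[α₀p, β₀p, (a+c)_p, α₀s, β₀s, w_SLDR, f_s(parent), f_s(resistant)] are
estimated jointly by seeded random-walk Metropolis with a Gaussian
likelihood on -ln S, following the two-stage design used experimentally:
the split-dose analysis supplies the (a+c)_p prior, flow-cytometry ALDH(+)
fractions supply the f_s priors.

## Worked example

```python
import imksurv as ik

ctx = ik.REFERENCE_CONTEXT                    # 150 kVp X rays, 0.5 µm domains
parent = ik.SAS_FAMILY.parent_model()         # SAS oral squamous carcinoma
resistant = ik.SAS_FAMILY.resistant_model()   # its radioresistant sibling

print(ik.gamma_coefficient(ctx))              # 0.9547 Gy per event per domain
print(ik.survival_curve(parent, ctx, [2, 6, 10])["surviving_fraction"].round(5).tolist())
print(ik.survival_curve(resistant, ctx, [2, 6, 10])["surviving_fraction"].round(5).tolist())
```

prints

```
0.9546987752918343
[0.51136, 0.04772, 0.00129]
[0.54535, 0.0671, 0.00341]
```

— at 10 Gy the resistant line survives 2.6× better, and the gap keeps
widening with dose as the stem-like component dominates.  The
`examples/` directory has one narrative script per capability
(dose-response curves, split-dose SLDR estimation, dose-rate effects, and
the full Bayesian family fit); each prints the numbers it computes and a
line on what they mean.  A thin CLI mirrors the pipeline:
`imksurv simulate | sldr-estimate | fit-family | predict | report`.

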