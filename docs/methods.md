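# Methods

## Physical model

Backbone amide ¹⁵N relaxation is modelled with two mechanisms: the
¹H–¹⁵N dipolar interaction, d = (μ₀ h γH γN)/(8π² r³NH), and ¹⁵N
chemical-shift anisotropy, c = ωN Δσ/√3.  Internal and overall motion
are assumed statistically independent (the central model-free
assumption), giving the extended spectral density

    J(ω) = (2/5)[ S² τm/(1+(ωτm)²) + (S²f − S²) τ′/(1+(ωτ′)²) ],
    1/τ′ = 1/τm + 1/τe,   S² = S²f · S²s,

whose single-timescale form is the S²f = 1 special case.  Conformational
exchange on the µs–ms timescale enters R₂ as an additive term Rex valid
at the field of the record's context; when records from several fields
are combined, Rex is treated as field-specific (each record carries its
own context) rather than rescaled.

Axially symmetric overall tumbling replaces the single τm Lorentzian
pair by the three-component sum with weights A₁ = (3cos²θ−1)²/4,
A₂ = 3sin²θcos²θ, A₃ = (3/4)sin⁴θ (θ = angle between the N–H vector and
the unique axis) and correlation times 1/(6D⊥), 1/(5D⊥+D∥),
1/(2D⊥+4D∥), with τm interpreted as 1/(6D_iso).  It reduces exactly to
the isotropic form at D∥/D⊥ = 1.  Because per-residue N–H orientations
require a coordinate frame the pipeline CLI wires up only the isotropic
model; the axial form is available in the library.

### Constants

| parameter | default | unit | why |
|---|---|---|---|
| proton frequency | 600.13 | MHz | what a "600 MHz" spectrometer actually runs at; configurable |
| r(N–H) | 1.02 | Å | long-standing community default for backbone amides |
| Δσ(¹⁵N) | −160 | ppm | standard backbone value |
| γH/γN | −9.8656 | – | sign carried only into the NOE |

All are exposed on `SpectrometerContext` so sensitivity to them can be
tested.  With these constants, refitting the published mutant-loop
relaxation triplets reproduces the published S² values to well within
their uncertainties, while the published (S², τe) pairs do not
back-predict the published rates exactly — the printed τe values are
consistent only with the (unprinted) constant set of the original
analysis.  The package therefore treats the *inverse* direction
(rates → parameters) as the validated one.

## Rate estimation from decay series

R₁ and R₂ come from nonlinear least squares of I(t) = I₀e^(−Rt) on the
untransformed heights (correct error model for intensity noise), two
free parameters, initialised from a log-linear regression.  Two distinct
delays are the formal minimum — they determine the exponential exactly;
realistic schedules have ten.  No baseline offset is fitted by default
(¹⁵N heteronuclear decays go to zero).  Replicates are fitted
independently; the reported rate is their mean and the reported
uncertainty the larger of the propagated fit error of the mean and the
half-range across replicates — a deliberately conservative rule, since
the original report's ± values are not defined as either.  Fitted rates
outside 0.01–100 s⁻¹ trigger a unit-plausibility warning (the classic
ms-vs-s delay mistake).  The NOE is the mean saturated/reference
peak-height ratio over experiment pairs with the sample SD over pairs
as its uncertainty (zero for a single pair).

## Model-free fitting and selection

Five parameterisations are fitted per residue by bounded multi-start
least squares on the weighted residuals of (R₁, R₂, NOE): m1 {S²},
m2 {S², τe}, m3 {S², Rex}, m4 {S², τe, Rex}, m5 {S²f, S²s, τe}.
Bounds: S², S²f, S²s ∈ [0, 1], τe ∈ [0, τm], Rex ∈ [0, 20] s⁻¹.  Starts
span S² ∈ {0.3, 0.6, 0.9}, τe ∈ {10 ps, 100 ps, 1 ns}, Rex ∈ {0, 2} s⁻¹
because the χ² surface is multimodal in τe; in addition every model is
warm-started from the exact embedding of its nested simpler models'
optima, which enforces nested χ² dominance (χ²(m4) ≤ χ²(m2) ≤ χ²(m1))
up to optimizer tolerance.  Start points are themselves scored as
candidate solutions, so an optimizer step can never end worse than the
best embedding.  τe is optimised on its own (ns) scale; uncertainties
below 0.5 % of an observable are floored at 0.5 % so that χ² stays
finite and no single over-precise observable dominates.

Selection is stepwise: m1 is accepted if its χ² passes a goodness-of-fit
test at the 90 % level whose critical value comes from 500 Monte-Carlo
simulations of the record (simulate from the fitted model with the
record's uncertainties, refit, take the 90th percentile of the refitted
χ² distribution).  Otherwise m2 and m3 are tested the same way, with an
additional F-test against m1 at the 80 % level for the added parameter.
If neither passes, the three-parameter models m4/m5 (zero degrees of
freedom on a one-field triplet, so no goodness-of-fit test can be
formed) compete by lowest χ², ties breaking toward the lower model id.
Because the simulated null distribution tracks a χ² law distorted by the
parameter bounds, the simulation is bracketed analytically: observed χ²
below the 5th percentile of the analytic law is accepted outright and χ²
above three times its 1−10⁻⁶ quantile rejected outright, which is
conservative in both directions and avoids simulating foregone
conclusions.  All Monte-Carlo draws are seeded from the selection
config and the residue id, making selection fully deterministic.

Parameter uncertainties are the SDs of refitted parameters over seeded
Gaussian resamples of the back-calculated rates.

## Overall correlation time

The initial estimate inverts the rigid-body R₂/R₁ ratio (10 %-trimmed
mean over residues with NOE > 0.65) numerically.  The final value
minimises the summed χ² of a rigid "core" subset — NOE > 0.65 and
R₂/R₁ within 1.5 SD of that subset's mean, which screens out
exchange-broadened residues — with per-residue re-selection between m1
and m2 (F-test) at each trial τm.  The 0.1-ns scan grid is restricted
to ±1.5 ns around the R₂/R₁ seed (the seed is accurate to a few
percent, so the window always brackets the minimum) and the best grid
point is refined by bounded scalar minimisation.  τm is a molecular
property: records from different fields are fitted jointly to one
value.  Fewer than five records is treated as underdetermined and
rejected.

## Comparison report

Percent-higher 100(a−b)/b, percent-lower 100(a−b)/a, and the symmetric
fold ratio max/min ≥ 1 are computed per residue and quantity; rendered
reports round percentages to integers and folds to one decimal
(matching the field's table style) while the machine-readable TSV keeps
full precision.  τe bands are half-open: slow > 500 ps ≥ intermediate
> 50 ps ≥ fast; the band edges themselves belong to the faster class,
a convention the package documents because the source legend does not
define it.  The composite amide shift difference uses the standard
weighting √(ΔδH² + (ΔδN/5)²) with a configurable nitrogen weight and a
0.3-ppm perturbation threshold.

## Synthetic data generator

`make_profile` builds a 68-residue ground truth: RGD-loop residues
(48–51) anchored to the published wild-type or mutant dynamics
parameters (e.g. mutant R49: S² = 0.53, τe = 1.04 ns, Rex = 0), a rigid
disulfide-bonded core (S² ~ N(0.82, 0.05) clipped to [0.70, 0.95], τe
< 50 ps, half of the residues purely rigid), flexible three-residue
termini (S² ∈ [0.45, 0.65], τe 0.1–0.5 ns) and moderately mobile loop
filler.  Prolines (positions 48 and 53 wild-type-like, 53 mutant-like)
are generated but withheld from all observable output, reproducing the
missing-data pattern of real amide-detected experiments.  Tumbling is
isotropic at τm = 6.38 ns by default.

`simulate_decays` produces peak heights I₀e^(−Rt)(1+ε), ε ~ N(0, cv),
on the experimental delay schedules (R₁: 30–3000 ms, R₂: 18–500 ms, ten
delays each), two replicates per rate and three NOE pairs.  Noise is
multiplicative (constant CV, default 2 %) because peak-height scatter
in well-resolved spectra scales with intensity; 2 % reproduces
published-scale ± errors.  What the generator does *not* emulate:
spectral overlap, baseline and phasing artefacts, anisotropic tumbling,
field-dependent Rex, or correlated replicate noise — so recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to every pathology of real spectra.

## Problem sizes and determinism

Recovery tests use the full 68-residue profile at 2 % height noise
(single seeded realisation) for the pipeline check, 25–30 residues for
nested-dominance and selection-frequency checks, and 1000 repeats for
the decay-fit calibration — sizes chosen to give stable medians and
proportions while keeping the suite quick.  Every stochastic step takes
an explicit seed; reruns are bitwise identical.

## Known limitations

- One field per record: no global multi-field fit of Rex dispersion.
- Axial diffusion needs user-supplied N–H angles; no coordinate-file
  reader is bundled, and the fully anisotropic tensor is out of scope.
- Model 5 on a single-field triplet is exactly determined; its selection
  rests on χ² comparison, not on a goodness-of-fit test.
- The replicate-uncertainty rule (max of propagated and half-range) is a
  convention; with only two replicates no rule is statistically sharp.
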