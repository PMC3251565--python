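# spindyn

Backbone-dynamics analysis of ¹⁵N spin-relaxation data in the
Lipari–Szabo model-free framework, built around the classic question:
*does a point mutation change a protein's structure, its motions, or
both?*  The motivating system is a small (68-residue) disulfide-rich
snake-venom disintegrin whose integrin-binding RGD loop keeps the same
backbone conformation in a P→A loop mutant while its picosecond–
nanosecond motions change markedly.

The package is for NMR spectroscopists and structural biologists who
have per-residue peak-height decay series (or already-reduced R₁/R₂/NOE
tables) and want a reproducible, scriptable route from raw peak heights
to order parameters and a wild-type-vs-mutant comparison report.

## What it computes

Relaxation of a backbone amide ¹⁵N is driven by the ¹H–¹⁵N dipolar
interaction and ¹⁵N chemical-shift anisotropy, both modulated by
rotational motion described by the spectral density

J(ω) = (2/5) [ S²τm / (1 + (ωτm)²) + (S²f − S²)τ′ / (1 + (ωτ′)²) ],  1/τ′ = 1/τm + 1/τe

with overall tumbling time τm, generalized order parameter S² (= S²f·S²s
in the extended two-timescale form) and effective internal correlation
time τe.  Observables follow the standard expressions

- R₁ = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c²J(ωN)
- R₂ = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)] + (c²/6)[4J(0) + 3J(ωN)] + Rex
- NOE = 1 + (d²/4)(γH/γN)(1/R₁)[6J(ωH+ωN) − J(ωH−ωN)]

The pipeline stages:

1. **decay fitting** — nonlinear least-squares monoexponential fits of
   peak height vs relaxation delay (R₁, R₂), NOE as the mean
   saturated/reference peak-height ratio over experiment pairs,
   replicate-aware uncertainties;
2. **model-free inference** — per-residue χ² fits of the five standard
   model-free parameterisations, stepwise model selection (Monte-Carlo
   goodness-of-fit at the 90 % level, F-tests at the 80 % level),
   τm optimisation on a rigid core subset, Monte-Carlo parameter errors;
3. **comparison reporting** — percent differences, fold changes, τe
   timescale bands, and composite amide chemical-shift screening
   between two proteins;
4. **synthetic data** — ground-truth profiles emulating the disintegrin
   (rigid disulfide core, flexible RGD loop, prolines withheld) with
   seeded multiplicative peak-height noise, so every stage can be
   validated against known truth.

## Worked example

Fit the published 600-MHz relaxation triplet of the mutant's R49 loop
residue (R₁ = 1.63 s⁻¹, R₂ = 5.98 s⁻¹, NOE = 0.42) at τm = 6.38 ns:

```python
from spindyn import (DiffusionModel, ResidueRelaxationRecord,
                     SpectrometerContext, fit_model, select_model)

ctx = SpectrometerContext()                     # 600.13 MHz, r_NH 1.02 A, CSA -160 ppm
diff = DiffusionModel(kind="isotropic", tm_s=6.38e-9)
rec = ResidueRelaxationRecord(residue_id=49, r1=1.63, r1_err=0.04,
                              r2=5.98, r2_err=0.01, noe=0.42, noe_err=0.01,
                              context=ctx)
fit = fit_model(rec, model_id=2, diffusion=diff)
print(f"S2 = {fit.params.s2:.3f}, te = {fit.params.te_s*1e9:.2f} ns")
sel = select_model(rec, diff)
print(f"selected model {sel.params.model_id}, Rex = {sel.params.rex:.2f} s^-1")
```

prints

```
S2 = 0.530, te = 0.68 ns
selected model 5, Rex = 0.00 s^-1
```

— a low order parameter with a slow (sub-ns) internal correlation time
and no conformational-exchange term: the mutant's arginine is mobile on
the ps–ns timescale but shows no µs–ms exchange broadening.  Running
the same fit on the corresponding wild-type triplet instead selects an
exchange-containing model with Rex > 0.

The same analysis from the shell, end to end on synthetic data:

```sh
spindyn simulate --preset rho_like  --seed 7 --out-dir wt
spindyn simulate --preset p48a_like --seed 7 --out-dir mut
spindyn rates wt/decays.tsv  --out-dir wt
spindyn rates mut/decays.tsv --out-dir mut
spindyn modelfree wt/rates.tsv  --tm-ns 6.38 --out-dir wt
spindyn modelfree mut/rates.tsv --tm-ns 6.38 --out-dir mut
spindyn compare wt/modelfree.tsv mut/modelfree.tsv \
    --rates-a wt/rates.tsv --rates-b mut/rates.tsv \
    --label-a WT --label-b P48A --out-dir cmp
```

Every stage writes a JSON run manifest; rerunning with the same seed
reproduces outputs byte for byte.

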