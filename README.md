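# quinoaphen

A phenomic characterization toolkit for quinoa (*Chenopodium quinoa*)
diversity panels, written for plant breeders and quantitative geneticists
evaluating germplasm in multi-environment greenhouse trials. It covers the
full post-harvest analysis chain for a randomized complete block design
(RCBD) replicated across greenhouses:

- **NIR spectral QC** — exclusion of predicted seed-composition samples by
  calibration-range filtering and Mahalanobis-distance outlier rejection
  (χ² upper tail, df = the 141 wavelengths of the 950–1650 nm / 5 nm grid),
  with covariance shrinkage for singular-prone pooled estimates;
- **seed-scan morphometry** — counting (with distance-transform watershed
  declumping of touching seeds), per-seed area, major/minor axes,
  eccentricity, and RGB color summaries from 1,200 dpi flatbed images;
- **derived traits** — days to growth stages, thousand seed weight (TSW),
  total seeds per plant, protein yield, and the study-style exclusion rules
  (yield < 0.5 g masks composition; < 97 counted seeds masks morphology);
- **mixed models** — REML variance components for
  `y_ijk = μ + g_i + e_j + (ge)_ij + r_jk + ε_ijk`, genotype BLUEs and
  BLUPs, and two heritabilities;
- **nutrition** — amino acid scores against WHO/FAO/UNU (2007) adult and
  infant requirements and limiting-amino-acid classification;
- **multivariate** — pairwise-complete correlations, PCA with uniform
  contribution thresholds (100/n traits), Ward and k-means grouping;
- **synthetic data** — generators for every input above with known ground
  truth (effect vectors, outlier labels, per-seed geometry), so the whole
  pipeline is testable without any external data.

## The statistics at the core

With variance components σ²g (genotype), σ²env, σ²g×e, σ²rep (replicate
within environment) and σ²err, and counts n_gen, n_env, n_rep:

```
H²_standard = σ²g / [σ²g + σ²env/n_env + σ²g×e/n_env + σ²rep/n_rep
                        + σ²err/(n_gen·n_env·n_rep)]

H²_Cullis   = 1 − v̄ΔBLUP / (2σ²g)
```

where v̄ΔBLUP is the mean prediction-error variance of a difference between
two genotype BLUPs (computed exactly over all pairs from the mixed-model
equations). Note the genotype count in the error divisor of H²_standard;
a conventional entry-mean variant without it is available via
`standard_h2(vc, conventional=True)`.

Balanced complete data is fit by the closed-form expected-mean-squares
estimator (identical to REML for interior estimates); unbalanced data by
EM-REML on Henderson's mixed-model equations with a gradient-based polish.

## Worked example

Simulate a full-scale panel (360 accessions × 2 greenhouses × 4 blocks)
with days-to-harvest variance components of a realistic magnitude, then
recover them and compute both heritabilities:

```python
from quinoaphen import (SimulationDesign, TrueComponents, simulate_phenotypes,
                        estimate_components, heritability)

design = SimulationDesign(n_gen=360, n_env=2, n_rep=4,
                          traits=("days_to_harvest",), seed=1)
truth = TrueComponents(sigma2_g=354.6, sigma2_env=9.1, sigma2_gxe=32.4,
                       sigma2_rep=7.9, sigma2_err=109.1)
sim = simulate_phenotypes(design, truth, grand_mean=110.0)

vc = estimate_components(sim.table, "days_to_harvest")
h2 = heritability(sim.table, "days_to_harvest", components=vc)
print(f"sigma2_g = {vc.sigma2_g:.1f}  (true 354.6)")
print(f"H2_standard = {h2.h2_standard:.3f}")
print(f"H2_Cullis   = {h2.h2_cullis:.3f}")
```

prints (one seed's realization):

```
sigma2_g = 318.7  (true 354.6)
H2_standard = 0.947
H2_Cullis   = 0.916
```

The genotypic variance estimate sits within sampling error of the truth
for a single trial, and both heritabilities are high, as expected when
σ²g dominates the design-divided nuisance components.

A full end-to-end synthetic run (spectra QC, seed scans, exclusions,
per-trait heritability table, nutrition classification, PCA and
clustering, with a manifest and exclusion audit):

```sh
quinoaphen run --outdir demo_run --seed 1
```

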