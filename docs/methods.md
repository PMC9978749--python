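# Methods

This note documents the models, estimators, numerical choices and known
limitations of `quinoaphen`, in the spirit of the methods documentation of
mature statistical packages.

## Trial model and variance components

Every quantitative trait is modelled per observation as

    y_ijk = μ + g_i + e_j + (ge)_ij + r_jk + ε_ijk

for genotype (accession) i = 1..n_gen, environment (greenhouse)
j = 1..n_env, and block k = 1..n_rep nested within environment. All
effects are independent Gaussian with mean zero and variances σ²g, σ²env,
σ²g×e, σ²rep, σ²err. Gaussian effects are an assumption, not a derivable
fact about real panels; it is the assumption implicit in fitting a linear
mixed model with REML, and the synthetic generator draws from exactly this
model so that estimator recovery can be scored against known truth.

### Estimation

`estimate_components` dispatches on the data:

- **Balanced complete data** (every genotype in every block of every
  environment, one observation per cell): closed-form expected-mean-squares
  (ANOVA) estimators. For this design,
  σ̂²err = MS_err, σ̂²g×e = (MS_GE − MS_err)/R, σ̂²rep = (MS_RE − MS_err)/G,
  σ̂²env = (MS_E − MS_GE − MS_RE + MS_err)/(GR), σ̂²g = (MS_G − MS_GE)/(ER).
  For interior (positive) estimates these coincide with REML on balanced
  data, which the test suite verifies to 1e-6 relative against the
  iterative path and against an external REML implementation (lme4).
- **Unbalanced data** (missing observations, masked cells): EM-REML on
  Henderson's mixed-model equations (MME). The coefficient matrix is the
  cross-product of [X | Z₁ … Z₄] with σ²err/σ²ₗ added to each random
  block's diagonal; EM updates are
  σ²ₗ ← (ûₗ'ûₗ + σ²err·tr(C⁻¹ₗₗ))/qₗ and
  σ²err ← (y'y − ŝ'W'y)/(n − p). The restricted log-likelihood is computed
  from the same factorization,
  −2ℓ_R = (n−p−q)·log σ²err + Σ qₗ log σ²ₗ + log|C| + y'Py,
  and is asserted non-decreasing across EM iterations. Convergence:
  |Δℓ| < 1e-8, max 500 iterations.

EM converges linearly and stalls short of full precision near the optimum,
so the EM solution is polished by L-BFGS-B on log-variances with the
analytic REML score (using the identities
y'PZₗZₗ'Py = ûₗ'ûₗ/σ⁴ₗ, tr(PZₗZₗ') = qₗ/σ²ₗ − σ²err·tr(C⁻¹ₗₗ)/σ⁴ₗ,
tr(P) = (n−p−q)/σ²err + Σ tr(C⁻¹ₗₗ)/σ²ₗ), followed by damped Newton steps
on the score with a finite-difference Jacobian. Step acceptance in the
Newton stage is by score-norm decrease, not objective decrease, because
near the optimum objective differences fall below floating-point
evaluation noise. Variances are floored at 1e-10 during iteration;
estimates at the floor are reported as 0 and flagged in
`VarianceComponents.clamped`.

With a single environment, σ²env and σ²g×e are structurally not estimable
and are reported as NaN; heritability formulas treat them as zero.

### BLUEs, BLUPs and heritability

BLUEs re-fit the model with genotype fixed (one column per accession, no
intercept, so the BLUE is directly an adjusted genotype mean) and the
remaining factors random at the variances from the all-random fit — a
generalized-least-squares solve through the same MME. BLUPs come from the
all-random MME; the prediction-error variance (PEV) matrix of the genotype
block is σ²err·(C⁻¹)_gg, and v̄ΔBLUP is the exact mean of
PEV_ii + PEV_jj − 2·PEV_ij over all genotype pairs (n_gen is at most a few
hundred here, so no pair sampling is needed).

Standard heritability uses the denominator
σ²g + σ²env/n_env + σ²g×e/n_env + σ²rep/n_rep + σ²err/(n_gen·n_env·n_rep).
The genotype count in the error divisor is unusual — the conventional
entry-mean form divides by n_env·n_rep only — but it is the convention this
package standardizes on for its reference outputs; the conventional form is
available behind `conventional=True`. With error variance divided by the
full observation count, the error term is nearly negligible at panel scale,
so H²_standard is driven by σ²g against the design-divided nuisance
components. Cullis heritability H² = 1 − v̄ΔBLUP/(2σ²g) is clamped to
[0, 1] and undefined (NaN) when σ²g = 0. Both statistics are invariant to
affine rescaling of the trait, which the suite checks numerically.

## Spectral quality control

Spectra live on a strictly increasing uniform wavelength grid; the
instrument default is 950–1650 nm at 5 nm (141 points). Two filters:

1. **Range filter.** A sample is excluded when any predicted analyte falls
   outside its packaged calibration [min, max]. Boundaries are inclusive
   (a value exactly at the limit is retained): "outside the range" is read
   strictly. Missing predictions never trigger exclusion. Hydroxylysine
   and hydroxyproline are carried in the packaged table but excluded from
   default filtering, as they are poorly predicted by the calibration.
2. **Mahalanobis filter.** d² = (x − c)' Σ⁻¹ (x − c) with c the
   per-wavelength mean of the calibration spectra and Σ the n−1-denominator
   covariance of the pooled calibration + experimental spectra (the pooled
   set is symmetric in ordering by construction). p = upper χ² tail of d²
   with df = number of wavelengths; excluded iff p < α (default 0.001).
   The squared distance is referred to χ² (not the unsquared distance) —
   the convention under which d² of a multivariate-normal deviation with
   known Σ is exactly χ²_p.

When the pooled count is ≤ the wavelength count (or Σ is numerically
singular), the covariance is shrunk toward its diagonal with the analytic
(Ledoit-Wolf-style, Schäfer–Strimmer) intensity
λ = Σ_{i≠j} Var(s_ij) / Σ_{i≠j} s²_ij; the report records λ. With
`shrinkage="never"` a singular Σ raises an error advising shrinkage.

Calibration of the realized false-positive rate: when the scored samples
are few relative to the pooled estimation set and n ≫ p, the flagged
fraction matches α within Monte-Carlo error. At the reference scale
(175 calibration + 200 experimental spectra, p = 141) the realized rate is
*below* nominal (~1e-4 at α = 0.001), because each scored spectrum
participates in Σ and its own distance is deflated (a Beta-type
finite-sample tail, lighter than χ²_p). The filter is therefore
conservative, never anticonservative, at that scale.

Moisture basis: dry-matter mass fractions convert to a fixed moisture
basis by multiplying by (1 − moisture), e.g. ×0.86 for the conventional
14%. Amino acids expressed per g protein are ratio-basis quantities and
pass through unchanged; their "14% moisture" annotation is metadata.

## Seed imaging

Scans are 8-bit RGB images of seeds on a matte-dark background, 1,200 dpi
by default. Segmentation is: Otsu threshold on luminance → connected
components → debris removal below `min_area_px` (default 30 px ≈
0.013 mm² at 1,200 dpi) → declumping by watershed on the smoothed
Euclidean distance transform. Watershed markers are local maxima of the
distance map at least 0.7 median-equivalent-radius apart and at least
0.4 of that radius deep. The geometry that makes this reliable: quinoa-like
seeds are nearly round (eccentricity ≈ 0.35, so minor/major ≈ 0.94), which
keeps the medial ridge of a single seed far shorter than the marker
spacing (one marker per seed), while two touching seeds' centers sit ≈1.8
radii apart (two markers). The distance-map smoothing σ scales with the
median radius to suppress discretization plateaus.

Geometry per region comes from the moment-equivalent ellipse
(scikit-image `regionprops`): area × (25.4/dpi)² in mm², axes × 25.4/dpi
in mm, eccentricity √(1 − (minor/major)²). Eccentricity is reported as the
true ellipse parameter — observed panel values (≈0.25–0.49) are only
consistent with this definition, not with a raw length:width ratio — and
the aspect ratio major/minor is exposed as a separate optional column.
Colour is the mean over all seed pixels per channel on the 0–255 scale
(float images in [0, 1] are rescaled by 255); sumRGB is the channel sum,
0–765, larger meaning closer to white.

The generator renders seeds as filled ellipses from a normal
equivalent-diameter distribution (default 1.8 ± 0.1 mm, giving areas near
2.5 mm²), jittered per-seed colour around a base RGB, and a configurable
fraction of seeds placed in touching pairs whose centre distance is
shortened by at most 20% of the smaller boundary radius along the actual
contact direction — touching but far from occluded, which is the regime
the watershed declumper is designed for. Subsample mass is proportional to
total true seed area at 1.3 mg/mm², chosen so default sizes give
thousand-seed weights inside the observed 0.8–4.7 g range.

## Derived traits and exclusions

TSW = subsample mass / counted seeds × 1000; total seeds per plant =
yield / TSW × 1000 (rounded); protein yield = crude protein fraction ×
yield. Exclusion rules mask trait groups without dropping rows, each mask
carrying a reason code: composition columns for yield < 0.5 g
(`low_yield`), morphology columns for < 97 counted seeds or a failed scan
(`few_seeds`), and the two in-season height columns for replanted pots
(`replanted`). Both thresholds are strict less-than (a 0.5 g yield or a
97-seed scan is retained). Yield itself is never masked — zero yields are
data. The rules are independent and idempotent, so application order does
not matter. The 97-seed rule is applied to the imaged subsample count, the
count the rule's wording refers to. Missing phenology is left missing; no
imputation.

## Nutrition

Amino acid scores divide content (mg g⁻¹ protein, 14% moisture basis) by
the WHO/FAO/UNU (2007) requirement of the target age group (adult or
infant; infants have the higher requirement for every amino acid, so
infant-complete implies adult-complete). SAA = methionine + cysteine and
AAA = phenylalanine + tyrosine are scored as compounds. A score below 1
marks the amino acid limiting; exactly 1 meets the requirement — the
boundary must count as meeting, since a panel-mean threonine of 31.38
against an infant requirement of 31 is a "meets" case by construction of
the packaged tables. Digestibility-adjusted scores (PDCAAS/DIAAS) are out
of scope.

## Multivariate analysis

Correlations are pairwise-complete Pearson or Spearman (average ranks for
ties) with two-sided t-approximation p-values; cells with p > 0.05 can be
masked as non-significant in the heatmap. PCA standardizes each trait
(mean 0, SD 1, ddof = 1) and eigendecomposes the resulting correlation
structure; rows with any missing selected trait are dropped and logged.
Loadings columns are sign-fixed so the largest-magnitude entry is
positive; a trait's contribution to a component is 100·loading²/Σloading²,
judged against the uniform threshold 100/n_traits (5.56% for the
18-trait reference set).

Ward clustering uses the true minimum-variance criterion ("ward.D2"
semantics — scipy's `linkage(method="ward")` on raw observations); the
alternative variant applied to unsquared distances is not exposed because
the minimum-variance form is the one with the exhaustive-search oracle the
suite verifies against. Inputs are standardized by default (switchable).
k-means is best-of-25-restarts Lloyd's with a fixed default seed of 1 on
standardized traits. Accessions with missing inputs are left unlabelled
with their ids recorded, mirroring how panels report unassignable
accessions.

## Pipeline and problem sizes

`run_pipeline` chains all stages with per-stage child seeds spawned from
the run seed (byte-identical reruns). The default synthetic run uses 60
accessions × 2 greenhouses × 4 blocks, three seed scans of 70–150 seeds,
120 + 120 spectra on the full 141-point grid, and 200 composition
samples — large enough for every stage to exercise its full code path
while a complete run stays in the tens of seconds; the generators accept
panel-scale parameters (360 accessions, 2,880 rows) directly, and the
acceptance-level recovery checks run at that full scale. Default trait
generating models (variance components and grand means) are set to
magnitudes reported for a real 360-accession greenhouse panel, so
simulated heritabilities land in the realistic 0.5–1.0 band.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the study inputs — the RCBD
layout and additive variance components, smooth AR-1-correlated spectra
(ρ = 0.98 across the 5 nm grid) with shift outliers, elliptical seeds with
touching pairs, Gaussian composition profiles around the packaged panel
means. They do not emulate day-length-sensitivity physiology, BBCH stage
dynamics, real NIR chemistry (phenology values are plain quantitative
traits; spectra are one multivariate normal), non-elliptical or occluded
seeds, or non-Gaussian trait distributions. Passing tests therefore
demonstrate correctness of the estimators and filters under the stated
model, not robustness to every failure mode of real scans or spectra.
Group memberships of the real panel are not reproducible from synthetic
data; the clustering checks verify algorithmic correctness (oracle
agreement, separable-case recovery), not biological grouping.

## Other numerical choices

- Covariance denominators are n−1 throughout.
- The wavelength-grid constructor requires the span to be divisible by the
  step (to 1e-9 relative) and returns the inclusive grid.
- `simulate_composition` draws via Cholesky when the covariance is
  positive definite and via eigendecomposition otherwise (so a zero
  covariance reproduces the mean exactly).
- Ties in k-means restarts resolve deterministically through the fixed
  seed; Ward ties follow scipy's ordering.
- Seed placement uses rejection sampling with a retry budget; exhausting
  it raises an error reporting the achieved count rather than silently
  under-filling the scan.
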