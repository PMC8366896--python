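# Methods

## Scientific setting

`rumenbalance` analyzes macronutrient balancing in a browsing ruminant from
the chemistry of rumen contents and of the available winter forage.  The
observational unit is one rumen sample (roughly one meal) or one pooled
plant sample, described by proximate analysis: ash, Kjeldahl nitrogen,
fiber-bound nitrogen (ADF-N), the detergent-fiber ladder (NDF ≥ ADF ≥
lignin), and — depending on the material — lipids, sugars, starch and a
purine marker of microbial biomass, all in % of dry matter (dm).

## Macronutrient derivation

Derived quantities (module `composition`):

- crude protein CP = 6.25 · total N; available protein AP = 6.25 · (total N
  − ADF-N).  The 6.25 factor is the standard protein/N conversion
  (proteins ≈ 16 % N) and is a definition, not a parameter.  For rumen
  material AP includes microbial protein and is denoted AP_R in output.
- hemicellulose = NDF − ADF; cellulose = ADF − lignin.
- plant nonstructural carbohydrates TNC1 = sugars + starch (enzymatic);
  rumen TNC2+lipids = 100 − (NDF + AP + ash) by subtraction, because
  quickly digested constituents cannot be assayed reliably in partially
  fermented digesta.  The subtraction route fixes the closure
  AP + NDF + ash + TNC2+lipids = 100 exactly.
- microbial-N = 1.1 · purine marker (g yeast-RNA equivalents / 100 g dm).

Degenerate inputs: derived values in (−0.5, 0) %-points are treated as
input-rounding artifacts, clipped to 0 with a logged warning; anything more
negative rejects the record with a named reason.  Rejection rather than
repair prevents silent propagation of impossible chemistry.  All units are
% of dm throughout; the purine marker is converted from mg/g on ingestion.

## Mixture-triangle geometry

A right-angle mixture triangle (module `rmt`) represents the
three-component mixture (TNC+lipids, AP, fiber = cellulose +
hemicellulose) as a 2-D point: x = %TNC+lipids and y = %AP of the
macronutrient total, with fiber implicit (i = 100 − x − y).  Lignin and
ash are excluded from the denominator.  The projection is scale invariant
and the x + y + i = 100 identity is exact.  The balance ratio is y/x
(protein per unit of highly digestible energy).  Nutritional spaces are
convex hulls in the (x, y) plane (`scipy.spatial.ConvexHull`), vertices
returned counter-clockwise from the lexicographically smallest vertex for
deterministic output, area by the shoelace formula; fewer than three
distinct or non-collinear points give a degenerate zero-area space rather
than an error.

## Statistics

All tests are two-sided at α = 0.05 (module `stats`).

- *Isometry test.* Variables are z-scored (sample SD, n−1), fitted by OLS,
  and the slope tested against 1 with t = (β − 1)/SE(β).  On standardized
  data the OLS slope equals Pearson r and R² = r², which the tests assert
  to 1e−12.  OLS (not standardized-major-axis) is used deliberately: the
  analysis asks whether y tracks x 1:1, not for a symmetric line-of-best
  fit.  Numerically perfect fits (1 − R² < 1e−14) are reported with SE 0
  and degenerate t-statistics instead of dividing by ~0.
- *Balance ratio vs fiber.* Without diet types, OLS on standardized
  variables; with diet types, a full-interaction linear model on raw
  scales (reference level = first type in sorted order), plus a
  quasi-binomial GLM cross-check: the ratio is rescaled to (0, 1) by its
  ceiling of 1.5 — the ratio at the extreme corner of the observed range
  box (36 % AP / 24 % TNC) — fitted with a logit link and Pearson-χ²/df
  dispersion.  The two routes are expected to agree in slope sign and
  interaction significance, which is tested.
- *Correlation matrices.* Pearson r with p from the t distribution with
  n−2 df; constant columns raise instead of propagating NaN.
- *One-way ANOVA + Tukey HSD* via `scipy.stats.f_oneway` and
  `statsmodels`' studentized-range implementation; the two-group identity
  F = t² and a brute-force sum-of-squares oracle pin the implementation.
- *Subpopulation regression.* Mean calf body mass per management unit
  regressed on the unit's mean per-sample balance ratio (mean of ratios,
  not ratio of means — the per-sample ratio is the regulated quantity;
  the alternative aggregation is a caller-side one-liner).

## Synthetic data generator

The generator (module `synthetic`) emulates the study conditions rather
than any mechanistic rumen model.

*Correlation structure.* The six measured constituents (ash, lignin,
microbial-N, AP, cellulose, hemicellulose) are drawn from a Gaussian
copula with the published 6×6 correlation submatrix (eigenvalue-clipped to
PSD if user-modified).  TNC2+lipids is then *defined* by the subtraction
closure, exactly as on real data, so closure holds to machine precision
and the TNC2 correlation row is induced rather than imposed.  The marginal
SD proportions are the solution of the consistency system "induced TNC2
row = target TNC2 row" (solver shipped as `calibrate_closure_sds`; the
frozen defaults reproduce the target row to < 0.01).  The overall SD scale
and the marginal means (ash 6.5, lignin 16.5, microbial-N 1.0, AP 13.0,
cellulose 25.5, hemicellulose 15.0 % dm, hence TNC2+lipids 23.5) were
chosen once so that projected points span most of the observed mixture-
triangle range box (7–36 % AP, 24–48 % TNC, 16–69 % fiber) with ~1 %
rejection; candidates outside the box or with non-positive constituents
are redrawn, and the mild truncation is why empirical correlations sit
within a few hundredths of the targets rather than exactly on them.

*Population structure.* Samples nest in management units (subpopulations)
within lettered management areas, using the published 30-unit layout
(16 broadleaf, 8 shrub-and-sugar, 6 conifer units) at study scale.  The
latent field carries a subpopulation random effect (ICC 0.30, same
correlation matrix at both levels, so the marginal structure is
preserved).  When simulating far more samples than the study, the number
of units grows to keep ~16 samples per unit — subpopulation-level noise
only averages out if units replicate.  Diet types are attached by
*ranking* the exchangeable unit-level effects (shrub-and-sugar units get
the highest lignin + microbial-N effects, conifer units the highest fiber
effects among the rest).  Because this only permutes i.i.d. draws, the
joint sample distribution — and thus the correlation contract — is
untouched, while the qualitative between-diet contrasts of the field data
(shrub-and-sugar highest in microbial-N and lignin; conifer confined to
the high-fiber range) emerge.  Additive per-diet shifts remain available
(`diet_effects`) but are off by default: an additive shift of realistic
size inflates lignin variance enough to visibly attenuate its
correlations.

*Metadata.* Age-sex classes are drawn with the study frequencies (52 %
calves, 14 % yearlings, 20 % adult females, 14 % adult males, split by
sex as observed); dates span the October–February season with a 70:30
early:late split, inverted in area A; calf carcass mass is N(65, 7²) kg
with a 4-kg subpopulation SD, independent of the balance ratio by default
(the field study's null result), with an optional injected slope for
known-truth recovery tests.  Total N is split into ADF-N with a fixed
available fraction of 0.8, a value typical for winter browse digesta; no
per-sample distribution of ADF-N is published.

*What the generator does not claim.* Marginals are clipped Gaussians, not
compositional (logistic-normal) laws; diet-type contrasts are ordinal, not
calibrated to the published subpopulation means (the published microbial-N
share of available N, ~49 %, and the published between-diet differences
cannot both be matched exactly — the share is anchored); and plant-intake
bookkeeping, fermentation kinetics and seasonal drift are out of scope.
Passing tests therefore demonstrate that the *analysis* recovers known
structure of this kind, not that the generator reproduces every feature of
field data.

*Spectra.* NIRS-like spectra are linear mixtures: composition-weighted
fixed Gaussian-band component spectra on a 780–2498 nm grid at 4 nm, plus
a gently sloped baseline and i.i.d. Gaussian noise (default SD 0.01
absorbance units, set so that calibration achieves sub-% of dm prediction
error, the performance class reported for real instruments).  Real NIR
physics (scatter, particle-size effects, water bands) is deliberately
absent; the stage exists to exercise the chemometric code path.

## Chemometric stage

Representative-subset selection whitens the first three PC scores of the
standardized spectra (Mahalanobis metric) and picks samples
Kennard–Stone style: the most extreme sample first, then iteratively the
sample farthest from all chosen ones, ties broken by index.  This covers
extremes first and stratifies the interior, and guarantees both halves of
a bimodal set are represented for k ≥ 2.  Calibration is standard PLS
(`scikit-learn`), component count chosen by 5-fold (or leave-one-out)
cross-validated RMSE and capped at n_train − 2; evaluation reports RMSEP
on the constituent scale and R², with R² ≤ 0 flagged as degenerate.  An
orthogonal-projection refinement of PLS would reorganize the latent space
for interpretability but not change the prediction contract tested here.
Real calibration statistics from the field study are not reproducible
without the original spectra; the contract on synthetic spectra is exact
recovery at zero noise and R² ≥ 0.9 for the available-protein analog at
default noise.

## Pipeline defaults

The `PipelineConfig` defaults encode the study's filters: pooled,
sample-based analyses (projection, isometry) use every sample; restricted
analyses keep units with ≥ 5 samples dated on/after 23 October (leaf-fall
cutoff).  The date threshold and unit minimum are configuration, not
constants, because the exact subsetting of the restricted models is not
fully specified in the source material.  Every run writes a provenance
block (config hash, seed, package version).

## Problem sizes

Default test and acceptance runs use n = 481 samples (study size) for
regression recovery, n = 10⁴ for generator-fidelity checks, 1000
replicates for type-I calibration, and 300 samples / 430 wavelengths for
the chemometric stage.

## Known limitations

- The packaged plant table keeps the printed 1-decimal values even though
  its fiber components are internally inconsistent with printed NDF by up
  to ~3 %-points; recomputed statistics can differ from published ones in
  the third decimal.
- The supplementary-feed table is a synthetic stand-in beyond its three
  published sugar/starch anchors (see `data/feeds_synthetic.csv`).
- Generated extremes at n = 481 approach but do not reach the edges of the
  configured range box; sample extrema are not calibration targets.
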