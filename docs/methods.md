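# Methods

## Scope and data model

`peavigour` reconstructs an image-based early-vigour phenotyping analysis
for field pea seedlings as a reproducible pipeline.  A *plant-day* is one
multi-view observation (one top view, three side views at 0/120/240°
rotations); a *trait record* holds the digital traits derived from it; a
*growth series* is the EB-vs-DAS trajectory of a plant or genotype; and
the genotype comparison table aggregates trait means, ANOVA columns and
ranks.  No raw images or harvest data exist for the original experiment,
so the package's synthetic generators define the study conditions under
which everything is validated.

## Segmentation and traits

Plant pixels are recovered by a hue–saturation–value rule: hue inside a
green window (default [0.17, 0.50] on the [0, 1) hue circle), saturation ≥
0.25 and value ≥ 0.10, minus pixels matching the blue cage window
([0.52, 0.80]).  The defaults are tuned to the synthetic palette (green
plant ≈ hue 1/3, blue cage ≈ hue 2/3, near-white background with
saturation ≈ 0); the rule generalises to any scene whose classes are
colour-separable, which the blue-support-cage scene design guarantees.
The original platform's segmentation rules were proprietary and are not
recoverable, so the colour rule is this package's own, validated against
painted ground truth.  Connected components smaller than `min_size`
(default 50 px, 8-connectivity) are removed as noise.

Conventions, chosen once and used throughout:

* **EB** is the *sum* of plant-pixel counts over the three side views plus
  the top view (not a mean); all downstream statistics are
  scale-consistent either way.
* **Convex hull (TVCH)** treats pixels as unit squares: the hull is taken
  over all pixel corner points and a grid cell belongs to the filled hull
  when its centre lies inside or on the hull boundary.  This makes the
  hull a superset of the mask, so TVCOM = TVA/TVCH ≤ 1 identically, with
  equality exactly when rasterisation adds no cell (a solid convex
  region).  The alternative (polygon shoelace area over pixel centres)
  can undercount and push TVCOM above 1 for thin objects.
* **EH** is the maximum inclusive row span over the three side views;
  rows are 0-based from the image top.
* **kilopixel** = pixel count / 1000, reported to 3 decimals.
* TVCOM is computed per plant-day and then averaged per genotype, not
  taken as the ratio of genotype-mean TVA to genotype-mean TVCH (the two
  differ by Jensen-type effects of order 0.01 at realistic noise).
* An empty view mask yields NaN in every dependent trait plus an explicit
  flag — missing data is never a silent zero.  Missing-view plant-days
  are excluded (and counted in the logs) at the analysis stage.

No pixel-to-centimetre calibration is implemented: digital traits are
compared with measured ones only through correlation, which a common
scale factor does not affect.

## Two-phase growth model

Seedling biomass shows a lag phase then a linear growth phase.  The model
is continuous piecewise-linear with one breakpoint: y(t) = Y + s₁(t − X)
for t ≤ X, Y + s₂(t − X) for t > X.  Continuity is enforced — the
breakpoint coordinates plus two slopes parameterisation only makes sense
if the two lines meet at (X, Y).

Estimation profiles X on a dense grid (default 0.01 day) between the 2nd
and (n−1)th observed days, so at least two observations lie strictly on
each side of any candidate.  At each candidate the model is linear in
{1, t − X, (t − X)₊} and solved by batched normal equations; ties in SSE
break toward the smallest X; the grid optimum is polished by bounded
Brent minimisation within one grid cell.  This estimator is deliberately
simple and oracle-checkable (a dense brute-force scan reproduces its SSE)
rather than relying on any particular statistics package's split-line
internals; round-tripping all 44 published genotype parameter sets
(regenerate noise-free at days 11–39, refit) recovers X within 0.05 day
and both slopes within 0.5%.

Adjusted R² uses p = 4 free parameters: adj R² = 1 − (1 − R²)(n − 1)/(n − 5).
Perfectly collinear input returns a flagged degenerate fit (equal slopes,
X at the first SSE minimum) instead of raising, so batch runs over many
genotypes never abort.  Genotype fits use per-day replicate means by
default; replicate-level series can be fitted the same way.

The *linear-phase onset* is the smallest integer day strictly greater
than the maximum fitted breakpoint across genotypes — for the packaged
44-genotype table (max X = 26.26) this is day 27.  Strictness matters: an
integer-valued breakpoint maps to the following day.

**Negative lag-line extrapolation.**  Three of the 44 published parameter
rows (Dinkum, Helena, Laura) extrapolate marginally below zero at day 11
(down to −1.04 kPix).  The growth simulator therefore tolerates a small
negative mean value at the first grid day only (clamped to the positive
floor below); a curve that is non-positive at any later day, or far below
zero at the start, is rejected as not a growth trajectory.  Growth series
themselves only require finite values; positivity is enforced where the
mathematics needs it (the log transform in RGR).

## Synthetic data

The scene generator paints declarative pixel sets (or parametric
stem-plus-blob plants with exact per-view pixel counts) in three colours
— plant (0, 160, 0), cage (40, 60, 200), background (245, 245, 245) —
adds independent per-channel Gaussian noise (default sd 5 on the 0–255
scale), and returns the noiseless masks as ground truth.  Cage occludes
plant where they overlap, as the physical wire does.  Scene colours must
be pairwise separated by more than 2 × noise_sd in at least one channel,
the condition under which a colour rule can separate the classes.

Growth trajectories are drawn as m(t)·(1 + cv·ε), ε ~ N(0, 1), on the
integer day grid 11–39 — multiplicative noise, because biomass
measurement error scales with plant size; the original study reports no
residual model, so the noise form and the default cv = 3% (consistent
with the study's adjusted R² > 0.99 at 8 replicates) are this package's
choices.  Draws are truncated at a floor of 10⁻³ kPix.  Field
reflectance records fix the band sum R760 + R670 (default 0.8) and solve
the pair from a target NDVI that is an affine function of genotype
biomass plus Gaussian noise (default sd 0.02), rejecting links that leave
(−1, 1).

What the generators do *not* emulate: real pea morphology (overlapping
leaves, tendrils, self-occlusion between views), illumination gradients,
soil/pot clutter, or spatially correlated noise.  Passing tests therefore
demonstrate correctness of the *computation* — segmentation under the
colour-separability the scene design establishes, exact trait
bookkeeping, estimator consistency — not robustness to real-image
nuisances, which would need real data.  Plant height in particular
saturates quickly for the parametric plants (the stem spans most of the
raster), so EH is exercised but not discriminative in synthetic cohorts.

## Statistics

* One-way ANOVA by the standard decomposition; s.e.d. = √(2·MSE/n) and
  LSD = t(0.975, df_error)·s.e.d. assume a balanced design, with the
  harmonic mean group size (and a warning) otherwise.  Zero MSE
  degenerates to F = ∞, p = 0 when group means differ, NaN/NaN when they
  do not.  The glasshouse layout's blocking is not modelled; the
  analysis matches the one-way procedure the study states.
* Pearson r by the product-moment formula on pairwise-complete rows
  (≥ 3 required), p from the t transform with n − 2 df, stars at
  0.05/0.01/0.001.  Correlation p-values are unadjusted by default (a
  Holm option exists) — matching common practice for descriptive trait
  correlation panels.
* Outlier screening uses Tukey fences (1.5 × IQR beyond the quartiles,
  linear-interpolation quartile convention) within genotype and trait,
  applied before averaging and before ANOVA, and only when at least 4
  replicates are available.
* Ranking is by measured biomass when a destructive harvest is supplied
  (the reference analysis orders genotypes that way), else by EB; ties
  break by EB, then genotype name.  eWUE is never imputed: the original
  water totals were recorded by the platform but not published, so eWUE
  requires an explicit water log (synthetic or user-supplied).

## Pipeline and problem sizes

The four CLI stages communicate only via declared files and validate
their input schemas; configuration is strict YAML (unknown keys
rejected).  Sub-stream seeds are derived from the pipeline seed with
`numpy.random.SeedSequence`, making all outputs byte-reproducible.  The
default configuration mirrors the reference experiment's scale (44
genotypes × 8 replicates, days 11–39, images off); the bundled
reduced-cohort settings used in the end-to-end tests (8 genotypes × 4
replicates × 10 imaging days at 200 × 200 px, and a smaller 4 × 2 × 6
cohort at 96 × 96 px for the fast tests) were chosen to exercise every
code path at desk scale.  When rendering images, the per-view pixel
target is the replicate's series value scaled by `pixel_scale`
(default 0.05 per kPix across 4 views), floored at 150 px so early
seedlings stay above the component-size filter; the analyze stage
compares genotypes at the first imaged day at or after the onset day and
reports both days.

## Known limitations

* One breakpoint only; logistic/Gompertz growth and mixed-effects
  formulations are out of scope.
* No organ-level segmentation, leaf counting or 3-D reconstruction from
  the rotational views; overlapping leaves are not corrected for.
* The grid-profile breakpoint estimator is exact only to the grid/Brent
  tolerance (≪ 0.01 day in practice) and assumes homoscedastic residuals
  within the least-squares criterion even though the simulator's noise is
  multiplicative.
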