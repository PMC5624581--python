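# Methods

This note documents the models, parameters and numerical choices behind
`uvcover`, and what the synthetic phantoms do and do not establish about
real UV photographs.

## Image model

A UV reflectance photograph of a sunscreen-treated face is modelled as an
8-bit greyscale image with four intensity populations: dark background,
dark sunscreen-covered skin, bright uncovered skin, and two artifact
classes (bright specular glare, dark deep-dermal pigment spots). The
physical basis is UV absorption: melanin and sunscreen absorb, so darker
Fitzpatrick phototypes and covered areas render dark; unprotected skin
renders light.

### Phantom generator

* **Face**: an ellipse (default semi-axes 92 × 120 px in a 256 × 320
  frame) of uncovered skin over background (intensity 20), with Gaussian
  sensor noise (σ = 2 grey levels). Landmarks are emitted as ground truth
  at fixed fractions of the face bounding box; no detector is needed for
  any test.
* **Skin tone**: Fitzpatrick classes map to six evenly spaced intensity
  bands on [120, 230] (class 1 → 230, class 6 → 120), reflecting melanin's
  UV absorption. The default cohort draws classes 1–4 only (weighted 42:15
  light : darker, mirroring a northern-European study population); classes
  5–6 render below any single threshold that still separates sunscreen
  (intensity 70) from skin and were not exercised by the population the
  pipeline is designed around — a documented limitation rather than a
  hidden failure mode.
* **Coverage**: missed patches are unions of seeded random discs
  (radii 3–14 px) carved out of full coverage, because real missed areas
  are contiguous patches, not pixel noise. Carving iterates with the disc
  radius tracking the remaining deficit until the achieved missed fraction
  is within 0.5 percentage points of target; unreachable targets raise an
  error rather than silently undershooting. Fractions are expressed in
  the same units the scorer reports: missed pixels over region-rectangle
  pixels. A 2 px guard band keeps letterbox blobs from abutting the
  canthal boxes so the binary canthal ground truth remains unambiguous
  under the scorer's smoothing.
* **Artifacts**: glare = bright discs (intensity 245, radius 2–5 px) that
  are *not* missed skin; damage = dark discs (intensity 45, radius 1–3 px)
  that are *not* sunscreen. Neither touches the truth mask.

### Cohort model

Per-person application skill is a single latent trait: letterbox and
rest-of-face missed fractions are log-normal with medians 0.14 and 0.07
and log-scale spread 0.35, rank-coupled through a Gaussian copula whose
Pearson parameter is chosen as ρ = 2·sin(π·ρ_s/6) to hit the requested
Spearman ρ_s (default 0.84). The second visit shrinks each person's missed
fraction by a factor proportional to their first-visit miss (default
median relative reductions 0.30 for the letterbox, 0.15 for the rest, with
multiplicative log-normal noise, σ = 0.25), so the poorest initial
performers improve most. Canthal failure is Bernoulli per visit
(defaults 44/57 and 37/57) with a person-level Gaussian-copula correlation
of 0.5 across visits. Demographics (27:30 male:female, cream/spray 50:50)
carry no simulated effect, so gender, skin-type and formulation
comparisons are null analyses (type-I behaviour is what the tests check).

The log-scale spread 0.35 was chosen so that the sample median of a
57-person draw concentrates tightly around the configured median
(SE ≈ 0.8 points for the letterbox); the cost is a narrower spread of
extreme performers than a real cohort would show (few near-zero misses).

## Scoring pipeline

Stage order is fixed: adaptive equalisation → landmark regions → face crop
→ Gaussian blur → value mapping → threshold → metrics.

* **Equalisation**: per-block transform `g = round(255 · CDF(f))` over the
  block's histogram; 8 × 8 px blocks; clip limit 2.0 × the uniform bin
  height with uniform redistribution of the excess; bilinear blending of
  block transforms between block centres. With the clip disabled the
  per-block map is the plain cumulative-histogram equalisation, and an
  interpolation-off mode exists purely so tests can compare each tile with
  the stand-alone block transform. Rounding is half away from zero
  throughout (deterministic, matches common image libraries).
* **Gaussian kernel**: θ is a standard deviation (the exponent divides by
  2θ²); the discrete kernel is evaluated on the integer grid, truncated at
  radius 3θ and normalised to unit sum. Borders reflect, which avoids dark
  halos at the face boundary. Default θ = 1.0 px.
* **Threshold**: 0.52 on the equalised value channel, the single most
  sensitive free parameter. It was calibrated **once** against the phantom
  generator and frozen: with the cohort's skin bands (164–230 after
  equalisation) against the sunscreen band (~73), 0.52·255 ≈ 133 balances
  the sub-pixel edge displacement between the brightest and darkest skin
  types, keeping per-image recovery error well under 2 percentage points.
  A larger blur (θ = 2) at any single global threshold displaces blob
  edges by about a pixel for the extreme skin bands and breaks that bound,
  which is why the smoothing default is θ = 1.
* **Regions** (fractions of the inter-ocular distance, IOD, unless noted):
  letterbox = outer eye corners ± 10% IOD horizontally, brow line − 15%
  IOD to eye line + 60% of the eye-to-nose-tip distance vertically;
  canthal squares have side 25% IOD (forced odd so the square centres
  exactly on the inner-eye landmark); face box = outline bounding box with
  5% IOD margin and a 25% IOD allowance above the brow. Rectangles are
  half-open, 0-based, x rightward, y downward.
* **Canthal rule**: not covered as soon as ≥ 1 missed pixel appears in the
  box, implementing the "any missed skin" criterion literally; a
  noise-robust alternative (a configurable fraction of the box area) is
  selectable.

## Statistics

Mann-Whitney and Wilcoxon p-values are exact whenever the outcome space
(C(n₁+n₂, n₁) label assignments, or 2ⁿ sign assignments of the nonzero
differences) has at most 4096 elements: the null is enumerated over the
observed midranks, which handles ties without approximation. Larger
samples use the normal approximation with tie correction and a 0.5
continuity correction; the chosen path is recorded in each result. Zero
differences are dropped from the Wilcoxon test (Wilcoxon's original
treatment). The canthal 2 × 2 comparison is the textbook uncorrected
Pearson chi-square on the visit-by-coverage margins (Yates optional); a
paired McNemar-style test would be the natural alternative when
per-person pairing of the binary outcome is of interest. Box summaries
report medians with 5/25/75/95 percentiles using linear interpolation
between order statistics. The improvement-vs-initial analysis reports
both Spearman and Pearson coefficients, labelled, since either convention
appears in practice. Significance is p < 0.05 everywhere.

## Problem sizes

The default conditions are a 57-participant, two-visit cohort
(114 images of 256 × 320 px) — generated, scored and analysed in roughly
ten seconds on one CPU. Repeated-seed calibration checks (Wilcoxon power,
formulation type-I control, skill-correlation banding) run on the drawn
cohort fractions directly, without rendering images, over 100 seeds.
End-to-end byte-reproducibility is exercised with a 6-participant cohort
through the full simulate → score → analyze chain.

## Limitations

* Phantoms are bimodal and piecewise-flat; real UV photographs have
  continuous shading, pose variation and hair/clothing occlusion. Passing
  ground-truth recovery here validates the pipeline's logic and its edge
  behaviour, not detector robustness on natural images.
* Only the ground-truth sidecar landmark provider ships; an external face
  detector can be plugged in through the same `detect` contract but is
  never required.
* The rectangular face crop includes background corners, so whole-face
  percentages are diluted relative to an elliptical skin mask — the same
  convention the scorer and generator both use, so comparisons are
  internally consistent.
* The visit-2 improvement model never worsens a participant
  (multiplicative shrinkage), whereas real cohorts show some regression.
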