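# Methods

`mammotriage` implements an automated triage pipeline for screening
mammogram sets built around one idea: in a healthy subject the left and
right breasts are approximately mirror images, so after mirroring and
deformable registration their pixelwise difference should be small, and a
unilateral lesion — a malignant mass or a calcification cluster — shows up
as residual asymmetry. The pipeline turns that residual (together with the
raw views) into a large named feature vector and selects a sparse linear
triage model from it.

## Pipeline model and assumptions

1. **Segmentation.** A mammogram is assumed to contain one large bright
   tissue region over detector background noise. The background noise SD is
   estimated robustly as 1.4826 x MAD over a 20-column border strip on the
   chest-wall-opposite side (chosen automatically as the vertical border
   strip with the lower median intensity). The initial mask keeps pixels
   strictly above the strip median + 5 noise SDs, holes are closed with a
   3x3 structuring element, and the largest 8-connected component is the
   breast. Pixels outside it are zeroed. The pectoral muscle is deliberately
   not removed: axillary abnormalities are themselves diagnostically
   relevant, and the muscle is roughly bilaterally symmetric so it largely
   cancels in the subtraction.

2. **Registration.** The left view is mirrored and registered onto the
   right view with a multiresolution cubic B-spline transform driven by
   Mattes mutual information. Defaults: 3 pyramid levels (shrink 4x/2x/1x),
   one control-point mesh at ~64 px spacing optimized through all levels,
   50 histogram bins, 10% random metric sampling with a seed derived from
   the configuration (ITK interprets seed 0 as wall-clock, so the internal
   seed is kept nonzero), and LBFGSB with at most 200 iterations per level.
   These are conventional values for mammogram-scale monomodal B-spline
   registration; none is critical. If the optimized transform scores worse
   than the identity at the finest level the identity is kept, so the
   reported metric never worsens. A result is flagged non-converged when
   the optimizer errors out or the displacement field folds (non-positive
   Jacobian determinant anywhere); non-converged subjects are excluded from
   cohort analyses and counted, and a run aborts if more than 20% of
   subjects fail.

3. **Subtraction.** The asymmetry map is |right − warped left|, restricted
   to the intersection of the two tissue masks and zero elsewhere.

4. **Enhancement and texture.** Four operators are applied to the right,
   left (in its native orientation) and subtraction image of each view:
   MoF (image minus its 5x5 grayscale erosion, enhancing fiber-like
   high-frequency structure), LoG (Gaussian sigma = 2 px followed by the
   3x3 discrete Laplacian; small sigma keeps the high-frequency target),
   LSD (3x3 local standard deviation), and LFD (local fractal dimension by
   the triangular prism surface area method at window sizes 3, 5, 9 px —
   a near-geometric progression from fine to medium texture). Per window
   the four corner intensities plus their mean at the center define four
   3-D triangles; the summed area, normalized by the planar cell area, is
   fitted as log(area) vs log(scale) by least squares, and D = 2 − slope,
   clipped to [2, 3]. Flat and affine surfaces give exactly D = 2. All
   windowed operators use replicate padding so mask edges do not inject
   gradients.

5. **Feature bank.** Every image contributes 43 first-order features:
   8 shape features of the mask (area, compactness P²/A with P the count of
   exposed 4-neighbor pixel edges, bounding-box elongation, binary
   centroid, second-order central moments), 28 histogram features (moments,
   entropy −Σ f log f, tail fractions, ten quantiles by linear
   interpolation, 5%-trimmed statistics renormalized over the retained
   bins), and 7 intensity-weighted moment features including the signal
   surface area Δxy·Σ√(Δxy² + 4(I−Î)²)/2 with Î the 4-neighbor mean.
   Histogram features index integer bins: raw/MoF images use native
   intensities; float-valued maps (LoG, LSD, LFD, subtraction-derived) are
   linearly quantized to 1,024 bins over their masked min–max range first,
   because an integer-indexed histogram is otherwise undefined for them.
   Degenerate statistics (zero SD, zero total mass) return 0 rather than
   dividing by zero — constant subtraction images do occur.
   Per subject: 43 x 15 images x 2 views = 1,290 features, plus the
   left-right average and absolute difference of each feature for every
   view/variant pair, 43 x 2 x 5 x 2 = 860 symmetric features; 2,150 in
   total, with deterministic lexicographic naming
   `{VIEW}_{VARIANT}_{SIDE}_f{NN}`.

6. **Modeling.** A Spearman redundancy filter greedily scans feature pairs
   and, for |rho| > 0.96, keeps one member chosen uniformly at random
   (seeded); constant features (undefined rho) are retained. The filter and
   the normalizations are fitted on the full cohort, matching the stage
   ordering of the original analysis. Two normalizations are offered:
   percentile rank against a reference cohort (midpoint convention), and
   the rank-based inverse normal transform with Blom offsets
   Phi^-1((r − 3/8)/(n + 1/4)) fitted on the healthy subjects only. For
   values outside the healthy reference range the piecewise-linear map is
   continued with the Gaussian-tail slope 1/SD(reference) rather than
   clamped: clamping would collapse out-of-range (typically diseased)
   values onto a single score, introducing ties that change rank-based
   statistics, while the tail extension is strictly monotone — preserving
   every univariate AUC exactly — and bounded in scale (an edge-segment
   slope, by contrast, can explode when the outermost reference values
   nearly coincide). The classifier is an L1-penalized linear regression of the
   0/1 class label (squared-error loss, taken literally from the method it
   reimplements, not logistic loss) on a seeded class-balanced training
   sample; the penalty is chosen to maximize leave-one-out cross-validated
   accuracy at a 0.5 decision threshold over a 15-point log grid below the
   analytic lambda_max, with ties broken toward the sparser model. Nonzero
   coefficients are the selected features; everyone outside the training
   sample is the blind test set. Blind performance is accuracy at the 0.5
   threshold with a 2,000-resample bootstrap percentile 95% CI (the CI
   method is a package choice), the Mann-Whitney rank AUC with ties
   counting one half, and an ROC traced over unique score thresholds.

7. **Sensitivity and triage.** The side-swap sensitivity analysis exchanges
   every left/right per-image feature value with its contralateral
   counterpart in the full raw table, then pushes the swapped subjects
   through the already-fitted filter and normalizer before scoring —
   swapping after column selection would be ill-defined because a feature's
   contralateral twin may have been filtered out. Triage arithmetic derives
   per-model score cutoffs achieving target sensitivity (default 0.90) and
   specificity (default 0.90) on a labeled calibration set, flags the
   high-priority group as subjects caught by either model at its
   specificity cutoff, clears the low-priority group as subjects passed by
   both sensitivity cutoffs, and reports the independence-approximation
   expected fractions 1 − spec1·spec2 and low1·low2. Unachievable targets
   fall back to the nearest achievable cutoff and are flagged.

## The phantom generator

Tests and the acceptance experiments run on synthetic mammogram sets. Each
subject has four 12-bit views (right/left CC and MLO, default 256x192).
A view's tissue is a half-elliptical blob anchored to the chest-wall edge
with a smooth low-order harmonic boundary perturbation, an interior
intensity profile (base 600 units tapering toward the boundary), and
shared Gaussian-field texture at two scales (8 px at 8% of base and 2 px
at 4%, emulating coarse parenchymal density plus finer structural detail
— multi-scale texture is also what gives the mutual-information metric
something to lock onto). The left side is the same tissue field warped by a smooth random
displacement (default peak 3 px, emulating positioning and compression
differences) and mirrored, so healthy subjects are nearly but not exactly
symmetric. Images sit on a positive film-base pedestal (default 50 units)
carrying zero-mean Gaussian noise (default SD 5); a pedestal is physically
the film base + fog level and keeps the clipped-at-zero pathology out of
the noise estimator. Lesions are unilateral: a mass is one Gaussian blob
(SD 10-20 px) of default contrast 400, a calcification cluster is 12
points of radius 1-2 px within a 15 px radius disc at the same contrast.
All randomness flows from one seeded generator; cohort members get
deterministic per-subject seeds, and identical parameters reproduce
bit-identical images.

What the phantom does **not** emulate: X-ray physics, scatter, compression
mechanics, parenchymal texture statistics, film digitization artifacts, or
pectoral muscle. Passing the end-to-end test therefore demonstrates that
the pipeline's machinery (segmentation, registration, asymmetry features,
selection, evaluation) is wired correctly and can recover a planted
unilateral signal — not that the reported discrimination transfers to real
screening data, where lesions are far subtler. On the phantom's default
conditions the planted lesions are conspicuous and blind AUC is typically
near 1.

## Problem sizes and numerical choices

The registration recovery experiments run at 384x288 (a typical working
resolution for downsampled digitized films, where the 64 px control mesh
has enough degrees of freedom for a 10 px warp). The end-to-end study uses
an 80-subject balanced healthy/calcification cohort at 256x192 with a
40-subject balanced training sample and a 40-subject blind set — the same
design as the original 100-training-subject study, scaled to a cohort this
size. Quantiles use the (n−1)p linear-interpolation convention. LFD areas
are floored at 1e-300 before logs. The LASSO path uses warm-started
coordinate descent per LOOCV split; a zero penalty is solved by ordinary
least squares. Bootstrap CIs, cohort sampling, the redundancy filter's
random survivor choice and ITK's metric sampling are all driven by
explicit seeds.

## Known limitations

- Squared-error LASSO on a 0/1 label is a linear probability model; scores
  are not calibrated probabilities, and the 0.5 threshold is a convention.
- The correlation filter's surviving set depends on the seed and on column
  order (greedy scan), as in the original random-survivor design.
- The rank-INT linear extension beyond the reference range is arbitrary up
  to its slope; any strictly monotone extension gives identical rank-based
  results.
- B-spline registration with mutual information can silently trade anatomy
  for histogram overlap on pathological inputs; the Jacobian fold check
  catches only outright folding.
- Shape features of the subtraction image use the joint mask, so they
  mostly reflect registration overlap rather than lesion geometry.
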