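# Methods

## Problem setting

Periodontitis destroys the deep periodontium — root cementum, the
periodontal ligament (PDL) and alveolar bone. Regeneration studies in
rodent models read out recovery on stained histological sections through
a small set of quantitative measures: how *organized* the PDL collagen
fibers are, how much cementum has been re-deposited below the
cemento-enamel junction (CEJ), how far the alveolar crest sits from the
CEJ, and how vascularized the ligament is. This package implements that
measurement pipeline, its aggregation protocol, and the comparison layer
of a split-mouth design (treated and control defects paired within
animal), plus a synthetic data generator that stands in for slide images.

## Fiber-organization entropy

### Model

Fiber orientation is axial data: a fiber at θ and θ + 180° is the same
fiber, so all orientations live on [0°, 180°). The statistic is the
Shannon entropy, in bits, of a probability distribution over 180
one-degree orientation bins, derived from a straight-line Hough
transform of the edge map of the red channel of the vertically oriented
section. Low entropy = concentrated orientations = well-organized
fibers; the ceiling log₂ 180 ≈ 7.492 bits corresponds to isotropy.

### Pipeline stages and choices

- **Orientation.** The section is rigidly rotated about its center by the
  minimal angle mapping the annotated root tangent to the image y-axis;
  the canvas is enlarged so nothing is cropped, and padding uses the
  median border intensity so no artificial high-contrast frame edge is
  injected. Resampling uses a cubic spline (`scipy.ndimage`,
  `grid-constant` boundary): linear interpolation measurably blurs fiber
  edges — under a rotate-30°-and-restore round trip it perturbed the
  final entropy by up to ≈ 0.18 bits, versus ≈ 0.03 bits with the cubic
  kernel — so the cubic kernel is the default and only mode.
- **Red channel.** Masson's trichrome renders collagen such that fibers
  contrast best in the red component; the R plane is used bit-exactly,
  with no further color normalization (a deliberate non-goal).
- **ROI masking.** Fiber classes (horizontal vs oblique) are assigned by
  the annotator's labeled PDL polygons, one entropy per polygon. Polygon
  membership is the even-odd rule evaluated at integer pixel centers —
  one explicit convention shared by cropping and area measurement, so
  pixel counts are exactly reproducible (and are tested against an
  independent point-in-polygon oracle).
- **Edges.** Sobel gradient magnitude thresholded by Otsu's method over
  in-mask values (or a fixed threshold). The mask is eroded by 2 px and
  out-of-mask pixels are replaced by the in-mask mean *before* the
  gradient, so the polygon boundary itself never votes. A constant
  raster yields a valid, empty edge map.
- **Hough transform.** Standard normal parameterization
  ρ = x·cosθ + y·sinθ, θ bins centered at −90°, …, +89° (Δθ = 1°), ρ bins
  at Δρ = 1 px spanning ± the crop diagonal. Every edge pixel votes once
  per θ bin into the nearest ρ bin. The accumulator is produced by direct
  voting (not a library call) because the exact vote matrix is the object
  the statistic is defined on; it is verified bit-for-bit against an
  exhaustive per-pixel, per-bin oracle.
- **Angular distribution.** A consequence of one-vote-per-θ-bin voting is
  that plain column sums are *identical across θ* (each equals the edge
  count), carrying no orientation signal at all; the distribution must
  weight collinear structure within each column. The default derivation
  takes the strongest single line support per angle,
  p(θ) ∝ (maxρ votes[ρ, θ])^q with q = 4; a vote-energy alternative
  Σρ votes^q is available (`column_stat="energy"`). The exponent q
  controls suppression of the diffuse background floor: during design
  exploration, energy with q = 2 left < 0.3 % contrast between isotropic
  and aligned fields and could not recover the dominant direction to
  ± 2°, while the max-statistic with q = 4 separates the κ ladder by many
  standard errors and recovers direction to ≈ 1°. Both knobs are exposed
  in `PipelineConfig`.
- **Entropy.** H = −Σ p log₂ p with 0·log 0 := 0, base 2 (bits). No
  normalization by the maximum is applied; comparisons are unaffected by
  base or ceiling, which are constant across images at fixed Δθ.
- **Line extraction** (overlay QC only): greedy non-maximum suppression
  over a 5 × 5 (ρ, θ) window, ties toward the lower θ bin; never feeds
  the entropy.

### Orientation conventions

Pixel coordinates are (x, y) = (col, row), origin top-left, y down. The
reported fiber orientation of a Hough bin is θ + 90° (mod 180°), i.e.
0° = horizontal in the oriented image, 90° = parallel to the root axis.
The circular mean of an angular distribution uses the angle-doubling
construction appropriate for axial data.

## Histomorphometry

- **CEJ–crest distance**: Euclidean, in pixels (µm additionally when a
  pixel scale is supplied). Rigid-motion invariant, so it may be measured
  in either the raw or oriented frame.
- **Cementum area**: cementum-positive pixels inside the annotator-drawn
  measuring frame (compartment `cementum_frame`). The frame must
  rasterize to 1,000 px² within ± 2 % or the measurement is refused —
  the frame's *shape* is free (its exact geometry beyond area and
  CEJ anchoring is an annotation-protocol matter), but its area is the
  normalizing constant that makes sections comparable.
- **Vessel counts**: vessels are annotation marks with a measured
  diameter (vessel *detection* is deliberately out of scope — counts are
  made at the microscope). PDL marks split at 50 µm; a diameter of
  exactly 50 µm goes to the large class, a convention required because
  "> 50" and "< 50" alone leave the boundary unassigned. Alveolar bone
  and gingiva counts are not size-split.
- **Aggregation**: per section, the two blinded replicate measurements
  are averaged (their absolute difference is reported as replicate
  agreement; a missing replicate falls back to the single value with a
  warning flag); per defect, the ≥ 5 section values are averaged. The
  5-section minimum is enforced but relaxable for small synthetic
  datasets.

## Synthetic data

### Fiber fields

`generate_fiber_image` renders straight fiber segments on a Masson-like
blue-green background: orientations follow an axial von Mises
distribution (doubled angles ~ von Mises(2µ, κ); κ = 0 is uniform),
centers uniform, lengths Gaussian, constant width, red-dominant
intensity, plus i.i.d. Gaussian pixel noise. Ground truth (drawn angles,
fiber mask) is returned for oracle tests. Defaults — 192 × 192 px, 60
fibers, length 55 ± 14 px, width 2 px, intensity 200 on (40, 70, 110),
noise SD 8 — were fixed once as a realistic density for a PDL field at
this scale and give the entropy statistic a clear dose response over
κ ∈ {0, 1, 4, 16, 64}.

What the generator does *not* emulate: fiber curvature and crimp,
stain variability, out-of-plane sectioning artifacts, real vessel or
cell texture. Passing tests therefore demonstrate correctness of the
measurement machinery and its statistical behavior under a controlled
angular model — not segmentation robustness on real slides.

### Split-mouth studies

`generate_study` emits a complete dataset: 24 colonized animals split
evenly over the 0/1/6/12-week timepoints plus 6 healthy (never
colonized) reference animals by default, two defects per animal
(experimental and contralateral control — the paired split-mouth
design), 5 sections per defect, two replicate annotation files per
section. Study sections are 128 × 128 px with two half-field PDL ROIs
(horizontal-fiber population, mean 0°, and oblique population, mean
60°), a 25 × 40 px cementum frame anchored at the CEJ with a
programmatic cementum mask, and Poisson vessel marks; the smaller field
keeps a whole-study analysis to a few seconds.

Programmed effects live in per-cell dictionaries: fiber concentration κ,
cementum area fraction, and vessel Poisson means per (side, timepoint).
The animal random effect multiplies κ by exp(N(0, σ)) with σ = 0.25,
shared by both sides of an animal — this is what makes pairing
informative. Replicate noise is applied to the re-measured annotations
(landmark and frame jitter, SD 1 px), not to the pixels: replicates are
re-measurements of the same physical section, so the two replicate rows
share one section image. Cementum area is a deterministic fraction of
the frame plus Gaussian jitter truncated to [0, frame area].

Default cell parameters encode the qualitative pattern such studies
report: no side differences in healthy or baseline animals, progressive
reorganization from week 6 with the treated side reaching near-healthy κ
and full cementum recovery by week 12, and a two- to four-fold vessel
increase on the treated side at weeks 6–12 (alveolar bone at week 6
only).

## Statistics

- **Side contrast (within timepoint).** For a two-level paired design,
  the ANOVA with a random animal intercept and fixed side effect is
  algebraically the paired t-test (F(1, n−1) = t²); the `mixed_anova`
  engine computes it that way. The `permutation` engine is the exact
  distribution-free reference: within-animal sign flips of the paired
  differences, fully enumerated for n ≤ 20 pairs (Monte-Carlo with
  10,000 draws and a recorded seed beyond that), two-sided, with the
  observed arrangement counted once in Monte-Carlo so p > 0. Degenerate
  all-zero differences give p = 1 by convention. Note the exact test's
  granularity: with 6 pairs the smallest two-sided p is 2/64 ≈ 0.031, so
  rejection at α = 0.05 requires unanimous difference signs.
- **Reference contrasts.** Experimental-side values at each later
  timepoint vs the 0-week baseline group or the non-colonized group
  (independent animals): Welch's t (`mixed_anova`) or a label-shuffle
  permutation (exact when C(n₁+n₂, n₁) ≤ 20,000). The Bonferroni family
  is the set of timepoint contrasts for one measurement and one
  reference; side contrasts are reported unadjusted, mirroring the
  per-timepoint star convention of such studies.
- **All tests two-sided; α = 0.05** with flags at 0.05/0.01/0.001.
- Operating characteristics are verified by simulation at the study's
  per-timepoint scale (6 animals per group): null family-wise error of
  the Bonferroni family ≤ 0.07 over 1,000 simulated tables, power ≥ 0.8
  at a standardized paired effect d = 1.5 over 500, and t/permutation
  rejection agreement ≥ 95 % at the effect size the programmed study
  actually produces (d ≈ 4).

## Numerical conventions and degenerate inputs

- ρ-bin assignment uses round-half-even (both the implementation and the
  oracle), making accumulator equality exact.
- Empty edge maps produce an all-zero accumulator without error; an
  all-zero accumulator raises "no fiber signal in ROI" at the
  distribution stage.
- Entropy of empirical distributions is clamped at 0 against negative
  floating-point dust.
- A timepoint value is either an integer in {0, 1, 6, 12} or the string
  `not_colonized`; CSV round trips normalize the mixed column.
- Peaks in `extract_lines` break vote ties toward the lower θ bin index,
  making overlay output deterministic.

## Problem sizes used in validation

The test suite and the acceptance script deliberately run at scaled-down
but statistically meaningful sizes, chosen as part of the package's
validation design: 20 images per κ for the dose-response and
direction-recovery checks (direction is asserted on the seed-averaged
distribution — the cell-level estimate; single 60-fiber images carry
von Mises sampling spread of several degrees), 10 images for rotation
coherence, 100 random edge maps for Hough exactness, 1,000/500/200
simulated measurement tables for FWER/power/engine agreement, and an
18-animal, 3-timepoint programmed study for the end-to-end flag check.

## Known limitations

- The angular distribution derivation (column statistic and exponent) is
  a modeling choice; absolute entropy values depend on it, so only
  within-configuration comparisons are meaningful.
- The entropy of dense fields saturates: beyond κ ≈ 16 the response
  flattens, and because the response is nonlinear in log κ, an animal
  random effect on κ leaks a little variance into paired differences.
- Rasterized straight fibers can produce spurious lattice-diagonal
  (45°/135°) line support in single images; seed-averaged distributions
  wash this out.
- The exact sign-flip test is conservative at very small n (see above);
  with 3–4 pairs it cannot reject at α = 0.05 at all, which is a
  property of the design, not the implementation.
- Landmark placement, ROI drawing and vessel identification are operator
  inputs; the package quantifies them but cannot correct them.
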