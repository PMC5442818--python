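# fiberent

Quantitative histology of periodontal regeneration: a Hough-transform
angular-entropy statistic for periodontal ligament (PDL) collagen fiber
organization, landmark histomorphometry (bone-crest distance, fixed-frame
cementum area, vessel counts), the replicate/section aggregation protocol,
and the paired statistics layer of a split-mouth animal study — together
with a synthetic histology generator so the whole pipeline is testable
without any slide images.

## Who this is for

Groups measuring tooth-supporting tissue regeneration (e.g. after cell
grafting in rodent periodontitis models) on Masson-trichrome-stained
sections, and anyone who needs a reproducible, oracle-tested
implementation of orientation-entropy analysis for fibrous tissue.

## The statistic

Healthy PDL anchors the root through tightly organized horizontal and
oblique collagen fiber groups; disease disorganizes them. For each
annotated PDL region the pipeline computes:

1. **Orientation** — the section is rotated so the annotated root tangent
   is vertical (fibers perpendicular to the root then read "horizontal").
2. **Red channel** — Masson-stained collagen fibers contrast best in the
   red plane.
3. **Edges** — Sobel gradient magnitude, Otsu-thresholded, ROI-masked.
4. **Hough transform** — every edge pixel (x, y) votes once per angle bin
   θ ∈ [−90°, +90°), Δθ = 1°, into the offset bin nearest
   ρ = x·cosθ + y·sinθ (implemented by direct voting and verified
   bit-for-bit against an exhaustive oracle).
5. **Angular distribution** — p(θ) ∝ (maxρ votes[ρ, θ])^q, the θ-profile
   of strongest line support (q = 4 by default; a vote-energy variant
   Σρ votes^q is available as `column_stat="energy"`).
6. **Entropy** — H = −Σ p log₂ p, in bits. H ranges from 0 (one
   direction) to log₂ 180 ≈ 7.492 (isotropy); *lower entropy means
   better-oriented fibers*.

Around it: Euclidean CEJ-to-alveolar-crest distance, cementum-positive
area inside a 1,000 px² frame anchored below the CEJ, vessel counts per
compartment with PDL vessels split at 50 µm diameter, per-defect
aggregation (two blinded replicates averaged per section, ≥ 5 sections
averaged per defect), and paired experimental-vs-control contrasts with
an animal random effect (paired t / exact sign-flip permutation),
baseline and healthy-reference contrasts with Bonferroni adjustment at
α = 0.05.

## Worked example

```python
from fiberent import FiberFieldParams, generate_fiber_image, fiber_entropy_pipeline

for kappa in (0, 4, 64):
    params = FiberFieldParams(seed=7, concentration_kappa=kappa, mean_direction_deg=60)
    section, annotations, truth = generate_fiber_image(params)
    result = fiber_entropy_pipeline(section, annotations)[0]
    print(f"kappa={kappa:>3}  entropy = {result.entropy_bits:.3f} bits "
          f"(max {result.n_bins} bins -> 7.492)")
```

prints

```
kappa=  0  entropy = 7.357 bits (max 180 bins -> 7.492)
kappa=  4  entropy = 7.134 bits (max 180 bins -> 7.492)
kappa= 64  entropy = 6.864 bits (max 180 bins -> 7.492)
```

`concentration_kappa` is the von Mises concentration of the generated
fiber orientations: κ = 0 is an isotropic field and its entropy sits near
the 7.492-bit ceiling; as κ grows the fibers align and the entropy falls
— the dose-response the statistic exists to detect.

From the shell, the same pipeline is available as

```sh
fiberent simulate --out data/ --seed 1           # synthetic split-mouth study
fiberent analyze  --data data/ --out report/     # measurements + contrasts
fiberent entropy  --image sec.png --annotations sec.json --out entropy.csv
```

`analyze` writes `defects.csv` (per-defect means), `comparisons.csv` (one
row per contrast with estimate, p, Bonferroni-adjusted p and */**/***
flags) and a human-readable `summary.md`.

## Layout

- `src/fiberent/preprocess.py` — section/annotation types, orientation,
  red channel, ROI cropping
- `src/fiberent/fiber_entropy.py` — edges, Hough transform, angular
  distribution, entropy
- `src/fiberent/histomorphometry.py` — distances, areas, vessel counts,
  aggregation rules
- `src/fiberent/synthetic.py` — fiber-field and split-mouth study
  generators (deterministic per seed)
- `src/fiberent/stats.py` — paired/reference contrasts, Bonferroni,
  study report
- `docs/methods.md` — models, assumptions, parameter choices, limitations
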