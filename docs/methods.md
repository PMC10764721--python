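# Methods

## The model

A low-magnification RGB overview of an H&E-stained slide is normalised so
each channel is a float in `[0, 1]` (8-bit planes divided by 255, 16-bit by
65535; an alpha plane is composited over white first, since scanners pad
with white). The single-channel representation

```
T = ReLU(R − G) ⊙ ReLU(B − G)
```

encodes the assumption that H&E tissue — eosin pink plus haematoxylin
purple — is the only slide content that is simultaneously more red and more
blue than green. Consequences used throughout:

- **Achromatic content is exactly zero.** `R = G = B` gives `R − G = 0`, so
  `T = 0` in exact floating-point arithmetic (no tolerance needed). This
  covers background, black pens, scanner bounding boxes and dark blobs/text.
- **Green-dominant and blue-dominant pens are zero** (`G ≥ R` kills the
  first factor); **red/orange pens are zero** (`B ≤ G` kills the second).
- `T` is degree-2 homogeneous under channel scaling, monotone decreasing in
  G and increasing in R and B, bounded by `[0, 1]` with the maximum attained
  only at pure magenta `(1, 0, 1)`.
- On the RGB lattice with `n` samples per channel the `T > 0` region is
  exactly `{r > g and b > g}`, with `Σ_g (n−1−g)² / n³` of the cube's
  points — the analytic cross-check used in the tests.

Tissue/non-tissue separation is a single Otsu cut on `T`. A pixel is tissue
iff `T` is **strictly greater** than the threshold; the strict inequality
guarantees the (typically dominant) exact-zero mass can never be labelled
tissue. The baseline pipeline applies the same solver to Rec. 601 luminance
(`0.299 R + 0.587 G + 0.114 B`, the de-facto greyscale conversion) with the
opposite orientation: tissue is *darker* than the cut.

## The Otsu solver

Written from scratch because the solver's conventions matter to the
pipeline and need to be pinned down (the installed `skimage` solver is used
in the tests as an independent cross-check only):

- **Histogram**: `n_bins = 256` equal-width bins (Otsu's classical grey-level
  resolution) over `[0, max(values)]`, right-most bin closed. The domain
  follows the data rather than `[0, 1]` because realistic stain colours top
  out near `T ≈ 0.2`; a fixed unit domain would collapse the tissue mass
  into a handful of bins. The domain is recorded in the report metadata.
- **Criterion**: maximise `σ_b² = w₀ w₁ (μ₀ − μ₁)²` over all bin boundaries
  with both classes non-empty, class means taken at bin centres. Maximising
  `σ_b²` and minimising the within-class variance pick the same boundary;
  the suite asserts this on random data.
- **Ties**: boundaries within a relative `1e-9` of the maximum form a
  plateau (exactly flat when the inter-mode gap holds no data); the midpoint
  of the contiguous maximising run is returned. Deterministic and symmetric:
  two equal point masses at 0 and 0.8 give a threshold of exactly 0.4.
- **Degenerate histograms** (all mass in one bin — e.g. a slide with no
  pinkish pixels at all) admit no two-class split: the result carries a
  `degenerate` flag, the pipeline returns an all-false mask and logs a
  warning rather than inventing an arbitrary cut.
- A brute-force oracle (`brute_force_threshold`) re-evaluates `σ_b²` at
  every boundary by direct masking and averaging over the quantised values,
  with no cumulative-sum shortcuts; solver and oracle must agree exactly on
  random inputs.

Different Otsu implementations disagree on plateau tie-breaking and
histogram domain, so the `skimage` cross-check compares the achieved
between-class variance (on the raw data) and the inter-mode placement of
the cut, not the cut value itself.

## Pipeline choices

- Overview extraction caps the longer side at `max_dim = 2048` px by
  default — small enough for interactive runtimes, fine enough to preserve
  pen-stroke widths. Pyramidal TIFFs are read from the smallest level still
  at least `max_dim` on the longer side, then downscaled (never upsampled).
- No morphological post-processing by default; optional small-object
  removal sits behind `min_object_px` (off by default). The method itself
  has no tunable parameters beyond `n_bins`.
- Masks use row-major, origin top-left, 0-based coordinates everywhere,
  and are written as single-channel PNG with 0 = non-tissue, 255 = tissue.
  `mask_to_full_resolution` upscales by nearest-neighbour index mapping so
  patch pipelines can carry the mask to level-0 coordinates.
- Maps and images are kept in double precision throughout. Single-precision
  storage was considered and rejected: a 2048-px overview costs only ~32 MB
  in doubles, and double precision lets the algebraic guarantees (exact
  zeroing, degree-2 homogeneity at `1e-12`) hold as stated.

## The synthetic slide generator

The generator emulates the content classes the method claims to handle, not
histology texture. Each slide (default 256×320 px) is reproducible from its
seed and carries mutually exclusive, jointly exhaustive ground-truth masks
for tissue, background, pen, box and scanner classes (priority when drawing
overlaps: scanner > box > pen > tissue, with pen/tissue priority flipped by
`pen_over_tissue=False`).

- **Background**: achromatic near-white, per-slide grey level `U(0.92, 0.99)`
  with mild achromatic grain — real slide glass plus scanner padding.
- **Tissue**: 2 irregular blobs by default — wobbled discs whose radius
  (12–22% of the short side) is modulated by a Gaussian-smoothed random
  field with kernel width 5% of the short side. One base stain colour per
  slide, `R ~ U(0.75, 0.95)`, `G ~ U(0.45, 0.65)`, `B ~ U(G+0.10, 0.85)`,
  with per-pixel jitter `N(0, 0.02)` truncated at one standard deviation
  and clipped to `[0, 1]`. The per-slide base colour reflects that serial
  sections on one slide share a stain batch, so tissue pixels form one
  tight `T` cluster; the `B − G` margin of 0.10 keeps even the faintest
  base colour's jittered cluster separated from the zero mass, which is
  what makes the `T` distribution bimodal — the regime the method is
  designed for, and the regime real eosin staining occupies (`B − G`
  typically 0.1–0.25). Fainter pinks would defeat any Otsu-based cut and
  would misrepresent the clinical material the method targets.
- **Pens**: random polylines (3–5 vertices) dilated to the requested stroke
  width. Colour ranges per class are constructed so the rejection guarantee
  is provable: blue/green/black force `G ≥ R`, red/orange force `B < G`,
  hence `T = 0` on every sampled pixel. Pink pens are drawn from the tissue
  colour model on purpose — the documented failure mode must occur. The
  orange range forces `B < G`; whether real orange inks are rejected via
  the `B − G` or the `R − G` factor varies by ink, and this is a modelling
  choice.
- **Boxes**: a 3-px dark achromatic rectangle near the border.
- **Scanner artefacts**: dark achromatic discs and text-like bar runs.

What passing the synthetic suite does **not** show: robustness to stain
variation between scanners, to semi-transparent ink over tissue (synthetic
pen pixels are opaque), to tissue folds/blur, or to stains that are not
pink/purple. The suite establishes the colour-geometry of the method — which
content classes can and cannot be separated by the `T` channel — not
clinical performance.

## Evaluation rubric

The qualitative "all tissue segmented / all background, boxes and artefacts
rejected" verdict is replaced by quantitative proxies, since absolutes are
unattainable on rasterised fixtures: a segmentation succeeds when tissue
recall ≥ 0.95 and each non-tissue class contributes ≤ 1% of its pixels to
the mask. Thresholds are module constants (`TISSUE_RECALL_MIN`,
`INCLUSION_MAX`) echoed into the JSON summaries. Dice is reported against
the truth tissue mask and defined as 1.0 when both masks are empty; an
inclusion fraction over an empty truth class is defined as 0.0.

The default comparison suite is 60 slides — 30 clean, 15 with pen marks
cycling blue/green/black/red, 15 with a bounding box plus scanner blobs —
mirroring the composition of the clinical material the method was designed
for, at desk-scale raster sizes (256×320). On it the transform pipeline
cleans every artefact slide while the luminance baseline fails every pen
slide; both succeed on clean slides.

## Known limitations

- Pink (eosin-coloured) pen cannot be rejected, by construction; the
  package asserts this failure rather than hiding it.
- A slide with no pinkish content yields a degenerate threshold and an
  empty mask (flagged, not guessed).
- Very faint staining pushes the tissue `T` cluster toward the zero mass
  and Otsu will truncate its lower tail.
- Only H&E; other stains require a different channel representation.
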