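# Methods

## Pipeline model and assumptions

`chisel` quantifies nuclei in DAB&H-stained IHC images under three
assumptions: (i) nuclei — both DAB-brown immunopositive and
hematoxylin-blue immunonegative — are darker than their surroundings in
the HSV Value channel, so a single adaptive threshold can detect both
classes and color is needed only for the later classification step;
(ii) stain color and intensity vary too much across labs for fixed color
cut-offs, so cluster splitting must be shape-only; (iii) class membership
is recoverable from local color/texture once the object outline is known.

Processing order per image: tile → (optional patch QC) → Value channel →
adaptive threshold → active-contour refinement → recursive split →
sub-50-px artifact removal, all per ROI; then strict-majority fusion of
the ROI masks, one image-level re-split/re-filter (per-ROI label
identities do not survive binary fusion), and finally feature extraction
and classification per object.

## Tunable parameters

| parameter | unit | default | role |
|---|---|---|---|
| `roi_size` | px | 1000 | ROI side; tiles anchored so the last row/column ends at the image edge |
| `scheme` | – | B | A: plain grid; B: + right/down shifts; C: + all four shifts.  Shift = `window // 2` |
| `window` | px | 51 | adaptive-threshold window, ≈ two nucleus diameters at 0.5 µm/px |
| `threshold_t` | % | 15 | relative cut-off below the local mean; the first of the two primary tuning knobs |
| `split_T` | px | 3 | starting EDT level of the splitter; the second primary knob |
| `split_dT` | px | 1 | EDT level increment per recurrence |
| `max_recurrences` | – | 10 | cap on threshold evaluations per component chain |
| `min_seed_area` | px | 5 | smallest EDT piece accepted as a seed |
| `min_area` | px | 50 | artifact cut-off (12.5 µm² at 20×, 3.125 µm² at 40×) |
| `ac_iterations` | – | 50 | morphological Chan–Vese iterations per component |
| `pixel_size_um` | µm | 0.5 | only used for optional µm² reporting |

`threshold_t` and `split_T` are exposed to the precision–recall sweep
(`chisel.evaluation.sweep_parameter`, twofold CV via `tune_twofold`)
because they dominate detection quality: `threshold_t` trades noise
pickup against missed faint nuclei, and `split_T` trades cluster
resolution against processing time (lower values inspect more levels).

## Numerical and algorithmic choices

* **Threshold polarity and borders.** Foreground is `V < mean·(1−t/100)`
  (nuclei are dark).  The local mean uses an integral image; at borders
  the window shrinks to the valid region rather than mirroring, which is
  the convention the naive reference implementation and the tests pin
  down.  The threshold is invariant under multiplicative rescaling of V.
* **Active contour.** Morphological Chan–Vese (region-based, smoothing
  weight 1), run per connected component on its 8-px-padded bounding box;
  evolved foreground that detaches from the initial component is
  discarded, so refinement can reshape but never invent objects.
  `iterations=0` is an exact identity.
* **Splitting recursion.** Per component the EDT threshold escalates
  `T, T+dT, …` until the thresholded set has ≥ 2 accepted seeds (split)
  or vanishes / the recurrence cap is reached (keep whole).  Two
  refinements proved necessary: (1) each component crop is padded by one
  background pixel so the EDT sees the true boundary at the bounding box;
  (2) levels are evaluated only *strictly below* the component's EDT
  maximum — a cut at the maximum selects the ridge of a single basin and,
  on elongated nuclei (the 0.50-circularity preset has semi-minor axes
  ≈ 4.8 px), digitization dips in that ridge would otherwise manufacture
  false splits.  With the gate in place, the finer defaults `dT=1`,
  `min_seed_area=5` resolve roughly twice as many true clusters as the
  more conservative `dT=2`/`10` with no false splits on single nuclei.
* **Seed assignment.** Pixels go to the geodesically nearest seed within
  the component (8-connected, step costs 1/√2, scipy shortest paths);
  ties within 1e-6 go to the lowest seed id so the partition is
  deterministic and engine-independent.  Rare disconnected cells are
  reattached to the neighboring part with the largest shared boundary.
* **Fusion tie-break.** A pixel is foreground only under a *strict*
  majority of covering, non-skipped, non-padded tiles; even-coverage ties
  and uncovered pixels are background.
* **Features.** "103 per channel" is taken literally (309 total), with
  the geometric block repeated per channel; `dedup_geometric=True` gives
  the 287-value variant.  Texture blocks use a 64×64 window centered on
  the object centroid with non-object pixels set to the window's
  background mean, making all features invariant to translating an object
  together with its surroundings.  GLRLM uses 16 gray levels and 4
  directions; Haar energies come from 5 DWT levels (64→2 px); the
  autoregression block fits the four causal neighbors (W, N, NW, NE) by
  least squares and reports the residual sd.
* **Networks.** Both the nucleus classifier (in→20→2) and the patch QC
  model (18→10→2) share one trainer: Nguyen–Widrow hidden-layer
  initialization, full-batch scaled conjugate gradient on mean
  cross-entropy with an L2 penalty of 1e-4, fixed epoch cap (1000 for the
  classifier), z-scored inputs, stratified 70/15/15 split for the
  classifier.  Training is exactly reproducible given the seed.
* **Matching and aggregation.** Object-wise scoring is
  containment-based: an object containing ≥ 1 marker is one TP, surplus
  markers in it are FNs, markerless objects FPs, objectless markers FNs
  (so TP+FN = markers and TP+FP = objects always).  Multi-image sweeps
  macro-average per-image metrics by default; pooled counts are the
  alternative.  Degenerate 0/0 ratios are 0.

## The synthetic generator

`chisel.synthetic` renders what the algorithms actually consume: randomly
oriented ellipses with truncated-normal areas and circularities (solved to
ellipse aspect ratios via the Ramanujan perimeter), DAB-brown
(HSV ≈ 0.07, V 0.42) or hematoxylin-blue (≈ 0.60, V 0.38) on a pale
background (V 0.93), a configurable clustered fraction placed to overlap a
neighbor by 20–40 % of the equivalent radius, Gaussian blur (σ 0.5 px) and
pixel noise (σ 0.01), plus an optional smooth background-texture field for
low-contrast experiments.  Ground truth is exact: overlaps are resolved by
z-order, and each nucleus gets one marker at its own label pixel nearest
the centroid.  The `iispv` and `wbcd` presets reproduce the published
shape statistics of the two tissue types (means verified within one
printed sd by the tests).

What the generator does *not* emulate: chromatin texture, stain
heterogeneity within a nucleus, stromal structures, folds, out-of-focus
gradients, or densely confluent sheets of cells.  Passing tests therefore
demonstrate algorithmic correctness and end-to-end behavior under
controlled morphology and contrast — not clinical-grade performance on
real slides, where contrast, texture and packing are all harsher.

## Problem sizes used by tests and the acceptance script

Oracle equivalence runs on twenty random 64×64 channels across a
{9,17,33} × {5,15,25} window/sensitivity grid; splitter parity on
dumbbell and triple-blob fixtures at two parameter settings.  The seam
experiment uses one 2000×2000 scene with 350 nuclei (30 % clustered),
comparing whole-image processing with scheme-B tiling at ROI 500.  The
end-to-end experiment trains the classifier on the pipeline's own
detections from three 800×800 scenes (70 nuclei each) and evaluates on a
1000×1000 scene with 100 nuclei, 30 % clustered.  These sizes keep the
full suite and the acceptance script at a few minutes on one CPU while
leaving every mechanism (tiling, fusion, splitting, classification)
genuinely exercised.

## Known limitations

* Clusters joined by a thick neck relative to the nucleus radius — or by
  shallow concavities — are not split; on the default clustered scenes
  roughly 40 % of overlapping pairs resolve.  This is the documented
  failure mode of shape-only EDT splitting and bounds the end-to-end TPR
  (≈ 0.81–0.85) and, through mixed-class merges, the matched-object
  classification accuracy (≈ 0.95–0.98).
* The patch QC network is trained on synthetic blank/blurred patches;
  its features (V histogram, Laplacian energy, Otsu foreground fraction)
  are simple by design and no claim is made about real-slide QC accuracy.
* Whole-slide container formats (SVS/NDPI) and TMA de-arraying are out of
  scope; inputs are plain PNG/TIFF rasters.
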