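# Methods

## The augmentation model

The package treats a labeled section as a pair `(X, Y)`: a multi-channel
intensity image `X ∈ [0,1]^(H×W×C)` and an integer label map `Y` whose
positive values are subregion IDs, grouped by a two-level taxonomy into
primary regions `1..P` (default `P = 11`). All geometry is row-major,
0-based, origin top-left. Samples of different sizes are made comparable by
padding the smaller grid with background, anchored top-left, so pixel
coordinates never move.

A primary-region mix replaces whole primary regions of a target section
with the corresponding regions of one or more source sections:

* the source region mask is the union of its subregion masks,
  `M_sp = M_s1 ∪ … ∪ M_sk`;
* a random affine `T_aff = T_rot ∘ T_scale ∘ T_trans` perturbs `M_sp`
  (rotation and scaling about the mask's foreground centroid, then
  translation);
* the *overlap* of a placement is the pixel count
  `o = |M ∩ (1 − M_tp)|` — how much of the placed mask lands outside the
  target's own region `p`. If the unshifted placement has `o < τ`, it is
  accepted at its original location; otherwise a greedy scan over integer
  shifts `(s_x, s_y) ∈ [s_l, s_h]²` (outer loop `s_x`, inner `s_y`,
  ascending, fixed step) tracks the lowest overlap and stops at the first
  shift under tolerance;
* the winning transform-plus-shift is re-applied to every image channel
  (bilinear) and to the subregion labels (nearest-neighbor), so all
  channels and labels move as one coupled unit;
* composition is literal: pixels under the placed mask take the
  transported source content, pixels of the target's vacated region not
  covered by the paste become background (a `retain` mode keeps the target
  content instead), and everything else is untouched.

Because each region receives its own independent affine, the composite
exhibits non-linear, anatomy-like distortion without any elastic
deformation machinery.

Multi-source mixing draws the number of regions `r` uniformly from a
configured range (default 3–9), selects `r` distinct primary regions
uniformly among those present in the target and at least one source,
assigns each to a uniformly chosen eligible source, and folds the pairwise
law region by region. Two choices here were genuinely open:

* **Fold order.** The iterated composition is indexed by primary regions,
  so the fold proceeds region by region, smallest target region first.
  Small slots are thereby filled before any larger paste can spill across
  them.
* **Buried-slot fallback.** With spill tolerated up to τ (and more when
  the search cannot converge), an earlier paste can occasionally bury a
  small region that the original target did contain. In that case the
  placement slot falls back to the original target's region mask rather
  than skipping the region: the region was present when selected, and the
  pixels cleared by the fallback are spill artifacts, not original target
  content. Without the fallback roughly 1 in 500 default mixes replaced
  fewer regions than drawn.

## Hard-sample mining

The pairwise similarity is the mean, over primary regions present in at
least one of the two samples, of the IoU of their primary-region masks.
Regions present in only one sample contribute IoU = 0, so differing
missing-region patterns make a pair harder. Regions absent from both are
uninformative and excluded; two entirely-background samples have no defined
similarity (error). The scoring function is pluggable.

Per target, candidates are ranked by descending score with ties broken by
ascending sample ID; the top `ceil(easy_fraction · (N−1))` are "easy"
(default fraction 0.2), the rest "hard". Source draws are independent
Bernoulli choices of set (hard with probability `hard_fraction`, default
0.8) followed by a uniform draw within the set; an empty requested set
falls back to the other set with a warning. Mining is deterministic and the
score matrix is cacheable as CSV.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `tau` | 2% of the transformed region's area (≥ 1 px) | overlap tolerance; relative so it is size-invariant across regions spanning orders of magnitude. An absolute pixel count may be given instead. |
| rotation range | ±10° | per-region perturbation, kept small to respect parasagittal anatomy |
| scale range | [0.9, 1.1] | isotropic |
| translation range | ±5% of min(H, W) | initial placement offset |
| shift range | ±10% of min(H, W) | greedy search window |
| stepsize | max(1, min(H, W)//64) | search grid pitch |
| `n_mix_images` | 3 | target plus two sources |
| `regions_per_mix` | (3, 9) | drawn uniformly, inclusive |
| `hard_fraction` | 0.8 | oversampling bias toward hard sources |
| `opening_radius` | 1 | post-mix label smoothing |
| `easy_fraction` | 0.2 | mining partition |

The post-mix opening is applied to the label map only (the artifacts it
targets are annotation-boundary edges), label by label in ascending order,
with a square `(2r+1)²` footprint: at radius 1 this removes single-pixel
protrusions while leaving compact bodies intact, which a radius-1 disk
(a plus shape) does not. Opening never grows a mask, so label masks remain
disjoint and the operation is idempotent.

## Numerical choices

* Affine application uses `scipy.ndimage.affine_transform` with the exact
  inverse map; masks and label maps are resampled nearest-neighbor (masks
  stay strictly binary, labels are never invented), image channels
  bilinear. Out-of-bounds pixels become background/zero. Because mask and
  labels share one nearest-neighbor map, a transported label is a subregion
  of region *p* exactly where the transported mask is true.
* The greedy search seeds its best with the unshifted placement, so the
  returned overlap is never worse than the initial one, and ties keep the
  earliest-scanned shift — results are bit-reproducible under a seed.
  With early stopping disabled and stepsize 1 the search provably returns
  the exhaustive minimum over the shift grid (tested against brute force).
* τ interpretation: overlaps are stored as absolute pixel counts; the
  relative default is converted per call from the transformed mask's area.
* Degenerate cases: a transform that empties the mask raises (or, with
  multi-restart enabled, retries); an all-background sample pair has no
  similarity; `lam` outside `[0,1]` and shape mismatches are rejected.
* Per-mix seeds in the pipeline derive from
  `sha256(seed | target_id | pass_index)` (< 2³¹), so fold passes are
  independent and individually recomputable.

## The phantom generator

Phantoms emulate the structural statistics the method depends on, not the
appearance of microscopy:

* an elliptical tissue boundary whose area is
  `f = ratio/(1+ratio)` of the grid with `ratio = 0.84` by default,
  with small area-preserving axis jitter;
* a two-level hierarchy: primary territories grown by nearest-seed
  (Voronoi) assignment from random interior seeds — contiguous and
  adjacency-rich, which stresses the placement search the way real
  anatomy does — each subdivided the same way into its subregions
  (default 2–12 per primary, totals near the ~10² of real protocols);
* per-subregion channel means drawn over a configurable contrast range,
  channels correlated within a region (coupled synaptic markers), plus
  Gaussian texture noise (sd 0.05) and near-zero background;
* Bernoulli region dropout (default 0.1): a dropped region contributes no
  seed, so its territory falls to neighbors, emulating regions lost to the
  cutting plane.

What phantoms do **not** emulate: realistic region shapes and their
between-animal consistency, intensity texture beyond Gaussian noise,
stitching artifacts, tears or folds. Consequently placement convergence
rates on phantoms are pessimistic — independent random tessellations
differ far more between samples than real sections do — and passing tests
demonstrate the machinery's correctness and accounting, not segmentation
benefit on real data. The default grid is 256×512; tests run the same code
at smaller grids (down to 16×16 for the brute-force search comparisons),
the package's standard scaling for exhaustive checks.

## Pipeline semantics

Offline augmentation runs mining once, then for each fold pass over each
target: draw sources (hard-biased), draw `r` regions uniformly from all
primaries, and *skip the whole mix* — counted and logged with the offending
regions — if any drawn region is absent from the target or from every
source. Skipped mixes are not redrawn by default, keeping
`outputs + skips = n_targets × fold`. Metrics follow the standard
categorical definitions (precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1,
IoU `TP/(TP+FP+FN)`, percent scale, macro-averaged over classes present in
prediction or truth).

## Known limitations

* Only the shift is optimized greedily; rotation and scale stay at their
  sampled values (an optional multi-restart resamples them). A source
  region much larger than its target slot can therefore spill well beyond
  τ when the search cannot converge.
* Overlap counts spill onto background as well as onto foreign regions
  (the literal complement); a foreground-only variant is available by
  config flag.
* MixUp's soft label maps are exported as per-class weight planes; the
  argmax export discards the soft information.
* The bundled default taxonomy ships the 11 primary-region names with a
  configurable subregion map; full ~118-entry anatomical assignments vary
  by protocol and are supplied by the user (or generated, for phantoms).
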