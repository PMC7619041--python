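# prmix — region-aware copy-paste augmentation for dense brain segmentation

Dense whole-brain delineation of fluorescence microscopy sections is starved
for training data: expert annotation of ~100 anatomical subregions per
section is so expensive that datasets hold on the order of a hundred images,
while the foreground is nearly dense (foreground:background ≈ 0.84) and
region boundaries are ambiguous. Classical mixing augmentations fare poorly
here — MixUp blends anatomy into ambiguity, and CutMix/CarveMix paste single
patches that break global brain structure.

`prmix` implements a *primary-region mix*: subregion labels are grouped into
11 coarse anatomical units (CB, TH, MB, HB, Isocortex, HY, OLF, CTXsp, STR,
PAL, HPF), and whole primary regions are transplanted between labeled
sections. Three pieces make the composites realistic:

1. **Offline hard-sample mining.** Every pair of training samples is scored
   once by a mask-overlap similarity (mean per-primary-region IoU of label
   masks). For each target, the top 20% most similar candidates are "easy",
   the rest "hard"; mixing draws sources with an 80% bias to the hard set.
2. **Overlap-aware placement (OAA).** For each transplanted region *p*, the
   source mask `M_sp` (the union of its subregion masks) receives a random
   affine perturbation `T_aff = T_rot ∘ T_scale ∘ T_trans`. If its overlap
   with the complement of the target's own region,
   `o = |T_aff(M_sp) ∩ (1 − M_tp)|`, is at least a tolerance τ, a greedy
   grid search over integer shifts finds the placement with minimal
   overlap, stopping early once `o < τ`. The winning geometry is re-applied
   to all image channels and subregion labels as one coupled unit, so
   within-region channel co-localization is preserved exactly.
3. **Multi-source iteration.** A mix draws 3–9 primary regions and replaces
   each from one of several source sections (default: one target plus two
   sources), folding the pairwise law
   `X̃ = X̂_sp ⊙ M̂_sp + X_t ⊙ (1 − M_tp)` region by region. A per-label
   morphological opening smooths the pasted boundaries.

Comparator mixers (MixUp, rectangular CutMix and semantic CarveMix mask
forms), categorical precision/recall/F1/mIoU metrics, and a synthetic
phantom generator (elliptical two-channel "sections" with a two-level label
hierarchy, region dropout and the 0.84 foreground ratio) make the whole
pipeline testable without any microscopy data.

## Worked example

```python
import numpy as np
from prmix import (PhantomConfig, generate_dataset, mine, sample_sources,
                   MixConfig, prmix_multi)

config = PhantomConfig(grid=(96, 128), n_primary=11, subregions_per_primary=(2, 4))
samples, taxonomy = generate_dataset(6, config, seed=0)

table = mine(samples, taxonomy, easy_fraction=0.2)
t = samples[0].sample_id
print(f"target {t}: easy = {table.easy[t]}")

rng = np.random.default_rng(1)
sources = sample_sources(table, t, n_sources=2, hard_fraction=0.8, rng=rng)
by_id = {s.sample_id: s for s in samples}
result = prmix_multi([by_id[s] for s in sources], samples[0], taxonomy,
                     MixConfig(), rng)
for p, src in sorted(result.replaced.items()):
    d = result.diagnostics[p]
    print(f"region {p:2d} ({taxonomy.primary_names[p]:9s}) <- {src}  "
          f"overlap {d['overlap']:4d} px (tau {d['tau']}), shift {tuple(d['shift'])}")
```

prints

```
target phantom_000: easy = ['phantom_004']
region  1 (CB       ) <- phantom_005  overlap  111 px (tau 3), shift (0, 0)
region  2 (TH       ) <- phantom_005  overlap  107 px (tau 3), shift (-10, 10)
region  3 (MB       ) <- phantom_005  overlap  607 px (tau 13), shift (0, 0)
region  4 (HB       ) <- phantom_005  overlap  484 px (tau 10), shift (0, 0)
region  5 (Isocortex) <- phantom_005  overlap  520 px (tau 16), shift (-10, 1)
region  6 (HY       ) <- phantom_005  overlap 1014 px (tau 21), shift (0, 0)
region  9 (STR      ) <- phantom_005  overlap  412 px (tau 9), shift (0, 0)
region 11 (HPF      ) <- phantom_005  overlap  572 px (tau 18), shift (-10, 10)
```

Eight primary regions of the target were replaced from a hard source. Each
line reports the residual overlap of the placed region with foreign target
territory (in pixels, against the per-region tolerance τ = 2% of the region
area) and the shift the greedy search chose. Random Voronoi phantoms vary
far more between samples than real anatomy does, so residual overlaps above
τ are common here; the search still returns the best placement on its grid.

The same workflow is available from the shell:

```bash
prmix phantom --n 6 --out data/ --seed 1
prmix mine --input data/ --out sim.csv
prmix augment --input data/ --out augmented/ --method prmix --fold 5 --seed 1
prmix evaluate --pred augmented/ --truth augmented/
```

`augment` writes image/label TIFF pairs plus a `manifest.json` recording
every output's sources, replaced regions, placement diagnostics, skip log
and config hash; reruns with the same seed are bit-identical.

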