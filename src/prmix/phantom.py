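"""Synthetic labeled "brain section" phantoms.

Real parasagittal sections are near-dense label maps: an elliptical tissue
boundary, a foreground:background ratio around 0.84, a two-level anatomical
hierarchy (on the order of a hundred subregions grouped into 11 primary
regions), two coupled fluorescence channels with region-specific intensity,
and per-section missing regions caused by the cutting plane.  The phantoms
here emulate exactly those structural features — an ellipse partitioned into
contiguous primary regions by seeded Voronoi growth, each subdivided into
subregions the same way, with correlated per-channel region intensities,
Gaussian texture noise, and Bernoulli region dropout — so every other module
is testable without any microscopy data.

They make no attempt at photorealism: no synapse-scale texture, no stitching
artifacts, tears or folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .data_model import (
    DEFAULT_PRIMARY_NAMES,
    LabeledSample,
    RegionTaxonomy,
    save_sample,
)

__all__ = ["PhantomConfig", "build_taxonomy", "generate_phantom", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom generator parameters.

    ``foreground_ratio_target`` is the desired foreground:background pixel
    ratio (0.84 matches dense whole-section annotation).
    ``subregions_per_primary`` is the inclusive range of subregion counts
    drawn per primary region; at the defaults the expected total is near
    80–120, echoing real annotation protocols.  ``dropout_prob`` is the
    per-sample probability that a primary region is absent (its territory
    absorbed by neighbors), emulating regions lost to the cutting plane.
    ``intensity_contrast`` is the width of the uniform range the per-region
    channel means are drawn from.
    """

    grid: tuple[int, int] = (256, 512)
    n_primary: int = 11
    subregions_per_primary: tuple[int, int] = (2, 12)
    foreground_ratio_target: float = 0.84
    channel_count: int = 2
    intensity_contrast: float = 0.6
    dropout_prob: float = 0.1
    texture_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if not (0 < self.foreground_ratio_target < 1e6):
            raise ValueError("foreground_ratio_target must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        lo, hi = self.subregions_per_primary
        if not (1 <= lo <= hi):
            raise ValueError("invalid subregions_per_primary range")
        f = self.foreground_ratio_target / (1 + self.foreground_ratio_target)
        if self.grid[0] * self.grid[1] * f / self.n_primary < 4:
            raise ValueError(
                f"grid {self.grid} too small for {self.n_primary} primary regions"
            )


def build_taxonomy(config: PhantomConfig, rng: np.random.Generator) -> RegionTaxonomy:
    """Draw a two-level hierarchy: contiguous subregion IDs per primary.

    Primary names reuse the standard 11 anatomical group names, cycling if
    ``n_primary`` exceeds 11.
    """
    names = {
        p: DEFAULT_PRIMARY_NAMES[(p - 1) % len(DEFAULT_PRIMARY_NAMES)]
        + ("" if p <= len(DEFAULT_PRIMARY_NAMES) else f"_{p}")
        for p in range(1, config.n_primary + 1)
    }
    lo, hi = config.subregions_per_primary
    sub_map: dict[int, int] = {}
    next_id = 1
    for p in range(1, config.n_primary + 1):
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            sub_map[next_id] = p
            next_id += 1
    return RegionTaxonomy(subregion_to_primary=sub_map, primary_names=names)


def _voronoi_assign(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Index of the nearest seed for each point (Euclidean)."""
    return cKDTree(seeds).query(points)[1]


def generate_phantom(
    config: PhantomConfig | None = None,
    rng: np.random.Generator | None = None,
    taxonomy: RegionTaxonomy | None = None,
    sample_id: str = "phantom",
) -> tuple[LabeledSample, RegionTaxonomy]:
    """Generate one phantom section and its (possibly shared) taxonomy.

    An elliptical foreground occupying ``f = ratio / (1 + ratio)`` of the
    grid is partitioned into primary territories by nearest-seed (Voronoi)
    growth from random interior seeds; dropped-out regions contribute no
    seed, so their territory falls to neighbors.  Each territory is
    subdivided the same way into its taxonomy-assigned subregions.  Each
    subregion gets per-channel mean intensities (channels correlated within
    the region, emulating coupled synaptic markers) plus Gaussian texture.
    """
    config = config or PhantomConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if taxonomy is None:
        taxonomy = build_taxonomy(config, rng)
    H, W = config.grid

    # elliptical tissue boundary with area f*H*W
    f = config.foreground_ratio_target / (1 + config.foreground_ratio_target)
    s = sqrt(4 * f / pi)
    u = rng.uniform(0.95, 1.05)  # area-preserving axis jitter
    a, b = H / 2 * s * u, W / 2 * s / u
    cr = H / 2 + rng.uniform(-0.01, 0.01) * H
    cc = W / 2 + rng.uniform(-0.01, 0.01) * W
    rr, cc_grid = np.mgrid[0:H, 0:W]
    brain = ((rr - cr) / a) ** 2 + ((cc_grid - cc) / b) ** 2 <= 1.0
    fg_pts = np.argwhere(brain)

    # region dropout: absent regions contribute no seed
    present = [p for p in range(1, config.n_primary + 1) if rng.random() >= config.dropout_prob]
    if not present:
        present = [int(rng.integers(1, config.n_primary + 1))]

    seeds = fg_pts[rng.choice(len(fg_pts), size=len(present), replace=False)]
    owner = _voronoi_assign(fg_pts, seeds)

    labels = np.zeros((H, W), dtype=np.int64)
    for i, p in enumerate(present):
        terr = fg_pts[owner == i]
        subs = taxonomy.subregions_of(p)
        k = min(len(subs), len(terr))
        sub_seeds = terr[rng.choice(len(terr), size=k, replace=False)]
        sub_owner = _voronoi_assign(terr, sub_seeds)
        for j in range(k):
            pix = terr[sub_owner == j]
            labels[pix[:, 0], pix[:, 1]] = subs[j]

    # intensities: correlated channel means per subregion + texture noise
    C = config.channel_count
    image = np.zeros((H, W, C))
    base_lo = 0.2
    for sub in np.unique(labels):
        if sub == 0:
            continue
        m0 = rng.uniform(base_lo, base_lo + config.intensity_contrast)
        means = [m0] + [
            float(np.clip(m0 + rng.normal(0, 0.08), 0.05, 0.95)) for _ in range(C - 1)
        ]
        region = labels == sub
        for ch in range(C):
            image[region, ch] = means[ch]
    image += rng.normal(0, config.texture_noise_sd, size=image.shape)
    image[~brain] = np.abs(rng.normal(0, config.texture_noise_sd / 4, size=image[~brain].shape))
    image = np.clip(image, 0.0, 1.0)

    return LabeledSample(image, labels, sample_id), taxonomy


def generate_dataset(
    n: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> tuple[list[LabeledSample], RegionTaxonomy]:
    """Generate ``n`` phantoms sharing one taxonomy.

    The taxonomy is drawn from ``seed``; sample ``i`` uses the derived seed
    ``seed + 1 + i``, so the dataset is reproducible and samples are
    independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PhantomConfig()
    taxonomy = build_taxonomy(config, np.random.default_rng(seed))
    samples = []
    for i in range(n):
        s, _ = generate_phantom(
            config,
            rng=np.random.default_rng(seed + 1 + i),
            taxonomy=taxonomy,
            sample_id=f"phantom_{i:03d}",
        )
        samples.append(s)
    return samples, taxonomy


def write_dataset(
    samples: list[LabeledSample], taxonomy: RegionTaxonomy, out_dir: str | Path
) -> None:
    """Write samples as image/label TIFF pairs plus the taxonomy JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy.to_json(out / "taxonomy.json")
    for s in samples:
        save_sample(s, out / f"{s.sample_id}_image.tif", out / f"{s.sample_id}_labels.tif")
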