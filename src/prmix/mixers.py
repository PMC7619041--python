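"""Mixing laws for labeled samples.

Four composites of a (source, target) pair are provided, in increasing
anatomical awareness:

* ``mixup`` — global convex blend of images and one-hot label maps.
* ``masked_mix`` — binary-mask paste; CutMix with a rectangular mask,
  CarveMix-style with a label-derived semantic mask.
* ``prmix_pair`` — per-primary-region replacement: each requested region of
  the target is vacated and the source's corresponding region, placed by the
  overlap-aware search, is pasted in with its subregion labels; all channels
  move as one coupled unit.
* ``prmix_multi`` — the pairwise law folded over several sources, each
  replaced region assigned to one source, for composites drawing on three
  or more sections at once.

A per-label morphological opening smooths the artificial boundary edges the
pasting introduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import opening as _binary_opening

from .data_model import (
    LabeledSample,
    RegionTaxonomy,
    extract_primary_mask,
    pad_to,
    pad_to_common,
)
from .oaa import DegenerateResultError, RegionAbsentError, SearchConfig, oaa

__all__ = [
    "MixConfig",
    "MixupResult",
    "PRMixResult",
    "mixup",
    "masked_mix",
    "rectangle_mask",
    "carve_mask",
    "prmix_pair",
    "prmix_multi",
    "morphological_opening",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixConfig:
    """Parameters of a mixing run.

    ``n_mix_images`` counts the target plus its sources (3 means one target
    and two sources).  ``regions_per_mix`` bounds how many primary regions a
    multi-source mix replaces.  ``hard_fraction`` is the probability each
    source is drawn from the target's hard-candidate set.  ``vacated_mode``
    controls pixels the target region occupied but the pasted region does
    not cover: ``"background"`` zeroes them (the default), ``"retain"``
    keeps the target content.
    """

    n_mix_images: int = 3
    regions_per_mix: tuple[int, int] = (3, 9)
    hard_fraction: float = 0.8
    search: SearchConfig = field(default_factory=SearchConfig)
    opening_radius: int = 1
    vacated_mode: str = "background"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_mix_images < 2:
            raise ValueError("n_mix_images must be >= 2")
        lo, hi = self.regions_per_mix
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid regions_per_mix {self.regions_per_mix}")
        if not (0 <= self.hard_fraction <= 1):
            raise ValueError("hard_fraction must be in [0, 1]")
        if self.vacated_mode not in ("background", "retain"):
            raise ValueError(f"unknown vacated_mode {self.vacated_mode!r}")


# -- MixUp ------------------------------------------------------------------


@dataclass
class MixupResult:
    """A blended image with soft per-class label weights.

    ``weights[..., k]`` is the weight of ``classes[k]`` at each pixel; the
    weights at every pixel sum to 1.  Hard labels are ill-defined under a
    convex blend, so an ``argmax_labels`` export is provided for consumers
    that need an integer map.
    """

    image: np.ndarray  # (H, W, C)
    classes: np.ndarray  # (K,) sorted label values, background included
    weights: np.ndarray  # (H, W, K)
    lam: float

    def argmax_labels(self) -> np.ndarray:
        return self.classes[np.argmax(self.weights, axis=-1)]


def mixup(source: LabeledSample, target: LabeledSample, lam: float) -> MixupResult:
    """Convex blend: ``X = lam*Xs + (1-lam)*Xt`` with matching soft labels."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    source, target = pad_to_common(source, target)
    image = source.image * lam + target.image * (1.0 - lam)
    classes = np.union1d(np.unique(source.labels), np.unique(target.labels))
    weights = np.zeros(source.shape + (len(classes),))
    for k, c in enumerate(classes):
        weights[:, :, k] = lam * (source.labels == c) + (1.0 - lam) * (target.labels == c)
    return MixupResult(image=image, classes=classes, weights=weights, lam=lam)


# -- masked paste (CutMix / CarveMix form) ----------------------------------


def rectangle_mask(shape: tuple[int, int], top: int, left: int, height: int, width: int) -> np.ndarray:
    """Axis-aligned rectangular mask (the CutMix mask form)."""
    m = np.zeros(shape, dtype=bool)
    m[top : top + height, left : left + width] = True
    return m


def carve_mask(labels: np.ndarray, label_values) -> np.ndarray:
    """Semantic mask covering the given label values (the CarveMix form)."""
    return np.isin(labels, np.atleast_1d(label_values))


def masked_mix(source: LabeledSample, target: LabeledSample, mask: np.ndarray) -> LabeledSample:
    """Paste the masked part of the source over the target.

    ``X = Xs*M + Xt*(1-M)`` and likewise for the label maps.
    """
    source, target = pad_to_common(source, target)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != source.shape:
        raise ValueError(f"mask shape {mask.shape} != grid {source.shape}")
    image = np.where(mask[:, :, None], source.image, target.image)
    labels = np.where(mask, source.labels, target.labels)
    return LabeledSample(image, labels, f"{source.sample_id}+{target.sample_id}")


# -- region mix -------------------------------------------------------------


@dataclass
class PRMixResult:
    """A region-mixed sample with its provenance record.

    ``replaced`` maps each replaced primary region to the source sample it
    came from; ``diagnostics`` holds the placement search outcome per region
    (overlap, shift, tolerance, convergence); ``skipped`` lists regions that
    were requested but could not be replaced.
    """

    sample: LabeledSample
    replaced: dict[int, str] = field(default_factory=dict)
    diagnostics: dict[int, dict] = field(default_factory=dict)
    skipped: list[int] = field(default_factory=list)

    @property
    def n_replaced(self) -> int:
        return len(self.replaced)


def _paste_region(running: LabeledSample, res, target_mask: np.ndarray, vacated_mode: str) -> None:
    """Vacate the target's region and paste the placed source region, in place."""
    if vacated_mode == "background":
        running.image[target_mask] = 0.0
        running.labels[target_mask] = 0
    running.image[res.mask] = res.image_patch[res.mask]
    running.labels[res.mask] = res.labels_patch[res.mask]


def prmix_pair(
    source: LabeledSample,
    target: LabeledSample,
    regions: list[int],
    taxonomy: RegionTaxonomy,
    config: MixConfig | None = None,
    rng: np.random.Generator | None = None,
    strict: bool = True,
    slot: LabeledSample | None = None,
) -> PRMixResult:
    """Replace the listed primary regions of the target with the source's.

    For each region the overlap-aware search places the source region, the
    target's own region pixels are vacated (background by default), and the
    placed mask receives the source's subregion labels and channel
    intensities under one shared geometric transform.  Pixels outside
    replaced regions and their vacated remainders are untouched.

    With ``strict`` (the default) a region absent from either sample raises
    :class:`RegionAbsentError`; otherwise it is skipped with a warning.
    ``slot`` supplies a fallback sample (on the same grid) whose region
    masks define the placement slot when the target has lost a region —
    used by the multi-source fold, where earlier pastes can bury a small
    region that the original target did contain.
    """
    config = config or MixConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    source, target = pad_to_common(source, target)
    running = target.copy()
    out = PRMixResult(sample=running)
    for p in regions:
        src_has = extract_primary_mask(source.labels, taxonomy, p).mask.any()
        tgt_mask = extract_primary_mask(running.labels, taxonomy, p).mask
        slot_sample = running
        if src_has and not tgt_mask.any() and slot is not None:
            fallback = extract_primary_mask(slot.labels, taxonomy, p).mask
            if fallback.any():
                tgt_mask, slot_sample = fallback, slot
        if not src_has or not tgt_mask.any():
            msg = f"region {p} absent from {'source' if not src_has else 'target'}"
            if strict:
                raise RegionAbsentError(msg)
            logger.warning("%s; skipping", msg)
            out.skipped.append(p)
            continue
        try:
            res = oaa(source, slot_sample, p, taxonomy, config.search, rng)
        except DegenerateResultError:
            logger.warning("region %d: degenerate placement; target content retained", p)
            out.skipped.append(p)
            continue
        _paste_region(running, res, tgt_mask, config.vacated_mode)
        out.replaced[p] = source.sample_id
        out.diagnostics[p] = {
            "overlap": res.overlap,
            "shift": list(res.shift),
            "tau": res.tau,
            "converged": res.converged,
            "rotation": res.params.rotation,
            "scale": res.params.scale,
            "translation": list(res.params.translation),
        }
    running.sample_id = f"{target.sample_id}|mix"
    return out


def prmix_multi(
    sources: list[LabeledSample],
    target: LabeledSample,
    taxonomy: RegionTaxonomy,
    config: MixConfig | None = None,
    rng: np.random.Generator | None = None,
    regions: list[int] | None = None,
    assignment: dict[int, int] | None = None,
) -> PRMixResult:
    """Fold the pairwise region mix over several sources.

    Draws the number of regions to replace uniformly from
    ``config.regions_per_mix``, selects that many distinct primary regions
    uniformly among those present in the target and in at least one source,
    assigns each to a uniformly chosen eligible source, then applies the
    pairwise mix source by source on the running target.  Explicit
    ``regions`` (and optionally ``assignment``: region -> source index)
    override the draws.

    If no region is eligible the target is returned unchanged with a warning.
    """
    if not sources:
        raise ValueError("need at least one source")
    config = config or MixConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shape = (
        max(s.shape[0] for s in [target, *sources]),
        max(s.shape[1] for s in [target, *sources]),
    )
    target = pad_to(target, shape)
    sources = [pad_to(s, shape) for s in sources]

    present_t = {
        p for p in taxonomy.primary_names
        if extract_primary_mask(target.labels, taxonomy, p).mask.any()
    }
    present_s = [
        {
            p for p in taxonomy.primary_names
            if extract_primary_mask(s.labels, taxonomy, p).mask.any()
        }
        for s in sources
    ]

    if regions is None:
        lo, hi = config.regions_per_mix
        r = int(rng.integers(lo, hi + 1))
        eligible = sorted(p for p in present_t if any(p in ps for ps in present_s))
        if not eligible:
            logger.warning("no eligible region to mix; returning target unchanged")
            return PRMixResult(sample=target.copy())
        r = min(r, len(eligible))
        regions = sorted(rng.choice(eligible, size=r, replace=False).tolist())
    if assignment is None:
        assignment = {}
        for p in regions:
            owners = [i for i, ps in enumerate(present_s) if p in ps]
            if not owners:
                continue
            assignment[p] = int(owners[rng.integers(len(owners))])

    # iterate region by region (the composition is over primary regions),
    # smallest target region first so a small slot is filled before any
    # larger paste can spill across it
    def target_area(p: int) -> int:
        return int(extract_primary_mask(target.labels, taxonomy, p).mask.sum())

    running = target.copy()
    out = PRMixResult(sample=running)
    for p in sorted((q for q in regions if q in assignment), key=lambda q: (target_area(q), q)):
        src = sources[assignment[p]]
        step = prmix_pair(src, running, [p], taxonomy, config, rng, strict=False, slot=target)
        running = step.sample
        out.replaced.update(step.replaced)
        out.diagnostics.update(step.diagnostics)
        out.skipped.extend(step.skipped)
    out.skipped.extend(p for p in regions if p not in assignment)
    out.sample = running
    running.sample_id = f"{target.sample_id}|mix"
    return out


def morphological_opening(labels: np.ndarray, radius: int) -> np.ndarray:
    """Per-label binary opening with a square footprint, ascending label order.

    The footprint is the ``(2*radius+1)``-pixel square, so radius 1 removes
    single-pixel protrusions while leaving compact bodies intact.  Opening
    never grows a label's mask, so label masks stay disjoint; pixels an
    opening removes and no other label claims become background.  Radius 0
    is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return labels.copy()
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    out = np.zeros_like(labels)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        opened = _binary_opening(labels == lab, footprint)
        out[opened] = lab
    return out
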