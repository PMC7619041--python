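"""Offline dataset-level augmentation driver and segmentation metrics.

``augment_dataset`` expands a labeled dataset by a fold multiplier: the
similarity table is mined once, then for every pass over every target,
sources are drawn (oversampling hard candidates), a set of primary regions
is drawn, and the selected mixing law is applied.  Mixes whose drawn regions
are absent from the target or from every source are skipped and counted,
mirroring how augmentation behaves when section geometry leaves regions out.
Every output and every skip is recorded in a JSON manifest, and one
top-level seed derives all per-mix seeds, so runs are bit-reproducible and
individual mixes are independently recomputable.

``evaluate_segmentation`` provides the categorical precision / recall / F1 /
mean-IoU metrics used to compare label maps, on a percent scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    LabeledSample,
    RegionTaxonomy,
    extract_primary_mask,
    load_sample,
    pad_to_common,
    save_sample,
)
from .mining import SimilarityTable, mine, sample_sources
from .mixers import (
    MixConfig,
    carve_mask,
    masked_mix,
    mixup,
    morphological_opening,
    prmix_multi,
    rectangle_mask,
)
from .oaa import AffineParams, apply_affine

__all__ = [
    "RunConfig",
    "PreTransforms",
    "SegMetrics",
    "augment_samples",
    "augment_dataset",
    "evaluate_segmentation",
]

logger = logging.getLogger(__name__)

METHODS = ("prmix", "mixup", "cutmix", "carvemix")


@dataclass(frozen=True)
class PreTransforms:
    """Standard pre-processing toggles applied to each mixed sample.

    All off by default: intensity normalization rescales each channel to
    [0, 1]; color jitter applies a random per-channel gain/offset; global
    affine applies one small random rotation/scale/shift to image and
    labels together.
    """

    intensity_normalization: bool = False
    color_jitter: bool = False
    global_affine: bool = False


@dataclass(frozen=True)
class RunConfig:
    """One offline augmentation run."""

    input_dir: str = ""
    output_dir: str = ""
    fold_multiplier: int = 5
    mix: MixConfig = field(default_factory=MixConfig)
    method: str = "prmix"
    pre_transforms: PreTransforms = field(default_factory=PreTransforms)
    easy_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_multiplier < 1:
            raise ValueError("fold_multiplier must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(seed: int, target_id: str, pass_index: int) -> int:
    """Stable per-mix seed below 2**31 from the run seed and mix identity."""
    blob = f"{seed}|{target_id}|{pass_index}".encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)


def _apply_pre_transforms(
    sample: LabeledSample, pre: PreTransforms, rng: np.random.Generator
) -> LabeledSample:
    img, lab = sample.image, sample.labels
    if pre.color_jitter:
        gain = rng.uniform(0.9, 1.1, size=img.shape[2])
        offset = rng.uniform(-0.05, 0.05, size=img.shape[2])
        img = np.clip(img * gain + offset, 0.0, 1.0)
    if pre.global_affine:
        params = AffineParams(
            rotation=float(rng.uniform(-5, 5)),
            scale=float(rng.uniform(0.95, 1.05)),
            translation=(float(rng.uniform(-3, 3)), float(rng.uniform(-3, 3))),
        )
        center = (img.shape[0] / 2, img.shape[1] / 2)
        img = apply_affine(img, params, center=center, order=1)
        lab = apply_affine(lab, params, center=center, order=0)
        img = np.clip(img, 0.0, 1.0)
    if pre.intensity_normalization:
        img = img.copy()
        for ch in range(img.shape[2]):
            lo, hi = img[:, :, ch].min(), img[:, :, ch].max()
            if hi > lo:
                img[:, :, ch] = (img[:, :, ch] - lo) / (hi - lo)
    return LabeledSample(img, lab, sample.sample_id)


def _mix_one(
    method: str,
    sources: list[LabeledSample],
    target: LabeledSample,
    regions: list[int],
    taxonomy: RegionTaxonomy,
    mix_cfg: MixConfig,
    rng: np.random.Generator,
) -> tuple[LabeledSample, dict]:
    """Dispatch one mix; returns (sample, method-specific manifest extras)."""
    if method == "prmix":
        assignment = {}
        for p in regions:
            owners = [
                i for i, s in enumerate(sources)
                if extract_primary_mask(s.labels, taxonomy, p).mask.any()
            ]
            assignment[p] = int(owners[rng.integers(len(owners))])
        res = prmix_multi(
            sources, target, taxonomy, mix_cfg, rng, regions=regions, assignment=assignment
        )
        return res.sample, {
            "replaced": {str(k): v for k, v in res.replaced.items()},
            "diagnostics": {str(k): v for k, v in res.diagnostics.items()},
            "regions_skipped_in_mix": res.skipped,
        }
    src, tgt = pad_to_common(sources[0], target)
    if method == "mixup":
        lam = float(rng.uniform(0.0, 1.0))
        res = mixup(src, tgt, lam)
        out = LabeledSample(res.image, res.argmax_labels(), tgt.sample_id)
        return out, {"lam": lam, "source": src.sample_id}
    if method == "cutmix":
        H, W = tgt.shape
        h = int(rng.integers(max(1, H // 8), max(2, H // 2)))
        w = int(rng.integers(max(1, W // 8), max(2, W // 2)))
        top = int(rng.integers(0, H - h + 1))
        left = int(rng.integers(0, W - w + 1))
        mask = rectangle_mask((H, W), top, left, h, w)
        return masked_mix(src, tgt, mask), {
            "rect": [top, left, h, w], "source": src.sample_id,
        }
    # carvemix: paste the drawn regions' semantic mask from the source
    subs = [s for p in regions for s in taxonomy.subregions_of(p)]
    mask = carve_mask(src.labels, subs)
    return masked_mix(src, tgt, mask), {"carved_regions": regions, "source": src.sample_id}


def augment_samples(
    samples: list[LabeledSample],
    taxonomy: RegionTaxonomy,
    config: RunConfig,
    table: SimilarityTable | None = None,
) -> tuple[list[LabeledSample], dict]:
    """Run the offline augmentation loop in memory.

    Returns the augmented samples and the run manifest.  Output count is
    ``len(samples) * fold_multiplier - skips``; each skip is logged with the
    regions that caused it.
    """
    if len(samples) < 2:
        raise ValueError("augmentation needs at least 2 input samples")
    if table is None:
        table = mine(samples, taxonomy, easy_fraction=config.easy_fraction)
    by_id = {s.sample_id: s for s in samples}
    mix_cfg = config.mix
    lo, hi = mix_cfg.regions_per_mix
    all_primaries = sorted(taxonomy.primary_names)

    outputs: list[LabeledSample] = []
    manifest: dict = {
        "seed": config.seed,
        "method": config.method,
        "config_hash": config.config_hash(),
        "outputs": [],
        "skips": [],
    }
    for pass_index in range(config.fold_multiplier):
        for target in samples:
            rng = np.random.default_rng(derive_seed(config.seed, target.sample_id, pass_index))
            src_ids = sample_sources(
                table, target.sample_id, mix_cfg.n_mix_images - 1, mix_cfg.hard_fraction, rng
            )
            sources = [by_id[i] for i in src_ids]
            r = int(rng.integers(lo, min(hi, len(all_primaries)) + 1))
            regions = sorted(rng.choice(all_primaries, size=r, replace=False).tolist())

            # exclusion rule: drop the whole mix if any drawn region is
            # absent from the target or from every source
            missing = [
                p for p in regions
                if not extract_primary_mask(target.labels, taxonomy, p).mask.any()
                or not any(
                    extract_primary_mask(s.labels, taxonomy, p).mask.any() for s in sources
                )
            ]
            if missing:
                manifest["skips"].append(
                    {
                        "target": target.sample_id,
                        "pass": pass_index,
                        "sources": src_ids,
                        "regions": regions,
                        "missing_regions": missing,
                    }
                )
                continue

            mixed, extras = _mix_one(
                config.method, sources, target, regions, taxonomy, mix_cfg, rng
            )
            mixed.labels = morphological_opening(mixed.labels, mix_cfg.opening_radius)
            mixed = _apply_pre_transforms(mixed, config.pre_transforms, rng)
            mixed.sample_id = f"{target.sample_id}_f{pass_index:02d}"
            outputs.append(mixed)
            entry = {
                "id": mixed.sample_id,
                "target": target.sample_id,
                "pass": pass_index,
                "sources": src_ids,
                "regions": regions,
            }
            entry.update(extras)
            manifest["outputs"].append(entry)
    manifest["skip_count"] = len(manifest["skips"])
    manifest["output_count"] = len(outputs)
    return outputs, manifest


def load_dataset(input_dir: str | Path) -> tuple[list[LabeledSample], RegionTaxonomy]:
    """Load a dataset directory: taxonomy.json plus *_image / *_labels pairs."""
    d = Path(input_dir)
    tax_path = d / "taxonomy.json"
    if not tax_path.exists():
        raise FileNotFoundError(f"no taxonomy.json in {d}")
    taxonomy = RegionTaxonomy.from_json(tax_path)
    samples = []
    bad: list[str] = []
    for img_path in sorted(d.glob("*_image.*")):
        stem = img_path.name.rsplit("_image", 1)[0]
        lab_candidates = [p for p in d.glob(f"{stem}_labels.*")]
        if not lab_candidates:
            bad.append(str(img_path))
            continue
        try:
            samples.append(load_sample(img_path, lab_candidates[0], taxonomy, sample_id=stem))
        except Exception:
            bad.append(str(img_path))
    if bad:
        raise IOError(f"unreadable input files: {bad}")
    return samples, taxonomy


def augment_dataset(config: RunConfig) -> dict:
    """Load a dataset directory, augment it, and write outputs + manifest."""
    samples, taxonomy = load_dataset(config.input_dir)
    if len(samples) < 2:
        raise ValueError(f"input dir {config.input_dir} holds {len(samples)} samples; need >= 2")
    outputs, manifest = augment_samples(samples, taxonomy, config)
    if not outputs:
        raise RuntimeError("zero producible mixes under this configuration")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy.to_json(out / "taxonomy.json")
    for s in outputs:
        save_sample(s, out / f"{s.sample_id}_image.tif", out / f"{s.sample_id}_labels.tif")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# -- metrics ----------------------------------------------------------------


@dataclass
class SegMetrics:
    """Categorical segmentation metrics on a percent scale.

    ``per_class`` maps each evaluated class to its precision, recall, F1 and
    IoU; the top-level fields are macro averages over evaluated classes.
    Classes absent from both prediction and truth are excluded.
    """

    per_class: dict[int, dict[str, float]]
    precision: float
    recall: float
    f1: float
    mean_iou: float
    classes: list[int]


def evaluate_segmentation(
    pred: np.ndarray, truth: np.ndarray, classes: list[int] | None = None
) -> SegMetrics:
    """Per-class precision, recall, F1 and IoU between two label maps.

    Background (0) is excluded from the class list unless passed explicitly.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if classes is None:
        classes = sorted(int(c) for c in np.union1d(np.unique(pred), np.unique(truth)) if c != 0)
    per_class: dict[int, dict[str, float]] = {}
    for c in classes:
        pm, tm = pred == c, truth == c
        if not pm.any() and not tm.any():
            continue  # undefined: absent from both
        tp = int(np.count_nonzero(pm & tm))
        fp = int(np.count_nonzero(pm & ~tm))
        fn = int(np.count_nonzero(~pm & tm))
        prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        rec = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        iou = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1, "iou": iou}
    if not per_class:
        raise ValueError("no class present in either map")
    ks = sorted(per_class)
    return SegMetrics(
        per_class=per_class,
        precision=float(np.mean([per_class[c]["precision"] for c in ks])),
        recall=float(np.mean([per_class[c]["recall"] for c in ks])),
        f1=float(np.mean([per_class[c]["f1"] for c in ks])),
        mean_iou=float(np.mean([per_class[c]["iou"] for c in ks])),
        classes=ks,
    )
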