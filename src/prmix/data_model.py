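"""Core containers: region taxonomy, labeled samples, binary region masks, and file I/O.

A labeled sample is a multi-channel fluorescence image plus a co-registered
integer label map whose positive values are fine anatomical *subregion* IDs
(0 is background).  A :class:`RegionTaxonomy` groups those subregions into a
small number of coarse *primary regions* — the units that region-aware mixing
swaps between images.

Conventions: arrays are row-major, 0-based, indexed ``(row, col)`` with the
origin at the top-left.  Images are float arrays of shape ``(H, W, C)`` with
intensities in ``[0, 1]``; label maps are integer ``(H, W)`` arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "RegionTaxonomy",
    "LabeledSample",
    "BinaryRegionMask",
    "DEFAULT_PRIMARY_NAMES",
    "bundled_taxonomy",
    "default_taxonomy",
    "load_sample",
    "save_sample",
    "extract_primary_mask",
    "pad_to",
    "pad_to_common",
]

#: The 11 coarse anatomical groups used for parasagittal mouse-brain sections.
DEFAULT_PRIMARY_NAMES = (
    "CB", "TH", "MB", "HB", "Isocortex", "HY", "OLF", "CTXsp", "STR", "PAL", "HPF",
)


class TaxonomyError(ValueError):
    """A label value has no primary-region assignment."""


class DimensionError(ValueError):
    """Image and label grids disagree in shape."""


@dataclass(frozen=True)
class RegionTaxonomy:
    """Two-level label hierarchy: subregion ID -> primary-region ID.

    Parameters
    ----------
    subregion_to_primary
        Maps every positive subregion label to a primary-region ID in ``1..P``.
        Background (0) is never a key.
    primary_names
        Maps primary-region ID to a display name.  IDs must form the
        contiguous range ``1..P``.
    """

    subregion_to_primary: dict[int, int]
    primary_names: dict[int, str]

    def __post_init__(self) -> None:
        ids = sorted(self.primary_names)
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"primary-region IDs must be contiguous 1..P, got {ids}")
        if 0 in self.subregion_to_primary:
            raise ValueError("background label 0 cannot be assigned to a primary region")
        for sub, p in self.subregion_to_primary.items():
            if sub <= 0:
                raise ValueError(f"subregion labels must be positive, got {sub}")
            if p not in self.primary_names:
                raise TaxonomyError(f"subregion {sub} maps to unknown primary region {p}")

    @property
    def P(self) -> int:
        """Number of primary regions."""
        return len(self.primary_names)

    def primary_of(self, subregion: int) -> int:
        try:
            return self.subregion_to_primary[subregion]
        except KeyError:
            raise TaxonomyError(f"label value {subregion} is not in the taxonomy") from None

    def subregions_of(self, p: int) -> list[int]:
        """All subregion labels belonging to primary region ``p``, ascending."""
        if p not in self.primary_names:
            raise TaxonomyError(f"unknown primary region {p}")
        return sorted(s for s, q in self.subregion_to_primary.items() if q == p)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "primary": {str(k): v for k, v in sorted(self.primary_names.items())},
            "map": {str(k): v for k, v in sorted(self.subregion_to_primary.items())},
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionTaxonomy":
        obj = json.loads(Path(path).read_text())
        return cls(
            subregion_to_primary={int(k): int(v) for k, v in obj["map"].items()},
            primary_names={int(k): str(v) for k, v in obj["primary"].items()},
        )


def bundled_taxonomy() -> RegionTaxonomy:
    """Load the taxonomy JSON shipped with the package (11 primary regions,
    one placeholder subregion per primary; real protocols supply their own
    subregion map)."""
    from importlib.resources import files

    obj = json.loads(files("prmix").joinpath("data/default_taxonomy.json").read_text())
    return RegionTaxonomy(
        subregion_to_primary={int(k): int(v) for k, v in obj["map"].items()},
        primary_names={int(k): str(v) for k, v in obj["primary"].items()},
    )


def default_taxonomy(subregions_per_primary: int = 1) -> RegionTaxonomy:
    """The bundled 11-primary-region taxonomy.

    The primary-region names are fixed; the subregion map is configurable
    because fine-grained assignments vary between annotation protocols.  With
    ``subregions_per_primary=k`` subregion IDs are assigned contiguously:
    primary ``p`` owns subregions ``(p-1)*k+1 .. p*k``.
    """
    names = {i + 1: n for i, n in enumerate(DEFAULT_PRIMARY_NAMES)}
    k = subregions_per_primary
    sub = {(p - 1) * k + j: p for p in names for j in range(1, k + 1)}
    return RegionTaxonomy(subregion_to_primary=sub, primary_names=names)


@dataclass
class LabeledSample:
    """A multi-channel intensity image with its co-registered label map."""

    image: np.ndarray  # (H, W, C) float, in [0, 1]
    labels: np.ndarray  # (H, W) int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim == 2:
            self.image = self.image[:, :, None]
        if self.image.ndim != 3:
            raise DimensionError(f"image must be (H, W, C), got shape {self.image.shape}")
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("label map must be an integer array")
        if self.labels.ndim != 2:
            raise DimensionError(f"label map must be (H, W), got shape {self.labels.shape}")
        if self.image.shape[:2] != self.labels.shape:
            raise DimensionError(
                f"image grid {self.image.shape[:2]} != label grid {self.labels.shape}"
            )
        if not np.all(np.isfinite(self.image)) or self.image.min() < 0:
            raise ValueError("image intensities must be finite and nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_channels(self) -> int:
        return self.image.shape[2]

    def validate_labels(self, taxonomy: RegionTaxonomy) -> None:
        """Check every nonzero label is known to the taxonomy."""
        present = np.unique(self.labels)
        for v in present:
            if v != 0 and int(v) not in taxonomy.subregion_to_primary:
                raise TaxonomyError(f"label value {int(v)} is not in the taxonomy")

    def copy(self) -> "LabeledSample":
        return LabeledSample(self.image.copy(), self.labels.copy(), self.sample_id)


@dataclass(frozen=True)
class BinaryRegionMask:
    """Boolean grid marking one primary region's territory in a sample."""

    mask: np.ndarray  # (H, W) bool
    region: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def extract_primary_mask(
    labels: np.ndarray, taxonomy: RegionTaxonomy, p: int
) -> BinaryRegionMask:
    """Union of all subregion masks belonging to primary region ``p``.

    A primary region absent from the map yields an all-false mask; an
    unknown ``p`` is an error.
    """
    if p not in taxonomy.primary_names:
        raise TaxonomyError(f"unknown primary region {p}")
    subs = taxonomy.subregions_of(p)
    mask = np.isin(labels, subs) if subs else np.zeros_like(labels, dtype=bool)
    return BinaryRegionMask(mask=mask, region=p)


def pad_to(sample: LabeledSample, shape: tuple[int, int]) -> LabeledSample:
    """Pad a sample with background to the given grid, anchored top-left.

    A sample already on the grid is returned as-is (no copy).
    """
    H, W = shape
    if sample.shape == (H, W):
        return sample
    if sample.shape[0] > H or sample.shape[1] > W:
        raise DimensionError(f"cannot pad {sample.shape} down to {(H, W)}")
    h, w = sample.shape
    img = np.zeros((H, W, sample.n_channels), dtype=sample.image.dtype)
    img[:h, :w] = sample.image
    lab = np.zeros((H, W), dtype=sample.labels.dtype)
    lab[:h, :w] = sample.labels
    return LabeledSample(img, lab, sample.sample_id)


def pad_to_common(a: LabeledSample, b: LabeledSample) -> tuple[LabeledSample, LabeledSample]:
    """Pad both samples with background to their common bounding size.

    Anchoring is top-left, so existing pixel coordinates are preserved.
    Samples already on a common grid are returned as-is (no copy).
    """
    shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
    return pad_to(a, shape), pad_to(b, shape)


# -- file I/O ---------------------------------------------------------------


def _read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        # multi-channel TIFFs may come back channel-first
        if arr.ndim == 3 and arr.shape[0] < min(arr.shape[1], arr.shape[2]):
            arr = np.moveaxis(arr, 0, -1)
        return arr
    return iio.imread(path)


def load_sample(
    image_path: str | Path,
    label_path: str | Path,
    taxonomy: RegionTaxonomy,
    sample_id: str | None = None,
) -> LabeledSample:
    """Load and validate an image / label-map pair.

    Integer images are rescaled to ``[0, 1]`` by their dtype maximum; float
    images are taken as already normalized.  Single-channel images are
    promoted to ``C=1``.
    """
    img = _read_image(image_path)
    lab = _read_image(label_path)
    if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
        raise DimensionError(
            f"label map must decode to an integer (H, W) array, got "
            f"{lab.dtype} with shape {lab.shape}"
        )
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(img.dtype).max
    else:
        img = img.astype(np.float64)
    sample = LabeledSample(
        img, lab.astype(np.int64), sample_id or Path(image_path).stem
    )
    sample.validate_labels(taxonomy)
    return sample


def save_sample(sample: LabeledSample, image_path: str | Path, label_path: str | Path) -> None:
    """Write the image as float32 TIFF and the label map as int32 TIFF.

    The label round trip is bit-exact; image intensities survive up to
    float32 precision.
    """
    tifffile.imwrite(Path(image_path), sample.image.astype(np.float32))
    tifffile.imwrite(Path(label_path), sample.labels.astype(np.int32))
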