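"""Overlap-aware augmentation: greedy low-collision placement of a region.

When a primary region is copied from a source section into a target section,
a naive paste can spill heavily onto the target's *other* regions, because
section geometry varies between animals and cutting planes.  OAA mitigates
this: the source region's mask is given a random affine perturbation
(rotation about its centroid, isotropic scaling, translation), and if the
perturbed mask's overlap with the complement of the target's same-named
region exceeds a tolerance ``tau``, a greedy grid search over integer pixel
shifts looks for a placement with minimal overlap, stopping early at the
first placement under tolerance.  The winning geometry is then re-applied to
all image channels as one coupled unit, so within-region channel
co-localization is preserved exactly.

Independent per-region affines give the composite image non-linear,
anatomy-like distortion without any elastic deformation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np
from scipy import ndimage

from .data_model import BinaryRegionMask, LabeledSample, extract_primary_mask, pad_to_common

__all__ = [
    "AffineParams",
    "SearchConfig",
    "OAAResult",
    "RegionAbsentError",
    "DegenerateResultError",
    "random_affine",
    "apply_affine",
    "shift_grid",
    "overlap",
    "oaa",
]


class RegionAbsentError(ValueError):
    """The requested primary region has no pixels in the source sample."""


class DegenerateResultError(RuntimeError):
    """The affine transform pushed the whole region off the grid."""


@dataclass(frozen=True)
class AffineParams:
    """A sampled affine perturbation: rotation (degrees), isotropic scale,
    and a (row, col) translation in pixels."""

    rotation: float
    scale: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.rotation):
            raise ValueError("rotation must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the placement search.

    ``tau`` is the overlap tolerance in pixels; when ``None`` it is resolved
    per call as ``ceil(tau_fraction * area)`` of the transformed region, so
    the tolerance scales with regions whose areas span orders of magnitude.
    ``translation_range``, ``shift_range`` and ``stepsize`` default to
    grid-relative values (±5% / ±10% of ``min(H, W)`` and
    ``max(1, min(H, W) // 64)``) resolved against the working grid.
    """

    tau: int | None = None
    tau_fraction: float = 0.02
    rotation_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range: tuple[float, float] | None = None
    shift_range: tuple[int, int] | None = None
    stepsize: int | None = None
    early_stop: bool = True
    foreground_only: bool = False
    n_restarts: int = 1

    def __post_init__(self) -> None:
        for name in ("rotation_range", "scale_range", "translation_range", "shift_range"):
            rng = getattr(self, name)
            if rng is not None and rng[0] > rng[1]:
                raise ValueError(f"{name} low > high: {rng}")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.stepsize is not None and self.stepsize < 1:
            raise ValueError("stepsize must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def resolve(self, shape: tuple[int, int]) -> "SearchConfig":
        """Fill grid-relative defaults for a concrete (H, W)."""
        m = min(shape)
        tr = self.translation_range or (-0.05 * m, 0.05 * m)
        sr = self.shift_range or (-max(1, round(0.10 * m)), max(1, round(0.10 * m)))
        step = self.stepsize or max(1, m // 64)
        return replace(self, translation_range=tr, shift_range=sr, stepsize=step)

    def resolve_tau(self, area: int) -> int:
        return self.tau if self.tau is not None else max(1, ceil(self.tau_fraction * area))


@dataclass
class OAAResult:
    """Outcome of one placement search.

    ``overlap`` is the pixel count ``|mask & ~target_region|`` of the
    returned mask, recomputable from ``mask`` itself; ``converged`` is true
    iff ``overlap < tau``.  ``image_patch`` and ``labels_patch`` are the
    source image channels / subregion labels carried under the identical
    composed geometry, zeroed outside ``mask``.
    """

    mask: np.ndarray  # (H, W) bool
    image_patch: np.ndarray  # (H, W, C) float, zero outside mask
    labels_patch: np.ndarray  # (H, W) int, zero outside mask
    overlap: int
    shift: tuple[int, int]
    converged: bool
    params: AffineParams
    tau: int
    center: tuple[float, float]
    n_evaluated: int


def random_affine(config: SearchConfig, rng: np.random.Generator) -> AffineParams:
    """Draw rotation, scale and translation uniformly from their ranges."""
    if config.translation_range is None:
        raise ValueError("translation_range unresolved; call config.resolve(shape) first")
    rot = rng.uniform(*config.rotation_range)
    sc = rng.uniform(*config.scale_range)
    tr = (rng.uniform(*config.translation_range), rng.uniform(*config.translation_range))
    return AffineParams(rotation=float(rot), scale=float(sc), translation=(float(tr[0]), float(tr[1])))


def _affine_matrix(params: AffineParams, center: tuple[float, float]):
    """Inverse-map matrix/offset for scipy.ndimage.affine_transform.

    Forward map: p_out = s·R·(p_in − c) + c + t, i.e. rotate about the
    centroid, scale about it, then translate.
    """
    th = np.deg2rad(params.rotation)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    A = params.scale * R
    Ainv = np.linalg.inv(A)
    c = np.asarray(center, dtype=float)
    t = np.asarray(params.translation, dtype=float)
    offset = c - Ainv @ (c + t)
    return Ainv, offset


def apply_affine(
    grid: np.ndarray,
    params: AffineParams,
    center: tuple[float, float] | None = None,
    order: int | None = None,
) -> np.ndarray:
    """Apply the composed affine to a mask, label map or channel stack.

    Rotation is about ``center`` (default: the grid's foreground centroid
    for masks; for images pass the companion mask's centroid so mask and
    image stay in register).  Boolean masks and integer label maps are
    resampled nearest-neighbor; float channel stacks bilinear.  Pixels
    mapped from outside the grid become background/zero.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty grid")
    is_mask = grid.dtype == bool
    is_int = np.issubdtype(grid.dtype, np.integer)
    if center is None:
        fg = grid.any(axis=-1) if grid.ndim == 3 else (grid != 0)
        if not fg.any():
            return grid.copy()
        center = tuple(np.argwhere(fg).mean(axis=0))
    Ainv, offset = _affine_matrix(params, center)
    if order is None:
        order = 0 if (is_mask or is_int) else 1
    if grid.ndim == 2:
        work = grid.astype(np.uint8) if is_mask else grid
        out = ndimage.affine_transform(
            work, Ainv, offset=offset, order=order, mode="constant", cval=0
        )
        return out.astype(bool) if is_mask else out
    out = np.empty_like(grid)
    for ch in range(grid.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            grid[:, :, ch], Ainv, offset=offset, order=order, mode="constant", cval=0
        )
    return out


def shift_grid(arr: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer (row, col) shift with zero fill (pixels leave the grid)."""
    dr, dc = int(shift[0]), int(shift[1])
    out = np.zeros_like(arr)
    H, W = arr.shape[:2]
    r0, r1 = max(dr, 0), min(H + dr, H)
    c0, c1 = max(dc, 0), min(W + dc, W)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = arr[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def overlap(query_mask, target_mask) -> int:
    """Pixels of the query mask falling outside the target's own region."""
    q = query_mask.mask if isinstance(query_mask, BinaryRegionMask) else query_mask
    t = target_mask.mask if isinstance(target_mask, BinaryRegionMask) else target_mask
    if q.shape != t.shape:
        raise ValueError(f"shape mismatch: {q.shape} vs {t.shape}")
    return int(np.count_nonzero(q & ~t))


def _search_shifts(M0, allowed, tau, config):
    """Greedy scan over the shift grid; returns (best_o, best_shift, n_eval).

    The unshifted placement seeds the best; scan order is sx outer, sy
    inner, ascending, ties keep the earliest-scanned shift.
    """
    best_o = overlap(M0, allowed)
    best_shift = (0, 0)
    n_eval = 1
    if best_o < tau:
        return best_o, best_shift, n_eval
    sl, sh = config.shift_range
    step = config.stepsize
    stop = False
    for sx in range(sl, sh + 1, step):
        for sy in range(sl, sh + 1, step):
            o = overlap(shift_grid(M0, (sx, sy)), allowed)
            n_eval += 1
            if o < best_o:
                best_o, best_shift = o, (sx, sy)
                if config.early_stop and best_o < tau:
                    stop = True
                    break
        if stop:
            break
    return best_o, best_shift, n_eval


def oaa(
    source: LabeledSample,
    target: LabeledSample,
    p: int,
    taxonomy,
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> OAAResult:
    """Place source primary region ``p`` into the target with minimal spill.

    Draws an affine perturbation, applies it to the source region mask, and
    if the perturbed mask overlaps the complement of the target's region ``p``
    by ``tau`` pixels or more, scans integer shifts greedily for the lowest
    overlap (early-stopping under tolerance unless disabled).  The winning
    transform is re-applied to the source image channels and subregion
    labels synchronously.

    With ``config.n_restarts > 1`` the affine draw is repeated and the best
    restart kept (lowest overlap; first restart wins ties).
    """
    config = config or SearchConfig()
    rng = rng if rng is not None else np.random.default_rng()
    source, target = pad_to_common(source, target)
    cfg = config.resolve(source.shape)

    Msp = extract_primary_mask(source.labels, taxonomy, p).mask
    if not Msp.any():
        raise RegionAbsentError(f"primary region {p} absent from source {source.sample_id!r}")
    Mtp = extract_primary_mask(target.labels, taxonomy, p).mask
    if cfg.foreground_only:
        # count spill only onto other regions' territory, not background
        allowed = Mtp | (target.labels == 0)
    else:
        allowed = Mtp

    best: tuple[int, tuple[int, int], AffineParams, np.ndarray, tuple[float, float], int, int] | None = None
    total_eval = 0
    for _ in range(cfg.n_restarts):
        params = random_affine(cfg, rng)
        center = tuple(np.argwhere(Msp).mean(axis=0))
        M0 = apply_affine(Msp, params, center=center)
        if not M0.any():
            if cfg.n_restarts == 1:
                raise DegenerateResultError(
                    f"transform left region {p} of {source.sample_id!r} empty"
                )
            continue
        tau = cfg.resolve_tau(int(M0.sum()))
        o, shift, n_eval = _search_shifts(M0, allowed, tau, cfg)
        total_eval += n_eval
        if best is None or o < best[0]:
            best = (o, shift, params, M0, center, tau, n_eval)
        if o < tau:
            break
    if best is None:
        raise DegenerateResultError(f"all restarts left region {p} empty")

    o, shift, params, M0, center, tau, _ = best
    mask = shift_grid(M0, shift)
    # re-apply the winning geometry to image channels (bilinear) and
    # subregion labels (nearest) as one coupled unit
    warped_img = shift_grid(apply_affine(source.image, params, center=center), shift)
    warped_lab = shift_grid(apply_affine(source.labels, params, center=center), shift)
    image_patch = warped_img * mask[:, :, None]
    labels_patch = np.where(mask, warped_lab, 0)
    o_final = overlap(mask, allowed)
    return OAAResult(
        mask=mask,
        image_patch=image_patch,
        labels_patch=labels_patch,
        overlap=o_final,
        shift=shift,
        converged=o_final < tau,
        params=params,
        tau=tau,
        center=center,
        n_evaluated=total_eval,
    )
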