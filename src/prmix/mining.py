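"""Offline hard-sample mining.

Mixing random pairs produces feature-inconsistent composites, while mixing
only look-alike pairs is too easy to teach anything.  The compromise used
here: score every pair of training samples once, offline, by a *mask overlap
score*; for each target sample rank the rest, call the most similar fraction
"easy" and the remainder "hard"; at augmentation time oversample sources from
the hard set (80% by default).

The score is the mean, over primary regions present in at least one of the
two samples, of the intersection-over-union of their primary-region masks.
Regions present in only one sample contribute IoU = 0, so differing
missing-region patterns push a pair toward "hard".  The scoring function is
pluggable for experimentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data_model import LabeledSample, RegionTaxonomy, extract_primary_mask, pad_to_common

__all__ = ["SimilarityTable", "mask_overlap_score", "mine", "sample_sources"]

logger = logging.getLogger(__name__)


def mask_overlap_score(
    a: LabeledSample, b: LabeledSample, taxonomy: RegionTaxonomy
) -> float:
    """Mean per-primary-region IoU between two samples' label maps.

    Regions absent from both samples are excluded from the mean; a region
    present in only one contributes 0.  Returns a value in ``[0, 1]``;
    1.0 iff every present region's mask is identical in the two samples.

    Raises
    ------
    ValueError
        If both samples are entirely background (no region to compare).
    """
    a, b = pad_to_common(a, b)
    ious = []
    for p in sorted(taxonomy.primary_names):
        ma = extract_primary_mask(a.labels, taxonomy, p).mask
        mb = extract_primary_mask(b.labels, taxonomy, p).mask
        union = int(np.count_nonzero(ma | mb))
        if union == 0:
            continue  # absent from both: uninformative
        inter = int(np.count_nonzero(ma & mb))
        ious.append(inter / union)
    if not ious:
        raise ValueError("similarity undefined: both samples are entirely background")
    return float(np.mean(ious))


@dataclass
class SimilarityTable:
    """Pairwise similarity scores with a per-target easy/hard partition.

    ``easy[t]`` holds the ``ceil(easy_fraction * (N-1))`` candidates most
    similar to target ``t`` (ties broken by ascending sample ID);
    ``hard[t]`` is the complement.  The diagonal holds self-similarity
    (1.0 for any sample compared with itself).
    """

    ids: list[str]
    score: np.ndarray  # (N, N) symmetric, values in [0, 1]
    easy_fraction: float = 0.2
    easy: dict[str, list[str]] = field(default_factory=dict)
    hard: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.easy:  # partition not supplied: derive it
            self._partition()

    def _partition(self) -> None:
        n = len(self.ids)
        n_easy = ceil(self.easy_fraction * (n - 1))
        for i, t in enumerate(self.ids):
            others = [(j, self.ids[j]) for j in range(n) if j != i]
            # descending score, ties by ascending sample ID
            ranked = sorted(others, key=lambda jx: (-self.score[i, jx[0]], jx[1]))
            self.easy[t] = sorted(x for _, x in ranked[:n_easy])
            self.hard[t] = sorted(x for _, x in ranked[n_easy:])

    def score_of(self, a: str, b: str) -> float:
        return float(self.score[self.ids.index(a), self.ids.index(b)])

    # -- cache --------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the score matrix with an ID header row and column."""
        lines = ["," + ",".join(self.ids)]
        for i, t in enumerate(self.ids):
            lines.append(t + "," + ",".join(f"{v:.17g}" for v in self.score[i]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, easy_fraction: float = 0.2) -> "SimilarityTable":
        rows = Path(path).read_text().strip().splitlines()
        ids = rows[0].split(",")[1:]
        score = np.array(
            [[float(v) for v in r.split(",")[1:]] for r in rows[1:]], dtype=float
        )
        return cls(ids=ids, score=score, easy_fraction=easy_fraction)


def mine(
    dataset: Sequence[LabeledSample],
    taxonomy: RegionTaxonomy,
    easy_fraction: float = 0.2,
    score_fn: Callable[[LabeledSample, LabeledSample, RegionTaxonomy], float] | None = None,
) -> SimilarityTable:
    """Score all pairs and build the easy/hard partition for every target.

    Deterministic: reruns on the same dataset are bit-identical.  The result
    is cacheable via :meth:`SimilarityTable.to_csv`.
    """
    if len(dataset) < 2:
        raise ValueError(f"mining needs at least 2 samples, got {len(dataset)}")
    if not (0 < easy_fraction < 1):
        raise ValueError(f"easy_fraction must be in (0, 1), got {easy_fraction}")
    fn = score_fn or mask_overlap_score
    ids = [s.sample_id for s in dataset]
    if len(set(ids)) != len(ids):
        raise ValueError("sample IDs must be unique")
    n = len(dataset)
    score = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            score[i, j] = score[j, i] = fn(dataset[i], dataset[j], taxonomy)
    return SimilarityTable(ids=ids, score=score, easy_fraction=easy_fraction)


def sample_sources(
    table: SimilarityTable,
    target_id: str,
    n_sources: int,
    hard_fraction: float = 0.8,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw mixing sources for a target, oversampling the hard set.

    Each source is drawn independently: with probability ``hard_fraction``
    uniformly from the target's hard set, otherwise uniformly from its easy
    set.  If the chosen set is empty the draw falls back to the other set
    with a warning.  Draws are reproducible under a seeded ``rng``.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if not (0 <= hard_fraction <= 1):
        raise ValueError(f"hard_fraction must be in [0, 1], got {hard_fraction}")
    rng = rng if rng is not None else np.random.default_rng()
    easy, hard = table.easy[target_id], table.hard[target_id]
    if not easy and not hard:
        raise ValueError(f"target {target_id!r} has no candidates")
    out: list[str] = []
    for _ in range(n_sources):
        pool = hard if rng.random() < hard_fraction else easy
        if not pool:
            other = "easy" if pool is hard else "hard"
            logger.warning(
                "target %s: requested set empty, falling back to %s set", target_id, other
            )
            pool = easy if pool is hard else hard
        out.append(pool[rng.integers(len(pool))])
    return out
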