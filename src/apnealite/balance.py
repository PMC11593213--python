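"""Dataset splitting, SMOTE class balancing, and flip augmentation.

The pipeline order is fixed by construction: the data are first split
8:1:1 into train/validation/test, then SMOTE brings the apnea class of
the *training* part up to parity with the normal class, then flipping
doubles the balanced training set.  Validation and test sets pass
through untouched, so the per-class equality and exact doubling of the
training counts are structural invariants.

SMOTE (synthetic minority oversampling) draws a random minority segment
``a``, one of its k nearest minority neighbors ``b`` (Euclidean distance
on the raw segment vectors), and emits the convex combination
``a + u * (b - a)`` with ``u ~ Uniform(0, 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .preprocess import APNEA, NORMAL, SegmentSet

__all__ = [
    "SplitSpec",
    "SmoteConfig",
    "split_indices",
    "split",
    "smote_oversample",
    "balance_to_parity",
    "flip_augment",
    "balance_training_set",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios (normalized), seed, stratification flag."""

    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        total = sum(self.ratios)
        object.__setattr__(self, "ratios", tuple(r / total for r in self.ratios))


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _allot(n: int, ratios: Tuple[float, float, float]) -> Tuple[int, int, int]:
    """Largest-remainder rounding of n into three integer parts."""
    raw = [n * r for r in ratios]
    base = [int(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(3), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return tuple(base)  # type: ignore[return-value]


def split_indices(labels: np.ndarray, spec: SplitSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic, optionally stratified index partition.

    With stratification each class is allotted to the three parts by
    largest-remainder rounding, so class proportions per part deviate by
    at most one segment from the overall ratios.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("cannot split an empty set")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    parts: list[list[np.ndarray]] = [[], [], []]
    groups = [np.flatnonzero(labels == c) for c in np.unique(labels)] if spec.stratify else [np.arange(n)]
    for idx in groups:
        idx = rng.permutation(idx)
        n_tr, n_va, n_te = _allot(len(idx), spec.ratios)
        parts[0].append(idx[:n_tr])
        parts[1].append(idx[n_tr : n_tr + n_va])
        parts[2].append(idx[n_tr + n_va :])
    return tuple(np.sort(np.concatenate(p)) for p in parts)  # type: ignore[return-value]


def split(data: SegmentSet, spec: SplitSpec = SplitSpec()) -> Tuple[SegmentSet, SegmentSet, SegmentSet]:
    """Disjoint, exhaustive train/val/test partition of a segment set."""
    tr, va, te = split_indices(data.labels, spec)
    return data.subset(tr), data.subset(va), data.subset(te)


def smote_oversample(
    minority: np.ndarray, n_new: int, cfg: SmoteConfig = SmoteConfig()
) -> np.ndarray:
    """Synthesize ``n_new`` minority rows by convex neighbor interpolation."""
    minority = np.asarray(minority, dtype=np.float32)
    if minority.ndim != 2:
        raise ValueError("minority must be a 2-D segment matrix")
    if minority.shape[0] < cfg.k_neighbors + 1:
        raise ValueError(
            f"SMOTE needs at least k+1 = {cfg.k_neighbors + 1} minority rows, "
            f"got {minority.shape[0]}"
        )
    if n_new == 0:
        return np.empty((0, minority.shape[1]), np.float32)
    # k+1 neighbors because each point is its own nearest neighbor
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(minority)
    neighbor_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    a_idx = rng.integers(0, minority.shape[0], size=n_new)
    b_pick = rng.integers(0, cfg.k_neighbors, size=n_new)
    b_idx = neighbor_idx[a_idx, b_pick]
    u = rng.random(n_new, dtype=np.float32)[:, None]
    a = minority[a_idx]
    return a + u * (minority[b_idx] - a)


def balance_to_parity(train: SegmentSet, cfg: SmoteConfig = SmoteConfig()) -> SegmentSet:
    """Oversample the apnea class of a training set to parity with normal.

    Originals are preserved; synthetic rows are appended with
    ``smote:`` provenance ids.  A no-op (with a warning) when apnea is
    not the minority class.
    """
    n_apnea, n_normal = train.n_apnea, train.n_normal
    if n_apnea >= n_normal:
        if n_apnea > n_normal:
            warnings.warn("apnea is not the minority class; skipping SMOTE")
        return train
    n_new = n_normal - n_apnea
    synth = smote_oversample(train.segments[train.labels == APNEA], n_new, cfg)
    extra = SegmentSet(
        segments=synth,
        labels=np.full(n_new, APNEA, np.int8),
        fs=train.fs,
        modality=train.modality,
        window_seconds=train.window_seconds,
        source_ids=[f"smote:{i:06d}" for i in range(n_new)],
    )
    return SegmentSet.concatenate([train, extra])


def flip_augment(train: SegmentSet, mode: Literal["time", "amplitude"] = "time") -> SegmentSet:
    """Double a training set by adding flipped copies of every segment.

    ``time`` reverses each segment; ``amplitude`` negates it.  Labels
    are preserved and flipped rows carry ``flip:`` provenance ids.
    """
    if len(train) == 0:
        raise ValueError("cannot augment an empty set")
    flipped = train.segments[:, ::-1] if mode == "time" else -train.segments
    extra = SegmentSet(
        segments=np.ascontiguousarray(flipped),
        labels=train.labels.copy(),
        fs=train.fs,
        modality=train.modality,
        window_seconds=train.window_seconds,
        source_ids=[f"flip:{s}" for s in train.source_ids],
    )
    return SegmentSet.concatenate([train, extra])


def balance_training_set(
    train: SegmentSet,
    smote_cfg: SmoteConfig = SmoteConfig(),
    flip_mode: Literal["time", "amplitude"] = "time",
) -> SegmentSet:
    """SMOTE to class parity, then flip augmentation (training data only)."""
    return flip_augment(balance_to_parity(train, smote_cfg), mode=flip_mode)
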