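"""Segmentation of annotated ECG/SpO2 recordings into labeled 12-s windows.

Two annotation conventions are supported, mirroring the two public
apnea corpora this pipeline targets:

*Minute-based* — one apnea/normal label per minute of recording; the
label describes apneic activity at the start of the minute, so the
first 12 s of each annotated minute become one segment and the rest of
the minute is discarded.

*Event-based* — apneic activities are given as (onset, duration)
intervals together with a sleep-onset time.  The recording is cut into
consecutive non-overlapping 12-s windows from sleep onset; a window is
labeled apnea when it contains at least 10 s of apneic activity
(apnea is clinically defined by a breathing cessation of >= 10 s),
otherwise normal.

Segments can then be resampled to a common classifier input length.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Literal, Optional, Sequence

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "APNEA",
    "NORMAL",
    "WINDOW_SECONDS",
    "APNEA_MIN_OVERLAP_S",
    "EventAnnotation",
    "Recording",
    "SegmentSet",
    "segment_minute_scheme",
    "segment_event_scheme",
    "resample",
    "resample_set",
    "save_segments",
    "load_segments",
]

# Label encoding used throughout the package: apnea is the positive class.
APNEA: int = 1
NORMAL: int = 0

WINDOW_SECONDS: float = 12.0
# minimum apneic overlap for a window to be labeled apnea
APNEA_MIN_OVERLAP_S: float = 10.0


@dataclass(frozen=True)
class EventAnnotation:
    """One apneic activity interval, in seconds from recording start."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class Recording:
    """A single-channel physiological recording with apnea annotations.

    Exactly one annotation style must be present: ``minute_labels`` (one
    apnea/normal label per minute) or ``events`` (interval annotations
    plus ``sleep_onset``).
    """

    samples: np.ndarray
    fs: float
    modality: Literal["ecg", "spo2"]
    minute_labels: Optional[np.ndarray] = None
    events: Optional[List[EventAnnotation]] = None
    sleep_onset: float = 0.0
    record_id: str = "rec"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")
        if (self.minute_labels is None) == (self.events is None):
            raise ValueError("exactly one of minute_labels / events must be set")
        if self.minute_labels is not None:
            self.minute_labels = np.asarray(self.minute_labels, dtype=np.int8)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SegmentSet:
    """Fixed-length labeled segments cut from one or more recordings.

    ``source_ids`` records per-row provenance (recording and window, and
    later any oversampling/augmentation lineage), which downstream code
    uses to verify that only training data is ever synthesized.
    """

    segments: np.ndarray  # (n, L) float32
    labels: np.ndarray  # (n,) int8, APNEA/NORMAL
    fs: float
    modality: str
    window_seconds: float = WINDOW_SECONDS
    source_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float32)
        if self.segments.ndim != 2:
            self.segments = self.segments.reshape(len(self.labels), -1)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.segments.shape[0] != self.labels.shape[0]:
            raise ValueError("segments and labels disagree in length")
        if not self.source_ids:
            self.source_ids = [f"seg{i:06d}" for i in range(len(self.labels))]
        if len(self.source_ids) != len(self.labels):
            raise ValueError("source_ids and labels disagree in length")

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def n_apnea(self) -> int:
        return int((self.labels == APNEA).sum())

    @property
    def n_normal(self) -> int:
        return int((self.labels == NORMAL).sum())

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(
            segments=self.segments[idx],
            labels=self.labels[idx],
            fs=self.fs,
            modality=self.modality,
            window_seconds=self.window_seconds,
            source_ids=[self.source_ids[i] for i in idx],
        )

    @staticmethod
    def concatenate(parts: Sequence["SegmentSet"]) -> "SegmentSet":
        first = parts[0]
        return SegmentSet(
            segments=np.vstack([p.segments for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            fs=first.fs,
            modality=first.modality,
            window_seconds=first.window_seconds,
            source_ids=[s for p in parts for s in p.source_ids],
        )


def segment_minute_scheme(rec: Recording) -> SegmentSet:
    """One 12-s segment per annotated minute (minute-based convention).

    Segment *i* covers samples ``[60*i*fs, 60*i*fs + 12*fs)`` and takes
    minute *i*'s label; trailing partial minutes are dropped.
    """
    if rec.minute_labels is None:
        raise ValueError("recording carries no minute labels")
    fs = rec.fs
    seg_len = int(round(WINDOW_SECONDS * fs))
    n_minutes = min(len(rec.minute_labels), int(rec.samples.size // (60 * fs)))
    if n_minutes == 0:
        warnings.warn(f"{rec.record_id}: recording shorter than one minute; no segments")
        return SegmentSet(
            segments=np.empty((0, seg_len), np.float32),
            labels=np.empty(0, np.int8),
            fs=fs,
            modality=rec.modality,
            source_ids=[],
        )
    rows = [
        rec.samples[int(60 * i * fs) : int(60 * i * fs) + seg_len] for i in range(n_minutes)
    ]
    return SegmentSet(
        segments=np.stack(rows),
        labels=rec.minute_labels[:n_minutes],
        fs=fs,
        modality=rec.modality,
        source_ids=[f"{rec.record_id}:min{i:04d}" for i in range(n_minutes)],
    )


def _union_overlap(events: Sequence[EventAnnotation], t0: float, t1: float) -> float:
    """Total seconds of [t0, t1) covered by the union of the events."""
    ivs = sorted(
        (max(e.onset, t0), min(e.end, t1)) for e in events if e.onset < t1 and e.end > t0
    )
    total, cur_a, cur_b = 0.0, None, None
    for a, b in ivs:
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


def _max_single_overlap(events: Sequence[EventAnnotation], t0: float, t1: float) -> float:
    best = 0.0
    for e in events:
        best = max(best, max(0.0, min(e.end, t1) - max(e.onset, t0)))
    return best


def segment_event_scheme(
    rec: Recording, overlap_mode: Literal["union", "single"] = "union"
) -> SegmentSet:
    """Consecutive 12-s windows from sleep onset, labeled by apneic overlap.

    A window ``[t, t+12)`` is apnea when its apneic overlap is at least
    10 s; ``overlap_mode`` selects whether overlap aggregates the union
    of all events (default) or only the single longest event.
    """
    if rec.events is None:
        raise ValueError("recording carries no event annotations")
    fs = rec.fs
    seg_len = int(round(WINDOW_SECONDS * fs))
    events = []
    for e in rec.events:
        if e.end > rec.duration:
            warnings.warn(
                f"{rec.record_id}: event at {e.onset:.1f}s extends past recording end; clipped"
            )
            if e.onset >= rec.duration:
                continue
            e = EventAnnotation(e.onset, rec.duration - e.onset)
        events.append(e)

    overlap = _union_overlap if overlap_mode == "union" else _max_single_overlap
    n_windows = int(math.floor((rec.duration - rec.sleep_onset) / WINDOW_SECONDS))
    rows, labels, ids = [], [], []
    for w in range(max(n_windows, 0)):
        t0 = rec.sleep_onset + w * WINDOW_SECONDS
        start = int(round(t0 * fs))
        rows.append(rec.samples[start : start + seg_len])
        lab = APNEA if overlap(events, t0, t0 + WINDOW_SECONDS) >= APNEA_MIN_OVERLAP_S else NORMAL
        labels.append(lab)
        ids.append(f"{rec.record_id}:win{w:05d}")
    if not rows:
        return SegmentSet(
            segments=np.empty((0, seg_len), np.float32),
            labels=np.empty(0, np.int8),
            fs=fs,
            modality=rec.modality,
            source_ids=[],
        )
    return SegmentSet(
        segments=np.stack(rows),
        labels=np.array(labels, np.int8),
        fs=fs,
        modality=rec.modality,
        source_ids=ids,
    )


def resample(
    seg: np.ndarray, n_target: int, method: Literal["poly", "linear"] = "poly"
) -> np.ndarray:
    """Resample one segment row to ``n_target`` samples.

    ``poly`` uses polyphase filtering (shape-preserving for band-limited
    signals); ``linear`` is plain linear interpolation.  Either way a
    constant input stays constant and an already-matching length returns
    the row unchanged.
    """
    if n_target < 2:
        raise ValueError(f"n_target must be >= 2, got {n_target}")
    seg = np.asarray(seg, dtype=np.float32)
    n = seg.shape[-1]
    if n == n_target:
        return seg.copy()
    if method == "linear":
        x_old = np.linspace(0.0, 1.0, n)
        x_new = np.linspace(0.0, 1.0, n_target)
        return np.interp(x_new, x_old, seg).astype(np.float32)
    g = math.gcd(n_target, n)
    # line-extrapolated padding avoids zero-padding droop at segment edges
    out = resample_poly(seg.astype(np.float64), n_target // g, n // g, padtype="line")
    return out.astype(np.float32)


def resample_set(
    segset: SegmentSet, n_target: int, method: Literal["poly", "linear"] = "poly"
) -> SegmentSet:
    """Resample every row of a segment set to a common target length."""
    if len(segset) == 0:
        return replace_segments(segset, np.empty((0, n_target), np.float32))
    rows = np.stack([resample(r, n_target, method) for r in segset.segments])
    return replace_segments(segset, rows)


def replace_segments(segset: SegmentSet, segments: np.ndarray) -> SegmentSet:
    # effective rate follows the new row length over the fixed window
    return SegmentSet(
        segments=segments,
        labels=segset.labels.copy(),
        fs=segments.shape[1] / segset.window_seconds,
        modality=segset.modality,
        window_seconds=segset.window_seconds,
        source_ids=list(segset.source_ids),
    )


# ---------------------------------------------------------------------------
# Segment store: one CSV matrix + JSON sidecar


def save_segments(segset: SegmentSet, path: str | Path) -> None:
    """Write segments as ``<path>.csv`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    np.savetxt(path.with_suffix(".csv"), segset.segments, delimiter=",", fmt="%.6g")
    meta = {
        "fs": segset.fs,
        "modality": segset.modality,
        "window_seconds": segset.window_seconds,
        "labels": segset.labels.tolist(),
        "source_ids": segset.source_ids,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_segments(path: str | Path) -> SegmentSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    segments = np.loadtxt(path.with_suffix(".csv"), delimiter=",", ndmin=2, dtype=np.float32)
    return SegmentSet(
        segments=segments,
        labels=np.array(meta["labels"], np.int8),
        fs=meta["fs"],
        modality=meta["modality"],
        window_seconds=meta["window_seconds"],
        source_ids=meta["source_ids"],
    )
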