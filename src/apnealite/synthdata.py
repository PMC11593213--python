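"""Synthetic ECG/SpO2 recordings with apnea events and both annotation schemes.

The generator emulates the physiological structure an apnea classifier
learns from, at desk scale:

* apneic events of >= 10 s (apnea is defined by a breathing cessation of
  at least 10 s), plus optional sub-10-s activities that must be labeled
  normal by the segmentation rule;
* oxygen desaturations of >= 4 % below baseline, starting a circulation
  lag after each event onset, with exponential resaturation;
* apnea-linked heart-rate modulation in the ECG — RR intervals lengthen
  during events and rebound briefly afterwards — on top of a fixed
  P-QRS-T beat template.

It is deliberately not a physiological simulator: morphology pathology,
movement artifacts and oximeter-specific noise are out of scope.  Output
recordings can be written to a plain-text on-disk format under either
annotation scheme and read back by :mod:`apnealite.preprocess`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Sequence, Tuple

import numpy as np

from .preprocess import (
    APNEA,
    APNEA_MIN_OVERLAP_S,
    NORMAL,
    EventAnnotation,
    Recording,
    _union_overlap,
)

__all__ = [
    "SynthConfig",
    "generate_events",
    "synth_ecg",
    "synth_spo2",
    "make_recording_pair",
    "write_dataset",
    "read_record",
    "read_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the study conditions.

    Rates are per hour, durations and lags in seconds, SpO2 values in
    percent, heart rate in beats per minute.  ``apnea_brady_taper`` is
    the fractional RR-interval lengthening during an event.
    """

    duration: float = 3600.0
    fs_ecg: float = 100.0
    fs_spo2: float = 8.0
    event_rate: float = 30.0
    event_duration: Tuple[float, float] = (10.0, 60.0)
    sub10_rate: float = 4.0
    sub10_duration: Tuple[float, float] = (3.0, 9.0)
    spo2_baseline: float = 97.0
    desat_depth: float = 4.0
    desat_lag: float = 6.0
    hr_baseline: float = 75.0
    apnea_brady_taper: float = 0.20
    noise_sd_ecg: float = 0.05
    noise_sd_spo2: float = 0.15
    quantize_spo2: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.event_rate < 0 or self.sub10_rate < 0:
            raise ValueError("event rates must be non-negative")
        lo, hi = self.event_duration
        if not (0 < lo <= hi):
            raise ValueError("event_duration range must be positive and ordered")
        if not (85.0 <= self.spo2_baseline <= 100.0):
            raise ValueError("spo2_baseline must lie in [85, 100]")
        if self.desat_depth < 4.0:
            raise ValueError("desat_depth below the 4% desaturation criterion")
        if self.hr_baseline <= 0:
            raise ValueError("hr_baseline must be positive")


MIN_EVENT_GAP_S = 12.0


def generate_events(cfg: SynthConfig, rng: np.random.Generator | None = None) -> List[EventAnnotation]:
    """Draw a non-overlapping, sorted apneic-activity schedule.

    Event counts follow the configured per-hour rates; durations are
    uniform in their ranges.  Inter-event gaps are at least 12 s (one
    analysis window) and are otherwise allotted randomly; an explicit
    error is raised when rate and duration cannot fit the recording.
    """
    rng = rng or np.random.Generator(np.random.PCG64(cfg.seed))
    hours = cfg.duration / 3600.0
    n_main = int(round(cfg.event_rate * hours))
    n_sub = int(round(cfg.sub10_rate * hours))
    durations = np.concatenate([
        rng.uniform(*cfg.event_duration, size=n_main),
        rng.uniform(*cfg.sub10_duration, size=n_sub),
    ])
    rng.shuffle(durations)
    n = durations.size
    if n == 0:
        return []
    free = cfg.duration - durations.sum() - MIN_EVENT_GAP_S * (n + 1)
    if free < 0:
        raise ValueError(
            f"cannot place {n} events totaling {durations.sum():.0f}s with "
            f"{MIN_EVENT_GAP_S}s gaps in a {cfg.duration:.0f}s recording"
        )
    gaps = MIN_EVENT_GAP_S + rng.dirichlet(np.ones(n + 1)) * free
    events, t = [], 0.0
    for gap, dur in zip(gaps, durations):
        t += gap
        events.append(EventAnnotation(onset=float(t), duration=float(dur)))
        t += dur
    return events


def _rr_factor(t: float, events: Sequence[EventAnnotation], taper: float) -> float:
    """RR lengthening during events, shortening rebound for 5 s after."""
    for e in events:
        if e.onset <= t < e.end:
            return 1.0 + taper
        if e.end <= t < e.end + 5.0:
            return 1.0 - 0.5 * taper
    return 1.0


def _pqrst_template(fs: float) -> Tuple[np.ndarray, int]:
    """One beat as a sum of Gaussian waves, centered on the R peak."""
    t = np.arange(-0.30, 0.45, 1.0 / fs)
    waves = [  # (center s, width s, amplitude)
        (-0.20, 0.030, 0.15),   # P
        (-0.030, 0.012, -0.10), # Q
        (0.0, 0.015, 1.00),     # R
        (0.030, 0.012, -0.20),  # S
        (0.25, 0.060, 0.30),    # T
    ]
    tpl = np.zeros_like(t)
    for c, w, a in waves:
        tpl += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return tpl.astype(np.float32), int(round(0.30 * fs))


def synth_ecg(
    events: Sequence[EventAnnotation], cfg: SynthConfig, record_id: str = "rec",
    rng: np.random.Generator | None = None,
) -> Recording:
    """Template beat train with apnea-linked RR modulation plus noise."""
    rng = rng or np.random.Generator(np.random.PCG64(cfg.seed + 1))
    fs = cfg.fs_ecg
    n = int(round(cfg.duration * fs))
    sig = np.zeros(n, np.float32)
    tpl, r_offset = _pqrst_template(fs)
    base_rr = 60.0 / cfg.hr_baseline
    t = 0.0
    while t < cfg.duration:
        start = int(round(t * fs)) - r_offset
        lo, hi = max(start, 0), min(start + tpl.size, n)
        if hi > lo:
            sig[lo:hi] += tpl[lo - start : hi - start]
        t += base_rr * _rr_factor(t, events, cfg.apnea_brady_taper)
    if cfg.noise_sd_ecg > 0:
        sig += rng.normal(0.0, cfg.noise_sd_ecg, n).astype(np.float32)
    return Recording(samples=sig, fs=fs, modality="ecg", events=list(events),
                     record_id=record_id)


def synth_spo2(
    events: Sequence[EventAnnotation], cfg: SynthConfig, record_id: str = "rec",
    rng: np.random.Generator | None = None,
) -> Recording:
    """Baseline saturation with a desaturation dip per apneic activity.

    The dip starts ``desat_lag`` after event onset, ramps linearly to
    its nadir at event end, then recovers exponentially (tau = 10 s).
    Nadir depth is ``desat_depth`` for full (>= 10 s) events and scales
    down proportionally for shorter activities.  Values are clipped to
    [0, 100] and optionally quantized to 1 % steps.
    """
    rng = rng or np.random.Generator(np.random.PCG64(cfg.seed + 2))
    fs = cfg.fs_spo2
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs
    sig = np.full(n, cfg.spo2_baseline, np.float32)
    tau = 10.0
    for e in events:
        depth = cfg.desat_depth * min(1.0, e.duration / APNEA_MIN_OVERLAP_S)
        t_start = e.onset + cfg.desat_lag
        t_nadir = max(e.end, t_start + 2.0)
        ramp = (t >= t_start) & (t < t_nadir)
        sig[ramp] -= depth * (t[ramp] - t_start) / (t_nadir - t_start)
        rec_mask = t >= t_nadir
        sig[rec_mask] -= depth * np.exp(-(t[rec_mask] - t_nadir) / tau)
    if cfg.noise_sd_spo2 > 0:
        sig += rng.normal(0.0, cfg.noise_sd_spo2, n).astype(np.float32)
    if cfg.quantize_spo2:
        sig = np.round(sig)
    sig = np.clip(sig, 0.0, 100.0)
    return Recording(samples=sig.astype(np.float32), fs=fs, modality="spo2",
                     events=list(events), record_id=record_id)


def make_recording_pair(
    cfg: SynthConfig, record_id: str = "rec"
) -> Tuple[Recording, Recording, List[EventAnnotation]]:
    """Paired ECG and SpO2 recordings driven by one event schedule."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    events = generate_events(cfg, rng)
    ecg = synth_ecg(events, cfg, record_id, rng)
    spo2 = synth_spo2(events, cfg, record_id, rng)
    return ecg, spo2, events


# ---------------------------------------------------------------------------
# Plain-text dataset store
#
#   <id>_<modality>.sig.csv   one sample per line
#   <id>_<modality>.hea.json  {record_id, modality, fs, n_samples, sleep_onset}
#   <id>.events.csv           onset_s,duration_s          (event scheme)
#   <id>.minutes.csv          one 0/1 label per minute    (minute scheme)
#   manifest.json             record ids, modalities, scheme


def _minute_labels_from_events(
    events: Sequence[EventAnnotation], duration: float
) -> np.ndarray:
    """Label each full minute by its first 12 s under the overlap rule."""
    n_minutes = int(duration // 60)
    labels = np.empty(n_minutes, np.int8)
    for i in range(n_minutes):
        t0 = 60.0 * i
        ov = _union_overlap(events, t0, t0 + 12.0)
        labels[i] = APNEA if ov >= APNEA_MIN_OVERLAP_S else NORMAL
    return labels


def write_dataset(
    recordings: Sequence[Recording],
    scheme: Literal["minute", "event"],
    out_dir: str | Path,
) -> dict:
    """Write recordings plus annotations; returns the manifest dict.

    Under the minute scheme, per-minute labels are derived from each
    recording's events by applying the >= 10 s overlap rule to the first
    12 s of every complete minute.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"scheme": scheme, "records": []}
    seen_annotations = set()
    for rec in recordings:
        stem = f"{rec.record_id}_{rec.modality}"
        np.savetxt(out / f"{stem}.sig.csv", rec.samples, fmt="%.7g")
        header = {
            "record_id": rec.record_id,
            "modality": rec.modality,
            "fs": rec.fs,
            "n_samples": int(rec.samples.size),
            "sleep_onset": rec.sleep_onset,
        }
        (out / f"{stem}.hea.json").write_text(json.dumps(header))
        if rec.record_id not in seen_annotations:
            if rec.events is None:
                raise ValueError("write_dataset expects event-annotated recordings")
            if scheme == "event":
                lines = ["onset_s,duration_s"] + [
                    f"{e.onset:.6f},{e.duration:.6f}" for e in rec.events
                ]
                (out / f"{rec.record_id}.events.csv").write_text("\n".join(lines) + "\n")
            else:
                labels = _minute_labels_from_events(rec.events, rec.duration)
                (out / f"{rec.record_id}.minutes.csv").write_text(
                    "\n".join(str(int(v)) for v in labels) + "\n"
                )
            seen_annotations.add(rec.record_id)
        manifest["records"].append({"record_id": rec.record_id, "modality": rec.modality})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_record(
    data_dir: str | Path, record_id: str, modality: str, scheme: Literal["minute", "event"]
) -> Recording:
    """Read one recording (and its annotations) from a dataset directory."""
    data_dir = Path(data_dir)
    stem = f"{record_id}_{modality}"
    header = json.loads((data_dir / f"{stem}.hea.json").read_text())
    samples = np.loadtxt(data_dir / f"{stem}.sig.csv", dtype=np.float32)
    kwargs: dict = {}
    if scheme == "event":
        events = []
        lines = (data_dir / f"{record_id}.events.csv").read_text().strip().splitlines()
        for line in lines[1:]:
            onset, dur = map(float, line.split(","))
            events.append(EventAnnotation(onset, dur))
        kwargs["events"] = events
    else:
        labels = np.loadtxt(data_dir / f"{record_id}.minutes.csv", dtype=np.int8, ndmin=1)
        kwargs["minute_labels"] = labels
    return Recording(
        samples=samples,
        fs=header["fs"],
        modality=header["modality"],
        sleep_onset=header["sleep_onset"],
        record_id=record_id,
        **kwargs,
    )


def read_dataset(data_dir: str | Path) -> List[Recording]:
    """Read every recording listed in a dataset manifest."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    return [
        read_record(data_dir, entry["record_id"], entry["modality"], manifest["scheme"])
        for entry in manifest["records"]
    ]
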