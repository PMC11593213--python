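"""Classification metrics, end-to-end pipeline, and the command line.

Apnea is the positive class throughout.  Metrics with a zero denominator
(e.g. precision when nothing is predicted apneic) are reported as NaN
with a warning — a silent zero would corrupt model comparisons.

``run_pipeline`` chains the full study: synthesize annotated recordings,
segment them under an annotation scheme, split 8:1:1, SMOTE + flip the
training part only, build and train the requested model (pretraining
and fusing branches for the fusion variants), and evaluate on the
held-out test split.  Every stage is driven by explicit seeds recorded
in the output manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import click
import numpy as np
import yaml

from . import __version__
from .archspec import (
    PAPER_MODEL_IDS,
    ModelSpec,
    make_paper_fusion,
    make_paper_spec,
    spec_from_yaml,
)
from .balance import SmoteConfig, SplitSpec, flip_augment, smote_oversample, split_indices
from .complexity import EnergyModel, analyze, format_report_table
from .netbuild import TrainConfig, build, fuse, save_weights, train
from .preprocess import (
    APNEA,
    NORMAL,
    SegmentSet,
    load_segments,
    resample_set,
    save_segments,
    segment_event_scheme,
    segment_minute_scheme,
)
from .synthdata import SynthConfig, make_recording_pair, read_dataset, write_dataset

log = logging.getLogger("apnealite")

ALL_MODEL_IDS = PAPER_MODEL_IDS + ("sc_fusion", "dsc_fusion")


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix metrics with apnea as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def compute_metrics(y_true, y_pred) -> Metrics:
    """Accuracy, precision, recall, F1 and specificity from hard labels.

    Labels may be the package's integer encoding (1 = apnea) or the
    strings "apnea"/"normal".
    """
    def encode(y):
        arr = np.asarray(y)
        if arr.dtype.kind in "UO":
            return np.array([APNEA if str(v) == "apnea" else NORMAL for v in arr])
        return arr.astype(int)

    yt, yp = encode(y_true), encode(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if yt.size == 0:
        raise ValueError("cannot compute metrics on empty label lists")
    tp = int(((yt == APNEA) & (yp == APNEA)).sum())
    fp = int(((yt == NORMAL) & (yp == APNEA)).sum())
    fn = int(((yt == APNEA) & (yp == NORMAL)).sum())
    tn = int(((yt == NORMAL) & (yp == NORMAL)).sum())
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f1 = (
        _safe_ratio(2 * precision * recall, precision + recall, "f1")
        if not (np.isnan(precision) or np.isnan(recall))
        else float("nan")
    )
    return Metrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / yt.size,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end synthetic run."""

    model_id: str = "dsc_fusion"
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_recordings: int = 6
    scheme: str = "event"
    split: SplitSpec = field(default_factory=SplitSpec)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    flip_mode: str = "time"
    ecg_target_len: int = 1200
    spo2_target_len: int = 128
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.model_id not in ALL_MODEL_IDS:
            raise ValueError(f"model_id must be one of {ALL_MODEL_IDS}")

    def reseed(self, seed: int) -> "PipelineConfig":
        """Derive all stage seeds from one master seed."""
        return dataclasses.replace(
            self,
            seed=seed,
            synth=dataclasses.replace(self.synth, seed=seed),
            split=dataclasses.replace(self.split, seed=seed + 1),
            smote=dataclasses.replace(self.smote, seed=seed + 2),
            train=dataclasses.replace(self.train, seed=seed + 3),
        )

    @staticmethod
    def from_yaml(text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = dict(raw)
        for key, cls in (
            ("synth", SynthConfig),
            ("split", SplitSpec),
            ("smote", SmoteConfig),
            ("train", TrainConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                if key == "split" and "ratios" in sub:
                    sub["ratios"] = tuple(sub["ratios"])
                if key == "synth":
                    for rng_key in ("event_duration", "sub10_duration"):
                        if rng_key in sub:
                            sub[rng_key] = tuple(sub[rng_key])
                kwargs[key] = cls(**sub)
        return PipelineConfig(**kwargs)


def _spec_for(model_id: str, spo2_len: int) -> ModelSpec:
    if model_id.endswith("fusion"):
        return make_paper_fusion(model_id.split("_")[0], spo2_input_length=spo2_len)
    return make_paper_spec(model_id, spo2_input_length=spo2_len)


def synthesize_paired_segments(
    cfg: PipelineConfig,
) -> Tuple[SegmentSet, SegmentSet]:
    """Generate recordings and return aligned ECG / SpO2 segment sets.

    Both modalities are cut at the same window boundaries from the same
    event schedules, so row *i* of the two sets shares its window and
    label; ECG rows are resampled (if needed) to the ECG input length,
    SpO2 rows to the SpO2 input length.
    """
    ecg_sets, spo2_sets = [], []
    for r in range(cfg.n_recordings):
        rec_cfg = dataclasses.replace(cfg.synth, seed=cfg.synth.seed + 101 * r)
        ecg, spo2, _ = make_recording_pair(rec_cfg, record_id=f"syn{r:03d}")
        e_set = segment_event_scheme(ecg)
        s_set = segment_event_scheme(spo2)
        n = min(len(e_set), len(s_set))
        ecg_sets.append(e_set.subset(np.arange(n)))
        spo2_sets.append(s_set.subset(np.arange(n)))
    ecg_all = SegmentSet.concatenate(ecg_sets)
    spo2_all = SegmentSet.concatenate(spo2_sets)
    if not np.array_equal(ecg_all.labels, spo2_all.labels):
        raise RuntimeError("paired modalities disagree on window labels")
    ecg_all = resample_set(ecg_all, cfg.ecg_target_len)
    spo2_all = resample_set(spo2_all, cfg.spo2_target_len)
    return ecg_all, spo2_all


def _balance_pair(
    ecg: SegmentSet, spo2: SegmentSet, smote: SmoteConfig, flip_mode: str
) -> Tuple[SegmentSet, SegmentSet]:
    """SMOTE + flip a paired training set, keeping rows aligned.

    SMOTE interpolates the concatenated [ecg | spo2] vectors so each
    synthetic pair is internally consistent; flipping is applied per
    modality.
    """
    joint = np.hstack([ecg.segments, spo2.segments])
    labels = ecg.labels
    n_new = int((labels == NORMAL).sum() - (labels == APNEA).sum())
    w = ecg.segments.shape[1]
    if n_new > 0:
        synth = smote_oversample(joint[labels == APNEA], n_new, smote)
        ids = [f"smote:{i:06d}" for i in range(n_new)]
        ecg = SegmentSet.concatenate([
            ecg,
            SegmentSet(synth[:, :w], np.full(n_new, APNEA, np.int8), ecg.fs,
                       ecg.modality, ecg.window_seconds, list(ids)),
        ])
        spo2 = SegmentSet.concatenate([
            spo2,
            SegmentSet(synth[:, w:], np.full(n_new, APNEA, np.int8), spo2.fs,
                       spo2.modality, spo2.window_seconds, list(ids)),
        ])
    return flip_augment(ecg, flip_mode), flip_augment(spo2, flip_mode)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute synth -> segment -> split -> balance -> train -> evaluate."""
    log.info("pipeline: model=%s seed=%d", cfg.model_id, cfg.seed)
    ecg_all, spo2_all = synthesize_paired_segments(cfg)
    if len(ecg_all) == 0:
        raise ValueError("pipeline produced no segments; increase duration or recordings")

    idx_tr, idx_va, idx_te = split_indices(ecg_all.labels, cfg.split)
    if len(idx_te) == 0 or len(idx_va) == 0:
        raise ValueError("validation/test split is empty; not enough segments")
    parts = {
        name: (ecg_all.subset(i), spo2_all.subset(i))
        for name, i in (("train", idx_tr), ("val", idx_va), ("test", idx_te))
    }
    tr_e, tr_s = _balance_pair(*parts["train"], cfg.smote, cfg.flip_mode)
    va_e, va_s = parts["val"]
    te_e, te_s = parts["test"]

    fusion = cfg.model_id.endswith("fusion")
    spec = _spec_for(cfg.model_id, cfg.spo2_target_len)
    histories: dict = {}
    if fusion:
        kind = cfg.model_id.split("_")[0]
        branch_models = []
        for branch_id, tr_set, va_set in (
            (f"{kind}_ecg", tr_e, va_e),
            (f"{kind}_spo2", tr_s, va_s),
        ):
            m = build(_spec_for(branch_id, cfg.spo2_target_len), seed=cfg.train.seed)
            m, hist = train(m, tr_set.segments, tr_set.labels,
                            va_set.segments, va_set.labels, cfg.train)
            histories[branch_id] = dataclasses.asdict(hist)
            branch_models.append(m)
        model = fuse(*branch_models, freeze_branches=True, seed=cfg.train.seed,
                     name=cfg.model_id)
        model, hist = train(
            model,
            (tr_e.segments, tr_s.segments), tr_e.labels,
            (va_e.segments, va_s.segments), va_e.labels,
            cfg.train,
        )
        histories[cfg.model_id] = dataclasses.asdict(hist)
        y_pred = model.predict((te_e.segments, te_s.segments))
    else:
        tr_set, va_set, te_set = (
            (tr_e, va_e, te_e) if cfg.model_id.endswith("ecg") else (tr_s, va_s, te_s)
        )
        model = build(spec, seed=cfg.train.seed)
        model, hist = train(model, tr_set.segments, tr_set.labels,
                            va_set.segments, va_set.labels, cfg.train)
        histories[cfg.model_id] = dataclasses.asdict(hist)
        y_pred = model.predict(te_set.segments)

    metrics = compute_metrics(te_e.labels, y_pred)
    report = analyze(spec)
    manifest = {
        "version": __version__,
        "model_id": cfg.model_id,
        "seed": cfg.seed,
        "stage_seeds": {
            "synth": cfg.synth.seed,
            "split": cfg.split.seed,
            "smote": cfg.smote.seed,
            "train": cfg.train.seed,
        },
        "n_segments": {
            "train_raw": len(parts["train"][0]),
            "train_balanced": len(tr_e),
            "val": len(va_e),
            "test": len(te_e),
        },
    }
    result = {
        "metrics": metrics.to_dict(),
        "complexity": dataclasses.asdict(report),
        "history": histories,
        "manifest": manifest,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(result, indent=1))
        save_weights(model, str(out / "weights.npz"))
    return result


# ---------------------------------------------------------------------------
# CLI (thin wrappers; exit code 2 = validation error, 1 = runtime failure)


def _setup_logging(level: str) -> None:
    logging.basicConfig(stream=sys.stderr, level=level.upper(),
                        format="%(levelname)s %(name)s: %(message)s")


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """Lightweight separable-convolution apnea-detection toolkit."""
    _setup_logging(log_level)


def _fail(exc: Exception) -> None:
    code = 2 if isinstance(exc, (ValueError, FileNotFoundError)) else 1
    click.echo(f"error: {exc}", err=True)
    sys.exit(code)


@cli.command()
@click.option("--duration", default=3600.0, show_default=True, help="Seconds per recording.")
@click.option("--n-recordings", default=2, show_default=True)
@click.option("--scheme", type=click.Choice(["minute", "event"]), default="event")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def synth(duration: float, n_recordings: int, scheme: str, seed: int, out: str) -> None:
    """Generate a synthetic paired ECG/SpO2 dataset on disk."""
    try:
        recs = []
        for r in range(n_recordings):
            cfg = SynthConfig(duration=duration, seed=seed + 101 * r)
            ecg, spo2, _ = make_recording_pair(cfg, record_id=f"syn{r:03d}")
            recs += [ecg, spo2]
        write_dataset(recs, scheme, out)  # type: ignore[arg-type]
        click.echo(f"wrote {len(recs)} recordings to {out}")
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


@cli.command()
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--scheme", type=click.Choice(["minute", "event"]), default="event")
@click.option("--modality", type=click.Choice(["ecg", "spo2"]), required=True)
@click.option("--target-len", default=None, type=int, help="Resample rows to this length.")
@click.option("--out", required=True, type=click.Path())
def segment(data_dir: str, scheme: str, modality: str, target_len: Optional[int], out: str) -> None:
    """Cut recordings from a dataset directory into labeled segments."""
    try:
        recs = [r for r in read_dataset(data_dir) if r.modality == modality]
        seg_fn = segment_event_scheme if scheme == "event" else segment_minute_scheme
        segset = SegmentSet.concatenate([seg_fn(r) for r in recs])
        if target_len:
            segset = resample_set(segset, target_len)
        save_segments(segset, out)
        click.echo(f"{len(segset)} segments ({segset.n_apnea} apnea) -> {out}.csv/.json")
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


@cli.command()
@click.option("--segments", "store", required=True, type=click.Path())
@click.option("--ratios", default="8:1:1", show_default=True)
@click.option("--smote-k", default=5, show_default=True)
@click.option("--flip-mode", type=click.Choice(["time", "amplitude"]), default="time")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def balance(store: str, ratios: str, smote_k: int, flip_mode: str, seed: int, out: str) -> None:
    """Split a segment store and balance+augment the training part."""
    from .balance import balance_training_set, split as split_set

    try:
        data = load_segments(store)
        r = tuple(float(x) for x in ratios.split(":"))
        tr, va, te = split_set(data, SplitSpec(ratios=r, seed=seed))  # type: ignore[arg-type]
        tr = balance_training_set(tr, SmoteConfig(k_neighbors=smote_k, seed=seed),
                                  flip_mode)  # type: ignore[arg-type]
        for name, part in (("train", tr), ("val", va), ("test", te)):
            save_segments(part, f"{out}_{name}")
        click.echo(f"train {len(tr)} (balanced), val {len(va)}, test {len(te)}")
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


@cli.command()
@click.option("--model", "model_id", required=True,
              help="Model id (e.g. dsc_fusion) or path to a spec YAML.")
@click.option("--e-mac", default=0.39, show_default=True, help="pJ per 16-bit MAC.")
@click.option("--e-add", default=0.020, show_default=True, help="pJ per 16-bit addition.")
@click.option("--out", default=None, type=click.Path(), help="Write the report as JSON.")
def analyze_cmd(model_id: str, e_mac: float, e_add: float, out: Optional[str]) -> None:
    """Analytic parameter/operation/energy report for a model."""
    try:
        if model_id in ALL_MODEL_IDS:
            spec = _spec_for(model_id, 128)
        else:
            spec = spec_from_yaml(Path(model_id).read_text())
        report = analyze(spec, EnergyModel(e_mac_pj=e_mac, e_add_pj=e_add))
        click.echo(format_report_table([report]))
        if out:
            Path(out).write_text(json.dumps(dataclasses.asdict(report), indent=1))
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


cli.add_command(analyze_cmd, name="analyze")


@cli.command(name="train")
@click.option("--model", "model_id", type=click.Choice(list(PAPER_MODEL_IDS)), required=True)
@click.option("--train-segments", required=True, type=click.Path())
@click.option("--val-segments", required=True, type=click.Path())
@click.option("--epochs", default=20, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def train_cmd(model_id: str, train_segments: str, val_segments: str,
              epochs: int, seed: int, out: str) -> None:
    """Train a single-signal model on stored segment sets."""
    try:
        tr = load_segments(train_segments)
        va = load_segments(val_segments)
        spec = make_paper_spec(model_id, spo2_input_length=tr.segments.shape[1]
                               if model_id.endswith("spo2") else 128)
        model = build(spec, seed=seed)
        cfg = TrainConfig(max_epochs=epochs, seed=seed)
        model, hist = train(model, tr.segments, tr.labels, va.segments, va.labels, cfg)
        save_weights(model, out)
        click.echo(f"best val acc {max(hist.val_accuracy):.3f} -> {out}")
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


@cli.command()
@click.option("--y-true", required=True, type=click.Path(exists=True),
              help="JSON list of true labels.")
@click.option("--y-pred", required=True, type=click.Path(exists=True),
              help="JSON list of predicted labels.")
def evaluate(y_true: str, y_pred: str) -> None:
    """Confusion-matrix metrics from two JSON label lists."""
    try:
        m = compute_metrics(json.loads(Path(y_true).read_text()),
                            json.loads(Path(y_pred).read_text()))
        click.echo(json.dumps(m.to_dict(), indent=1))
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


@cli.command()
@click.option("--config", "config_path", default=None, type=click.Path(exists=True),
              help="Pipeline config YAML (defaults used when omitted).")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", default=None, type=click.Path())
def run(config_path: Optional[str], seed: int, out: Optional[str]) -> None:
    """End-to-end synthetic pipeline run."""
    try:
        cfg = (
            PipelineConfig.from_yaml(Path(config_path).read_text())
            if config_path
            else PipelineConfig()
        )
        cfg = cfg.reseed(seed)
        if out:
            cfg.out_dir = out
        result = run_pipeline(cfg)
        click.echo(json.dumps(result["metrics"], indent=1))
    except Exception as exc:  # noqa: BLE001
        _fail(exc)


if __name__ == "__main__":
    cli()
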