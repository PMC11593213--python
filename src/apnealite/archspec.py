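"""Declarative descriptions of the 1-D convolutional apnea classifiers.

A :class:`ModelSpec` is a plain, serializable record of an architecture:
an ordered list of :class:`LayerSpec` entries plus the input geometry.
Everything downstream — analytic parameter/operation counting
(:mod:`apnealite.complexity`) and the executable networks
(:mod:`apnealite.netbuild`) — is computed from this one object, so the
two routes can be checked against each other.

Six concrete models are provided: single-signal ECG and SpO2 classifiers
in both a spatial-convolution (SC) and a depthwise-separable-convolution
(DSC) variant, and the two fusion models obtained by concatenating the
flatten-layer features of an ECG and an SpO2 branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional, Sequence

import yaml

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "ShapeTrace",
    "PAPER_MODEL_IDS",
    "make_paper_spec",
    "infer_shapes",
    "fuse_specs",
    "spec_to_yaml",
    "spec_from_yaml",
    "batchnorm",
    "conv",
    "maxpool",
    "flatten",
    "dropout",
    "dense",
]

LayerKind = Literal[
    "batchnorm", "conv_sc", "conv_dsc", "maxpool", "flatten", "dropout", "dense"
]
Padding = Literal["same", "valid"]
Activation = Literal["relu", "softmax", "none"]

CONV_KINDS = ("conv_sc", "conv_dsc")


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a 1-D network.

    Only the fields relevant to ``kind`` are meaningful; the rest stay
    ``None``.  ``filters`` is the output-channel count (written c' in the
    separable-convolution literature), ``kernel_size`` the kernel extent
    in samples.
    """

    kind: LayerKind
    kernel_size: Optional[int] = None
    filters: Optional[int] = None
    stride: int = 1
    padding: Padding = "same"
    pool_size: Optional[int] = None
    rate: Optional[float] = None
    units: Optional[int] = None
    activation: Activation = "none"

    def __post_init__(self) -> None:
        if self.kind in CONV_KINDS:
            if self.kernel_size is None or self.kernel_size < 1:
                raise ValueError(f"conv layer needs kernel_size >= 1, got {self.kernel_size}")
            if self.filters is None or self.filters < 1:
                raise ValueError(f"conv layer needs filters >= 1, got {self.filters}")
            if self.stride < 1:
                raise ValueError(f"stride must be >= 1, got {self.stride}")
        elif self.kind == "maxpool":
            if self.pool_size is None or self.pool_size < 1:
                raise ValueError(f"maxpool needs pool_size >= 1, got {self.pool_size}")
        elif self.kind == "dropout":
            if self.rate is None or not (0.0 <= self.rate < 1.0):
                raise ValueError(f"dropout rate must lie in [0, 1), got {self.rate}")
        elif self.kind == "dense":
            if self.units is None or self.units < 1:
                raise ValueError(f"dense needs units >= 1, got {self.units}")


# Convenience constructors; keep the specs below readable.

def batchnorm() -> LayerSpec:
    return LayerSpec(kind="batchnorm")


def conv(
    kind: str,
    kernel_size: int,
    filters: int,
    stride: int = 1,
    padding: Padding = "same",
    activation: Activation = "relu",
) -> LayerSpec:
    if kind not in CONV_KINDS:
        raise ValueError(f"conv kind must be one of {CONV_KINDS}, got {kind!r}")
    return LayerSpec(
        kind=kind,  # type: ignore[arg-type]
        kernel_size=kernel_size,
        filters=filters,
        stride=stride,
        padding=padding,
        activation=activation,
    )


def maxpool(pool_size: int = 2) -> LayerSpec:
    return LayerSpec(kind="maxpool", pool_size=pool_size)


def flatten() -> LayerSpec:
    return LayerSpec(kind="flatten")


def dropout(rate: float) -> LayerSpec:
    return LayerSpec(kind="dropout", rate=rate)


def dense(units: int, activation: Activation = "softmax") -> LayerSpec:
    return LayerSpec(kind="dense", units=units, activation=activation)


@dataclass(frozen=True)
class ModelSpec:
    """An architecture: input geometry plus an ordered layer list.

    Fusion models carry two truncated branch specs in ``fusion_branches``
    and use ``layers`` for the shared head (dropout + dense); their
    effective input is the pair of branch inputs.
    """

    name: str
    input_length: int
    input_channels: int = 1
    layers: tuple[LayerSpec, ...] = ()
    fusion_branches: Optional[tuple["ModelSpec", "ModelSpec"]] = None

    def __post_init__(self) -> None:
        if self.input_length < 1 or self.input_channels < 1:
            raise ValueError("input_length and input_channels must be >= 1")
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.fusion_branches is not None:
            if len(self.fusion_branches) != 2:
                raise ValueError("fusion_branches must hold exactly two branch specs")

    @property
    def is_fusion(self) -> bool:
        return self.fusion_branches is not None

    def iter_layers(self) -> Iterator[LayerSpec]:
        return iter(self.layers)


@dataclass(frozen=True)
class ShapeTrace:
    """Per-layer (length, channels) output shapes plus the flatten width."""

    shapes: tuple[tuple[int, int], ...]
    flatten_width: int


PAPER_MODEL_IDS = ("sc_ecg", "dsc_ecg", "sc_spo2", "dsc_spo2")

# Input lengths in samples for 12-s segments fed to the classifiers.  The
# ECG length (1200 = 12 s at 100 Hz) is used directly; the SpO2 length is
# a model choice (128 by default; 96 selects the shorter downsampling
# target) — see docs/methods.md for the reconciliation.
ECG_INPUT_LENGTH = 1200
SPO2_INPUT_LENGTH = 128


def _single_model_layers(
    conv_kind: str, convs: Sequence[tuple[int, int, int]]
) -> tuple[LayerSpec, ...]:
    """Batchnorm, three conv+pool stages, flatten, dropout, softmax head."""
    layers: list[LayerSpec] = [batchnorm()]
    for k, c_out, stride in convs:
        layers.append(conv(conv_kind, kernel_size=k, filters=c_out, stride=stride))
        layers.append(maxpool(2))
    layers += [flatten(), dropout(0.25), dense(2, activation="softmax")]
    return tuple(layers)


def make_paper_spec(model_id: str, spo2_input_length: int = SPO2_INPUT_LENGTH) -> ModelSpec:
    """Construct one of the four single-signal reference architectures.

    ``model_id`` is one of ``sc_ecg``, ``dsc_ecg``, ``sc_spo2``,
    ``dsc_spo2``.  ECG models take 1200-sample single-channel segments;
    their three convolutions are (k=100, c'=3, stride 2), (k=10, c'=50)
    and (k=30, c'=30), each followed by a pool of 2.  SpO2 models take
    ``spo2_input_length`` samples with convolutions (k=25, c'=6),
    (k=10, c'=50) and (k=15, c'=30), all stride 1.
    """
    if model_id not in PAPER_MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {PAPER_MODEL_IDS}")
    conv_kind = "conv_sc" if model_id.startswith("sc") else "conv_dsc"
    if model_id.endswith("ecg"):
        convs = [(100, 3, 2), (10, 50, 1), (30, 30, 1)]
        input_length = ECG_INPUT_LENGTH
    else:
        convs = [(25, 6, 1), (10, 50, 1), (15, 30, 1)]
        input_length = spo2_input_length
    return ModelSpec(
        name=model_id,
        input_length=input_length,
        input_channels=1,
        layers=_single_model_layers(conv_kind, convs),
    )


def _conv_out_length(length: int, layer: LayerSpec) -> int:
    if layer.padding == "same":
        return math.ceil(length / layer.stride)
    if layer.kernel_size > length:  # type: ignore[operator]
        raise ValueError(
            f"valid-padding kernel {layer.kernel_size} exceeds input length {length}"
        )
    return (length - layer.kernel_size) // layer.stride + 1  # type: ignore[operator]


def infer_shapes(spec: ModelSpec) -> ShapeTrace:
    """Propagate (length, channels) through a non-fusion spec.

    Same-padding convolutions give ``ceil(L / stride)`` outputs; pooling
    with size = stride = p gives ``floor((L - p)/p) + 1``.  Raises if any
    intermediate shape collapses to zero.
    """
    if spec.is_fusion:
        raise ValueError("infer_shapes applies to single-branch specs; fusion widths "
                         "are the sum of branch flatten widths")
    length, channels = spec.input_length, spec.input_channels
    shapes: list[tuple[int, int]] = []
    flatten_width = 0
    for layer in spec.layers:
        if layer.kind in CONV_KINDS:
            length = _conv_out_length(length, layer)
            channels = layer.filters  # type: ignore[assignment]
        elif layer.kind == "maxpool":
            p = layer.pool_size  # type: ignore[assignment]
            length = (length - p) // p + 1
        elif layer.kind == "flatten":
            flatten_width = length * channels
            length, channels = flatten_width, 1
        elif layer.kind == "dense":
            length, channels = layer.units, 1  # type: ignore[assignment]
        # batchnorm / dropout leave shapes unchanged
        if length < 1 or channels < 1:
            raise ValueError(f"layer {layer.kind} collapses the shape to ({length}, {channels})")
        shapes.append((length, channels))
    return ShapeTrace(shapes=tuple(shapes), flatten_width=flatten_width)


def _truncate_at_flatten(spec: ModelSpec) -> ModelSpec:
    for i, layer in enumerate(spec.layers):
        if layer.kind == "flatten":
            return replace(spec, layers=spec.layers[: i + 1])
    raise ValueError(f"branch {spec.name!r} has no flatten layer; cannot fuse")


def fuse_specs(
    branch_a: ModelSpec,
    branch_b: ModelSpec,
    name: Optional[str] = None,
    dropout_rate: float = 0.25,
) -> ModelSpec:
    """Fuse two single-signal specs at their flatten layers.

    Each branch is truncated after its flatten layer (the branch dense
    heads are discarded), the flattened features are concatenated, and a
    fresh dropout + two-unit softmax head is appended.
    """
    trunk_a = _truncate_at_flatten(branch_a)
    trunk_b = _truncate_at_flatten(branch_b)
    head = (dropout(dropout_rate), dense(2, activation="softmax"))
    return ModelSpec(
        name=name or f"{branch_a.name}+{branch_b.name}",
        input_length=branch_a.input_length,
        input_channels=branch_a.input_channels,
        layers=head,
        fusion_branches=(trunk_a, trunk_b),
    )


def fusion_width(spec: ModelSpec) -> int:
    """Concatenated flatten width of a fusion spec."""
    if not spec.is_fusion:
        raise ValueError("not a fusion spec")
    a, b = spec.fusion_branches  # type: ignore[misc]
    return infer_shapes(a).flatten_width + infer_shapes(b).flatten_width


def make_paper_fusion(conv_kind: str = "dsc", spo2_input_length: int = SPO2_INPUT_LENGTH) -> ModelSpec:
    """The SC or DSC fusion model (``conv_kind`` in {"sc", "dsc"})."""
    if conv_kind not in ("sc", "dsc"):
        raise ValueError("conv_kind must be 'sc' or 'dsc'")
    ecg = make_paper_spec(f"{conv_kind}_ecg")
    spo2 = make_paper_spec(f"{conv_kind}_spo2", spo2_input_length=spo2_input_length)
    return fuse_specs(ecg, spo2, name=f"{conv_kind}_fusion")


# ---------------------------------------------------------------------------
# YAML round-trip.  One document per model; fusion specs nest their branches.

_LAYER_FIELDS = ("kind", "kernel_size", "filters", "stride", "padding",
                 "pool_size", "rate", "units", "activation")


def _layer_to_dict(layer: LayerSpec) -> dict:
    d = {}
    for f in _LAYER_FIELDS:
        v = getattr(layer, f)
        if v is not None and not (f == "stride" and v == 1 and layer.kind not in CONV_KINDS):
            d[f] = v
    return d


def _spec_to_dict(spec: ModelSpec) -> dict:
    d: dict = {
        "name": spec.name,
        "input_length": spec.input_length,
        "input_channels": spec.input_channels,
        "layers": [_layer_to_dict(l) for l in spec.layers],
    }
    if spec.is_fusion:
        d["fusion_branches"] = [_spec_to_dict(b) for b in spec.fusion_branches]  # type: ignore[union-attr]
    return d


def _spec_from_dict(d: dict) -> ModelSpec:
    branches = d.get("fusion_branches")
    return ModelSpec(
        name=d["name"],
        input_length=d["input_length"],
        input_channels=d.get("input_channels", 1),
        layers=tuple(LayerSpec(**ld) for ld in d["layers"]),
        fusion_branches=tuple(_spec_from_dict(b) for b in branches) if branches else None,
    )


def spec_to_yaml(spec: ModelSpec) -> str:
    return yaml.safe_dump(_spec_to_dict(spec), sort_keys=False)


def spec_from_yaml(text: str) -> ModelSpec:
    return _spec_from_dict(yaml.safe_load(text))
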