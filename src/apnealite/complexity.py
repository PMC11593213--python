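"""Analytic complexity and energy accounting for convolutional specs.

Two layers of accounting live here.

*Closed-form convolution costs.*  For a spatial (standard) convolution
with kernel extent ``k``, ``c`` input channels, ``c'`` output channels
and spatial extent ``m`` per dimension (stride 1, output size equal to
input size), the weight and operation counts are

    W_SC = k^d * c * c'          O_SC = m^d * k^d * c * c'

with ``d`` the dimensionality (1 for time series, 2 for images).  A
depthwise-separable convolution (per-channel depthwise pass followed by
a pointwise 1x1 channel mix) costs

    W_DSC = k^d * c + c * c'     O_DSC = m^d * k^d * c + m^d * c * c'

so the reduction factor of separable over standard convolution is

    R = W_DSC / W_SC = O_DSC / O_SC = 1/c' + 1/k^d

(bias-free, identical ``m``).  ``reduction_factor`` returns this as an
exact rational.

*Whole-model accounting.*  ``count_params`` walks a
:class:`~apnealite.archspec.ModelSpec` with the layer conventions of
mainstream deep-learning frameworks (batchnorm 4 parameters per channel,
2 of them non-trainable running statistics; standard conv and dense with
bias; separable conv with bias on the pointwise stage only).  These
conventions reproduce the published totals of all six reference apnea
models exactly.  ``count_ops`` counts per-inference multiplications and
additions under a documented convention of this package (see
docs/methods.md); ``energy_estimate`` turns multiplication/addition
counts into microjoules per inference under a 16-bit MAC energy model.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Tuple

from .archspec import (
    CONV_KINDS,
    ModelSpec,
    infer_shapes,
)

__all__ = [
    "ConvCostInputs",
    "EnergyModel",
    "ComplexityReport",
    "ParamCount",
    "sc_cost",
    "dsc_cost",
    "reduction_factor",
    "count_params",
    "count_ops",
    "energy_estimate",
    "efficiency_ratio",
    "analyze",
    "REFERENCE_OP_COUNTS",
    "format_report_table",
]


@dataclass(frozen=True)
class ConvCostInputs:
    """Geometry of one convolution for the closed-form cost formulas."""

    k: int
    c: int
    c_out: int
    m: int
    dims: int = 1

    def __post_init__(self) -> None:
        for name in ("k", "c", "c_out", "m"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.dims not in (1, 2):
            raise ValueError(f"dims must be 1 or 2, got {self.dims}")


@dataclass(frozen=True)
class EnergyModel:
    """Per-operation energies for 16-bit arithmetic, in picojoules.

    Defaults: 0.39 pJ per multiply-accumulate and 0.020 pJ (20 fJ) per
    standalone addition, representative of 28 nm FD-SOI logic.
    """

    e_mac_pj: float = 0.39
    e_add_pj: float = 0.020

    def __post_init__(self) -> None:
        if self.e_mac_pj <= 0 or self.e_add_pj <= 0:
            raise ValueError("per-operation energies must be strictly positive")


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int


@dataclass(frozen=True)
class ComplexityReport:
    """Parameters, per-inference operation counts, and energy for one model."""

    name: str
    total_params: int
    trainable_params: int
    non_trainable_params: int
    multiplications: int
    additions: int
    energy_uJ: float

    def __post_init__(self) -> None:
        if self.total_params != self.trainable_params + self.non_trainable_params:
            raise ValueError("total_params must equal trainable + non_trainable")
        if min(self.total_params, self.multiplications, self.additions) < 0:
            raise ValueError("counts must be non-negative")
        if self.energy_uJ < 0:
            raise ValueError("energy must be non-negative")


def sc_cost(inp: ConvCostInputs) -> Tuple[int, int]:
    """Weights and operations of a standard (spatial) convolution."""
    kd = inp.k**inp.dims
    md = inp.m**inp.dims
    weights = kd * inp.c * inp.c_out
    operations = md * kd * inp.c * inp.c_out
    return weights, operations


def dsc_cost(inp: ConvCostInputs) -> Tuple[int, int]:
    """Weights and operations of a depthwise-separable convolution."""
    kd = inp.k**inp.dims
    md = inp.m**inp.dims
    weights = kd * inp.c + inp.c * inp.c_out
    operations = md * kd * inp.c + md * inp.c * inp.c_out
    return weights, operations


def reduction_factor(k: int, c_out: int, dims: int = 1) -> Fraction:
    """Exact separable/standard cost ratio, 1/c' + 1/k^dims.

    Independent of the input-channel count and spatial extent; equals
    both the weight ratio and the operation ratio of ``dsc_cost`` over
    ``sc_cost``.
    """
    if k < 1 or c_out < 1:
        raise ValueError("k and c_out must be positive integers")
    if dims not in (1, 2):
        raise ValueError(f"dims must be 1 or 2, got {dims}")
    return Fraction(1, c_out) + Fraction(1, k**dims)


def _layer_params(kind: str, k: int, c_in: int, c_out: int) -> Tuple[int, int]:
    """(trainable, non_trainable) for one parametric layer."""
    if kind == "batchnorm":
        return 2 * c_in, 2 * c_in
    if kind == "conv_sc":
        return k * c_in * c_out + c_out, 0
    if kind == "conv_dsc":
        return k * c_in + c_in * c_out + c_out, 0
    if kind == "dense":
        return c_in * c_out + c_out, 0
    return 0, 0


def _walk_params(spec: ModelSpec) -> Tuple[int, int]:
    trace = infer_shapes(spec)
    trainable = non_trainable = 0
    length, channels = spec.input_length, spec.input_channels
    for layer, (out_len, out_ch) in zip(spec.layers, trace.shapes):
        if layer.kind == "batchnorm":
            t, n = _layer_params("batchnorm", 0, channels, channels)
        elif layer.kind in CONV_KINDS:
            t, n = _layer_params(layer.kind, layer.kernel_size, channels, layer.filters)
        elif layer.kind == "dense":
            t, n = _layer_params("dense", 0, length * channels, layer.units)
        else:
            t = n = 0
        trainable += t
        non_trainable += n
        length, channels = out_len, out_ch
    return trainable, non_trainable


def count_params(spec: ModelSpec) -> ParamCount:
    """Total/trainable/non-trainable parameter counts for a spec.

    Fusion specs count both truncated branches (dense heads already
    removed by ``fuse_specs``) plus the fresh head on the concatenated
    flatten width.
    """
    if spec.is_fusion:
        a, b = spec.fusion_branches  # type: ignore[misc]
        ta, na = _walk_params(a)
        tb, nb = _walk_params(b)
        width = infer_shapes(a).flatten_width + infer_shapes(b).flatten_width
        trainable, non_trainable = ta + tb, na + nb
        for layer in spec.layers:
            if layer.kind == "dense":
                t, n = _layer_params("dense", 0, width, layer.units)
                trainable += t
                non_trainable += n
                width = layer.units
    else:
        trainable, non_trainable = _walk_params(spec)
    return ParamCount(trainable + non_trainable, trainable, non_trainable)


def _walk_ops(spec: ModelSpec) -> Tuple[int, int]:
    trace = infer_shapes(spec)
    mults = adds = 0
    length, channels = spec.input_length, spec.input_channels
    for layer, (out_len, out_ch) in zip(spec.layers, trace.shapes):
        if layer.kind == "batchnorm":
            # one scale and one shift per input element
            mults += length * channels
            adds += length * channels
        elif layer.kind == "conv_sc":
            n = out_len * out_ch * layer.kernel_size * channels
            mults += n
            adds += n
        elif layer.kind == "conv_dsc":
            n = out_len * channels * layer.kernel_size + out_len * channels * out_ch
            mults += n
            adds += n
        elif layer.kind == "maxpool":
            # max selection approximated as one addition per comparison
            adds += out_len * out_ch * (layer.pool_size - 1)
        elif layer.kind == "dense":
            n_in = length * channels
            mults += n_in * layer.units
            adds += n_in * layer.units
        length, channels = out_len, out_ch
    return mults, adds


def count_ops(spec: ModelSpec) -> Tuple[int, int]:
    """Per-inference (multiplications, additions) under this package's convention.

    Per convolution output element the multiplications are ``k * c_in``
    (standard) or the depthwise/pointwise split (separable), with one
    accumulating addition per multiplication (bias folded into the
    accumulator); dense layers cost ``n_in * n_out`` of each; batchnorm
    one multiply and one add per input element; max-pooling
    ``pool_size - 1`` additions per output element; flatten and dropout
    are free.
    """
    if spec.is_fusion:
        a, b = spec.fusion_branches  # type: ignore[misc]
        ma, aa = _walk_ops(a)
        mb, ab = _walk_ops(b)
        mults, adds = ma + mb, aa + ab
        width = infer_shapes(a).flatten_width + infer_shapes(b).flatten_width
        for layer in spec.layers:
            if layer.kind == "dense":
                mults += width * layer.units
                adds += width * layer.units
                width = layer.units
        return mults, adds
    return _walk_ops(spec)


def energy_estimate(
    multiplications: int, additions: int, model: EnergyModel = EnergyModel()
) -> float:
    """Energy per inference in microjoules.

    Each multiplication is paired with one addition into a MAC costing
    ``e_mac``; additions in excess of the multiplications (pool
    selections and the like) cost ``e_add`` each.  Returned unrounded;
    round only for display.
    """
    if multiplications < 0 or additions < 0:
        raise ValueError("operation counts must be non-negative")
    surplus = max(0, additions - multiplications)
    picojoules = multiplications * model.e_mac_pj + surplus * model.e_add_pj
    return picojoules * 1e-6


def efficiency_ratio(energy_a_uJ: float, energy_b_uJ: float, decimals: int = 2) -> float:
    """Ratio of two per-inference energies after rounding each to 2 d.p.

    Published energy-efficiency factors are quoted as ratios of the
    tabulated (2-decimal) energies, so the rounding happens before the
    division; the result is rounded to ``decimals``.
    """
    a = round(energy_a_uJ, 2)
    b = round(energy_b_uJ, 2)
    if b == 0:
        raise ValueError("reference energy rounds to zero; ratio undefined")
    return round(a / b, decimals)


# Published per-inference multiplication/addition counts for the six
# reference apnea models.  The exact counting convention behind these
# totals is not recoverable (it differs from ``count_ops``; see
# docs/methods.md), so the energy accounting treats them as inputs.
REFERENCE_OP_COUNTS: dict[str, Tuple[int, int]] = {
    "sc_ecg": (6_534_116, 6_546_647),
    "dsc_ecg": (579_439, 580_311),
    "sc_spo2": (1_270_016, 1_272_876),
    "dsc_spo2": (103_866, 105_432),
    "sc_fusion": (7_809_352, 7_824_743),
    "dsc_fusion": (683_303, 684_721),
}


def analyze(
    spec: ModelSpec,
    energy_model: EnergyModel = EnergyModel(),
    op_counts: Tuple[int, int] | None = None,
) -> ComplexityReport:
    """Full complexity report for one spec.

    ``op_counts`` overrides the package's own operation counter, e.g. to
    evaluate the energy model on externally published counts.
    """
    params = count_params(spec)
    mults, adds = op_counts if op_counts is not None else count_ops(spec)
    return ComplexityReport(
        name=spec.name,
        total_params=params.total,
        trainable_params=params.trainable,
        non_trainable_params=params.non_trainable,
        multiplications=mults,
        additions=adds,
        energy_uJ=energy_estimate(mults, adds, energy_model),
    )


def format_report_table(reports: list[ComplexityReport]) -> str:
    """Fixed-width text table of complexity reports."""
    header = f"{'Model':<14}{'Parameters':>12}{'Mults':>14}{'Adds':>14}{'Energy (uJ)':>13}"
    lines = [header, "-" * len(header)]
    for r in reports:
        lines.append(
            f"{r.name:<14}{r.total_params:>12,}{r.multiplications:>14,}"
            f"{r.additions:>14,}{r.energy_uJ:>13.2f}"
        )
    return "\n".join(lines)
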