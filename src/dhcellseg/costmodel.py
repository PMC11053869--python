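"""Analytic cost model for heterogeneous dilated convolution layers.

A standard convolution layer producing a ``Dw x Dh`` output with ``N``
filters of shape ``K x K x C`` costs ``Dw*Dh*N*K*K*C`` multiply-accumulate
operations (MACs).  A heterogeneous layer keeps only a fraction ``P`` of the
``K x K`` kernels in each filter and replaces the rest with pointwise
``1 x 1`` kernels, so its cost is the sum of a large-kernel term scaled by
``P`` and a pointwise term; the resulting cost ratio relative to the standard
layer is ``P + (1 - P) / K**2``.  Dilation enlarges the kernel's spatial
extent to ``(K - 1)*r + 1`` per side without adding taps, so it never changes
any MAC count.

Counting convention: one MAC = one FLOP (no factor 2 for the add), biases
excluded, non-convolution layers (normalization, activation, pooling)
excluded.  Ratios are exact :class:`fractions.Fraction` values whenever the
inputs are rational.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Sequence

logger = logging.getLogger("dhcellseg")

__all__ = [
    "KernelGeometry",
    "LayerCost",
    "LayerDesc",
    "dilated_kernel_extent",
    "flops_standard",
    "flops_het",
    "flops_ratio",
    "count_model_flops",
    "as_fraction",
]


def as_fraction(p) -> Fraction:
    """Coerce ``p`` to an exact Fraction (floats via nearest small rational)."""
    if isinstance(p, Rational):
        return Fraction(p)
    if isinstance(p, float):
        return Fraction(p).limit_denominator(10**6)
    if isinstance(p, str):
        return Fraction(p)
    raise TypeError(f"cannot interpret {p!r} as a rational number")


def _check_positive_int(name: str, value) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return int(value)


def dilated_kernel_extent(base_size: int, dilation_rate: int) -> int:
    """Spatial extent of a dilated kernel: ``(base_size - 1)*rate + 1``.

    With rate 1 this is the base size itself (standard convolution is the
    degenerate case of dilation).
    """
    k = _check_positive_int("base_size", base_size)
    r = _check_positive_int("dilation_rate", dilation_rate)
    return (k - 1) * r + 1


@dataclass(frozen=True)
class KernelGeometry:
    """Geometry of one (possibly dilated) square convolution kernel."""

    base_size: int
    dilation_rate: int
    effective_size: int = field(init=False)

    def __post_init__(self):
        if self.base_size % 2 != 1:
            raise ValueError(f"base_size must be odd, got {self.base_size}")
        object.__setattr__(
            self,
            "effective_size",
            dilated_kernel_extent(self.base_size, self.dilation_rate),
        )


def flops_standard(
    out_w: int, out_h: int, n_filters: int, kernel_size: int, in_channels: int
) -> int:
    """MAC count of a standard convolution layer: ``Dw*Dh*N*K*K*C``."""
    dw = _check_positive_int("out_w", out_w)
    dh = _check_positive_int("out_h", out_h)
    n = _check_positive_int("n_filters", n_filters)
    k = _check_positive_int("kernel_size", kernel_size)
    c = _check_positive_int("in_channels", in_channels)
    return dw * dh * n * k * k * c


@dataclass(frozen=True)
class LayerCost:
    """MAC accounting for one heterogeneous layer versus its standard form."""

    standard_flops: int
    large_kernel_flops: int
    pointwise_flops: int
    het_flops: int
    ratio: Fraction

    def __post_init__(self):
        if self.het_flops != self.large_kernel_flops + self.pointwise_flops:
            raise ValueError("het_flops must equal large + pointwise flops")
        if not 0 < self.ratio <= 1:
            raise ValueError(f"ratio must lie in (0, 1], got {self.ratio}")


def flops_het(
    out_w: int,
    out_h: int,
    n_filters: int,
    kernel_size: int,
    in_channels: int,
    p_fraction,
) -> LayerCost:
    """MAC accounting of a heterogeneous layer with large-kernel fraction P.

    The large-kernel branch costs ``standard * P``; the pointwise branch
    costs ``Dw*Dh*C*(N - N*P)``.  Dilation of the large kernels adds no MACs
    (holes carry no weights), so the count is independent of the dilation
    rate.
    """
    p = as_fraction(p_fraction)
    if not 0 < p <= 1:
        raise ValueError(f"p_fraction must lie in (0, 1], got {p}")
    n = _check_positive_int("n_filters", n_filters)
    c = _check_positive_int("in_channels", in_channels)
    if (c * p).denominator != 1:
        raise ValueError(
            f"p_fraction={p} does not divide the {c} channels of a filter "
            "into whole kernels"
        )
    flc = flops_standard(out_w, out_h, n_filters, kernel_size, in_channels)
    flk = flc * p
    fl1 = out_w * out_h * (n * c - n * c * p)
    total = int(flk) + int(fl1)
    return LayerCost(
        standard_flops=flc,
        large_kernel_flops=int(flk),
        pointwise_flops=fl1,
        het_flops=total,
        ratio=Fraction(total, flc),
    )


def flops_ratio(p_fraction, kernel_size: int) -> Fraction:
    """Cost ratio heterogeneous/standard: ``P + (1 - P)/K**2``.

    Equals 1 exactly when P = 1 (the layer degenerates to a standard
    convolution); 1/3 for the P = 1/4, K = 3 configuration.
    """
    p = as_fraction(p_fraction)
    if not 0 < p <= 1:
        raise ValueError(f"p_fraction must lie in (0, 1], got {p}")
    k = _check_positive_int("kernel_size", kernel_size)
    return p + Fraction(1 - p, k * k)


# ---------------------------------------------------------------------------
# Whole-model accounting


@dataclass(frozen=True)
class LayerDesc:
    """Structural description of one layer for whole-model MAC accounting.

    ``kind`` is ``"conv"`` (standard, possibly dilated), ``"dhconv"``
    (heterogeneous) or ``"dense"`` (fully connected head, counted only on
    request); anything else is counted as zero with a warning.
    """

    name: str
    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel_size: int = 1
    out_w: int = 0
    out_h: int = 0
    stride: int = 1
    p_fraction: Fraction = Fraction(1)
    dilation_rate: int = 1
    in_features: int = 0
    out_features: int = 0

    def param_count(self) -> int:
        if self.kind == "conv":
            return self.out_channels * self.in_channels * self.kernel_size**2
        if self.kind == "dhconv":
            p = as_fraction(self.p_fraction)
            m_large = int(self.in_channels * p)
            return self.out_channels * (
                m_large * self.kernel_size**2 + (self.in_channels - m_large)
            )
        if self.kind == "dense":
            return self.in_features * self.out_features
        return 0


def layer_flops(layer: LayerDesc, include_dense: bool = False) -> int:
    """MACs of one described layer under the module's counting convention."""
    if layer.kind == "conv":
        return flops_standard(
            layer.out_w, layer.out_h, layer.out_channels, layer.kernel_size,
            layer.in_channels,
        )
    if layer.kind == "dhconv":
        return flops_het(
            layer.out_w, layer.out_h, layer.out_channels, layer.kernel_size,
            layer.in_channels, layer.p_fraction,
        ).het_flops
    if layer.kind == "dense":
        return layer.in_features * layer.out_features if include_dense else 0
    logger.warning("unknown layer kind %r (%s) counted as 0 MACs",
                   layer.kind, layer.name)
    return 0


def count_model_flops(
    layers: Iterable[LayerDesc], include_dense: bool = False
) -> tuple[list[tuple[str, int]], int]:
    """Per-layer and total MAC counts for a sequence of layer descriptions."""
    per_layer: list[tuple[str, int]] = []
    total = 0
    for layer in layers:
        f = layer_flops(layer, include_dense=include_dense)
        per_layer.append((layer.name, f))
        total += f
    return per_layer, total
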