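"""Dilated heterogeneous convolution (DHConv) in plain numpy.

One DHConv filter mixes two kinds of kernels over its ``M`` input channels:
``M*P`` dilated ``K x K`` kernels (dilation rate ``r``, enlarging the
receptive field to ``(K-1)*r + 1`` per side at no extra cost) and
``M*(1-P)`` pointwise ``1 x 1`` kernels.  The layer is evaluated as two
parallel branches summed: a dilated convolution restricted to the
large-kernel channel positions and a pointwise convolution on the rest.
Same-padding keeps both branches spatially aligned so the layer is a drop-in
replacement for a stride-preserving ``K x K`` convolution.

A dense "oracle" evaluation is also provided: every (filter, channel) kernel
is materialized as a dense ``K_D x K_D`` array (large kernels scattered onto
the dilation grid, pointwise kernels as a single centre tap) and convolved
the ordinary way.  It exists to cross-check the branch implementation and to
count, empirically, the structural multiply-accumulates of the layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .costmodel import as_fraction, dilated_kernel_extent

__all__ = [
    "DHConvSpec",
    "DHConvWeights",
    "FeatureMap",
    "build_layout",
    "init_weights",
    "apply_dhconv",
    "dense_oracle",
    "measure_receptive_field",
    "param_count",
]


@dataclass(frozen=True)
class FeatureMap:
    """Channels-first activation array with explicit spatial semantics."""

    values: np.ndarray  # (channels, height, width)

    def __post_init__(self):
        if np.asarray(self.values).ndim != 3:
            raise ValueError("FeatureMap expects a (channels, height, width) array")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class DHConvSpec:
    """Full parameterization of one DHConv layer.

    ``p_fraction`` (P) is the fraction of input channels per filter that
    keep a large K x K kernel; it must satisfy ``1/P`` integer and
    ``in_channels * P`` integer so kernels divide evenly.  ``layout``
    chooses which channels those are: ``shifted`` staggers the large-kernel
    channels across filters (channel c is large in filter f iff
    ``(c + f) % (1/P) == 0``) so every input channel is seen by some large
    kernel; ``leading`` puts them on the first ``M*P`` channels of every
    filter.
    """

    in_channels: int
    out_channels: int
    kernel_size: int
    dilation_rate: int = 1
    p_fraction: Fraction = Fraction(1)
    stride: int = 1
    layout: str = "shifted"
    use_bias: bool = True

    def __post_init__(self):
        for name in ("in_channels", "out_channels", "kernel_size",
                     "dilation_rate", "stride"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        p = as_fraction(self.p_fraction)
        object.__setattr__(self, "p_fraction", p)
        if not 0 < p <= 1:
            raise ValueError(f"p_fraction must lie in (0, 1], got {p}")
        if (1 / p).denominator != 1:
            raise ValueError(f"1/p_fraction must be an integer, got 1/{p}")
        if (self.in_channels * p).denominator != 1:
            raise ValueError(
                f"in_channels ({self.in_channels}) not divisible by "
                f"1/p_fraction ({1 / p})"
            )
        if self.layout not in ("shifted", "leading"):
            raise ValueError(f"layout must be 'shifted' or 'leading', got {self.layout!r}")

    @property
    def group(self) -> int:
        """1/P: number of channels sharing one large kernel slot."""
        return int(1 / self.p_fraction)

    @property
    def n_large(self) -> int:
        """Large kernels per filter, M*P."""
        return int(self.in_channels * self.p_fraction)

    @property
    def effective_kernel(self) -> int:
        """Dilated extent K_D = (K-1)*r + 1."""
        return dilated_kernel_extent(self.kernel_size, self.dilation_rate)

    @property
    def padding(self) -> int:
        """Same-padding of the dilated branch: r*(K-1)/2 per side."""
        return self.dilation_rate * (self.kernel_size - 1) // 2


def build_layout(spec: DHConvSpec) -> np.ndarray:
    """Boolean (out_channels, in_channels) mask; True marks a large kernel.

    Each filter (row) holds exactly ``M*P`` True entries.  Under the shifted
    layout every input channel is large in the same fraction P of filters
    whenever ``out_channels`` is a multiple of ``1/P``.
    """
    g = spec.group
    f = np.arange(spec.out_channels)[:, None]
    c = np.arange(spec.in_channels)[None, :]
    if spec.layout == "shifted":
        mask = (c + f) % g == 0
    else:  # leading
        mask = np.broadcast_to(c < spec.n_large,
                               (spec.out_channels, spec.in_channels)).copy()
    return mask


@dataclass
class DHConvWeights:
    """Weights of one DHConv layer.

    ``large`` is (N, M, K, K) with entries outside the layout's large-kernel
    positions held at zero; ``point`` is (N, M) with entries outside the
    pointwise positions held at zero; ``bias`` is one shared value per
    filter across both branches, or None.
    """

    large: np.ndarray
    point: np.ndarray
    bias: Optional[np.ndarray]
    layout: np.ndarray = field(repr=False)


def param_count(spec: DHConvSpec) -> int:
    """True number of learnable weights: N*(M*P*K^2 + M*(1-P)) (+N bias)."""
    n, m, k = spec.out_channels, spec.in_channels, spec.kernel_size
    count = n * (spec.n_large * k * k + (m - spec.n_large))
    if spec.use_bias:
        count += n
    return count


def init_weights(spec: DHConvSpec, seed: int = 0) -> DHConvWeights:
    """Fan-in-scaled normal init; fan-in counts each kernel's true footprint.

    A filter's fan-in is ``M*P*K^2 + M*(1-P)`` taps (9 vs 1 per channel for
    K=3), and every tap is drawn N(0, sqrt(2/fan_in)).  Bias starts at zero.
    """
    rng = np.random.default_rng(seed)
    layout = build_layout(spec)
    n, m, k = spec.out_channels, spec.in_channels, spec.kernel_size
    fan_in = spec.n_large * k * k + (m - spec.n_large)
    std = np.sqrt(2.0 / fan_in)
    large = rng.normal(0.0, std, size=(n, m, k, k))
    large *= layout[:, :, None, None]
    point = rng.normal(0.0, std, size=(n, m))
    point *= ~layout
    bias = np.zeros(n) if spec.use_bias else None
    return DHConvWeights(large=large, point=point, bias=bias, layout=layout)


def _as_chw(x) -> np.ndarray:
    if isinstance(x, FeatureMap):
        x = x.values
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected (channels, height, width) input, got shape {x.shape}")
    return x


def _dilated_windows(xp: np.ndarray, k: int, r: int) -> np.ndarray:
    """(C, H, W, K, K) strided view selecting the dilated tap grid."""
    kd = (k - 1) * r + 1
    win = sliding_window_view(xp, (kd, kd), axis=(1, 2))
    return win[..., ::r, ::r]


def apply_dhconv(x, weights: DHConvWeights, spec: DHConvSpec) -> np.ndarray:
    """Evaluate the layer as dilated branch + pointwise branch (+ bias).

    Stride-1 output spatial size equals the input's (same padding on the
    dilated branch, none needed on the pointwise branch); stride s keeps
    every s-th row/column.
    """
    x = _as_chw(x)
    if x.shape[0] != spec.in_channels:
        raise ValueError(
            f"input has {x.shape[0]} channels, spec expects {spec.in_channels}"
        )
    q = spec.padding
    xp = np.pad(x, ((0, 0), (q, q), (q, q)))
    win = _dilated_windows(xp, spec.kernel_size, spec.dilation_rate)
    y = np.einsum("nckl,chwkl->nhw", weights.large, win, optimize=True)
    y += np.tensordot(weights.point, x, axes=([1], [0]))
    if weights.bias is not None:
        y += weights.bias[:, None, None]
    if spec.stride > 1:
        y = y[:, ::spec.stride, ::spec.stride]
    return y


@dataclass(frozen=True)
class DenseOracleResult:
    values: np.ndarray
    mac_count: int


def materialize_dense_kernels(
    weights: DHConvWeights, spec: DHConvSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (N, M, K_D, K_D) kernels and their structural-support mask.

    Large kernels are scattered onto the dilation grid with zeros in the
    holes; pointwise kernels occupy the single centre tap.  The support mask
    marks positions that carry an actual weight (not a hole), so its sum
    gives the per-output-pixel MAC count of the layer.
    """
    n, m, k = spec.out_channels, spec.in_channels, spec.kernel_size
    kd, r = spec.effective_kernel, spec.dilation_rate
    dense = np.zeros((n, m, kd, kd))
    support = np.zeros((n, m, kd, kd), dtype=bool)
    centre = kd // 2
    lay = weights.layout
    dense[:, :, ::r, ::r] = weights.large
    support[:, :, ::r, ::r] = lay[:, :, None, None]
    dense[~lay, centre, centre] = weights.point[~lay]
    support[~lay, centre, centre] = True
    return dense, support


def dense_oracle(x, weights: DHConvWeights, spec: DHConvSpec) -> DenseOracleResult:
    """One ordinary dense convolution with the materialized kernels.

    Also reports the number of structural multiply-accumulates actually
    available in the dense kernels (support positions times output pixels),
    the empirical counterpart of the analytic cost model.
    """
    x = _as_chw(x)
    if x.shape[0] != spec.in_channels:
        raise ValueError(
            f"input has {x.shape[0]} channels, spec expects {spec.in_channels}"
        )
    dense, support = materialize_dense_kernels(weights, spec)
    kd = spec.effective_kernel
    q = spec.padding
    xp = np.pad(x, ((0, 0), (q, q), (q, q)))
    win = sliding_window_view(xp, (kd, kd), axis=(1, 2))
    y = np.einsum("nckl,chwkl->nhw", dense, win, optimize=True)
    if weights.bias is not None:
        y += weights.bias[:, None, None]
    if spec.stride > 1:
        y = y[:, ::spec.stride, ::spec.stride]
    out_pixels = y.shape[1] * y.shape[2]
    return DenseOracleResult(values=y, mac_count=int(support.sum()) * out_pixels)


def measure_receptive_field(spec: DHConvSpec) -> int:
    """Receptive-field side length measured by impulse probing.

    Feeds unit impulses at every input position of a minimal single-filter
    probe layer with all-ones structural weights and records which positions
    produce a nonzero response at the central output unit; returns the side
    of the bounding box of that footprint.  Equals ``(K-1)*r + 1``.
    """
    if spec.stride != 1:
        raise ValueError("receptive field probing requires stride 1")
    probe = replace(
        spec,
        in_channels=spec.group,
        out_channels=1,
        stride=1,
        use_bias=False,
    )
    w = init_weights(probe, seed=0)
    w.large = w.layout[:, :, None, None].astype(float).repeat(
        probe.kernel_size, 2).repeat(probe.kernel_size, 3)
    w.point = (~w.layout).astype(float)
    size = probe.effective_kernel + 2
    centre = size // 2
    hit_rows, hit_cols = [], []
    for i in range(size):
        for j in range(size):
            x = np.zeros((probe.in_channels, size, size))
            x[:, i, j] = 1.0
            y = apply_dhconv(x, w, probe)
            if y[0, centre, centre] != 0:
                hit_rows.append(i)
                hit_cols.append(j)
    side_r = max(hit_rows) - min(hit_rows) + 1
    side_c = max(hit_cols) - min(hit_cols) + 1
    assert side_r == side_c
    return side_r
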