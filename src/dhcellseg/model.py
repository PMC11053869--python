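"""Detector built on DHConv layers, backbone conversion, training drivers.

Two levels live here:

* **Structural conversion** — :func:`resnet50_conv_layers` enumerates the
  convolutions of a ResNet-50 backbone (stem, 3+4+6+3 bottleneck blocks,
  downsample projections) as cost-model layer descriptions, and
  :func:`convert_backbone` swaps every selector-matched 3x3 convolution for
  a DHConv of the policy's P and r, reporting per-layer parameter and MAC
  counts before/after.  This is pure accounting and needs no weights.

* **A trainable compact detector** — a fully convolutional network whose
  hidden 3x3 convolutions are DHConv layers (heterogeneous dilated kernels
  per the conversion policy), with a sigmoid foreground head.  Instances are
  extracted from the thresholded foreground map by connected components,
  scored by mean foreground probability.  Forward and backward passes are
  hand-written numpy; training is SGD with momentum, weight decay, and a
  step learning-rate schedule (initial 0.001, x0.1 every 10 epochs by
  default).  The head bias starts at -2 so an untrained network predicts
  background everywhere rather than noise.

The full two-stage Mask R-CNN scaffolding (FPN, RPN, RoIAlign) is not
re-implemented; the detector here is deliberately compact so that the
DHConv backbone, its cost behaviour, and end-to-end train/evaluate cycles
are exercised on a CPU in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import costmodel, dhconv
from .costmodel import LayerDesc, as_fraction
from .dhconv import DHConvSpec, DHConvWeights

logger = logging.getLogger("dhcellseg")

__all__ = [
    "ConversionPolicy",
    "TrainConfig",
    "DetectionResult",
    "ConfigurationError",
    "resnet50_conv_layers",
    "convert_backbone",
    "convert_layer",
    "TrainableDHConv",
    "MaskRDHCNN",
    "build_mask_rdhcnn",
    "train",
    "predict",
]


class ConfigurationError(ValueError):
    """A conversion policy cannot be applied to a layer."""


@dataclass(frozen=True)
class ConversionPolicy:
    """How to replace backbone convolutions with DHConv.

    Defaults follow the reference configuration: keep one of the four 3x3
    kernels per filter group (P = 1/4) and dilate the survivors at rate 2.
    The default selector matches every 3x3 convolution inside residual
    bottleneck blocks; the stem and 1x1 projections are never touched.
    Converted layers always keep the original channel counts and stride.
    """

    p_fraction: Fraction = Fraction(1, 4)
    dilation_rate: int = 2
    target_kernel_size: int = 3
    preserve_stride: bool = True

    def __post_init__(self):
        object.__setattr__(self, "p_fraction", as_fraction(self.p_fraction))
        if not 0 < self.p_fraction <= 1:
            raise ConfigurationError(
                f"p_fraction must lie in (0, 1], got {self.p_fraction}")
        if self.dilation_rate < 1:
            raise ConfigurationError(
                f"dilation_rate must be >= 1, got {self.dilation_rate}")

    def matches(self, layer: LayerDesc) -> bool:
        return (
            layer.kind == "conv"
            and layer.kernel_size == self.target_kernel_size
            and ".conv" in layer.name  # inside a residual block, not the stem
        )


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule: lr(epoch) = initial_lr * decay^(epoch // decay_every)."""

    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    momentum: float = 0.9
    weight_decay: float = 0.0005
    max_epochs: int = 50
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        return self.initial_lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass
class DetectionResult:
    """One detected instance: image-sized mask, tight box, score, label."""

    mask: np.ndarray          # boolean (H, W)
    box: tuple[float, float, float, float]  # (x, y, w, h), half-open
    score: float
    label: int = 1


# ---------------------------------------------------------------------------
# ResNet-50 structural description and conversion


def resnet50_conv_layers(input_size: int = 224) -> list[LayerDesc]:
    """All convolution layers of a ResNet-50 backbone with output dims.

    Stage layout 3+4+6+3 bottleneck blocks (each 1x1 -> 3x3 -> 1x1, plus a
    1x1 downsample projection on the first block of a stage); spatial size
    halves at the stem, the post-stem pool, and the first 3x3 of stages 2-4.
    """
    layers: list[LayerDesc] = []
    size = input_size // 2  # stem stride 2
    layers.append(LayerDesc(
        name="conv1", kind="conv", in_channels=3, out_channels=64,
        kernel_size=7, stride=2, out_w=size, out_h=size))
    size //= 2  # max-pool stride 2
    in_ch = 64
    stage_spec = [(3, 64), (4, 128), (6, 256), (3, 512)]
    for stage_idx, (n_blocks, mid) in enumerate(stage_spec, start=1):
        out_ch = mid * 4
        for block in range(n_blocks):
            stride = 2 if stage_idx > 1 and block == 0 else 1
            if stride == 2:
                size //= 2
            prefix = f"layer{stage_idx}.{block}"
            layers.append(LayerDesc(
                name=f"{prefix}.conv1", kind="conv", in_channels=in_ch,
                out_channels=mid, kernel_size=1, stride=1,
                out_w=size * stride, out_h=size * stride))
            layers.append(LayerDesc(
                name=f"{prefix}.conv2", kind="conv", in_channels=mid,
                out_channels=mid, kernel_size=3, stride=stride,
                out_w=size, out_h=size))
            layers.append(LayerDesc(
                name=f"{prefix}.conv3", kind="conv", in_channels=mid,
                out_channels=out_ch, kernel_size=1, stride=1,
                out_w=size, out_h=size))
            if block == 0:
                layers.append(LayerDesc(
                    name=f"{prefix}.downsample", kind="conv", in_channels=in_ch,
                    out_channels=out_ch, kernel_size=1, stride=stride,
                    out_w=size, out_h=size))
            in_ch = out_ch
    return layers


@dataclass
class ConversionRow:
    name: str
    params_before: int
    params_after: int
    flops_before: int
    flops_after: int


@dataclass
class ConversionReport:
    rows: list[ConversionRow] = field(default_factory=list)

    @property
    def n_converted(self) -> int:
        return len(self.rows)

    @property
    def params_before(self) -> int:
        return sum(r.params_before for r in self.rows)

    @property
    def params_after(self) -> int:
        return sum(r.params_after for r in self.rows)

    @property
    def flops_before(self) -> int:
        return sum(r.flops_before for r in self.rows)

    @property
    def flops_after(self) -> int:
        return sum(r.flops_after for r in self.rows)

    @property
    def flops_ratio(self) -> Fraction:
        return Fraction(self.flops_after, self.flops_before)


def convert_backbone(
    layers: Sequence[LayerDesc], policy: Optional[ConversionPolicy] = None
) -> tuple[list[LayerDesc], ConversionReport]:
    """Replace selector-matched convolutions with DHConv descriptions.

    Channel counts and stride are preserved; the report lists each replaced
    layer with its parameter and MAC counts before and after.  A matched
    layer whose channel count is not divisible by 1/P is a configuration
    error naming the layer.
    """
    policy = policy or ConversionPolicy()
    group = int(1 / policy.p_fraction)
    converted: list[LayerDesc] = []
    report = ConversionReport()
    for layer in layers:
        if not policy.matches(layer):
            converted.append(layer)
            continue
        if layer.in_channels % group:
            raise ConfigurationError(
                f"layer {layer.name}: {layer.in_channels} channels not "
                f"divisible by 1/P = {group}")
        new = replace(layer, kind="dhconv", p_fraction=policy.p_fraction,
                      dilation_rate=policy.dilation_rate)
        report.rows.append(ConversionRow(
            name=layer.name,
            params_before=layer.param_count(),
            params_after=new.param_count(),
            flops_before=costmodel.layer_flops(layer),
            flops_after=costmodel.layer_flops(new),
        ))
        converted.append(new)
    return converted, report


# ---------------------------------------------------------------------------
# Trainable layer (forward + manual backward)


class TrainableDHConv:
    """A DHConv layer with hand-written gradients (stride 1 only).

    P = 1, r = 1 makes this an ordinary convolution, so the same class
    serves for the standard layers of a baseline network.
    """

    def __init__(self, spec: DHConvSpec, seed: int = 0):
        if spec.stride != 1:
            raise ValueError("TrainableDHConv supports stride 1 only")
        self.spec = spec
        self.weights = dhconv.init_weights(spec, seed=seed)
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return dhconv.apply_dhconv(x, self.weights, self.spec)

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Gradient of the loss w.r.t. input; stores parameter gradients."""
        spec, w = self.spec, self.weights
        k, r, q = spec.kernel_size, spec.dilation_rate, spec.padding
        x = self._x
        xp = np.pad(x, ((0, 0), (q, q), (q, q)))
        win = sliding_window_view(xp, ((k - 1) * r + 1,) * 2, axis=(1, 2))[..., ::r, ::r]
        g_large = np.einsum("nhw,chwkl->nckl", g, win, optimize=True)
        g_large *= w.layout[:, :, None, None]
        g_point = np.einsum("nhw,chw->nc", g, x, optimize=True)
        g_point *= ~w.layout
        self.grads = {"large": g_large, "point": g_point}
        if w.bias is not None:
            self.grads["bias"] = g.sum(axis=(1, 2))
        # input gradient: transpose convolution = correlation with the
        # spatially flipped kernels, plus the pointwise term
        gp = np.pad(g, ((0, 0), (q, q), (q, q)))
        gwin = sliding_window_view(gp, ((k - 1) * r + 1,) * 2, axis=(1, 2))[..., ::r, ::r]
        flipped = w.large[:, :, ::-1, ::-1]
        dx = np.einsum("nckl,nhwkl->chw", flipped, gwin, optimize=True)
        dx += np.einsum("nc,nhw->chw", w.point, g, optimize=True)
        return dx

    def parameters(self) -> dict[str, np.ndarray]:
        out = {"large": self.weights.large, "point": self.weights.point}
        if self.weights.bias is not None:
            out["bias"] = self.weights.bias
        return out


def convert_layer(layer: TrainableDHConv, policy: ConversionPolicy) -> TrainableDHConv:
    """Convert one trainable layer to the policy's DHConv configuration.

    With P = 1, r = 1 the dense weights are copied and the converted layer
    is numerically identical.  With P < 1 the surviving large kernels keep
    the original K x K weights on their layout positions and the pointwise
    entries inherit the original kernel's centre tap.
    """
    old_spec = layer.spec
    new_spec = replace(old_spec, p_fraction=policy.p_fraction,
                       dilation_rate=policy.dilation_rate)
    new = TrainableDHConv(new_spec, seed=0)
    centre = old_spec.kernel_size // 2
    new.weights.large = layer.weights.large * new.weights.layout[:, :, None, None]
    new.weights.point = (
        layer.weights.large[:, :, centre, centre] + layer.weights.point
    ) * ~new.weights.layout
    if layer.weights.bias is not None and new.weights.bias is not None:
        new.weights.bias = layer.weights.bias.copy()
    return new


# ---------------------------------------------------------------------------
# Compact detector


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


class MaskRDHCNN:
    """Compact fully convolutional cell detector with a DHConv backbone.

    Layers: 3 -> c1 standard 3x3, then two c1 -> c2 / c2 -> c2 DHConv 3x3
    layers per the conversion policy, ReLU between, and a 1x1 sigmoid
    foreground head.  ``policy=ConversionPolicy(p_fraction=1,
    dilation_rate=1)`` yields the all-standard baseline.
    """

    def __init__(
        self,
        num_classes: int = 2,
        policy: Optional[ConversionPolicy] = None,
        channels: tuple[int, int] = (8, 16),
        seed: int = 0,
    ):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2 (background + cell)")
        if num_classes > 2:
            raise ValueError("only a single foreground class is supported")
        self.num_classes = num_classes
        self.policy = policy or ConversionPolicy()
        self.channels = tuple(channels)
        self.seed = seed
        c1, c2 = self.channels
        p, r = self.policy.p_fraction, self.policy.dilation_rate
        self.layers = [
            TrainableDHConv(DHConvSpec(3, c1, 3, 1, Fraction(1)), seed=seed),
            TrainableDHConv(DHConvSpec(c1, c2, 3, r, p), seed=seed + 1),
            TrainableDHConv(DHConvSpec(c2, c2, 3, r, p), seed=seed + 2),
            TrainableDHConv(DHConvSpec(c2, 1, 1, 1, Fraction(1)), seed=seed + 3),
        ]
        # background prior: untrained net predicts background, not noise
        self.layers[-1].weights.bias[:] = -2.0

    # -- forward / loss ----------------------------------------------------

    @staticmethod
    def _prepare(image: np.ndarray) -> np.ndarray:
        """HWC (or HW) uint8/float image -> normalized (3, H, W) float."""
        image = np.asarray(image)
        if image.ndim == 2:
            image = np.repeat(image[:, :, None], 3, axis=2)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) or (H, W) image")
        x = image.astype(np.float64) / 255.0
        return np.moveaxis(x, 2, 0)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Foreground logit map (H, W)."""
        x = self._prepare(image)
        self._relu_masks = []
        for layer in self.layers[:-1]:
            x = layer.forward(x)
            self._relu_masks.append(x > 0)
            x = _relu(x)
        logits = self.layers[-1].forward(x)
        return logits[0]

    def loss_and_backward(self, image: np.ndarray, target: np.ndarray) -> float:
        """Mean pixelwise binary cross-entropy; populates layer gradients."""
        logits = self.forward(image)
        t = np.asarray(target, dtype=np.float64)
        if t.shape != logits.shape:
            raise ValueError(f"target shape {t.shape} != image shape {logits.shape}")
        p = _sigmoid(logits)
        eps = 1e-12
        loss = float(-np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
        g = ((p - t) / p.size)[None, :, :]
        g = self.layers[-1].backward(g)
        for layer, relu_mask in zip(reversed(self.layers[:-1]),
                                    reversed(self._relu_masks)):
            g = layer.backward(g * relu_mask)
        return loss

    # -- inference ---------------------------------------------------------

    def foreground_probability(self, image: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward(image))

    def predict(
        self,
        image: np.ndarray,
        score_threshold: float = 0.5,
        mask_threshold: float = 0.5,
        min_area: int = 16,
    ) -> list[DetectionResult]:
        """Detected instances, sorted by descending score.

        The foreground probability map is binarized at ``mask_threshold``,
        split into 4-connected components (discarding those below
        ``min_area`` pixels), and each component becomes one instance
        scored by its mean foreground probability.
        """
        image = np.asarray(image)
        if image.shape[0] < 32 or image.shape[1] < 32:
            raise ValueError(f"image must be at least 32x32, got {image.shape[:2]}")
        from scipy import ndimage
        prob = self.foreground_probability(image)
        labels, n = ndimage.label(prob > mask_threshold)
        results = []
        for lab in range(1, n + 1):
            mask = labels == lab
            if mask.sum() < min_area:
                continue
            score = float(prob[mask].mean())
            if score < score_threshold:
                continue
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            box = (float(cols[0]), float(rows[0]),
                   float(cols[-1] - cols[0] + 1), float(rows[-1] - rows[0] + 1))
            results.append(DetectionResult(mask=mask, box=box, score=score))
        results.sort(key=lambda d: -d.score)
        return results

    # -- accounting --------------------------------------------------------

    def layer_descs(self, input_size: int = 128) -> list[LayerDesc]:
        descs = []
        for i, layer in enumerate(self.layers):
            s = layer.spec
            kind = "dhconv" if s.p_fraction < 1 else "conv"
            descs.append(LayerDesc(
                name=f"net.{i}", kind=kind, in_channels=s.in_channels,
                out_channels=s.out_channels, kernel_size=s.kernel_size,
                out_w=input_size, out_h=input_size,
                p_fraction=s.p_fraction, dilation_rate=s.dilation_rate))
        return descs

    def param_count(self) -> int:
        return sum(dhconv.param_count(layer.spec) for layer in self.layers)

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.parameters().items():
                arrays[f"layer{i}.{name}"] = arr
        meta = np.array([self.num_classes, self.seed,
                         self.channels[0], self.channels[1],
                         int(self.policy.p_fraction.numerator),
                         int(self.policy.p_fraction.denominator),
                         self.policy.dilation_rate])
        np.savez(path, _meta=meta, **arrays)

    @classmethod
    def load(cls, path) -> "MaskRDHCNN":
        data = np.load(path)
        meta = data["_meta"]
        policy = ConversionPolicy(
            p_fraction=Fraction(int(meta[4]), int(meta[5])),
            dilation_rate=int(meta[6]))
        model = cls(num_classes=int(meta[0]), policy=policy,
                    channels=(int(meta[2]), int(meta[3])), seed=int(meta[1]))
        for i, layer in enumerate(model.layers):
            for name in layer.parameters():
                arr = data[f"layer{i}.{name}"]
                if name == "large":
                    layer.weights.large = arr
                elif name == "point":
                    layer.weights.point = arr
                else:
                    layer.weights.bias = arr
        return model


def build_mask_rdhcnn(
    num_classes: int = 2,
    policy: Optional[ConversionPolicy] = None,
    train_config: Optional[TrainConfig] = None,
    channels: tuple[int, int] = (8, 16),
) -> MaskRDHCNN:
    """Construct the detector with its backbone converted per the policy."""
    seed = train_config.seed if train_config is not None else 0
    return MaskRDHCNN(num_classes=num_classes, policy=policy,
                      channels=channels, seed=seed)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainResult:
    loss_history: list[float]          # mean loss per epoch
    checkpoint: Optional[str] = None


def train(
    model: MaskRDHCNN,
    dataset: Sequence[tuple[np.ndarray, Sequence[np.ndarray]]],
    config: TrainConfig,
    checkpoint_path=None,
) -> TrainResult:
    """SGD with momentum over (image, instance-mask list) samples.

    The training target of each sample is the union of its instance masks
    (foreground vs background).  Deterministic given ``config.seed`` up to
    floating-point accumulation order.  A non-finite loss aborts with a
    diagnostic.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    targets = []
    for image, masks in dataset:
        t = np.zeros(np.asarray(image).shape[:2], dtype=np.float64)
        for m in masks:
            t = np.maximum(t, np.asarray(m, dtype=np.float64))
        targets.append(t)
    velocity = {
        (i, name): np.zeros_like(arr)
        for i, layer in enumerate(model.layers)
        for name, arr in layer.parameters().items()
    }
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.max_epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(dataset))
        losses = []
        for idx in order:
            image, _ = dataset[idx]
            loss = model.loss_and_backward(image, targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, sample {idx}; "
                    "lower the learning rate or check the input scaling")
            losses.append(loss)
            for i, layer in enumerate(model.layers):
                params = layer.parameters()
                for name, arr in params.items():
                    g = layer.grads[name]
                    if name != "bias":
                        g = g + config.weight_decay * arr
                    v = velocity[(i, name)]
                    v *= config.momentum
                    v -= lr * g
                    arr += v
        history.append(float(np.mean(losses)))
        logger.info("epoch %d: lr=%.2e mean loss=%.5f", epoch, lr, history[-1])
    checkpoint = None
    if checkpoint_path is not None:
        model.save(checkpoint_path)
        checkpoint = str(checkpoint_path)
    return TrainResult(loss_history=history, checkpoint=checkpoint)


def predict(
    model: MaskRDHCNN, image: np.ndarray, score_threshold: float = 0.5
) -> list[DetectionResult]:
    """Module-level convenience wrapper around :meth:`MaskRDHCNN.predict`."""
    return model.predict(image, score_threshold=score_threshold)
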