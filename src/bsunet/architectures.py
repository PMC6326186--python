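"""The four segmentation networks and their building blocks.

Variants
--------
``unet``
    Conventional encoder-decoder: five encoder stages of three 3x3
    convolutions each, 2x2 max-pooling, a two-convolution bottleneck, and a
    mirrored decoder (nearest up-sampling + 3x3 convolution, skip
    concatenation, three 3x3 convolutions), closed by a 1x1 sigmoid output.
``dilated_unet``
    The same skeleton with every max-pool replaced by a dilated-convolution
    block — three parallel 3x3 branches with dilation rates 1, 2 and 3,
    channel concatenation, and a spatial-size-preserving 3x3 tail
    convolution — followed by a stride-2 3x3 convolution that performs the
    down-sampling.
``cascaded_unet``
    The conventional skeleton with a back-end fusion head: the probability
    map of a separately trained conventional U-net is concatenated with the
    final decoder features and digested by four 3x3 convolutions before the
    1x1 output.
``bsu_net``
    Boundary-specific U-net: residual blocks (entry 1x1, two 3x3 body
    convolutions under an identity shortcut, exit 1x1) in place of plain
    convolution stages, three-path BSU-pooling in place of max-pooling, a
    lightweight 1x1 up-path, and the same back-end cascade fusion (1x1
    reduce + three 3x3).

Reference channel schedules were frozen by a constraint search so that each
variant's convolution-layer and trainable-parameter totals are exact; see
``docs/methods.md``.  Every 1x1 / 3x3 convolution (including stride-2,
dilated and post-upsample convolutions) counts as a convolutional layer;
trainable parameters sum convolution kernels, biases and batch-norm
scale/shift.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, ShapeError
from .nn import (Adam, Conv2d, ConvBnRelu, MaxPool2x2, Module, Sequential,
                 Tensor, add, concat, relu, sigmoid, upsample2x)

__all__ = [
    "TensorShape", "NetworkConfig", "NetworkSummary",
    "ResidualBlock", "BsuPool", "DilatedBlock",
    "UNet", "build_network", "summarize_network", "attach_cascade",
    "reference_config", "REFERENCE_SCHEDULES", "VARIANTS",
]

VARIANTS = ("unet", "dilated_unet", "cascaded_unet", "bsu_net")
CASCADE_VARIANTS = ("cascaded_unet", "bsu_net")

#: Stage widths of the reference (width_multiplier = 1) configurations,
#: solved so that summarize_network reproduces the published layer and
#: parameter totals exactly.
REFERENCE_SCHEDULES = {
    "unet": (50, 100, 200, 346, 682, 1037),
    "dilated_unet": (46, 92, 184, 364, 512, 781),
    "cascaded_unet": (45, 90, 180, 281, 649, 1287),
    "bsu_net": (52, 104, 208, 354, 469, 870),
}

DEPTH = 5


@dataclass(frozen=True)
class TensorShape:
    """Spatial size and channel count of a network input."""
    width: int
    height: int
    channels: int = 1

    def __post_init__(self):
        if min(self.width, self.height, self.channels) < 1:
            raise ConfigError("TensorShape fields must be positive")


@dataclass
class NetworkConfig:
    """Declarative description from which any variant is built."""
    variant: str
    input_shape: TensorShape = field(default_factory=lambda: TensorShape(256, 256, 1))
    depth: int = DEPTH
    channel_schedule: Optional[Sequence[int]] = None
    width_multiplier: float = 1.0
    cascade_source: Optional[object] = None
    front_end_guidance: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.width_multiplier <= 1.0):
            raise ConfigError("width_multiplier must lie in (0, 1]")
        if self.channel_schedule is None:
            self.channel_schedule = REFERENCE_SCHEDULES[self.variant][: self.depth + 1]
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        if len(self.channel_schedule) != self.depth + 1:
            raise ConfigError("channel_schedule length must equal depth + 1")
        if self.variant in CASCADE_VARIANTS:
            if self.cascade_source is None:
                raise ConfigError(
                    f"{self.variant} requires a cascade_source (a trained "
                    "conventional U-net or a config describing one)")
        elif self.cascade_source is not None:
            raise ConfigError("cascade_source only applies to cascade variants")
        step = 2 ** self.depth
        if self.input_shape.width % step or self.input_shape.height % step:
            raise ShapeError(
                f"input {self.input_shape.width}x{self.input_shape.height} "
                f"not divisible by 2^{self.depth}")

    @property
    def widths(self) -> tuple[int, ...]:
        m = self.width_multiplier
        return tuple(max(1, round(c * m)) for c in self.channel_schedule)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = [self.input_shape.width, self.input_shape.height,
                            self.input_shape.channels]
        d.pop("cascade_source", None)
        return d


@dataclass(frozen=True)
class NetworkSummary:
    variant: str
    n_conv_3x3: int
    n_conv_1x1: int
    n_trainable_params: int

    @property
    def n_conv_total(self) -> int:
        return self.n_conv_3x3 + self.n_conv_1x1

    def to_dict(self) -> dict:
        return {"variant": self.variant, "n_conv_3x3": self.n_conv_3x3,
                "n_conv_1x1": self.n_conv_1x1,
                "n_conv_total": self.n_conv_total,
                "n_trainable_params": self.n_trainable_params}


# ---------------------------------------------------------------------------
# blocks

class ResidualBlock(Module):
    """Entry 1x1 -> [3x3, 3x3] body -> identity shortcut -> exit 1x1.

    The entry convolution matches the incoming channel count to the block
    width so the shortcut is addable; the body learns the residual; with
    body weights at zero the post-addition activation equals the entry
    output exactly.
    """

    def __init__(self, cin, width, rng=None):
        super().__init__()
        self.entry = ConvBnRelu(cin, width, 1, rng=rng)
        self.body1 = ConvBnRelu(width, width, 3, rng=rng)
        self.body2 = ConvBnRelu(width, width, 3, rng=rng, activation=False)
        self.exit = ConvBnRelu(width, width, 1, rng=rng)

    def forward_parts(self, x):
        u = self.entry.forward(x)
        s = self.body2.forward(self.body1.forward(u))
        core = relu(add(s, u))
        return u, core, self.exit.forward(core)

    def forward(self, x):
        return self.forward_parts(x)[2]


class BsuPool(Module):
    """Three-path down-sampling that halves spatial dims.

    Paths: 2x2 max-pool followed by a channel-matching 1x1; a stride-2 3x3;
    and a 1x1 followed by a stride-2 3x3.  Path outputs are concatenated and
    fused by a 1x1 convolution to the configured stage width.
    """

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        self.pool = MaxPool2x2()
        self.pool_match = ConvBnRelu(cin, cout, 1, rng=rng)
        self.path_a = ConvBnRelu(cin, cout, 3, stride=2, rng=rng)
        self.path_b1 = ConvBnRelu(cin, cout, 1, rng=rng)
        self.path_b2 = ConvBnRelu(cout, cout, 3, stride=2, rng=rng)
        self.fuse = ConvBnRelu(3 * cout, cout, 1, rng=rng)

    def forward(self, x):
        h, w = x.data.shape[2:]
        if h % 2 or w % 2:
            raise ShapeError(f"BSU-pooling requires even spatial dims, got {h}x{w}")
        p1 = self.pool_match.forward(self.pool.forward(x))
        p2 = self.path_a.forward(x)
        p3 = self.path_b2.forward(self.path_b1.forward(x))
        return self.fuse.forward(concat([p1, p2, p3]))


class DilatedBlock(Module):
    """Three parallel 3x3 branches at dilation rates 1, 2, 3 sharing the
    input, concatenated and reduced by a tail convolution.

    With ``stride=2`` on the tail (as in the dilated U-net) the block also
    performs the down-sampling that replaces max-pooling; with ``stride=1``
    spatial size is preserved.
    """

    def __init__(self, cin, cout, tail_stride=1, rng=None):
        super().__init__()
        self.branch1 = ConvBnRelu(cin, cin, 3, dilation=1, rng=rng)
        self.branch2 = ConvBnRelu(cin, cin, 3, dilation=2, rng=rng)
        self.branch3 = ConvBnRelu(cin, cin, 3, dilation=3, rng=rng)
        self.tail = ConvBnRelu(3 * cin, cout, 3, stride=tail_stride, rng=rng)

    def forward(self, x):
        b = concat([self.branch1.forward(x), self.branch2.forward(x),
                    self.branch3.forward(x)])
        return self.tail.forward(b)


def _stage(cin, w, n, rng):
    mods = [ConvBnRelu(cin, w, 3, rng=rng)]
    mods += [ConvBnRelu(w, w, 3, rng=rng) for _ in range(n - 1)]
    return Sequential(*mods)


# ---------------------------------------------------------------------------
# networks

class _Network(Module):
    """Common plumbing: input validation and probability-map output."""

    expects_guide = False

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config

    def predict_proba(self, x: np.ndarray, guide: np.ndarray | None = None) -> np.ndarray:
        """Forward pass in eval mode on a raw NCHW array."""
        self.eval()
        g = None if guide is None else Tensor(guide)
        return self.forward(Tensor(np.asarray(x, np.float32)), g).data


class UNet(_Network):
    def __init__(self, config, rng=None):
        super().__init__(config)
        w = config.widths
        d = config.depth
        cin = config.input_shape.channels
        if config.variant == "cascaded_unet" and config.front_end_guidance:
            cin += 1
        self.dilated = config.variant == "dilated_unet"
        self.enc = Sequential(*[
            _stage(cin if i == 0 else w[i - 1], w[i], 3, rng) for i in range(d)])
        if self.dilated:
            self.down = Sequential(*[
                Sequential(DilatedBlock(w[i], w[i], tail_stride=1, rng=rng),
                           ConvBnRelu(w[i], w[i], 3, stride=2, rng=rng))
                for i in range(d)])
        else:
            self.down = Sequential(*[MaxPool2x2() for _ in range(d)])
        self.bottleneck = _stage(w[d - 1], w[d], 2, rng)
        self.up = Sequential(*[
            ConvBnRelu(w[i + 1], w[i], 3, rng=rng) for i in range(d - 1, -1, -1)])
        self.dec = Sequential(*[
            _stage(2 * w[i], w[i], 3, rng) for i in range(d - 1, -1, -1)])
        self.back_end = config.variant == "cascaded_unet" and not config.front_end_guidance
        if self.back_end:
            self.head = Sequential(
                ConvBnRelu(w[0] + 1, w[0], 3, rng=rng),
                ConvBnRelu(w[0], w[0], 3, rng=rng),
                ConvBnRelu(w[0], w[0], 3, rng=rng),
                ConvBnRelu(w[0], w[0], 3, rng=rng))
        self.out = Conv2d(w[0], 1, 1, rng=rng)

    expects_guide = property(lambda self: self.config.variant == "cascaded_unet")

    def forward(self, x: Tensor, guide: Tensor | None = None) -> Tensor:
        self._check_input(x.data.shape)
        if self.config.variant == "cascaded_unet":
            self._check_guide(x.data.shape,
                              None if guide is None else guide.data.shape)
            if self.config.front_end_guidance:
                x = concat([x, guide])
        skips = []
        h = x
        for i in range(self.config.depth):
            h = self.enc.mods[i].forward(h)
            skips.append(h)
            h = self.down.mods[i].forward(h)
        h = self.bottleneck.forward(h)
        for j, i in enumerate(range(self.config.depth - 1, -1, -1)):
            h = self.up.mods[j].forward(upsample2x(h))
            h = self.dec.mods[j].forward(concat([h, skips[i]]))
        if self.back_end:
            h = self.head.forward(concat([h, guide]))
        return sigmoid(self.out.forward(h))

    def _check_input(self, shape):
        if len(shape) != 4:
            raise ShapeError("expected NCHW input")
        step = 2 ** self.config.depth
        if shape[2] % step or shape[3] % step:
            raise ShapeError(
                f"spatial dims {shape[2]}x{shape[3]} not divisible by 2^{self.config.depth}")

    def _check_guide(self, xshape, gshape):
        if gshape is None:
            raise ConfigError(f"{self.config.variant} requires a guidance map")
        if gshape[0] != xshape[0] or tuple(gshape[2:]) != tuple(xshape[2:]):
            raise ShapeError(f"guidance map {gshape} does not match input {xshape}")


class BSUNet(_Network):
    expects_guide = True

    def __init__(self, config, rng=None):
        super().__init__(config)
        w = config.widths
        d = config.depth
        cin = config.input_shape.channels
        if config.front_end_guidance:
            cin += 1
        self.enc = Sequential(*(
            [ResidualBlock(cin, w[0], rng=rng)]
            + [ResidualBlock(w[i], w[i], rng=rng) for i in range(1, d + 1)]))
        self.pools = Sequential(*[
            BsuPool(w[i], w[i + 1], rng=rng) for i in range(d)])
        self.up = Sequential(*[
            ConvBnRelu(w[i + 1], w[i], 1, rng=rng) for i in range(d - 1, -1, -1)])
        self.dec = Sequential(*[
            ResidualBlock(2 * w[i], w[i], rng=rng) for i in range(d - 1, -1, -1)])
        self.front_end = config.front_end_guidance
        if not self.front_end:
            self.reduce = ConvBnRelu(w[0] + 1, w[0], 1, rng=rng)
        self.head = Sequential(
            ConvBnRelu(w[0], w[0], 3, rng=rng),
            ConvBnRelu(w[0], w[0], 3, rng=rng),
            ConvBnRelu(w[0], w[0], 3, rng=rng))
        self.out = Conv2d(w[0], 1, 1, rng=rng)

    def forward(self, x: Tensor, guide: Tensor | None = None) -> Tensor:
        self._check_input(x.data)
        self._check_guide_arr(x.data, guide)
        if self.front_end:
            x = concat([x, guide])
        skips = []
        h = x
        for i in range(self.config.depth):
            h = self.enc.mods[i].forward(h)
            skips.append(h)
            h = self.pools.mods[i].forward(h)
        h = self.enc.mods[self.config.depth].forward(h)
        for j, i in enumerate(range(self.config.depth - 1, -1, -1)):
            h = self.up.mods[j].forward(upsample2x(h))
            h = self.dec.mods[j].forward(concat([h, skips[i]]))
        if not self.front_end:
            h = self.reduce.forward(concat([h, guide]))
        h = self.head.forward(h)
        return sigmoid(self.out.forward(h))

    def _check_input(self, arr):
        if arr.ndim != 4:
            raise ShapeError("expected NCHW input")
        step = 2 ** self.config.depth
        if arr.shape[2] % step or arr.shape[3] % step:
            raise ShapeError(
                f"spatial dims {arr.shape[2]}x{arr.shape[3]} not divisible by 2^{self.config.depth}")

    def _check_guide_arr(self, xarr, guide):
        if guide is None:
            raise ConfigError("bsu_net requires a guidance map")
        g = guide.data
        if g.shape[0] != xarr.shape[0] or g.shape[2:] != xarr.shape[2:]:
            raise ShapeError(f"guidance map {g.shape} does not match input {xarr.shape}")


# ---------------------------------------------------------------------------
# public operations

def build_network(config: NetworkConfig, seed: int = 0) -> Module:
    """Construct a trainable network from a validated config.

    For cascade variants this builds the second-stage network only; the
    stage-1 conventional U-net referenced by ``cascade_source`` is trained
    separately and its probability map is passed to ``forward`` as
    ``guide``.
    """
    rng = np.random.default_rng(seed)
    if config.variant == "bsu_net":
        return BSUNet(config, rng=rng)
    return UNet(config, rng=rng)


def attach_cascade(network: Module, unet_output: np.ndarray):
    """Bind a stage-1 probability map to a cascade-variant network.

    Returns a callable ``bound(x) -> probability map`` that concatenates the
    (validated) guidance at the network's fusion point.
    """
    if not network.expects_guide:
        raise ConfigError(f"{network.config.variant} takes no guidance map")
    g = np.asarray(unet_output, np.float32)
    if g.ndim == 2:
        g = g[None, None]
    elif g.ndim == 3:
        g = g[:, None]

    def bound(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if g.shape[2:] != x.shape[2:]:
            raise ShapeError(
                f"guidance spatial dims {g.shape[2:]} do not match input {x.shape[2:]}")
        return network.predict_proba(x, g)

    return bound


def summarize_network(config: NetworkConfig) -> NetworkSummary:
    """Count convolutional layers and trainable parameters.

    Pure function of the config: every 1x1 and 3x3 convolution (stride-2,
    dilated and post-upsample convolutions included; pooling excluded)
    counts as a layer; parameters sum convolution kernels, biases and
    batch-norm scale/shift.
    """
    net = build_network(config, seed=0)
    n3 = n1 = 0
    for m in net.modules():
        if isinstance(m, Conv2d):
            if m.kernel == 3:
                n3 += 1
            elif m.kernel == 1:
                n1 += 1
    return NetworkSummary(config.variant, n3, n1, net.n_parameters())


def reference_config(variant: str, **overrides) -> NetworkConfig:
    """The frozen reference configuration for a variant (256x256 input,
    width_multiplier 1)."""
    kw = dict(variant=variant, input_shape=TensorShape(256, 256, 1))
    if variant in CASCADE_VARIANTS:
        kw["cascade_source"] = "unet"
    kw.update(overrides)
    return NetworkConfig(**kw)
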