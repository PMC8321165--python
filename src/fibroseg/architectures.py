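"""U-Net and E-Net builders with exact parameter accounting.

Two 2D encoder–decoder segmentation networks for 512×512 single-channel CT
slices, two output classes (channel 0 = lung, channel 1 = background) with a
per-pixel soft-max head:

* a modified U-Net — four resolution levels with 32/64/128/256 feature maps,
  two zero-padded biased k×k convolutions per stage (k ∈ {3, 5}), a 10%
  dropout after every convolution, 2×2 max pooling between encoder stages and
  parameter-free nearest 2× upsampling with skip concatenation in the decoder;
* E-Net — the efficient bottleneck network designed for real-time semantic
  segmentation: an initial downsampling block (strided conv concatenated with
  a max pool of the input), encoder bottlenecks (each a 1×1 projection, a main
  convolution that may be regular, dilated or asymmetric 5×1+1×5, and a 1×1
  expansion, all batch-normalized, with PReLU activations and a residual
  skip), and a lightweight decoder with transposed-conv bottlenecks and ReLU.

Every layer is recorded in an ordered ledger, so trainable and non-trainable
parameter totals can be audited layer by layer. Batch-normalization moving
statistics are the only non-trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Var
from .nn.layers import (
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Dropout,
    Layer,
    MaxPool2D,
    Param,
    PReLU,
    ReLU,
    SpatialDropout2D,
    Upsample2D,
)


@dataclass
class UNetConfig:
    """Configuration of the modified U-Net."""

    kernel_size: int = 5
    base_filters: int = 32
    levels: int = 4
    dropout_rate: float = 0.10
    num_classes: int = 2
    input_size: int = 512
    in_channels: int = 1

    @property
    def max_filters(self) -> int:
        return self.base_filters * 2 ** (self.levels - 1)

    def validate(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_size % 2 ** (self.levels - 1) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.levels - 1}")


@dataclass
class ENetConfig:
    """Configuration of E-Net. `width` scales all channel counts (1.0 = full size)."""

    num_classes: int = 2
    input_size: int = 512
    in_channels: int = 1
    width: float = 1.0

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three 2x downsamplings)")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass
class ParamCount:
    trainable: int
    non_trainable: int

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


class NetworkHandle:
    """A constructed network: ordered layer ledger + forward pass."""

    def __init__(self, name: str, model):
        self.name = name
        self.model = model

    @property
    def layers(self) -> list[Layer]:
        return self.model.layers

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def ledger(self) -> list[dict]:
        return [layer.describe() for layer in self.layers]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Var:
        """Run the network on an (N, C, H, W) batch; returns soft-max probabilities."""
        return self.model.forward(Var(np.asarray(x, dtype=np.float32)), training, rng)

    def predict_probs(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference-mode probabilities, batched to bound memory."""
        outs = []
        for start in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[start:start + batch_size], training=False).data)
        return np.concatenate(outs, axis=0)

    def collect_grads(self) -> None:
        for layer in self.layers:
            layer.collect_grads()

    def summary(self) -> str:
        lines = [f"{self.name}"]
        for entry in self.ledger():
            extras = {k: v for k, v in entry.items()
                      if k not in ("kind", "name", "trainable", "non_trainable")}
            lines.append(f"  {entry['name']:<40} {entry['kind']:<18} "
                         f"train={entry['trainable']:<9} fixed={entry['non_trainable']:<6} {extras}")
        pc = count_parameters(self)
        lines.append(f"  TOTAL trainable={pc.trainable} non_trainable={pc.non_trainable}")
        return "\n".join(lines)


def count_parameters(net: NetworkHandle) -> ParamCount:
    """Sum weight-element counts over the ledger, split by trainability."""
    trainable = sum(p.size for p in net.parameters() if p.trainable)
    non_trainable = sum(p.size for p in net.parameters() if not p.trainable)
    return ParamCount(trainable, non_trainable)


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class _UNet:
    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers: list[Layer] = []
        k = cfg.kernel_size

        def conv(name, cin, cout):
            layer = Conv2D(name, cin, cout, k, k, rng, bias=True, pad="same")
            self.layers.append(layer)
            return layer

        def drop(name):
            layer = Dropout(name, cfg.dropout_rate)
            self.layers.append(layer)
            return layer

        self.enc: list[tuple] = []
        cin = cfg.in_channels
        for lvl in range(cfg.levels):
            f = cfg.base_filters * 2 ** lvl
            block = (conv(f"enc{lvl}.conv1", cin, f), drop(f"enc{lvl}.drop1"),
                     conv(f"enc{lvl}.conv2", f, f), drop(f"enc{lvl}.drop2"))
            self.enc.append(block)
            if lvl < cfg.levels - 1:
                self.layers.append(MaxPool2D(f"enc{lvl}.pool"))
            cin = f

        self.dec: list[tuple] = []
        for lvl in reversed(range(cfg.levels - 1)):
            f = cfg.base_filters * 2 ** lvl
            self.layers.append(Upsample2D(f"dec{lvl}.up"))
            cat_in = cin + f  # upsampled deeper features + skip
            block = (conv(f"dec{lvl}.conv1", cat_in, f), drop(f"dec{lvl}.drop1"),
                     conv(f"dec{lvl}.conv2", f, f), drop(f"dec{lvl}.drop2"))
            self.dec.append(block)
            cin = f

        self.head = Conv2D("head.conv1x1", cin, cfg.num_classes, 1, 1, rng,
                           bias=True, pad="valid")
        self.layers.append(self.head)

    def forward(self, x: Var, training: bool, rng) -> Var:
        # each convolution: conv -> ReLU -> dropout (ReLU carries no weights)
        skips = []
        for lvl, (c1, d1, c2, d2) in enumerate(self.enc):
            x = d1(ad.relu(c1(x)), training, rng)
            x = d2(ad.relu(c2(x)), training, rng)
            if lvl < self.cfg.levels - 1:
                skips.append(x)
                x = ad.maxpool2x2(x)
        for (c1, d1, c2, d2), skip in zip(self.dec, reversed(skips)):
            x = ad.concat([ad.upsample2x(x), skip], axis=1)
            x = d1(ad.relu(c1(x)), training, rng)
            x = d2(ad.relu(c2(x)), training, rng)
        return ad.softmax(self.head(x), axis=1)


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> NetworkHandle:
    """Construct the modified U-Net; see the module docstring for the layout."""
    cfg = cfg or UNetConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    return NetworkHandle(f"unet{cfg.kernel_size}", _UNet(cfg, rng))


# ---------------------------------------------------------------------------
# E-Net
# ---------------------------------------------------------------------------

class _EncoderBottleneck:
    """Projection → main conv (regular / dilated / asymmetric) → expansion,
    batch-normalized with PReLU, plus a max-pool residual path on downsampling."""

    def __init__(self, name, cin, cout, rng, layers, kind="regular", dilation=1,
                 downsample=False, dropout_rate=0.1):
        self.cin, self.cout, self.downsample = cin, cout, downsample
        internal = max(cout // 4, 1)
        reg = layers.append
        pk = 2 if downsample else 1
        self.proj = Conv2D(f"{name}.proj", cin, internal, pk, pk, rng,
                           stride=pk, bias=False, pad="valid")
        self.bn1 = BatchNorm2D(f"{name}.bn1", internal)
        self.act1 = PReLU(f"{name}.prelu1", internal)
        self.main: list[Layer] = []
        if kind == "asym":
            self.main = [Conv2D(f"{name}.asym5x1", internal, internal, 5, 1, rng,
                                bias=False, pad="same"),
                         Conv2D(f"{name}.asym1x5", internal, internal, 1, 5, rng,
                                bias=True, pad="same")]
        else:
            self.main = [Conv2D(f"{name}.conv", internal, internal, 3, 3, rng,
                                dilation=dilation, bias=True, pad="same")]
        self.bn2 = BatchNorm2D(f"{name}.bn2", internal)
        self.act2 = PReLU(f"{name}.prelu2", internal)
        self.expand = Conv2D(f"{name}.expand", internal, cout, 1, 1, rng,
                             bias=False, pad="valid")
        self.bn3 = BatchNorm2D(f"{name}.bn3", cout)
        self.drop = SpatialDropout2D(f"{name}.drop", dropout_rate)
        self.act_out = PReLU(f"{name}.prelu_out", cout)
        for layer in (self.proj, self.bn1, self.act1, *self.main, self.bn2,
                      self.act2, self.expand, self.bn3, self.drop, self.act_out):
            reg(layer)

    def forward(self, x, training, rng):
        y = self.act1(self.bn1(self.proj(x), training), training, rng)
        for layer in self.main:
            y = layer(y, training, rng)
        y = self.act2(self.bn2(y, training), training, rng)
        y = self.drop(self.bn3(self.expand(y), training), training, rng)
        skip = x
        if self.downsample:
            skip = ad.maxpool2x2(skip)
        if self.cout > self.cin:
            skip = ad.pad_channels(skip, self.cout - self.cin)
        return self.act_out(y + skip, training, rng)


class _DecoderBottleneck:
    """Decoder bottleneck with ReLU; upsampling variants use a 3×3 transposed
    conv in the main path and a bias-free 1×1 conv + BN + nearest 2× on the skip."""

    def __init__(self, name, cin, cout, rng, layers, upsample=False):
        self.cin, self.cout, self.upsample = cin, cout, upsample
        internal = max(cout // 4, 1)
        self.proj = Conv2D(f"{name}.proj", cin, internal, 1, 1, rng, bias=False, pad="valid")
        self.bn1 = BatchNorm2D(f"{name}.bn1", internal)
        if upsample:
            self.main: Layer = ConvTranspose2D(f"{name}.deconv", internal, internal, 3, rng,
                                               stride=2, bias=True)
        else:
            self.main = Conv2D(f"{name}.conv", internal, internal, 3, 3, rng,
                               bias=True, pad="same")
        self.bn2 = BatchNorm2D(f"{name}.bn2", internal)
        self.expand = Conv2D(f"{name}.expand", internal, cout, 1, 1, rng, bias=False, pad="valid")
        self.bn3 = BatchNorm2D(f"{name}.bn3", cout)
        self.skip_layers: list[Layer] = []
        if upsample or cin != cout:
            self.skip_conv = Conv2D(f"{name}.skip_conv", cin, cout, 1, 1, rng,
                                    bias=False, pad="valid")
            self.skip_bn = BatchNorm2D(f"{name}.skip_bn", cout)
            self.skip_layers = [self.skip_conv, self.skip_bn]
        for layer in (self.proj, self.bn1, self.main, self.bn2, self.expand,
                      self.bn3, *self.skip_layers):
            layers.append(layer)

    def forward(self, x, training, rng):
        y = ad.relu(self.bn1(self.proj(x), training))
        y = ad.relu(self.bn2(self.main(y, training, rng), training))
        y = self.bn3(self.expand(y), training)
        skip = x
        if self.skip_layers:
            skip = self.skip_bn(self.skip_conv(skip), training)
            if self.upsample:
                skip = ad.upsample2x(skip)
        return ad.relu(y + skip)


class _ENet:
    def __init__(self, cfg: ENetConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers: list[Layer] = []
        w = cfg.width
        c0 = max(int(round(16 * w)), cfg.in_channels + 1)
        c1 = max(int(round(64 * w)), 4)
        c2 = max(int(round(128 * w)), 4)

        # initial block: strided conv concatenated with a max pool of the input
        self.init_conv = Conv2D("initial.conv", cfg.in_channels, c0 - cfg.in_channels,
                                3, 3, rng, stride=2, bias=True, pad="same")
        self.init_bn = BatchNorm2D("initial.bn", c0)
        self.init_act = PReLU("initial.prelu", c0)
        self.layers += [self.init_conv, MaxPool2D("initial.pool"), self.init_bn, self.init_act]

        enc = []
        enc.append(_EncoderBottleneck("b1.0", c0, c1, rng, self.layers,
                                      downsample=True, dropout_rate=0.01))
        for i in range(1, 5):
            enc.append(_EncoderBottleneck(f"b1.{i}", c1, c1, rng, self.layers,
                                          dropout_rate=0.01))
        enc.append(_EncoderBottleneck("b2.0", c1, c2, rng, self.layers, downsample=True))
        for stage in (2, 3):
            plan = [("regular", 1), ("dilated", 2), ("asym", 1), ("dilated", 4),
                    ("regular", 1), ("dilated", 8), ("asym", 1), ("dilated", 16)]
            for i, (kind, dil) in enumerate(plan, start=1):
                enc.append(_EncoderBottleneck(f"b{stage}.{i}", c2, c2, rng, self.layers,
                                              kind=kind, dilation=dil))
        self.encoder = enc

        dec = [
            _DecoderBottleneck("b4.0", c2, c1, rng, self.layers, upsample=True),
            _DecoderBottleneck("b4.1", c1, c1, rng, self.layers),
            _DecoderBottleneck("b4.2", c1, c1, rng, self.layers),
            _DecoderBottleneck("b5.0", c1, c0, rng, self.layers, upsample=True),
            _DecoderBottleneck("b5.1", c0, c0, rng, self.layers),
        ]
        self.decoder = dec
        self.fullconv = ConvTranspose2D("fullconv", c0, cfg.num_classes, 2, rng,
                                        stride=2, bias=True)
        self.layers.append(self.fullconv)

    def forward(self, x: Var, training: bool, rng) -> Var:
        y = ad.concat([self.init_conv(x), ad.maxpool2x2(x)], axis=1)
        y = self.init_act(self.init_bn(y, training), training, rng)
        for block in self.encoder:
            y = block.forward(y, training, rng)
        for block in self.decoder:
            y = block.forward(y, training, rng)
        return ad.softmax(self.fullconv(y), axis=1)


def build_enet(cfg: ENetConfig | None = None, seed: int = 0) -> NetworkHandle:
    """Construct E-Net; see the module docstring for the layout."""
    cfg = cfg or ENetConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    return NetworkHandle("enet", _ENet(cfg, rng))


def build_model(kind: str, seed: int = 0, **overrides) -> NetworkHandle:
    """Build by name: 'unet3', 'unet5' or 'enet'."""
    if kind == "unet3":
        net = build_unet(UNetConfig(kernel_size=3, **overrides), seed)
    elif kind == "unet5":
        net = build_unet(UNetConfig(kernel_size=5, **overrides), seed)
    elif kind == "enet":
        net = build_enet(ENetConfig(**overrides), seed)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    net.build_spec = {"kind": kind, "overrides": overrides, "seed": seed}
    return net


def save_network(net: NetworkHandle, path) -> None:
    """Checkpoint: weights as .npz plus a JSON architecture sidecar.

    Only networks created through `build_model` carry the build spec needed
    to reconstruct them.
    """
    import json
    from pathlib import Path

    if not hasattr(net, "build_spec"):
        raise ValueError("only build_model() networks can be checkpointed")
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **{p.name: p.value for p in net.parameters()})
    path.with_suffix(".json").write_text(json.dumps(net.build_spec))


def load_network(path) -> NetworkHandle:
    """Rebuild a checkpointed network and restore its weights."""
    import json
    from pathlib import Path

    path = Path(path)
    spec = json.loads(path.with_suffix(".json").read_text())
    net = build_model(spec["kind"], seed=spec["seed"], **spec["overrides"])
    arrays = np.load(path.with_suffix(".npz"))
    for p in net.parameters():
        p.value = arrays[p.name]
    return net
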