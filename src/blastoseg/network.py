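"""Multiscale-aggregation segmentation network: spec, shapes, parameters, execution.

The architecture is an encoder-decoder for five-class blastocyst
segmentation built from four parallel branches that all consume the output
of a shared stride-2 input convolution (a 400x400 grayscale image becomes a
200x200x16 feature ``Fi``):

* **Scale-8** — a 3x3 entry convolution with stride 8 and dilation 8, eight
  depthwise-separable convolutions (DWSC), and three 2x2/stride-2 transposed
  convolutions back up to 200x200.
* **Scale-2** — stride-2/dilation-2 entry, plain 3x3 convolutions, the
  network's single max-pooling layer, two DWSC, and two transposed
  convolutions.
* **Scale-4** — stride-4/dilation-4 entry, plain convolutions, four DWSC and
  two transposed convolutions.
* **Feature booster block (FBB)** — four 3x3 stride-1 convolutions that keep
  the full 200x200 resolution so minor-class detail (ICM, TE, ZP) survives.

The four branch outputs are depth-concatenated into the aggregated feature
``SA`` (32+64+64+128 = 288 channels with the FBB, 160 without), which a
shallow upsampling block (three convolutions plus one transposed
convolution) decodes into per-pixel scores for the 5 classes at full input
resolution.  Every convolution except the final 1x1 class head is followed
by batch normalisation and ReLU.

Padding for every 3x3 convolution equals its dilation factor; this is the
unique choice under which the entry convolutions of the three scale branches
produce 25x25 / 100x100 / 50x50 maps from a 200x200 input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .dataio import CLASS_MAP

__all__ = [
    "BlockOutputs",
    "LayerSpec",
    "Network",
    "NetworkSpec",
    "ParameterCount",
    "TensorShape",
    "aggregate",
    "build_network",
    "canonical_spec",
    "count_parameters",
    "infer_shapes",
    "layer_output_shape",
    "predict",
]

N_CLASSES = CLASS_MAP.n_classes


@dataclass(frozen=True)
class TensorShape:
    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.channels) < 1:
            raise ValueError(f"non-positive tensor shape {self}")

    def __str__(self) -> str:
        return f"{self.height} x {self.width} x {self.channels}"


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer (or a run of identical layers)."""

    name: str
    kind: str  # conv | dwsc | tconv | maxpool | classhead
    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    dilation: int = 1
    repetition: int = 1
    bn_relu: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"conv", "dwsc", "tconv", "maxpool", "classhead"}:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if min(self.kernel, self.stride, self.dilation, self.repetition) < 1:
            raise ValueError(f"kernel/stride/dilation/repetition must be >= 1 in {self.name}")

    @property
    def padding(self) -> int:
        # dilation-sized padding for 3x3 layers reproduces the canonical
        # output sizes (200 -> 25 at S=8/DF=8 needs p=8, etc.); 1x1 and 2x2
        # layers take no padding.
        return self.dilation if self.kernel == 3 else 0

    def instances(self) -> list[tuple[str, int, int]]:
        """Expand repetition into (instance_name, in_ch, out_ch) triples."""
        if self.repetition == 1:
            return [(self.name, self.in_channels, self.out_channels)]
        out = [(f"{self.name}-1", self.in_channels, self.out_channels)]
        out += [
            (f"{self.name}-{i + 1}", self.out_channels, self.out_channels)
            for i in range(1, self.repetition)
        ]
        return out


@dataclass
class NetworkSpec:
    """Ordered block structure of the full network."""

    blocks: dict[str, tuple[LayerSpec, ...]]
    with_fbb: bool = True

    @property
    def branch_names(self) -> tuple[str, ...]:
        names = ("scale8", "scale2", "scale4")
        return names + ("fbb",) if self.with_fbb else names

    def to_dict(self) -> dict:
        return {
            "with_fbb": self.with_fbb,
            "blocks": {k: [asdict(l) for l in v] for k, v in self.blocks.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, raw: dict) -> "NetworkSpec":
        blocks = {
            k: tuple(LayerSpec(**l) for l in v) for k, v in raw["blocks"].items()
        }
        return cls(blocks=blocks, with_fbb=raw["with_fbb"])


def canonical_spec(with_fbb: bool = True) -> NetworkSpec:
    """The canonical layer list of the published architecture.

    With the FBB the aggregation operands carry (32, 64, 64, 128) channels;
    without it the FBB block is absent, the aggregated feature shrinks from
    288 to 160 channels, and the first upsampling convolution narrows
    accordingly.
    """
    L = LayerSpec
    blocks: dict[str, tuple[LayerSpec, ...]] = {}
    blocks["input"] = (L("Input-Conv", "conv", 1, 16, stride=2),)
    blocks["scale8"] = (
        L("S8-Conv-S", "conv", 16, 32, stride=8, dilation=8),
        L("S8-DWSC", "dwsc", 32, 32, repetition=8),
        L("S8-Tconv-A", "tconv", 32, 32, kernel=2, stride=2),
        L("S8-Tconv-B", "tconv", 32, 32, kernel=2, stride=2),
        L("S8-Tconv-C", "tconv", 32, 32, kernel=2, stride=2),
    )
    blocks["scale2"] = (
        # listed once with stride 8 in the published table, but its output
        # size and the prose fix stride = dilation = 2
        L("S2-Conv-S", "conv", 16, 32, stride=2, dilation=2),
        L("S2-Conv-A", "conv", 32, 64),
        L("S2-Conv-B", "conv", 64, 64),
        L("S2-Pool", "maxpool", 64, 64, kernel=2, stride=2),
        L("S2-Conv-C", "conv", 64, 128),
        L("S2-Conv-D", "conv", 128, 256),
        L("S2-DWSC", "dwsc", 256, 256, repetition=2),
        L("S2-Tconv-A", "tconv", 256, 128, kernel=2, stride=2),
        L("S2-Tconv-B", "tconv", 128, 64, kernel=2, stride=2),
    )
    blocks["scale4"] = (
        L("S4-Conv-S", "conv", 16, 32, stride=4, dilation=4),
        L("S4-Conv-A", "conv", 32, 64),
        L("S4-Conv-B", "conv", 64, 128),
        L("S4-DWSC-A", "dwsc", 128, 128, repetition=2),
        # two layers under one table row; 128->64 then 64->64 is the only
        # channel-consistent reading
        L("S4-DWSC-B", "dwsc", 128, 64, repetition=2),
        L("S4-Tconv-A", "tconv", 64, 128, kernel=2, stride=2),
        L("S4-Tconv-B", "tconv", 128, 64, kernel=2, stride=2),
    )
    if with_fbb:
        blocks["fbb"] = (
            L("FBB-Conv-A", "conv", 16, 32),
            L("FBB-Conv-B", "conv", 32, 64),
            L("FBB-Conv-C", "conv", 64, 64),
            L("FBB-Conv-D", "conv", 64, 128),
        )
    sa_channels = 32 + 64 + 64 + (128 if with_fbb else 0)
    blocks["upsampling"] = (
        L("US-Conv-A", "conv", sa_channels, 256),
        L("US-Conv-B", "conv", 256, 128),
        L("US-Conv-C", "conv", 128, 64),
        L("US-Tconv-A", "tconv", 64, 32, kernel=2, stride=2),
    )
    blocks["head"] = (
        L("Class-Mask-Conv", "classhead", 32, N_CLASSES, kernel=1, bn_relu=False),
    )
    return NetworkSpec(blocks=blocks, with_fbb=with_fbb)


def layer_output_shape(input_shape: TensorShape, layer: LayerSpec) -> TensorShape:
    """Shape of one layer instance's output (repetition not expanded)."""
    h, w, c = input_shape.height, input_shape.width, input_shape.channels
    if c != layer.in_channels:
        raise ValueError(
            f"{layer.name}: expected {layer.in_channels} input channels, got {c}"
        )
    if layer.kind in {"conv", "dwsc", "classhead"}:
        k, s, d, p = layer.kernel, layer.stride, layer.dilation, layer.padding
        ho = (h + 2 * p - d * (k - 1) - 1) // s + 1
        wo = (w + 2 * p - d * (k - 1) - 1) // s + 1
    elif layer.kind == "maxpool":
        ho, wo = h // 2, w // 2
    elif layer.kind == "tconv":
        ho, wo = 2 * h, 2 * w
    else:  # pragma: no cover
        raise ValueError(layer.kind)
    if ho < 1 or wo < 1:
        raise ValueError(f"{layer.name}: non-positive output size from input {h}x{w}")
    return TensorShape(ho, wo, layer.out_channels)


def infer_shapes(
    spec: NetworkSpec, input_shape: TensorShape = TensorShape(400, 400, 1)
) -> list[tuple[str, TensorShape]]:
    """Per-layer-instance output shapes, plus the feature-aggregation entry.

    Raises if the branch outputs disagree spatially at the concatenation,
    naming the offending operands.
    """
    table: list[tuple[str, TensorShape]] = []

    def run_block(layers: tuple[LayerSpec, ...], shape: TensorShape) -> TensorShape:
        for layer in layers:
            for inst_name, cin, cout in layer.instances():
                inst = LayerSpec(
                    inst_name, layer.kind, cin, cout, layer.kernel,
                    layer.stride, layer.dilation, 1, layer.bn_relu,
                )
                shape = layer_output_shape(shape, inst)
                table.append((inst_name, shape))
        return shape

    fi = run_block(spec.blocks["input"], input_shape)
    branch_out: dict[str, TensorShape] = {}
    for name in spec.branch_names:
        branch_out[name] = run_block(spec.blocks[name], fi)
    shapes = list(branch_out.values())
    ref = shapes[0]
    for name, shp in branch_out.items():
        if (shp.height, shp.width) != (ref.height, ref.width):
            first = spec.branch_names[0]
            raise ValueError(
                f"aggregation operands disagree spatially: {first} gives "
                f"{ref} but {name} gives {shp}"
            )
    sa = TensorShape(ref.height, ref.width, sum(s.channels for s in shapes))
    table.append(("Feature-Aggregation", sa))
    out = run_block(spec.blocks["upsampling"], sa)
    run_block(spec.blocks["head"], out)
    return table


@dataclass
class ParameterCount:
    per_layer: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.per_layer)

    @property
    def total_millions(self) -> float:
        """Total in millions at 3 significant figures (table convention)."""
        return float(f"{self.total / 1e6:.3g}")

    def as_dict(self) -> dict[str, int]:
        return dict(self.per_layer)


def count_parameters(spec: NetworkSpec) -> ParameterCount:
    """Learnable-parameter ledger: conv/tconv weights + biases + BN affine.

    DWSC layers count the depthwise 3x3 stage (k*k*Cin weights + Cin biases)
    plus the pointwise 1x1 stage (Cin*Cout weights + Cout biases); batch-norm
    contributes 2 affine parameters per normalised channel.  The class head
    has a bias but no batch norm.
    """
    counts = ParameterCount()
    for layers in spec.blocks.values():
        for layer in layers:
            for inst_name, cin, cout in layer.instances():
                k = layer.kernel
                if layer.kind in {"conv", "classhead"}:
                    n = k * k * cin * cout + cout
                elif layer.kind == "tconv":
                    n = k * k * cin * cout + cout
                elif layer.kind == "dwsc":
                    n = (3 * 3 * cin + cin) + (cin * cout + cout)
                elif layer.kind == "maxpool":
                    n = 0
                if layer.kind != "maxpool" and layer.bn_relu:
                    n += 2 * cout
                counts.per_layer.append((inst_name, n))
    return counts


def aggregate(*features: np.ndarray, names: tuple[str, ...] | None = None) -> np.ndarray:
    """Depth-wise concatenation of branch features in their fixed order."""
    if not features:
        raise ValueError("aggregate needs at least one operand")
    ref = features[0].shape[-2:]
    for i, f in enumerate(features):
        if f.shape[-2:] != ref:
            a = names[0] if names else "operand 0"
            b = names[i] if names else f"operand {i}"
            raise ValueError(
                f"spatial mismatch at aggregation: {a} is {ref}, {b} is {f.shape[-2:]}"
            )
    return np.concatenate(features, axis=-3)


@dataclass
class BlockOutputs:
    """Branch features and their aggregation from one forward pass."""

    FS8: np.ndarray
    FS2: np.ndarray
    FS4: np.ndarray
    FBB: np.ndarray | None
    SA: np.ndarray


def _build_layer(layer: LayerSpec, cin: int, cout: int, dtype) -> list[nn.Module]:
    mods: list[nn.Module] = []
    if layer.kind in {"conv", "classhead"}:
        mods.append(
            nn.Conv2d(
                cin, cout, kernel=layer.kernel, stride=layer.stride,
                dilation=layer.dilation, padding=layer.padding, dtype=dtype,
            )
        )
    elif layer.kind == "dwsc":
        # depthwise 3x3 then pointwise 1x1; BN+ReLU after the pointwise only
        mods.append(nn.DepthwiseConv2d(cin, dtype=dtype))
        mods.append(nn.Conv2d(cin, cout, kernel=1, dtype=dtype))
    elif layer.kind == "tconv":
        mods.append(nn.ConvTranspose2d(cin, cout, dtype=dtype))
    elif layer.kind == "maxpool":
        mods.append(nn.MaxPool2d())
    if layer.bn_relu and layer.kind != "maxpool":
        mods.append(nn.BatchNorm2d(cout, dtype=dtype))
        mods.append(nn.ReLU())
    return mods


class Network:
    """Forward/backward-executable network built from a :class:`NetworkSpec`.

    Weight initialisation is He-normal from a single seeded generator walked
    in fixed layer order, so two builds with the same seed are bit-identical.
    Trained from scratch only — there is no pretrained-weight path.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self._sections: list[tuple[str, nn.Sequential]] = []

        def build_block(name: str) -> nn.Sequential:
            mods: list[nn.Module] = []
            for layer in spec.blocks[name]:
                for _, cin, cout in layer.instances():
                    mods += _build_layer(layer, cin, cout, dtype)
            seq = nn.Sequential(*mods)
            self._sections.append((name, seq))
            return seq

        self.input_block = build_block("input")
        self.branches = [(name, build_block(name)) for name in spec.branch_names]
        self.upsampling = build_block("upsampling")
        self.head = build_block("head")
        self._branch_channels = [
            spec.blocks[name][-1].out_channels for name in spec.branch_names
        ]
        rng = np.random.default_rng(seed)
        for _, seq in self._sections:
            seq.init(rng)
        self.last_blocks: BlockOutputs | None = None

    # -- execution -----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input (N, 1, H, W) in [0,1] -> per-class scores (N, 5, H, W)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        fi = self.input_block.forward(x, training=training)
        outs = [seq.forward(fi, training=training) for _, seq in self.branches]
        sa = aggregate(*outs, names=tuple(n for n, _ in self.branches))
        self.last_blocks = BlockOutputs(
            FS8=outs[0], FS2=outs[1], FS4=outs[2],
            FBB=outs[3] if self.spec.with_fbb else None, SA=sa,
        )
        y = self.upsampling.forward(sa, training=training)
        return self.head.forward(y, training=training)

    def backward(self, dscores: np.ndarray) -> None:
        dy = self.head.backward(dscores)
        dsa = self.upsampling.backward(dy)
        dfi = None
        start = 0
        for (name, seq), ch in zip(self.branches, self._branch_channels):
            d = seq.backward(np.ascontiguousarray(dsa[:, start : start + ch]))
            dfi = d if dfi is None else dfi + d
            start += ch
        self.input_block.backward(dfi)

    __call__ = forward

    # -- parameters / state --------------------------------------------
    def parameters(self) -> list[nn.Param]:
        return [p for _, seq in self._sections for p in seq.parameters()]

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, seq in self._sections:
            for i, p in enumerate(seq.parameters()):
                state[f"{name}.p{i}"] = p.value
            for bname, buf in seq.buffers():
                state[f"{name}.buf.{bname}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, seq in self._sections:
            for i, p in enumerate(seq.parameters()):
                p.value[...] = state[f"{name}.p{i}"]
            for bname, buf in seq.buffers():
                buf[...] = state[f"{name}.buf.{bname}"]

    def save(self, path: str | Path) -> None:
        np.savez(Path(path), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, spec: NetworkSpec, dtype=np.float32) -> "Network":
        net = cls(spec, seed=0, dtype=dtype)
        with np.load(Path(path)) as data:
            net.load_state_dict(dict(data))
        return net


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> Network:
    """Construct an executable network; shape consistency is validated first."""
    infer_shapes(spec, TensorShape(400, 400, 1))  # raises on inconsistent specs
    return Network(spec, seed=seed, dtype=dtype)


def predict(network: Network, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment one image: per-pixel argmax label map + 5 binary class masks.

    Ties in the scores resolve to the lowest class index (BG first).  The
    masks are mutually exclusive and jointly exhaustive by construction.
    """
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    scores = network.forward(image[None, None, :, :], training=False)[0]
    label_map = scores.argmax(axis=0)  # first maximum -> lowest class index
    masks = np.stack([(label_map == c) for c in range(N_CLASSES)]).astype(np.uint8)
    return label_map, masks
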