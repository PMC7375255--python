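"""3D attention network (3DAN) and its attention-free ResNet twin.

The classifier is a 3D residual CNN for gray-matter density volumes: a stem
convolution, eight residual blocks arranged in four two-block stages with an
average-pooling stage after stage 1 and after stage 3, a spatial attention
module on the final feature maps, then global average pooling and a fully
connected layer producing two unnormalized class scores.

The attention module is a single 3x3x3 convolution to one channel followed
by a sigmoid; the resulting map M has one weight per spatial position i and
multiplies every feature channel at that position, ``H[i, c] = F[i, c] * M[i]``.
The map therefore reads as a per-location measure of how much the classifier
relies on that part of the volume.  With ``with_attention=False`` the module
is skipped and the model is a plain 3D ResNet baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._nn import (
    AvgPool3d,
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool3d,
    Linear,
    ReLU,
    Sigmoid,
    pooled_size,
)
from ._nn.layers import DTYPE

__all__ = [
    "NetworkSpec",
    "ResidualBlock",
    "AttentionModule",
    "AttentionNet3D",
    "apply_attention",
    "residual_block",
    "compute_attention_map",
    "attention_grid_shape",
    "save_model",
    "load_model",
    "load_classes",
]


@dataclass
class NetworkSpec:
    """Architecture description.

    ``block_channels`` gives the width of the four two-block stages
    (eight residual blocks in total).  The published sizes are not tied to
    any particular width, so toy grids can use narrow stages.
    """

    in_shape: tuple[int, int, int]
    stem_channels: int | None = None
    block_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    n_blocks: int = 8
    attention_kernel: int = 3
    pool_kernel: int = 3
    pool_stride: int = 2
    n_classes: int = 2
    with_attention: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks != 8 or len(self.block_channels) != 4:
            raise ValueError("architecture is fixed at eight residual blocks in four stages")
        if self.stem_channels is None:
            self.stem_channels = self.block_channels[0]

    @property
    def attention_shape(self) -> tuple[int, int, int]:
        """Spatial shape of the post-pooling grid carrying the attention map."""
        return attention_grid_shape(self.in_shape, self.pool_kernel, self.pool_stride)


def attention_grid_shape(in_shape: tuple[int, int, int], kernel: int = 3,
                         stride: int = 2) -> tuple[int, int, int]:
    """Shape after the two pooling stages (each axis n -> ceil(n/2)).

    A 91 x 109 x 91 input maps to 46 x 55 x 46 and then 23 x 28 x 23.
    """
    once = tuple(pooled_size(n, kernel, stride) for n in in_shape)
    return tuple(pooled_size(n, kernel, stride) for n in once)


class ResidualBlock:
    """Two 3x3x3 convolutions with batch norm and ReLU; identity shortcut.

    Output is ``ReLU(F(x) + x)`` where F is conv-bn-relu-conv-bn.  When the
    channel count changes, the shortcut is a 1x1x1 projection with its own
    batch norm so the addition is well-defined.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator) -> None:
        self.conv1 = Conv3d(in_channels, out_channels, 3, rng=rng)
        self.bn1 = BatchNorm3d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng=rng)
        self.bn2 = BatchNorm3d(out_channels)
        self.relu_out = ReLU()
        if in_channels != out_channels:
            self.proj = Conv3d(in_channels, out_channels, 1, rng=rng)
            self.proj_bn = BatchNorm3d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def layers(self) -> list:
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.conv1.forward(x, train)
        f = self.bn1.forward(f, train)
        f = self.relu1.forward(f, train)
        f = self.conv2.forward(f, train)
        f = self.bn2.forward(f, train)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        if f.shape != sc.shape:
            raise ValueError(f"residual branch shape {f.shape} != shortcut shape {sc.shape}")
        return self.relu_out.forward(f + sc, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ds = self.relu_out.backward(dout)
        df = self.bn2.backward(ds)
        df = self.conv2.backward(df)
        df = self.relu1.backward(df)
        df = self.bn1.backward(df)
        dx = self.conv1.backward(df)
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(ds))
        else:
            dx = dx + ds
        return dx


class AttentionModule:
    """Spatial attention: one 3x3x3 conv to a single channel, then sigmoid."""

    def __init__(self, in_channels: int, kernel: int, rng: np.random.Generator) -> None:
        self.conv = Conv3d(in_channels, 1, kernel, rng=rng)
        self.sigmoid = Sigmoid()
        self._cache: tuple | None = None

    def layers(self) -> list:
        return [self.conv]

    def attention(self, f: np.ndarray, train: bool = False) -> np.ndarray:
        """The map M in (0,1), shape (N, 1, h, w, d)."""
        return self.sigmoid.forward(self.conv.forward(f, train), train)

    def forward(self, f: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        m = self.attention(f, train)
        h = f * m
        self._cache = (f, m) if train else None
        return h, m

    def backward(self, dh: np.ndarray) -> np.ndarray:
        f, m = self._cache
        df = dh * m
        dm = (dh * f).sum(axis=1, keepdims=True)
        df += self.conv.backward(self.sigmoid.backward(dm))
        self._cache = None
        return df


def apply_attention(feature_maps: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """Weight every channel of ``feature_maps`` by the spatial attention map.

    ``feature_maps`` has shape (C, h, w, d) and ``attention`` (h, w, d);
    returns H with ``H[c, i] = F[c, i] * M[i]``.
    """
    feature_maps = np.asarray(feature_maps)
    attention = np.asarray(attention)
    if feature_maps.shape[-3:] != attention.shape:
        raise ValueError(
            f"spatial shape mismatch: features {feature_maps.shape[-3:]} vs map {attention.shape}")
    return feature_maps * attention[None]


def residual_block(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Run one residual block on a single (C, h, w, d) feature stack."""
    return block.forward(np.asarray(x, dtype=DTYPE)[None], train=False)[0]


def compute_attention_map(x_pre: np.ndarray, module: AttentionModule) -> np.ndarray:
    """Attention map for a single (C, h, w, d) feature stack; values in (0, 1)."""
    return module.attention(np.asarray(x_pre, dtype=DTYPE)[None], train=False)[0, 0]


class AttentionNet3D:
    """The assembled network; holds layers and the train/inference passes."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = spec.block_channels
        self.stem = Conv3d(1, spec.stem_channels, 3, rng=rng,
                           needs_input_grad=False)
        self.stem_bn = BatchNorm3d(spec.stem_channels)
        self.stem_relu = ReLU()
        self.stage1 = [ResidualBlock(spec.stem_channels, c1, rng),
                       ResidualBlock(c1, c1, rng)]
        self.pool1 = AvgPool3d(spec.pool_kernel, spec.pool_stride)
        self.stage2 = [ResidualBlock(c1, c2, rng), ResidualBlock(c2, c2, rng)]
        self.stage3 = [ResidualBlock(c2, c3, rng), ResidualBlock(c3, c3, rng)]
        self.pool2 = AvgPool3d(spec.pool_kernel, spec.pool_stride)
        self.stage4 = [ResidualBlock(c3, c4, rng), ResidualBlock(c4, c4, rng)]
        self.attention = AttentionModule(c4, spec.attention_kernel, rng) if spec.with_attention else None
        self.gap = GlobalAvgPool3d()
        self.fc = Linear(c4, spec.n_classes, rng=rng)

    @property
    def blocks(self) -> list[ResidualBlock]:
        return self.stage1 + self.stage2 + self.stage3 + self.stage4

    def layers(self) -> list:
        out = [self.stem, self.stem_bn, self.stem_relu]
        for b in self.blocks:
            out += b.layers()
        if self.attention is not None:
            out += self.attention.layers()
        out += [self.pool1, self.pool2, self.gap, self.fc]
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray | None]:
        """Return (logits, attention map) for a batch (N, 1, H, W, D).

        The attention map has shape (N, h, w, d) on the post-pooling grid,
        or is None for the attention-free baseline.
        """
        if x.shape[2:] != tuple(self.spec.in_shape):
            raise ValueError(f"input shape {x.shape[2:]} != spec in_shape {self.spec.in_shape}")
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for b in self.stage1:
            h = b.forward(h, train)
        h = self.pool1.forward(h, train)
        for b in self.stage2 + self.stage3:
            h = b.forward(h, train)
        h = self.pool2.forward(h, train)
        for b in self.stage4:
            h = b.forward(h, train)
        if self.attention is not None:
            h, m = self.attention.forward(h, train)
            att = m[:, 0]
        else:
            att = None
        pooled = self.gap.forward(h, train)
        logits = self.fc.forward(pooled, train)
        return logits, att

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.gap.backward(self.fc.backward(dlogits))
        if self.attention is not None:
            dh = self.attention.backward(dh)
        for b in reversed(self.stage4):
            dh = b.backward(dh)
        dh = self.pool2.backward(dh)
        for b in reversed(self.stage2 + self.stage3):
            dh = b.backward(dh)
        dh = self.pool1.backward(dh)
        for b in reversed(self.stage1):
            dh = b.backward(dh)
        dh = self.stem_relu.backward(dh)
        dh = self.stem_bn.backward(dh)
        self.stem.backward(dh)

    # --- serialization -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, ly in enumerate(self.layers()):
            for k, v in ly.params.items():
                state[f"p{i}_{k}"] = v
            if isinstance(ly, BatchNorm3d):
                state[f"p{i}_running_mean"] = ly.running_mean
                state[f"p{i}_running_var"] = ly.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, ly in enumerate(self.layers()):
            for k in ly.params:
                ly.params[k] = np.array(state[f"p{i}_{k}"])
            if isinstance(ly, BatchNorm3d):
                ly.running_mean = np.array(state[f"p{i}_running_mean"])
                ly.running_var = np.array(state[f"p{i}_running_var"])


def save_model(net: AttentionNet3D, path, classes=None) -> None:
    """Single-file archive holding the architecture spec and all parameters.

    ``classes`` optionally records the class labels a classifier was fitted
    with, so the score-column order survives the round trip.
    """
    spec = net.spec
    meta = dict(in_shape=list(spec.in_shape), stem_channels=spec.stem_channels,
                block_channels=list(spec.block_channels), n_classes=spec.n_classes,
                attention_kernel=spec.attention_kernel, pool_kernel=spec.pool_kernel,
                pool_stride=spec.pool_stride, with_attention=spec.with_attention)
    buf = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    extra = {}
    if classes is not None:
        extra["__classes__"] = np.asarray(classes, dtype="U32")
    np.savez(path, __spec__=buf, **extra, **net.state_arrays())


def load_classes(path) -> np.ndarray:
    """Class labels stored in a checkpoint (see :func:`save_model`)."""
    with np.load(path) as data:
        if "__classes__" not in data.files:
            raise ValueError(f"{path} stores no class labels")
        return np.array(data["__classes__"])


def load_model(path) -> AttentionNet3D:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__spec__"]).decode())
        spec = NetworkSpec(in_shape=tuple(meta["in_shape"]),
                           stem_channels=meta["stem_channels"],
                           block_channels=tuple(meta["block_channels"]),
                           attention_kernel=meta["attention_kernel"],
                           pool_kernel=meta["pool_kernel"],
                           pool_stride=meta["pool_stride"],
                           n_classes=meta["n_classes"],
                           with_attention=bool(meta["with_attention"]))
        net = AttentionNet3D(spec)
        net.load_state_arrays({k: data[k] for k in data.files
                               if not k.startswith("__")})
    return net
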