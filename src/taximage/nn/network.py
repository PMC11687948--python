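"""Residual CNN with per-block spatial attention.

Each residual block runs the eight-stage sequence: convolution,
batch-normalization, activation, convolution, batch-normalization, spatial
attention, identity (shortcut addition), activation.  The shortcut is the
block input, passed through a strided 1x1 projection + batch-norm whenever
the channel count or stride changes the shape.  The network is a stem
convolution, the residual blocks in order, global average pooling, and a
linear softmax head.  Architecture is specified as a plain list of
(n_filters, kernel_size, stride) block specs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    Param,
    ReLU,
    SpatialAttention,
)

__all__ = ["BlockSpec", "ResidualBlock", "AttentionCNN", "build_model", "softmax"]


@dataclass(frozen=True)
class BlockSpec:
    n_filters: int
    kernel_size: int
    stride: int = 1

    def __post_init__(self):
        if self.n_filters < 1 or self.stride < 1:
            raise ValueError(f"invalid block spec {self}")
        if self.kernel_size < 1 or self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd and positive: {self}")


STAGE_SEQUENCE = (
    "conv",
    "batchnorm",
    "activation",
    "conv",
    "batchnorm",
    "spatial_attention",
    "identity_add",
    "activation",
)


class ResidualBlock:
    def __init__(self, in_channels, spec: BlockSpec, rng, attention_kernel=7, name="block"):
        f, k, s = spec.n_filters, spec.kernel_size, spec.stride
        self.spec = spec
        self.conv1 = Conv2d(in_channels, f, k, stride=s, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(f, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(f, f, k, stride=1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(f, name=f"{name}.bn2")
        self.attention = SpatialAttention(attention_kernel, rng=rng, name=f"{name}.attn")
        self.relu_out = ReLU()
        if in_channels != f or s != 1:
            self.proj = Conv2d(in_channels, f, 1, stride=s, rng=rng, name=f"{name}.proj")
            self.proj_bn = BatchNorm2d(f, name=f"{name}.proj_bn")
        else:
            self.proj = None
            self.proj_bn = None

    def params(self):
        ps = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
            + self.attention.params()
        )
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def out_size(self, h, w):
        return self.conv1.out_size(h, w)

    def forward(self, x, train=False, trace=None):
        h = self.conv1.forward(x, train)
        _note(trace, "conv")
        h = self.bn1.forward(h, train)
        _note(trace, "batchnorm")
        h = self.relu1.forward(h, train)
        _note(trace, "activation")
        h = self.conv2.forward(h, train)
        _note(trace, "conv")
        h = self.bn2.forward(h, train)
        _note(trace, "batchnorm")
        h = self.attention.forward(h, train)
        _note(trace, "spatial_attention")
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            shortcut = x
        h = h + shortcut
        _note(trace, "identity_add")
        out = self.relu_out.forward(h, train)
        _note(trace, "activation")
        return out

    def backward(self, dout):
        dsum = self.relu_out.backward(dout)
        dmain = self.attention.backward(dsum)
        dmain = self.bn2.backward(dmain)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dx = self.conv1.backward(dmain)
        if self.proj is not None:
            dshort = self.proj_bn.backward(dsum)
            dx = dx + self.proj.backward(dshort)
        else:
            dx = dx + dsum
        return dx


def _note(trace, stage):
    if trace is not None:
        trace.append(stage)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AttentionCNN:
    """Stem conv -> residual attention blocks -> GAP -> linear softmax head."""

    def __init__(
        self,
        blocks: list[BlockSpec],
        n_classes: int,
        height: int,
        width: int,
        seed: int = 0,
        attention_kernel: int = 7,
    ):
        if not blocks:
            raise ValueError("need at least one block spec")
        if n_classes < 2:
            raise ValueError("need at least two classes")
        blocks = [b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in blocks]
        rng = np.random.default_rng(seed)
        self.block_specs = blocks
        self.input_shape = (height, width)
        self.n_classes = n_classes
        self.seed = seed

        stem_channels = blocks[0].n_filters
        self.stem = Conv2d(1, stem_channels, 3, stride=1, rng=rng, name="stem")
        self.stem_bn = BatchNorm2d(stem_channels, name="stem_bn")
        self.stem_relu = ReLU()

        h, w = height, width
        self.blocks: list[ResidualBlock] = []
        in_ch = stem_channels
        for i, spec in enumerate(blocks):
            block = ResidualBlock(
                in_ch, spec, rng, attention_kernel=attention_kernel, name=f"block{i}"
            )
            h, w = block.out_size(h, w)
            if h < 1 or w < 1:
                raise ValueError(
                    f"block {i} ({spec}) collapses spatial dims below 1x1"
                )
            self.blocks.append(block)
            in_ch = spec.n_filters
        self.feature_shape = (in_ch, h, w)
        self.pool = GlobalAvgPool()
        self.head = Linear(in_ch, n_classes, rng=rng)
        self.is_trained = False
        # input view, fixed at training time and applied inside forward so
        # prediction, saliency and occlusion all see the identical transform:
        # an optional concave rescale ("sqrt") that lifts low-abundance pixels
        # while keeping zeros at zero, then optional per-pixel standardization
        self.input_transform: str = "none"
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

        # populated on each forward/backward (used by Grad-CAM)
        self.block_outputs: list[np.ndarray] = []
        self.block_output_grads: list[np.ndarray | None] = []

    # --- parameters -----------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> dict[str, np.ndarray]:
        s = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._batchnorms()):
            s[f"_running_mean_{i}"] = bn.running_mean.copy()
            s[f"_running_var_{i}"] = bn.running_var.copy()
        if self.input_mean is not None:
            s["_input_mean"] = self.input_mean.copy()
            s["_input_std"] = self.input_std.copy()
        s["_input_transform"] = np.array(self.input_transform)
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"_running_mean_{i}"]
            bn.running_var[...] = state[f"_running_var_{i}"]
        if "_input_mean" in state:
            self.input_mean = state["_input_mean"].copy()
            self.input_std = state["_input_std"].copy()
        if "_input_transform" in state:
            self.input_transform = str(state["_input_transform"])

    def _batchnorms(self):
        bns = [self.stem_bn]
        for b in self.blocks:
            bns += [b.bn1, b.bn2] + ([b.proj_bn] if b.proj_bn is not None else [])
        return bns

    # --- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, trace: list | None = None):
        """x: (N, 1, H, W) -> logits (N, n_classes); block outputs cached."""
        if x.ndim == 3:
            x = x[:, None]
        if self.input_transform == "sqrt":
            x = np.sqrt(np.maximum(x, 0.0))
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_std
        h = self.stem.forward(x, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        self.block_outputs = []
        for block in self.blocks:
            block_trace = [] if trace is not None else None
            h = block.forward(h, train, trace=block_trace)
            if trace is not None:
                trace.append(block_trace)
            self.block_outputs.append(h)
        pooled = self.pool.forward(h, train)
        return self.head.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Propagate from logits; records gradients at every block output."""
        d = self.head.backward(dlogits)
        d = self.pool.backward(d)
        self.block_output_grads = [None] * len(self.blocks)
        for i in range(len(self.blocks) - 1, -1, -1):
            self.block_output_grads[i] = d
            d = self.blocks[i].backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        return self.stem.backward(d)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        if images.ndim == 2:
            images = images[None]
        out = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(images[start : start + batch_size], train=False)
            out.append(softmax(logits))
        return np.vstack(out)

    def layer_trace(self, x: np.ndarray) -> list[list[str]]:
        """Stage names executed per block during one forward pass."""
        trace: list[list[str]] = []
        self.forward(x, train=False, trace=trace)
        return trace


def build_model(
    blocks, n_classes: int, height: int, width: int, seed: int = 0, attention_kernel: int = 7
) -> AttentionCNN:
    """Construct an untrained network from a list of block specs."""
    return AttentionCNN(
        blocks, n_classes, height, width, seed=seed, attention_kernel=attention_kernel
    )
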