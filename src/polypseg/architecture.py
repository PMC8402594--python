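"""Construction and inspection of the modified SegNet VGG-19 networks.

The family has three depth variants — ``small`` (3 encoder depths, 100
primitive layers), ``proposed`` (5 depths, 154 layers) and ``large`` (7
depths, 208 layers). Relative to plain SegNet VGG-19 the modifications are:

* two extra 5x5 convolution blocks appended at encoder depths 1-2 and
  prepended at the mirrored decoder depths,
* a parameter-free skip merge from every encoder depth's pre-pool output to
  the matching decoder depth's input (addition by default; concatenation is
  available),
* a parallel pyramid of four dilated 3x3 convolution blocks (dilations 1, 6,
  12, 18) at the encoder bottleneck, concatenated along channels and
  projected back to the bottleneck width by a 1x1 convolution block.

Every convolution block is convolution + batch-norm + ReLU. Max pooling
records argmax indices which the mirrored max-unpooling layer scatters back
to, so the decoder recovers exact spatial positions without learned
upsampling.

The primitive-layer counting convention treats each convolution, batch-norm,
activation, pooling, unpooling, concatenation, merge, the input, the softmax
and the pixel-classification output as one layer each; it reproduces the
published totals 100/154/208.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import functional as F
from .specs import DILATION_SET, ArchitectureSpec, variant_spec

__all__ = [
    "FeatureMap",
    "PooledFeature",
    "ModelSummary",
    "SegmentationNetwork",
    "build_model",
    "conv_block",
    "pool_with_indices",
    "unpool_with_indices",
    "dilated_pyramid",
    "skip_merge",
    "count_trainable_parameters",
    "closed_form_parameter_count",
    "count_layers",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """A rank-3 (channels, height, width) activation map."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap requires a (C, H, W) array")
        if not np.isfinite(self.values).all():
            raise ValueError("FeatureMap values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def resolution(self) -> Tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class PooledFeature:
    """A pooled map plus the argmax indices its pooling produced."""

    pooled: FeatureMap
    indices: np.ndarray  # flat row-major positions in the pre-pool map
    pre_pool_size: Tuple[int, int]


@dataclass
class ModelSummary:
    trainable_parameter_count: int
    layer_count: int
    per_block_parameter_table: List[Tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trainable_parameter_count": self.trainable_parameter_count,
            "layer_count": self.layer_count,
            "per_block_parameter_table": [
                list(row) for row in self.per_block_parameter_table],
        }


# ---------------------------------------------------------------------------
# standalone operations (single-sample, (C, H, W) maps)
# ---------------------------------------------------------------------------

def conv_block(x: FeatureMap, weight: np.ndarray, bias: np.ndarray,
               dilation: int = 1,
               norm: Optional[Tuple[np.ndarray, np.ndarray]] = None
               ) -> FeatureMap:
    """One convolution block: ReLU(batch-norm(conv(x) + bias)).

    ``norm`` is an optional (mean, std) pair used to normalise the convolved
    map before the affine-free ReLU; passing None applies the identity
    normalisation (useful for hand-checkable examples). Same padding keeps
    the resolution.
    """
    weight = np.asarray(weight, dtype=np.float32)
    if weight.shape[1] != x.channels:
        raise ValueError(
            f"channel mismatch: input has {x.channels}, kernel expects "
            f"{weight.shape[1]}")
    out = F.conv2d(x.values[None], weight, np.asarray(bias, dtype=np.float32),
                   dilation=dilation)[0]
    if norm is not None:
        mean, std = norm
        out = (out - np.asarray(mean)[:, None, None]) / \
            np.asarray(std)[:, None, None]
    return FeatureMap(F.relu(out))


def pool_with_indices(x: FeatureMap) -> PooledFeature:
    """2x2/stride-2 max pooling recording argmax positions (row-major
    first-occurrence tie-break)."""
    if x.values.size == 0:
        raise ValueError("cannot pool an empty feature map")
    pooled, idx = F.maxpool2x2(x.values[None])
    return PooledFeature(pooled=FeatureMap(pooled[0]), indices=idx[0],
                         pre_pool_size=x.resolution)


def unpool_with_indices(p: PooledFeature) -> FeatureMap:
    """Scatter each pooled value back to its stored index; zeros elsewhere."""
    out = F.maxunpool2x2(p.pooled.values[None], p.indices[None],
                         p.pre_pool_size)
    return FeatureMap(out[0])


def skip_merge(encoder_feature: FeatureMap, decoder_feature: FeatureMap,
               mode: str = "add") -> FeatureMap:
    """Merge an encoder tap into the decoder path; no trainable parameters."""
    if encoder_feature.resolution != decoder_feature.resolution:
        raise ValueError("skip merge requires matching spatial resolution")
    if mode == "add":
        if encoder_feature.channels != decoder_feature.channels:
            raise ValueError("additive skip merge requires matching channels")
        return FeatureMap(encoder_feature.values + decoder_feature.values)
    if mode == "concat":
        return FeatureMap(np.concatenate(
            [encoder_feature.values, decoder_feature.values], axis=0))
    raise ValueError(f"unknown skip merge mode {mode!r}")


def dilated_pyramid(x: FeatureMap,
                    branch_params: Sequence[Tuple[np.ndarray, np.ndarray]],
                    projection_params: Tuple[np.ndarray, np.ndarray],
                    dilations: Sequence[int] = DILATION_SET) -> FeatureMap:
    """Four parallel dilated convolution blocks, concatenated and projected.

    Each branch is same-padded (padding equals its dilation for the 3x3
    kernels) so the resolution survives; the concatenation is projected back
    to a decoder-compatible width by a final convolution block.
    """
    if tuple(dilations) != DILATION_SET:
        raise ValueError(f"dilation set must be {list(DILATION_SET)}")
    if len(branch_params) != len(DILATION_SET):
        raise ValueError("one (weight, bias) pair per dilation is required")
    branches = [conv_block(x, w, b, dilation=l)
                for (w, b), l in zip(branch_params, dilations)]
    stacked = FeatureMap(np.concatenate([br.values for br in branches], axis=0))
    return conv_block(stacked, *projection_params)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

class SegmentationNetwork(nn.NetworkGraph):
    """A built variant; forward() accepts any (N, 3, H, W) batch and returns
    per-pixel 2-class probabilities at the same H x W.

    Inputs whose sides are not divisible by 2**depths are zero-padded on the
    bottom/right before the encoder and the output map is cropped back, so
    resolution preservation holds for every input.
    """

    def __init__(self, spec: ArchitectureSpec):
        super().__init__()
        self.spec = spec
        self.pool_multiple = 2 ** spec.depths
        self._crop: Optional[Tuple[int, int]] = None

    def _pad_batch(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        m = self.pool_multiple
        ph = (-h) % m
        pw = (-w) % m
        self._crop = (h, w)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        out = super().forward(self._pad_batch(x), training=training)
        h, w = self._crop
        return out[:, :, :h, :w]

    def backward(self, grad_out: np.ndarray, from_logits: bool = False) -> None:
        h, w = self._crop
        m = self.pool_multiple
        ph = (-h) % m
        pw = (-w) % m
        if ph or pw:
            grad_out = np.pad(grad_out, ((0, 0), (0, 0), (0, ph), (0, pw)))
        super().backward(grad_out, from_logits=from_logits)


def _add_block(g: nn.NetworkGraph, name: str, src: str, cin: int, cout: int,
               kernel: int, dilation: int = 1) -> str:
    g.add(nn.Conv2d(f"{name}_conv", [src], cin, cout, kernel, dilation))
    g.add(nn.BatchNorm2d(f"{name}_bn", [f"{name}_conv"], cout))
    g.add(nn.ReLU(f"{name}_relu", [f"{name}_bn"]))
    return f"{name}_relu"


def build_model(spec: ArchitectureSpec) -> SegmentationNetwork:
    """Build the full encoder-decoder graph for one variant."""
    spec.validate()
    g = SegmentationNetwork(spec)
    g.add(nn.Input("input"))
    cur = "input"
    cin = 3
    skip_taps: List[str] = []
    pools: List[nn.MaxPool2d] = []

    # encoder
    for d, cout in enumerate(spec.encoder_channels, start=1):
        for i, k in enumerate(spec.encoder_kernels(d - 1), start=1):
            cur = _add_block(g, f"enc_d{d}_b{i}", cur, cin, cout, k)
            cin = cout
        skip_taps.append(cur)
        pool = nn.MaxPool2d(f"pool_d{d}", [cur])
        g.add(pool)
        pools.append(pool)
        cur = pool.name

    # dilated-convolution pyramid at the bottleneck
    bottleneck = spec.bottleneck_channels
    branch_ch = spec.branch_channels
    branch_outs = []
    for l in spec.dilation_set:
        branch_outs.append(_add_block(g, f"pyramid_l{l}", cur, bottleneck,
                                      branch_ch, kernel=3, dilation=l))
    g.add(nn.Concat("pyramid_concat", branch_outs))
    cur = _add_block(g, "pyramid_proj", "pyramid_concat",
                     len(spec.dilation_set) * branch_ch, bottleneck,
                     kernel=spec.pyramid_projection_kernel)

    # decoder: exact mirror, fed by unpooling, skip-merged per depth
    for d in range(spec.depths, 0, -1):
        c_d = spec.encoder_channels[d - 1]
        c_next = spec.encoder_channels[d - 2] if d > 1 else spec.num_classes
        g.add(nn.MaxUnpool2d(f"unpool_d{d}", [cur], pools[d - 1]))
        if spec.skip_merge_mode == "add":
            g.add(nn.Add(f"merge_d{d}", [f"unpool_d{d}", skip_taps[d - 1]]))
            cin = c_d
        else:
            g.add(nn.Concat(f"merge_d{d}", [f"unpool_d{d}", skip_taps[d - 1]]))
            cin = 2 * c_d
        cur = f"merge_d{d}"
        kernels = list(reversed(spec.encoder_kernels(d - 1)))
        for i, k in enumerate(kernels, start=1):
            cout = c_next if i == len(kernels) else c_d
            cur = _add_block(g, f"dec_d{d}_b{i}", cur, cin, cout, k)
            cin = cout

    g.add(nn.Softmax("softmax", [cur]))
    g.add(nn.PixelClassification("pixel_classification", ["softmax"]))
    return g


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def count_layers(graph: nn.NetworkGraph) -> int:
    """Primitive-layer count: every node of the graph is one layer."""
    return len(graph)


def count_trainable_parameters(graph: nn.NetworkGraph) -> ModelSummary:
    """Walk the graph summing declared trainable tensors, grouped per
    convolution block (a block's batch-norm is tallied with its convolution)."""
    table: Dict[str, int] = {}
    for layer in graph:
        n = layer.n_params()
        if n == 0:
            continue
        block = layer.name
        for suffix in ("_conv", "_bn"):
            if block.endswith(suffix):
                block = block[: -len(suffix)]
        table[block] = table.get(block, 0) + n
    total = graph.n_parameters()
    assert total == sum(table.values())
    return ModelSummary(trainable_parameter_count=total,
                        layer_count=count_layers(graph),
                        per_block_parameter_table=sorted(table.items()))


def closed_form_parameter_count(spec: ArchitectureSpec) -> int:
    """Independent accounting: sum over convolutions of k_h*k_w*C_in*C_out
    + C_out, plus 2*C_out per batch-norm, computed from the plan arithmetic
    without building any layer."""

    def block(k: int, cin: int, cout: int) -> int:
        return k * k * cin * cout + cout + 2 * cout

    total = 0
    cin = 3
    for d in range(spec.depths):
        cout = spec.encoder_channels[d]
        for k in spec.encoder_kernels(d):
            total += block(k, cin, cout)
            cin = cout
    D = spec.bottleneck_channels
    B = spec.branch_channels
    total += len(spec.dilation_set) * block(3, D, B)
    total += block(spec.pyramid_projection_kernel, len(spec.dilation_set) * B, D)
    for d in range(spec.depths, 0, -1):
        c_d = spec.encoder_channels[d - 1]
        c_next = spec.encoder_channels[d - 2] if d > 1 else spec.num_classes
        cin = 2 * c_d if spec.skip_merge_mode == "concat" else c_d
        kernels = list(reversed(spec.encoder_kernels(d - 1)))
        for i, k in enumerate(kernels, start=1):
            cout = c_next if i == len(kernels) else c_d
            total += block(k, cin, cout)
            cin = cout
    return total


def model_summary(variant: str, **overrides) -> ModelSummary:
    """Convenience: build a named variant and summarise it."""
    return count_trainable_parameters(build_model(variant_spec(variant,
                                                               **overrides)))
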