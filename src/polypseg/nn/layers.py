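"""Primitive network layers.

Each layer is one node of a :class:`~polypseg.nn.graph.NetworkGraph` and
corresponds to exactly one countable primitive (convolution, batch-norm,
activation, pooling, unpooling, merge, softmax, ...). Trainable tensors are
declared by shape and allocated lazily, so a graph can be built and its
parameters counted without touching hundreds of megabytes of weights.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import functional as F


class Layer:
    """Base node: ``inputs`` are the names of upstream layers."""

    #: layers with trainable parameters map param name -> shape
    param_shapes: Dict[str, Tuple[int, ...]]

    def __init__(self, name: str, inputs: Sequence[str]):
        self.name = name
        self.inputs = list(inputs)
        self.param_shapes = {}
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}
        self._cache = None

    # -- parameters -------------------------------------------------------
    def n_params(self) -> int:
        return sum(int(np.prod(s)) for s in self.param_shapes.values())

    def initialize(self, rng: np.random.Generator) -> None:
        """Allocate parameters (He-style for conv kernels)."""
        for pname, shape in self.param_shapes.items():
            self.params[pname] = self._init_param(pname, shape, rng)

    def _init_param(self, pname, shape, rng):
        return np.zeros(shape, dtype=np.float32)

    # -- execution --------------------------------------------------------
    def forward(self, xs: List[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> List[np.ndarray]:
        """Return one gradient per input; fill ``self.grads`` for params."""
        raise NotImplementedError


class Input(Layer):
    def __init__(self, name="input"):
        super().__init__(name, [])

    def forward(self, xs, training):
        return xs[0]

    def backward(self, gout):
        return []


class Conv2d(Layer):
    def __init__(self, name, inputs, in_channels, out_channels,
                 kernel_size=3, dilation=1):
        super().__init__(name, inputs)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.param_shapes = {
            "weight": (out_channels, in_channels, kernel_size, kernel_size),
            "bias": (out_channels,),
        }

    def _init_param(self, pname, shape, rng):
        if pname == "weight":
            fan_in = self.in_channels * self.kernel_size ** 2
            std = math.sqrt(2.0 / fan_in)
            return rng.normal(0.0, std, size=shape).astype(np.float32)
        return np.zeros(shape, dtype=np.float32)

    def forward(self, xs, training):
        out, xp = F.conv2d(xs[0], self.params["weight"], self.params["bias"],
                           dilation=self.dilation, return_cache=True)
        self._cache = xp if training else None
        return out

    def backward(self, gout):
        gx, gw, gb = F.conv2d_backward(gout, self._cache,
                                       self.params["weight"], self.dilation)
        self.grads = {"weight": gw, "bias": gb}
        return [gx]


class BatchNorm2d(Layer):
    """Batch normalisation; scale and shift are the two trainable tensors."""

    def __init__(self, name, inputs, channels, momentum=0.1, eps=1e-5):
        super().__init__(name, inputs)
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.param_shapes = {"gamma": (channels,), "beta": (channels,)}
        # running statistics: state, not trainable, not counted
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def _init_param(self, pname, shape, rng):
        if pname == "gamma":
            return np.ones(shape, dtype=np.float32)
        return np.zeros(shape, dtype=np.float32)

    def forward(self, xs, training):
        y, cache = F.batchnorm(xs[0], self.params["gamma"], self.params["beta"],
                               self.running_mean, self.running_var,
                               training, self.momentum, self.eps)
        self._cache = cache
        return y

    def backward(self, gout):
        gx, gg, gb = F.batchnorm_backward(gout, self._cache,
                                          self.params["gamma"])
        self.grads = {"gamma": gg, "beta": gb}
        return [gx]


class ReLU(Layer):
    def forward(self, xs, training):
        out = F.relu(xs[0])
        self._cache = out if training else None
        return out

    def backward(self, gout):
        return [F.relu_backward(gout, self._cache)]


class MaxPool2d(Layer):
    """2x2/stride-2 max pooling; keeps argmax indices for the paired unpool."""

    def __init__(self, name, inputs):
        super().__init__(name, inputs)
        self.last_indices: Optional[np.ndarray] = None
        self.last_pre_size: Optional[Tuple[int, int]] = None

    def forward(self, xs, training):
        x = xs[0]
        pooled, idx = F.maxpool2x2(x)
        self.last_indices = idx
        self.last_pre_size = (x.shape[2], x.shape[3])
        return pooled

    def backward(self, gout):
        h, w = self.last_pre_size
        gx = F.maxunpool2x2(gout, self.last_indices, (h, w))
        return [gx]


class MaxUnpool2d(Layer):
    """Scatters values to the argmax positions recorded by ``pool_layer``."""

    def __init__(self, name, inputs, pool_layer: MaxPool2d):
        super().__init__(name, inputs)
        self.pool_layer = pool_layer

    def forward(self, xs, training):
        idx = self.pool_layer.last_indices
        size = self.pool_layer.last_pre_size
        if idx is None:
            raise RuntimeError(
                f"unpool layer {self.name!r} ran before its pool layer")
        self._cache = idx
        return F.maxunpool2x2(xs[0], idx, size)

    def backward(self, gout):
        return [F.maxunpool2x2_backward(gout, self._cache)]


class Add(Layer):
    """Parameter-free elementwise merge (the additive skip connection)."""

    def forward(self, xs, training):
        a, b = xs
        if a.shape != b.shape:
            raise ValueError(
                f"skip merge shape mismatch at {self.name!r}: "
                f"{a.shape} vs {b.shape}")
        return a + b

    def backward(self, gout):
        return [gout, gout]


class Concat(Layer):
    """Channel concatenation (the skip-merge alternative and the pyramid join)."""

    def forward(self, xs, training):
        shapes = {x.shape[2:] for x in xs}
        if len(shapes) > 1:
            raise ValueError(f"concat resolution mismatch at {self.name!r}")
        self._cache = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, gout):
        splits = np.cumsum(self._cache)[:-1]
        return list(np.split(gout, splits, axis=1))


class Softmax(Layer):
    def forward(self, xs, training):
        out = F.softmax_channels(xs[0])
        self._cache = out if training else None
        return out

    def backward(self, gout):
        # Gradient through channel softmax; the trainer normally bypasses
        # this by supplying the combined softmax+cross-entropy gradient.
        p = self._cache
        return [p * (gout - (gout * p).sum(axis=1, keepdims=True))]


class PixelClassification(Layer):
    """Terminal layer: per-pixel class decision (argmax of the distribution).

    Forward passes the probabilities through unchanged so the graph output
    remains differentiable; :meth:`labels` gives the hard segmentation.
    """

    def forward(self, xs, training):
        return xs[0]

    def backward(self, gout):
        return [gout]

    @staticmethod
    def labels(probs: np.ndarray) -> np.ndarray:
        return probs.argmax(axis=1)
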