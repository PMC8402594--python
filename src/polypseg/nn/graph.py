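"""The layer graph: an acyclic, single-input/single-output network.

Layers are stored in topological order (construction order); execution walks
the list forward, backpropagation walks it in reverse, accumulating gradients
where a layer's output fans out (skip connections).
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from .layers import Input, Layer, PixelClassification, Softmax


class NetworkGraph:
    def __init__(self):
        self.layers: List[Layer] = []
        self._by_name: Dict[str, Layer] = {}
        self._initialized = False

    # -- construction -----------------------------------------------------
    def add(self, layer: Layer) -> Layer:
        if layer.name in self._by_name:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        for dep in layer.inputs:
            if dep not in self._by_name:
                raise ValueError(
                    f"layer {layer.name!r} depends on unknown layer {dep!r}")
        self.layers.append(layer)
        self._by_name[layer.name] = layer
        return layer

    def __getitem__(self, name: str) -> Layer:
        return self._by_name[name]

    def __iter__(self) -> Iterator[Layer]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    # -- parameters -------------------------------------------------------
    def initialize(self, seed: int = 0) -> "NetworkGraph":
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.initialize(rng)
        self._initialized = True
        return self

    def parameters(self) -> Iterator[Tuple[str, str, np.ndarray]]:
        for layer in self.layers:
            for pname, arr in layer.params.items():
                yield layer.name, pname, arr

    def n_parameters(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    # -- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the graph on a (N, C, H, W) batch; returns the final output."""
        if not self._initialized:
            self.initialize()
        outputs: Dict[str, np.ndarray] = {}
        for layer in self.layers:
            if isinstance(layer, Input):
                outputs[layer.name] = layer.forward([x], training)
            else:
                xs = [outputs[d] for d in layer.inputs]
                outputs[layer.name] = layer.forward(xs, training)
        self._outputs = outputs if training else None
        return outputs[self.layers[-1].name]

    def backward(self, grad_out: np.ndarray, from_logits: bool = False) -> None:
        """Backpropagate ``grad_out`` from the terminal layer.

        With ``from_logits=True`` the gradient is taken with respect to the
        softmax *input* (the combined softmax+cross-entropy gradient), and the
        softmax / pixel-classification layers are skipped — the numerically
        stable route used in training.
        """
        if self._outputs is None:
            raise RuntimeError("backward() requires forward(training=True)")
        grads: Dict[str, np.ndarray] = {}
        start = len(self.layers) - 1
        if from_logits:
            while isinstance(self.layers[start], (Softmax, PixelClassification)):
                start -= 1
        grads[self.layers[start].name] = grad_out
        for k in range(start, -1, -1):
            layer = self.layers[k]
            g = grads.pop(layer.name, None)
            if g is None:
                continue
            gins = layer.backward(g)
            for dep, gi in zip(layer.inputs, gins):
                if dep in grads:
                    grads[dep] = grads[dep] + gi
                else:
                    grads[dep] = gi

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard per-pixel labels for a (N, C, H, W) batch."""
        return PixelClassification.labels(self.forward(x, training=False))

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Single-file weight archive (.npz) with running BN statistics."""
        arrays = {}
        for layer in self.layers:
            for pname, arr in layer.params.items():
                arrays[f"{layer.name}/{pname}"] = arr
            if hasattr(layer, "running_mean"):
                arrays[f"{layer.name}/running_mean"] = layer.running_mean
                arrays[f"{layer.name}/running_var"] = layer.running_var
        np.savez(path, **arrays)

    def load(self, path) -> "NetworkGraph":
        with np.load(path) as data:
            for layer in self.layers:
                for pname, shape in layer.param_shapes.items():
                    arr = data[f"{layer.name}/{pname}"]
                    if tuple(arr.shape) != tuple(shape):
                        raise ValueError(
                            f"checkpoint shape mismatch at {layer.name}/{pname}")
                    layer.params[pname] = arr
                if hasattr(layer, "running_mean"):
                    layer.running_mean = data[f"{layer.name}/running_mean"]
                    layer.running_var = data[f"{layer.name}/running_var"]
        self._initialized = True
        return self
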