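"""Sequential network container with gradient capture at interior layers.

The container is deliberately small: forward, backward, and a
``backward_to`` variant that stops at a named layer and returns the
gradient of a scalar output with respect to that layer's *output*
activations — the quantity Grad-CAM averages into channel weights.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, Layer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True,
                capture: bool = False):
        """Run the net; with ``capture`` also return per-layer outputs."""
        acts = []
        for layer in self.layers:
            x = layer.forward(x, train=train)
            if capture:
                acts.append(x)
        return (x, acts) if capture else x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def conv_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if isinstance(l, Conv2D)]

    def backward_to(self, grad: np.ndarray, layer_index: int) -> np.ndarray:
        """Backpropagate ``grad`` (w.r.t. final output) down to the output
        of ``self.layers[layer_index]`` and return it without going
        further. Requires a preceding ``forward(..., train=True)``."""
        if not 0 <= layer_index < len(self.layers) - 1:
            raise ValueError(f"layer_index {layer_index} out of range")
        for layer in reversed(self.layers[layer_index + 1:]):
            grad = layer.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))
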