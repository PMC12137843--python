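"""Grad-CAM saliency for the compact CNNs.

Classification: channel weights are spatial means of the class-score
gradient over a convolutional feature layer A,

    alpha_k^c = (1/Z) * sum_ij  d y_c / d A_ij^k,

and the map is the rectified weighted sum sum_k alpha_k^c A^k.

Regression uses a modified target. With x the predicted modulus and x'
the AFM-measured modulus, define d = 1 / |x - x'| and take

    alpha_k = (1/Z) * sum_ij  d d / d A_ij^k,
    dd/dA = (dd/dx) (dx/dA).

When x > x' (overestimate), dd/dx = -1/(x - x')^2 < 0 and the map marks
regions whose activation would *decrease* the output; when x < x' it
marks regions that would *increase* it. The mode is recorded alongside
the map; the signed map is kept and its absolute value offered for
display, since rectification conventions differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .models import StiffnessClassifier, StiffnessRegressor, _check_input
from .nn import Conv2D
from .synthetic import CellImage


@dataclass
class GradCAMContext:
    x: float  # model output (Pa for regression, class score otherwise)
    x_prime: float | None  # measured modulus (regression only)
    d: float | None  # 1/|x - x'|
    mode: str  # "decrease" | "increase" | "class:<c>"


@dataclass
class SaliencyMap:
    alpha: np.ndarray  # per-channel weights, length = channel count
    map: np.ndarray  # feature-layer-resolution spatial map
    Z: int  # spatial size of the feature layer

    def upsampled(self, shape=(50, 50)) -> np.ndarray:
        """Bilinear upsampling of the map to input resolution."""
        return resize(self.map.astype(float), shape, order=1,
                      preserve_range=True)

    def normalized(self) -> np.ndarray:
        """Map rescaled to [0, 1]; an all-zero map stays zero."""
        m = self.map.astype(float)
        lo, hi = m.min(), m.max()
        if hi - lo < 1e-30:
            return np.zeros_like(m)
        return (m - lo) / (hi - lo)


def _resolve_conv_layer(net, layer_index: int | None) -> int:
    conv_idx = net.conv_indices()
    if not conv_idx:
        raise ValueError("network has no convolutional layer")
    if layer_index is None:
        return conv_idx[-1]  # standard choice: last conv layer
    if not isinstance(net.layers[layer_index], Conv2D):
        raise ValueError(f"layer {layer_index} is not convolutional")
    return layer_index


def _feature_grad(net, x: np.ndarray, layer_index: int,
                  out_grad: np.ndarray):
    """Forward one input, return (feature activations A, dOut/dA)."""
    _, acts = net.forward(x, train=True, capture=True)
    grad = net.backward_to(out_grad, layer_index)
    return acts[layer_index][0], grad[0]  # drop batch axis


def _weights_and_map(a: np.ndarray, grad: np.ndarray):
    z = a.shape[0] * a.shape[1]
    alpha = grad.mean(axis=(0, 1))  # (1/Z) sum_ij
    cam = np.tensordot(a, alpha, axes=([2], [0]))
    return alpha, cam, z


def gradcam_classification(model: StiffnessClassifier, image,
                           class_c: int = 1,
                           layer_index: int | None = None) -> SaliencyMap:
    """Saliency for class ``class_c`` (default: stiff) at a conv layer.

    The class score is the pre-softmax logit; the returned map is the
    rectified weighted activation sum at feature-layer resolution.
    """
    x = _as_input(image)
    idx = _resolve_conv_layer(model.net, layer_index)
    n_out = model.spec.n_classes
    if not 0 <= class_c < n_out:
        raise IndexError(f"class {class_c} out of range")
    out_grad = np.zeros((1, n_out))
    out_grad[0, class_c] = 1.0
    a, grad = _feature_grad(model.net, x, idx, out_grad)
    alpha, cam, z = _weights_and_map(a, grad)
    return SaliencyMap(alpha=alpha, map=np.maximum(cam, 0.0), Z=z)


def gradcam_regression_modified(model: StiffnessRegressor, image,
                                x_prime: float,
                                layer_index: int | None = None,
                                ) -> tuple[SaliencyMap, GradCAMContext]:
    """Modified Grad-CAM against the measured modulus ``x_prime`` (Pa).

    Returns the signed saliency map plus the context (x, x', d, mode).
    Exact equality x == x' makes d undefined and raises.
    """
    x_in = _as_input(image)
    idx = _resolve_conv_layer(model.net, layer_index)

    raw = model.raw_output(x_in)  # scalar internal-scale output
    x = float(model._decode_output(raw)[0])
    if x == x_prime:
        raise ZeroDivisionError(
            "predicted value equals measured value: d = 1/|x - x'| undefined")
    diff = x - x_prime
    d = 1.0 / abs(diff)
    dd_dx = -np.sign(diff) / diff ** 2
    # chain through the internal target transform: x = decode(raw)
    if model.spec.log_target:
        dx_draw = math.log(10.0) * model.target_scale * x
    else:
        dx_draw = model.target_scale
    out_grad = np.array([[dd_dx * dx_draw]])
    a, grad = _feature_grad(model.net, x_in, idx, out_grad)
    alpha, cam, z = _weights_and_map(a, grad)
    mode = "decrease" if x > x_prime else "increase"
    ctx = GradCAMContext(x=x, x_prime=float(x_prime), d=float(d), mode=mode)
    return SaliencyMap(alpha=alpha, map=cam, Z=z), ctx


def overlay_heatmap(sal: SaliencyMap, image, alpha_blend: float = 0.45,
                    use_abs: bool = False) -> np.ndarray:
    """Alpha-blend a jet-colored saliency map onto the grayscale input.

    Returns an (H, W, 3) uint8 rendering; deterministic for fixed inputs.
    """
    from matplotlib import colormaps

    g = image.grayscale if isinstance(image, CellImage) else np.asarray(image)
    if g.ndim == 3:
        g = g[..., 0]
    m = np.abs(sal.map) if use_abs else sal.map
    lo, hi = float(m.min()), float(m.max())
    norm = np.zeros_like(m, dtype=float) if hi - lo < 1e-30 \
        else (m - lo) / (hi - lo)
    heat = resize(norm, g.shape, order=1, preserve_range=True)
    if heat.shape != g.shape:
        raise ValueError("saliency map incompatible with image shape")
    rgb_heat = colormaps["jet"](heat)[..., :3]
    base = np.repeat((g.astype(float) / 255.0)[..., None], 3, axis=-1)
    if hi - lo < 1e-30:
        blended = base  # all-zero map: show the plain image
    else:
        blended = (1 - alpha_blend) * base + alpha_blend * rgb_heat
    return np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)


def _as_input(image) -> np.ndarray:
    if isinstance(image, CellImage):
        from .preprocessing import normalize_intensity, resize_crop
        return _check_input(normalize_intensity(resize_crop(image)).values)
    return _check_input(image)
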