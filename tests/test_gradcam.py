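"""Grad-CAM: channel weights, the modified regression target
d = 1/|x - x'|, and the decrease/increase sign rule."""

import numpy as np
import pytest

from cellstiff.gradcam import (gradcam_classification,
                               gradcam_regression_modified, overlay_heatmap)
from cellstiff.models import (ClassifierSpec, RegressorSpec, _check_input,
                              build_classifier, build_regressor)


@pytest.fixture(scope="module")
def toy_regressor():
    m = build_regressor(RegressorSpec(seed=3))
    m.target_mean, m.target_scale = 2.9, 0.3
    return m


@pytest.fixture(scope="module")
def toy_input():
    return np.random.default_rng(3).uniform(-1, 1, size=(50, 50))


class TestModifiedRegressionGradCAM:
    def test_d_and_mode_overestimate(self, toy_regressor, toy_input):
        _, ctx = gradcam_regression_modified(toy_regressor, toy_input,
                                             x_prime=ctx_target(
                                                 toy_regressor, toy_input, -1))
        assert ctx.x > ctx.x_prime
        assert ctx.mode == "decrease"
        assert ctx.d == pytest.approx(1.0 / abs(ctx.x - ctx.x_prime))

    def test_d_and_mode_underestimate(self, toy_regressor, toy_input):
        _, ctx = gradcam_regression_modified(toy_regressor, toy_input,
                                             x_prime=ctx_target(
                                                 toy_regressor, toy_input, +1))
        assert ctx.x < ctx.x_prime
        assert ctx.mode == "increase"

    def test_d_invariant_under_swap(self, toy_regressor, toy_input):
        _, lo = gradcam_regression_modified(
            toy_regressor, toy_input,
            x_prime=ctx_target(toy_regressor, toy_input, -1))
        delta = lo.x - lo.x_prime
        _, hi = gradcam_regression_modified(toy_regressor, toy_input,
                                            x_prime=lo.x + delta)
        assert lo.d == pytest.approx(hi.d, rel=1e-12)
        assert {lo.mode, hi.mode} == {"decrease", "increase"}

    def test_exact_equality_rejected(self, toy_regressor, toy_input):
        from cellstiff.models import predict_modulus
        x_pred = float(predict_modulus(
            toy_regressor, _check_input(toy_input))[0])
        with pytest.raises(ZeroDivisionError):
            gradcam_regression_modified(toy_regressor, toy_input, x_pred)

    def test_alpha_matches_finite_differences(self, toy_regressor,
                                              toy_input):
        """alpha_k = (1/Z) sum_ij dd/dA via backprop equals a central
        finite-difference estimate on the feature activations."""
        m, x = toy_regressor, toy_input
        x_prime = 900.0
        sal, _ = gradcam_regression_modified(m, x, x_prime)
        idx = m.net.conv_indices()[-1]
        xin = _check_input(x)
        _, acts = m.net.forward(xin, train=True, capture=True)
        a0 = acts[idx]
        z = a0.shape[1] * a0.shape[2]

        def d_with_bump(k, eps):
            h = xin
            for i, layer in enumerate(m.net.layers):
                h = layer.forward(h, train=False)
                if i == idx:
                    bump = np.zeros_like(h)
                    bump[..., k] = eps
                    h = h + bump
            val = float(m._decode_output(h[:, 0])[0])
            return 1.0 / abs(val - x_prime)

        eps = 1e-5
        for k in range(min(4, len(sal.alpha))):
            num = (d_with_bump(k, eps) - d_with_bump(k, -eps)) / (2 * eps) / z
            assert sal.alpha[k] == pytest.approx(num, rel=1e-3)


class TestClassificationGradCAM:
    def test_constant_output_gives_zero_map(self):
        model = build_classifier(ClassifierSpec(seed=0))
        final = model.net.layers[-1]
        final.W[...] = 0.0
        final.b[...] = 0.0
        sal = gradcam_classification(model,
                                     np.zeros((50, 50)), class_c=1)
        assert np.all(sal.map == 0.0)
        assert np.all(sal.normalized() == 0.0)

    def test_map_nonnegative_and_normalized(self, toy_input):
        model = build_classifier(ClassifierSpec(seed=1))
        sal = gradcam_classification(model, toy_input, class_c=1)
        assert np.all(sal.map >= 0.0)
        norm = sal.normalized()
        assert norm.min() >= 0.0 and norm.max() <= 1.0

    def test_alpha_length_and_Z(self, toy_input):
        model = build_classifier(ClassifierSpec(seed=1))
        sal = gradcam_classification(model, toy_input)
        assert len(sal.alpha) == model.spec.conv_filters[-1]
        assert sal.Z == sal.map.shape[0] * sal.map.shape[1]

    def test_bad_class_and_layer_rejected(self, toy_input):
        model = build_classifier(ClassifierSpec(seed=1))
        with pytest.raises(IndexError):
            gradcam_classification(model, toy_input, class_c=5)
        with pytest.raises(ValueError):
            gradcam_classification(model, toy_input, layer_index=1)  # ReLU

    def test_upsampled_shape(self, toy_input):
        model = build_classifier(ClassifierSpec(seed=1))
        sal = gradcam_classification(model, toy_input)
        assert sal.upsampled((50, 50)).shape == (50, 50)


class TestOverlay:
    def test_zero_map_returns_plain_rendering(self, toy_input):
        model = build_classifier(ClassifierSpec(seed=0))
        final = model.net.layers[-1]
        final.W[...] = 0.0
        final.b[...] = 0.0
        img = (255 * np.random.default_rng(0).uniform(
            size=(50, 50))).astype(np.uint8)
        sal = gradcam_classification(model, toy_input)
        out = overlay_heatmap(sal, img)
        expected = np.repeat((img / 255.0)[..., None], 3, -1)
        np.testing.assert_array_equal(
            out, np.clip(np.round(expected * 255), 0, 255).astype(np.uint8))

    def test_deterministic_bytes(self, toy_input):
        model = build_classifier(ClassifierSpec(seed=1))
        sal = gradcam_classification(model, toy_input)
        img = (255 * (toy_input / 2 + 0.5)).astype(np.uint8)
        a = overlay_heatmap(sal, img)
        b = overlay_heatmap(sal, img)
        assert a.shape == (50, 50, 3)
        assert np.array_equal(a, b)


def ctx_target(model, x, direction):
    """A measured modulus strictly below (-1) or above (+1) the model's
    prediction, offset by 20%."""
    from cellstiff.models import predict_modulus
    pred = float(predict_modulus(model, _check_input(x))[0])
    return pred * (1.0 + 0.2 * direction)
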