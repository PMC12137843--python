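"""Compact CNNs for stiffness classification and regression.

The classifier is a small convolutional stack (ReLU hidden activations,
softmax output, categorical cross-entropy, Adam at lr 1e-5) whose
stiff-class output probability serves downstream as a continuous
"stiffness range". The regressor has a fixed census — one 3x3
convolution, two 2x2 pooling layers, and two fully-connected layers with
a linear scalar output — trained with MSE.

Regression targets are standardized log10-moduli internally: with Adam
the per-step parameter motion is bounded by the learning rate, so a raw
output head cannot reach targets of magnitude 10^2–10^3 Pa at lr 1e-5 in
any reasonable number of steps. The affine transform is stored on the
model and inverted at prediction time, so the public interface speaks
pascals throughout and the loss remains MSE (on the internal scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.losses import mean_squared_error, softmax, softmax_cross_entropy

INPUT_SIDE = 50


@dataclass
class ClassifierSpec:
    conv_filters: tuple = (16, 32)  # one 3x3 conv + 2x2 maxpool per entry
    dense_units: tuple = (64,)
    n_classes: int = 2
    lr: float = 1e-5
    seed: int = 0


@dataclass
class RegressorSpec:
    """Fixed architecture: 1 conv (3x3), 2 pools (2x2), 2 dense layers."""

    conv_filters: int = 8
    dense_units: int = 32
    lr: float = 1e-5
    seed: int = 0
    log_target: bool = True  # train on standardized log10(Pa)
    allow_nonstandard: bool = False


@dataclass
class TrainingRecord:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    epochs: int = 0
    batch_size: int = 32
    seed: int = 0


class StiffnessClassifier:
    """Wrapper pairing a Sequential net with its spec and optimizer."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        layers: list[nn.Layer] = []
        side, ch = INPUT_SIDE, 1
        for f in spec.conv_filters:
            layers += [nn.Conv2D(ch, f, 3, rng=rng), nn.ReLU(),
                       nn.MaxPool2D(2)]
            ch = f
            side //= 2
        layers.append(nn.Flatten())
        width = side * side * ch
        for u in spec.dense_units:
            layers += [nn.Dense(width, u, rng=rng), nn.ReLU()]
            width = u
        layers.append(nn.Dense(width, spec.n_classes, rng=rng))
        self.net = nn.Sequential(layers)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(_check_input(x), train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x))


class StiffnessRegressor:
    """Scalar-output CNN predicting Young's modulus in Pa."""

    def __init__(self, spec: RegressorSpec):
        if not spec.allow_nonstandard and (
                spec.conv_filters <= 0 or spec.dense_units <= 0):
            raise ValueError("invalid regressor spec")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        f = spec.conv_filters
        side = INPUT_SIDE // 4  # two 2x2 pools: 50 -> 25 -> 12
        # census: 1 conv, 2 pools, 2 dense
        self.net = nn.Sequential([
            nn.Conv2D(1, f, 3, rng=rng), nn.ReLU(),
            nn.MaxPool2D(2), nn.MaxPool2D(2),
            nn.Flatten(),
            nn.Dense(side * side * f, spec.dense_units, rng=rng), nn.ReLU(),
            nn.Dense(spec.dense_units, 1, rng=rng),
        ])
        # affine target transform (identity until fitted)
        self.target_mean = 0.0
        self.target_scale = 1.0

    def layer_census(self) -> dict:
        counts = {"conv": 0, "pool": 0, "dense": 0}
        for layer in self.net.layers:
            if isinstance(layer, nn.Conv2D):
                counts["conv"] += 1
            elif isinstance(layer, nn.MaxPool2D):
                counts["pool"] += 1
            elif isinstance(layer, nn.Dense):
                counts["dense"] += 1
        return counts

    def _encode_target(self, modulus_pa: np.ndarray) -> np.ndarray:
        t = np.log10(modulus_pa) if self.spec.log_target else modulus_pa
        return (t - self.target_mean) / self.target_scale

    def _decode_output(self, raw: np.ndarray) -> np.ndarray:
        t = raw * self.target_scale + self.target_mean
        return 10.0 ** t if self.spec.log_target else t

    def fit_target_transform(self, modulus_pa: np.ndarray) -> None:
        t = np.log10(modulus_pa) if self.spec.log_target else modulus_pa
        self.target_mean = float(np.mean(t))
        self.target_scale = float(max(np.std(t), 1e-9))

    def raw_output(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(_check_input(x), train=train)[:, 0]

    def predict_modulus(self, x: np.ndarray, clip_at_zero: bool = True
                        ) -> np.ndarray:
        pred = self._decode_output(self.raw_output(x))
        if np.any(pred < 0):
            warnings.warn("negative predicted moduli", stacklevel=2)
            if clip_at_zero:
                pred = np.maximum(pred, 0.0)
        return pred


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:  # single (50, 50) image
        x = x[None, ..., None]
    elif x.ndim == 3:
        if x.shape[:2] == (INPUT_SIDE, INPUT_SIDE) and x.shape[2] in (1, 3):
            x = x[None]  # single image with channel axis
        else:
            x = x[..., None]  # (N, 50, 50) batch
    if x.ndim != 4 or x.shape[1:3] != (INPUT_SIDE, INPUT_SIDE):
        raise ValueError(f"expected (N,{INPUT_SIDE},{INPUT_SIDE},1) inputs, "
                         f"got {x.shape}")
    if x.shape[3] == 3:  # channel-replicated grayscale
        x = x[..., :1]
    return x


def build_classifier(spec: ClassifierSpec | None = None) -> StiffnessClassifier:
    return StiffnessClassifier(spec or ClassifierSpec())


def build_regressor(spec: RegressorSpec | None = None) -> StiffnessRegressor:
    return StiffnessRegressor(spec or RegressorSpec())


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_model(model, x_train, y_train, x_val=None, y_val=None,
                epochs: int = 100, batch_size: int = 32, seed: int = 0,
                early_stopping: bool = True, patience: int = 10,
                verbose: bool = False):
    """Train a classifier (integer labels: 1 = stiff) or regressor
    (targets in Pa) with Adam; returns ``(model, TrainingRecord)``.

    Deterministic for a fixed seed. Early stopping monitors validation
    loss and restores the best weights. A NaN loss aborts with a
    diagnostic rather than continuing silently.
    """
    x_train = _check_input(x_train)
    y_train = np.asarray(y_train)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(x_train) != len(y_train):
        raise ValueError("inputs and targets must align")
    has_val = x_val is not None and len(x_val) > 0
    if has_val:
        x_val = _check_input(x_val)
        y_val = np.asarray(y_val)

    is_classifier = isinstance(model, StiffnessClassifier)
    if is_classifier:
        n_classes = model.spec.n_classes
        y_train_enc = _onehot(y_train.astype(int), n_classes)
        y_val_enc = _onehot(y_val.astype(int), n_classes) if has_val else None
    else:
        if np.any(y_train <= 0):
            raise ValueError("moduli must be positive Pa values")
        model.fit_target_transform(y_train)
        y_train_enc = model._encode_target(y_train.astype(float))
        y_val_enc = model._encode_target(y_val.astype(float)) if has_val \
            else None

    opt = nn.Adam(model.net.params(), lr=model.spec.lr)
    rng = np.random.default_rng(seed)
    record = TrainingRecord(batch_size=batch_size, seed=seed)
    best_val = np.inf
    best_weights = None
    stale = 0

    def eval_loss(x, y_enc, y_raw):
        out = model.net.forward(x, train=False)
        if is_classifier:
            loss, _ = softmax_cross_entropy(out, y_enc)
            acc = float(np.mean(out.argmax(1) == y_raw.astype(int)))
        else:
            loss, _ = mean_squared_error(out[:, 0], y_enc)
            acc = float("nan")
        return float(loss), acc

    n = len(x_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        # training loss/accuracy tracked as running averages over the
        # minibatches of the epoch (no extra full-set forward pass)
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            out = model.net.forward(x_train[idx], train=True)
            if is_classifier:
                loss, grad = softmax_cross_entropy(out, y_train_enc[idx])
                correct += int(np.sum(out.argmax(1)
                                      == y_train.astype(int)[idx]))
            else:
                loss, grad = mean_squared_error(out[:, 0], y_train_enc[idx])
                grad = grad[:, None]
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            loss_sum += float(loss) * len(idx)
            model.net.zero_grad()
            model.net.backward(grad)
            opt.step()

        record.train_loss.append(loss_sum / n)
        record.train_accuracy.append(correct / n if is_classifier
                                     else float("nan"))
        if has_val:
            va_loss, va_acc = eval_loss(x_val, y_val_enc, y_val)
            record.val_loss.append(va_loss)
            record.val_accuracy.append(va_acc)
            if early_stopping:
                if va_loss < best_val - 1e-9:
                    best_val = va_loss
                    best_weights = [p.copy() for p, _ in model.net.params()]
                    stale = 0
                else:
                    stale += 1
                    if stale > patience:
                        break
        if verbose:
            msg = f"epoch {epoch + 1}: train_loss={tr_loss:.4f}"
            if has_val:
                msg += f" val_loss={record.val_loss[-1]:.4f}"
            print(msg)
    record.epochs = len(record.train_loss)
    if best_weights is not None:
        for (p, _), w in zip(model.net.params(), best_weights):
            p[...] = w
    return model, record


def predict_proba(model: StiffnessClassifier, inputs) -> np.ndarray:
    """Per-input class probability pairs, order preserved."""
    return model.predict_proba(inputs)


def predict_modulus(model: StiffnessRegressor, inputs) -> np.ndarray:
    """Per-input predicted Young's modulus in Pa."""
    return model.predict_modulus(inputs)
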