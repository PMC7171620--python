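"""Neural-network engine that runs one code path on plain and encrypted scalars.

Layers are restricted to the operations the MORE scheme supports without
plaintext branching: dense and 3x3 same-padded convolutions (weighted sums),
2x2 average pooling (no comparisons, unlike max pooling), sigmoid/tanh
activations evaluated on ciphertext eigenvalues, softmax built from encrypted
exp and division, and inverted dropout driven by a *plaintext* Bernoulli mask
stream (multiplying a ciphertext by a plain 0 or 1/(1-rate) is a scalar
operation).  Training is plain minibatch SGD with momentum for a fixed number
of epochs -- an encrypted loss cannot feed a stopping rule, because a
ciphertext cannot be used in a conditional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crypto, engine
from .engine import CIPHER, PLAIN, Tensor

__all__ = [
    "Dense",
    "Conv2D",
    "AvgPool",
    "Flatten",
    "Dropout",
    "Activation",
    "ModelSpec",
    "TrainConfig",
    "ParameterSet",
    "cnn_mnist",
    "fcnn_wbc",
    "cnn_angio",
    "xavier_init",
    "encrypt_parameters",
    "decrypt_parameters",
    "forward",
    "loss_and_output_grad",
    "backward",
    "sgd_momentum_step",
    "train",
    "predict",
]


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dense:
    units: int
    kind: str = "dense"


@dataclass(frozen=True)
class Conv2D:
    """3x3 kernels, stride 1, zero "same" padding (the only variant used)."""

    filters: int
    kind: str = "conv2d"


@dataclass(frozen=True)
class AvgPool:
    """2x2 window, stride 2."""

    kind: str = "avgpool"


@dataclass(frozen=True)
class Flatten:
    kind: str = "flatten"


@dataclass(frozen=True)
class Dropout:
    rate: float = 0.25
    kind: str = "dropout"


@dataclass(frozen=True)
class Activation:
    fn: str  # sigmoid | tanh | linear | softmax
    kind: str = "activation"


LayerSpec = Dense | Conv2D | AvgPool | Flatten | Dropout | Activation


@dataclass
class ModelSpec:
    input_shape: tuple
    layers: list
    name: str = "custom"

    def output_shapes(self) -> list:
        """Per-layer output shapes (excluding the batch axis)."""
        shape = tuple(self.input_shape)
        out = []
        for layer in self.layers:
            if layer.kind == "dense":
                if len(shape) != 1:
                    raise ValueError("dense layer needs a flat input")
                shape = (layer.units,)
            elif layer.kind == "conv2d":
                if len(shape) != 3:
                    raise ValueError("conv2d needs a (C, H, W) input")
                shape = (layer.filters, shape[1], shape[2])
            elif layer.kind == "avgpool":
                c, h, w = shape
                if h % 2 or w % 2:
                    raise ValueError("avgpool needs even spatial dimensions")
                shape = (c, h // 2, w // 2)
            elif layer.kind == "flatten":
                shape = (int(np.prod(shape)),)
            # dropout / activation keep the shape
            out.append(shape)
        return out

    @property
    def output_shape(self) -> tuple:
        return self.output_shapes()[-1]


def cnn_mnist(scale: float = 1.0) -> ModelSpec:
    """Digit-classification CNN: 8/16-filter conv stack, 100-unit dense head,
    softmax over 10 classes.  ``scale`` shrinks filter/unit counts for
    desk-scale experiments (1.0 reproduces the reference topology)."""
    f1, f2, u = max(1, round(8 * scale)), max(1, round(16 * scale)), max(10, round(100 * scale))
    return ModelSpec(
        input_shape=(1, 28, 28),
        layers=[
            Conv2D(f1), Activation("sigmoid"), AvgPool(),
            Conv2D(f2), Activation("sigmoid"), AvgPool(),
            Flatten(),
            Dense(u), Activation("sigmoid"),
            Dense(10), Activation("softmax"),
        ],
        name="CNN-MNIST",
    )


def fcnn_wbc(n_inputs: int = 9, hidden: int = 40, n_outputs: int = 12) -> ModelSpec:
    """Hemodynamic-regression FCNN: three 40-unit hidden layers
    (tanh, tanh, sigmoid) and a linear 12-output head."""
    return ModelSpec(
        input_shape=(n_inputs,),
        layers=[
            Dense(hidden), Activation("tanh"),
            Dense(hidden), Activation("tanh"),
            Dense(hidden), Activation("sigmoid"),
            Dense(n_outputs), Activation("linear"),
        ],
        name="FCNN-WBC",
    )


def cnn_angio(size: int = 256) -> ModelSpec:
    """Angiographic view classifier: four conv/pool stages (4-32 filters),
    64-unit dense layer, 25% dropout, sigmoid output.  ``size`` sets the
    square input resolution (256 reproduces the reference topology)."""
    return ModelSpec(
        input_shape=(1, size, size),
        layers=[
            Conv2D(4), Activation("sigmoid"), AvgPool(),
            Conv2D(8), Activation("tanh"), AvgPool(),
            Conv2D(16), Activation("tanh"), AvgPool(),
            Conv2D(32), Activation("tanh"), AvgPool(),
            Flatten(),
            Dense(64), Activation("tanh"),
            Dropout(0.25),
            Dense(1), Activation("sigmoid"),
        ],
        name="CNN-Angio",
    )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Per-layer weights/biases plus momentum velocity buffers."""

    layers: list  # entry per model layer: dict(W=Tensor, b=Tensor) or None
    kind: str = PLAIN
    velocities: list = field(default_factory=list)

    def init_velocities(self):
        self.velocities = [
            None if entry is None else {k: engine.zeros(t.shape, t.kind) for k, t in entry.items()}
            for entry in self.layers
        ]

    def copy(self) -> "ParameterSet":
        ps = ParameterSet(
            layers=[None if e is None else {k: t.copy() for k, t in e.items()} for e in self.layers],
            kind=self.kind,
        )
        ps.init_velocities()
        return ps


def xavier_init(spec: ModelSpec, seed: int) -> ParameterSet:
    """Uniform draws in [-L, L], L = sqrt(6/(fan_in + fan_out)); biases zero.

    Convolution fans count kernel taps: fan = 3*3*channels.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.input_shape)
    layers = []
    for layer in spec.layers:
        if layer.kind == "dense":
            n_in, n_out = shape[0], layer.units
            L = np.sqrt(6.0 / (n_in + n_out))
            W = rng.uniform(-L, L, size=(n_in, n_out))
            layers.append({"W": engine.from_plain(W), "b": engine.from_plain(np.zeros(n_out))})
            shape = (n_out,)
        elif layer.kind == "conv2d":
            c = shape[0]
            fan_in, fan_out = 9 * c, 9 * layer.filters
            L = np.sqrt(6.0 / (fan_in + fan_out))
            K = rng.uniform(-L, L, size=(layer.filters, c, 9))
            layers.append(
                {"W": engine.from_plain(K), "b": engine.from_plain(np.zeros(layer.filters))}
            )
            shape = (layer.filters, shape[1], shape[2])
        else:
            layers.append(None)
            if layer.kind == "avgpool":
                shape = (shape[0], shape[1] // 2, shape[2] // 2)
            elif layer.kind == "flatten":
                shape = (int(np.prod(shape)),)
    ps = ParameterSet(layers=layers, kind=PLAIN)
    ps.init_velocities()
    return ps


def encrypt_parameters(params: ParameterSet, key, config) -> ParameterSet:
    out = ParameterSet(
        layers=[
            None
            if e is None
            else {k: engine.encrypt_tensor(t, key, config) for k, t in e.items()}
            for e in params.layers
        ],
        kind=CIPHER,
    )
    out.init_velocities()
    return out


def decrypt_parameters(params: ParameterSet, key) -> ParameterSet:
    out = ParameterSet(
        layers=[
            None if e is None else {k: engine.decrypt_tensor(t, key) for k, t in e.items()}
            for e in params.layers
        ],
        kind=PLAIN,
    )
    out.init_velocities()
    return out


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _softmax(z: Tensor) -> Tensor:
    e = engine.apply_fn("exp", z)
    s = engine.fsum(e, axis=1, keepdims=True)
    return engine.div(e, s)


def forward(spec: ModelSpec, params: ParameterSet, batch: Tensor, train_mode: bool = False,
            dropout_rng: np.random.Generator | None = None, dropout_rate: float | None = None):
    """Run the network; returns (output, caches) with per-layer records."""
    if batch.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"batch shape {batch.shape[1:]} does not match model input {spec.input_shape}"
        )
    x = batch
    caches = []
    for layer, entry in zip(spec.layers, params.layers):
        cache = {"in": x}
        if layer.kind == "dense":
            x = engine.dense_forward(x, entry["W"], entry["b"])
        elif layer.kind == "conv2d":
            patches = engine.conv_patches(x)
            cache["patches"] = patches
            x = engine.conv_forward(patches, entry["W"], entry["b"])
        elif layer.kind == "avgpool":
            x = engine.avgpool_forward(x)
        elif layer.kind == "flatten":
            x = x.reshape(x.shape[0], int(np.prod(x.shape[1:])))
        elif layer.kind == "dropout":
            if train_mode:
                rate = layer.rate if dropout_rate is None else dropout_rate
                if dropout_rng is None:
                    raise ValueError("train-mode dropout needs a mask stream")
                mask = (dropout_rng.random(x.shape) >= rate) / (1.0 - rate)
                cache["mask"] = mask
                x = engine.mul_plain(x, mask)
            # inference: identity
        elif layer.kind == "activation":
            if layer.fn == "linear":
                pass
            elif layer.fn == "softmax":
                x = _softmax(x)
            else:
                x = engine.apply_fn(layer.fn, x)
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        cache["out"] = x
        caches.append(cache)
    return x, caches


def loss_and_output_grad(loss: str, y_pred: Tensor, y_true):
    """Loss value and gradient at the network output.

    Returns (loss_tensor, grad_tensor, skip_last_activation).  Losses are
    summed over the minibatch (per-sample losses add; the epoch log divides
    by the sample count for readability).  For CE+softmax and BCE+sigmoid
    the combined simplification grad = (yhat - y) is used, so the gradient
    is taken at the *pre-activation* of the final layer and the final
    activation's backward step is skipped.  MSE uses the 1/(2n) convention
    (n = number of outputs) with grad (yhat - y)/n.  The target may stay
    plaintext even when predictions are ciphertext.
    """
    y_vals = y_true.values if isinstance(y_true, Tensor) else np.asarray(y_true, dtype=float)
    diff = engine.sub_mixed(y_pred, y_true)
    if loss == "mse":
        n = int(np.prod(y_pred.shape[1:]))
        sq = engine.mul(diff, diff)
        loss_t = engine.mul_plain(engine.total(sq), 1.0 / (2.0 * n))
        grad = engine.mul_plain(diff, 1.0 / n)
        return loss_t, grad, False
    if loss == "ce":
        if y_pred.kind == PLAIN and not (isinstance(y_true, Tensor) and y_true.kind == CIPHER):
            # 0*log(0) := 0 so a perfect one-hot prediction scores exactly 0
            safe = np.where(y_vals != 0.0, y_pred.values, 1.0)
            loss_t = Tensor(np.asarray(-np.sum(y_vals * np.log(safe))), PLAIN)
            return loss_t, diff, True
        logp = engine.apply_fn("log", y_pred)
        if isinstance(y_true, Tensor) and y_true.kind == CIPHER:
            term = engine.mul(y_true, logp)
        else:
            term = engine.mul_plain(logp, y_vals)
        loss_t = engine.mul_plain(engine.total(term), -1.0)
        return loss_t, diff, True
    if loss == "bce":
        logp = engine.apply_fn("log", y_pred)
        one_minus = engine.add_plain(engine.neg(y_pred), 1.0)
        log1m = engine.apply_fn("log", one_minus)
        if isinstance(y_true, Tensor) and y_true.kind == CIPHER:
            raise ValueError("binary targets are kept plaintext")
        t1 = engine.mul_plain(logp, y_vals)
        t2 = engine.mul_plain(log1m, 1.0 - y_vals)
        loss_t = engine.mul_plain(engine.total(engine.add(t1, t2)), -1.0)
        return loss_t, diff, True
    raise ValueError(f"unknown loss {loss!r}")


def backward(spec: ModelSpec, params: ParameterSet, caches, output_grad: Tensor,
             skip_last_activation: bool = False) -> list:
    """Chain-rule gradients; identical code path for both scalar kinds."""
    if len(caches) != len(spec.layers):
        raise ValueError("caches do not match the model layers")
    grads = [None] * len(spec.layers)
    g = output_grad
    start = len(spec.layers) - 1
    if skip_last_activation:
        last = spec.layers[-1]
        if last.kind != "activation":
            raise ValueError("combined loss gradient expects a final activation layer")
        start -= 1
    for idx in range(start, -1, -1):
        layer = spec.layers[idx]
        cache = caches[idx]
        entry = params.layers[idx]
        if layer.kind == "dense":
            grads[idx] = {
                "W": engine.dense_backward_w(cache["in"], g),
                "b": engine.fsum(g, axis=0),
            }
            g = engine.dense_backward_x(g, entry["W"])
        elif layer.kind == "conv2d":
            grads[idx] = {
                "W": engine.conv_backward_k(cache["patches"], g),
                "b": Tensor(
                    g.values.sum(axis=(0, 2, 3)), g.kind
                ),
            }
            g = engine.conv_backward_x(g, entry["W"], cache["in"].shape[1])
        elif layer.kind == "avgpool":
            g = engine.avgpool_backward(g)
        elif layer.kind == "flatten":
            g = g.reshape(*cache["in"].shape)
        elif layer.kind == "dropout":
            if "mask" in cache:
                g = engine.mul_plain(g, cache["mask"])
        elif layer.kind == "activation":
            a = cache["out"]
            if layer.fn == "linear":
                pass
            elif layer.fn == "sigmoid":
                one_minus = engine.add_plain(engine.neg(a), 1.0)
                g = engine.mul(g, engine.mul(a, one_minus))
            elif layer.fn == "tanh":
                one_minus_sq = engine.add_plain(engine.neg(engine.mul(a, a)), 1.0)
                g = engine.mul(g, one_minus_sq)
            else:
                raise ValueError(
                    "softmax backward is only reachable through the combined CE gradient"
                )
    return grads


def sgd_momentum_step(params: ParameterSet, grads: list, lr: float, mu: float) -> None:
    """v <- mu*v - lr*g;  w <- w + v  (in place, elementwise, both kinds)."""
    if not params.velocities:
        params.init_velocities()
    for entry, gentry, ventry in zip(params.layers, grads, params.velocities):
        if entry is None:
            continue
        for k in entry:
            v = ventry[k]
            v.values *= mu
            v.values -= lr * gentry[k].values
            entry[k].values += v.values


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    loss: str = "mse"  # mse | ce | bce
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 100
    shuffle_seed: int = 0
    dropout_seed: int = 1
    dropout_rate: float | None = None  # None -> layer default


def train(spec: ModelSpec, inputs: Tensor, targets, config: TrainConfig,
          params: ParameterSet | None = None, monitor_key=None):
    """Minibatch SGD with momentum for a fixed number of epochs.

    The shuffle and dropout mask streams are seeded and *plaintext*, so a
    ciphertext run and a plaintext run sharing seeds and initial parameters
    follow exactly the same dataflow; their decrypted parameters agree up to
    floating-point reordering error.  Returns (params, per-epoch mean loss
    list); with encrypted data the losses are decrypted when ``monitor_key``
    is supplied, otherwise the raw 2x2 loss blocks are recorded.
    """
    if params is None:
        if inputs.kind == CIPHER:
            raise ValueError("encrypted training needs pre-encrypted initial parameters")
        params = xavier_init(spec, seed=config.shuffle_seed)
    if params.kind != inputs.kind:
        raise ValueError("parameter and input scalar kinds must match")
    n = inputs.shape[0]
    shuffle_rng = np.random.default_rng(config.shuffle_seed)
    dropout_rng = np.random.default_rng(config.dropout_seed)
    losses = []
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0 if inputs.kind == PLAIN else np.zeros((2, 2))
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = Tensor(inputs.values[idx], inputs.kind)
            if isinstance(targets, Tensor):
                yb = Tensor(targets.values[idx], targets.kind)
            else:
                yb = np.asarray(targets)[idx]
            y_pred, caches = forward(
                spec, params, xb, train_mode=True,
                dropout_rng=dropout_rng, dropout_rate=config.dropout_rate,
            )
            loss_t, grad, skip = loss_and_output_grad(config.loss, y_pred, yb)
            grads = backward(spec, params, caches, grad, skip)
            sgd_momentum_step(params, grads, config.learning_rate, config.momentum)
            epoch_loss = epoch_loss + loss_t.values
        mean_loss = epoch_loss / n
        if inputs.kind == CIPHER:
            if monitor_key is not None:
                mean_loss = float(crypto.decrypt_array(mean_loss[None], monitor_key)[0])
            losses.append(mean_loss)
        else:
            losses.append(float(mean_loss))
    return params, losses


def predict(spec: ModelSpec, params: ParameterSet, inputs: Tensor, batch_size: int = 256) -> Tensor:
    """Forward pass without dropout; outputs are ciphertexts when inputs are."""
    outs = []
    for lo in range(0, inputs.shape[0], batch_size):
        xb = Tensor(inputs.values[lo : lo + batch_size], inputs.kind)
        y, _ = forward(spec, params, xb, train_mode=False)
        outs.append(y.values)
    return Tensor(np.concatenate(outs, axis=0), inputs.kind)
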