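"""Minimal NumPy neural-network core for the joint latent-space model.

Implements exactly what the model needs and nothing more: dense layers
with Glorot-uniform initialisation, batch normalisation, inverted
dropout, ReLU/sigmoid activations, a softmax + cross-entropy head, and
an RMSprop optimizer.  All randomness (initialisation, dropout masks)
flows through a single ``numpy.random.Generator`` so training is
bit-reproducible from one seed.

Layer blocks follow the order dense -> batch-norm -> activation ->
dropout on hidden layers; output layers are a plain dense with their
output activation (sigmoid for the latent code and the reconstruction,
softmax for the class head).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

# Keras-compatible numerics so behaviour matches the common framework defaults.
_BN_MOMENTUM = 0.99
_BN_EPS = 1e-3
_RMS_RHO = 0.9
_RMS_EPS = 1e-7


class Layer:
    """Base layer: stateless unless it declares params/grads dicts."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict:
        """Copy of all arrays needed to restore the layer (params + buffers)."""
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            target = self.params.get(k)
            if target is not None:
                target[...] = v


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(d_in, d_out)),
            "b": np.zeros(d_out),
        }
        self._x: Optional[np.ndarray] = None

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        self.grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalisation with running statistics for inference mode."""

    def __init__(self, dim: int):
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache = None

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            ivar = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (x - mu) * ivar
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mu
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
            self._cache = (xhat, ivar)
        else:
            ivar = 1.0 / np.sqrt(self.running_var + _BN_EPS)
            xhat = (x - self.running_mean) * ivar
            self._cache = None
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, ivar = self._cache  # backward only valid after a training forward
        B = dy.shape[0]
        self.grads = {"gamma": (dy * xhat).sum(axis=0), "beta": dy.sum(axis=0)}
        dxhat = dy * self.params["gamma"]
        return (ivar / B) * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        super().load_state(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train, rng):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if train and self.rate > 0.0:
            keep = 1.0 - self.rate
            self._mask = (rng.random(x.shape) < keep) / keep
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state(self):
        return [layer.state() for layer in self.layers]

    def load_state(self, state):
        for layer, s in zip(self.layers, state):
            layer.load_state(s)

    def param_items(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield (i, name), layer

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())


def mlp_block(widths: list[int], dropout_rate: float, rng: np.random.Generator,
              output_activation: Optional[str]) -> Sequential:
    """Hidden blocks of dense->BN->ReLU->dropout, then a dense output layer.

    ``output_activation`` is ``"sigmoid"`` or ``None`` (linear logits; the
    softmax head applies its activation inside the loss).
    """
    layers: list[Layer] = []
    for d_in, d_out in zip(widths[:-2], widths[1:-1]):
        layers += [Dense(d_in, d_out, rng), BatchNorm(d_out), ReLU(), Dropout(dropout_rate)]
    layers.append(Dense(widths[-2], widths[-1], rng))
    if output_activation == "sigmoid":
        layers.append(Sigmoid())
    elif output_activation is not None:
        raise ValueError(f"unknown output activation {output_activation!r}")
    return Sequential(layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(onehot * np.log(np.clip(probs, 1e-12, None)), axis=1)))


class RMSprop:
    """RMSprop with the conventional default learning rate."""

    def __init__(self, lr: float = 0.001, rho: float = _RMS_RHO, eps: float = _RMS_EPS):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict = {}

    def step(self, modules: dict[str, Sequential]) -> None:
        for mod_name, module in modules.items():
            for (i, pname), layer in module.param_items():
                g = layer.grads.get(pname)
                if g is None:
                    continue
                key = (mod_name, i, pname)
                acc = self._cache.get(key)
                if acc is None:
                    acc = np.zeros_like(g)
                    self._cache[key] = acc
                acc *= self.rho
                acc += (1 - self.rho) * g * g
                layer.params[pname] -= self.lr * g / (np.sqrt(acc) + self.eps)


class JointNet:
    """Encoder + mirror decoder + classifier head on the latent code."""

    def __init__(self, encoder_widths, decoder_widths, classifier_widths,
                 dropout_rate: float, rng: np.random.Generator):
        self.encoder = mlp_block(list(encoder_widths), dropout_rate, rng, "sigmoid")
        self.decoder = mlp_block(list(decoder_widths), dropout_rate, rng, "sigmoid")
        self.classifier = mlp_block(list(classifier_widths), dropout_rate, rng, None)

    @property
    def modules(self) -> dict[str, Sequential]:
        return {"encoder": self.encoder, "decoder": self.decoder, "classifier": self.classifier}

    def forward(self, x, train=False, rng=None):
        z = self.encoder.forward(x, train, rng)
        xr = self.decoder.forward(z, train, rng)
        probs = softmax(self.classifier.forward(z, train, rng))
        return z, xr, probs

    def losses(self, x, onehot, lam, train=False, rng=None):
        _, xr, probs = self.forward(x, train, rng)
        l_dec = float(np.mean((xr - x) ** 2))
        l_cls = cross_entropy(probs, onehot)
        return l_dec, l_cls, lam * l_dec + (1 - lam) * l_cls

    def train_batch(self, x, onehot, lam, optimizer: RMSprop, rng: np.random.Generator):
        """One forward/backward/update step on a minibatch."""
        B, D = x.shape
        z, xr, probs = self.forward(x, train=True, rng=rng)
        # decoder branch: d/dxr of lam * mean((xr - x)^2) over all B*D entries
        d_xr = lam * 2.0 * (xr - x) / (B * D)
        dz_dec = self.decoder.backward(d_xr)
        # classifier branch: fused softmax + cross-entropy gradient
        d_logits = (1 - lam) * (probs - onehot) / B
        dz_cls = self.classifier.backward(d_logits)
        self.encoder.backward(dz_dec + dz_cls)
        optimizer.step(self.modules)

    def state(self):
        return {name: mod.state() for name, mod in self.modules.items()}

    def load_state(self, state):
        for name, mod in self.modules.items():
            mod.load_state(state[name])

    def n_parameters(self) -> int:
        return sum(m.n_parameters() for m in self.modules.values())
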