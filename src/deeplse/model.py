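"""The joint latent-space encoding model (encoder + decoder + classifier).

The model is an autoencoder whose bottleneck (the latent space, dimension
``LV``) also feeds a small classifier head, and the three modules are
trained *jointly* under the convex combined loss

    L = lambda * L_decoder + (1 - lambda) * L_classification,

with ``L_decoder`` the mean squared reconstruction error over all feature
dimensions and samples and ``L_classification`` the cross-entropy of the
2-unit softmax head against one-hot targets.  With the default mixing
weight ``lambda = 0.99`` training attention is dominated by
reconstruction, yet the small classification term is enough to pull the
two classes apart in the latent space; ``lambda = 1`` recovers a
conventional autoencoder and ``lambda = 0`` a pure classifier.

Usage follows the model/results convention of statistical modelling
packages::

    model = DeepLSE(X_train, y_train, ModelConfig(N=5, k=2, LV=4, seed=0))
    res = model.fit()
    proba, labels = res.predict(X_test)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _nn
from .metrics import compute_confusion, compute_metrics, mse_db

__all__ = [
    "ModelConfig",
    "ModelSpec",
    "build_model",
    "combined_loss",
    "DeepLSE",
    "DeepLSEResults",
    "train",
    "encode_latent",
    "predict",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """All architecture and training hyperparameters.

    N
        Width multiplier for the encoder/decoder hidden layers
        (hidden widths N*10, N*5, N*2).
    k
        CKSAAP gap parameter; fixes the input width 400*(k+1).
    LV
        Latent-space dimension.
    lam
        Mixing weight of the combined loss, default 0.99.
    dropout_rate, max_epochs, patience
        Regularisation and early-stopping schedule (defaults 0.30,
        1000 epochs, patience 100 on the validation combined loss).
    learning_rate
        RMSprop learning rate, the conventional default 0.001.
    validation_fraction
        Stratified fraction of the training set held out internally to
        monitor early stopping (the monitoring split is never the test set).
    """

    N: int = 5
    k: int = 6
    LV: int = 6
    lam: float = 0.99
    dropout_rate: float = 0.30
    max_epochs: int = 1000
    patience: int = 100
    seed: int = 0
    batch_size: int = 32
    validation_fraction: float = 0.10
    learning_rate: float = 0.001
    classifier_hidden: tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.LV < 1:
            raise ValueError(f"LV must be >= 1, got {self.LV}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")

    @property
    def input_dim(self) -> int:
        return 400 * (self.k + 1)


@dataclass(frozen=True)
class ModelSpec:
    """The derived layer plan: encoder, mirror decoder, classifier head."""

    encoder_widths: tuple[int, ...]
    decoder_widths: tuple[int, ...]
    classifier_widths: tuple[int, ...]

    @property
    def input_dim(self) -> int:
        return self.encoder_widths[0]

    @property
    def latent_dim(self) -> int:
        return self.encoder_widths[-1]

    def parameter_count(self) -> int:
        """Trainable parameters: dense W+b plus batch-norm gamma+beta."""

        def seq(widths):
            n = sum((a + 1) * b for a, b in zip(widths[:-1], widths[1:]))
            n += sum(2 * h for h in widths[1:-1])  # BN on hidden layers only
            return n

        return seq(self.encoder_widths) + seq(self.decoder_widths) + seq(self.classifier_widths)


def build_model(config: ModelConfig) -> ModelSpec:
    """Derive the layer plan from the hyperparameters.

    Encoder hidden widths are N*10, N*5, N*2 down to the latent dimension;
    the decoder is its exact mirror; the classifier is a two-hidden-layer
    perceptron on the latent code ending in a 2-unit softmax.
    """
    hidden = (config.N * 10, config.N * 5, config.N * 2)
    if any(h < 1 for h in hidden):
        raise ValueError(f"non-positive hidden width in {hidden}")
    enc = (config.input_dim, *hidden, config.LV)
    dec = tuple(reversed(enc))
    cls = (config.LV, *config.classifier_hidden, 2)
    return ModelSpec(encoder_widths=enc, decoder_widths=dec, classifier_widths=cls)


def combined_loss(decoder_loss: float, classification_loss: float, lam: float) -> float:
    """The convex combination ``lam * L_dec + (1 - lam) * L_cls``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if not (np.isfinite(decoder_loss) and np.isfinite(classification_loss)):
        raise ValueError("losses must be finite")
    return lam * decoder_loss + (1 - lam) * classification_loss


def _check_features(X: np.ndarray, expected_dim: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != expected_dim:
        raise ValueError(f"feature matrix must be (n, {expected_dim}), got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    return X


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Seeded stratified holdout; returns (train_idx, val_idx)."""
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        val_idx.append(idx[:n_val])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


class DeepLSE:
    """Joint latent-space encoding model bound to a training dataset."""

    def __init__(self, features: np.ndarray, labels: Sequence[int], config: Optional[ModelConfig] = None):
        self.config = config if config is not None else ModelConfig()
        self.spec = build_model(self.config)
        self.features = _check_features(features, self.spec.input_dim)
        y = np.asarray(labels)
        if y.shape != (self.features.shape[0],):
            raise ValueError("labels must align with feature rows")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes present")
        self.labels = y.astype(np.int64)

    @classmethod
    def from_dataset(cls, dataset, cksaap_config=None, config: Optional[ModelConfig] = None) -> "DeepLSE":
        """Build directly from a labelled sequence dataset (encodes CKSAAP)."""
        from .cksaap import CksaapConfig, encode_dataset

        config = config if config is not None else ModelConfig()
        cc = cksaap_config if cksaap_config is not None else CksaapConfig(k=config.k)
        if cc.k != config.k:
            raise ValueError(f"cksaap k={cc.k} disagrees with model k={config.k}")
        X, y, _ = encode_dataset(dataset, cc)
        return cls(X, y, config)

    def fit(self, verbose: bool = False) -> "DeepLSEResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = _nn.JointNet(
            self.spec.encoder_widths,
            self.spec.decoder_widths,
            self.spec.classifier_widths,
            cfg.dropout_rate,
            rng,
        )
        opt = _nn.RMSprop(lr=cfg.learning_rate)

        tr_idx, val_idx = _stratified_split(self.labels, cfg.validation_fraction, rng)
        X_tr, y_tr = self.features[tr_idx], self.labels[tr_idx]
        X_val, y_val = self.features[val_idx], self.labels[val_idx]
        onehot_tr = np.eye(2)[y_tr]
        onehot_val = np.eye(2)[y_val]

        history = []
        best = {"epoch": -1, "val_combined": np.inf, "state": None}
        wait = 0
        for epoch in range(cfg.max_epochs):
            perm = rng.permutation(X_tr.shape[0])
            for start in range(0, perm.size, cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                if batch.size < 2:  # batch-norm needs at least two samples
                    continue
                net.train_batch(X_tr[batch], onehot_tr[batch], cfg.lam, opt, rng)

            tr_dec, tr_cls, tr_comb = net.losses(X_tr, onehot_tr, cfg.lam)
            va_dec, va_cls, va_comb = net.losses(X_val, onehot_val, cfg.lam)
            history.append(
                {
                    "epoch": epoch,
                    "train_decoder_loss": tr_dec,
                    "train_classifier_loss": tr_cls,
                    "train_combined_loss": tr_comb,
                    "val_decoder_loss": va_dec,
                    "val_classifier_loss": va_cls,
                    "val_combined_loss": va_comb,
                }
            )
            if verbose:
                print(f"epoch {epoch}: train {tr_comb:.6f}  val {va_comb:.6f}")

            if va_comb < best["val_combined"]:
                best = {"epoch": epoch, "val_combined": va_comb, "state": net.state()}
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break

        net.load_state(best["state"])
        return DeepLSEResults(
            net=net,
            config=cfg,
            spec=self.spec,
            history=pd.DataFrame(history),
            best_epoch=best["epoch"],
            model=self,
        )


class DeepLSEResults:
    """Fitted parameters, training history, and inference methods."""

    def __init__(self, net, config: ModelConfig, spec: ModelSpec, history: pd.DataFrame,
                 best_epoch: int, model: Optional[DeepLSE] = None):
        self._net = net
        self.config = config
        self.spec = spec
        self.history = history
        self.best_epoch = best_epoch
        self.model = model

    # ---- inference (always deterministic: dropout off, BN running stats) ----

    def encode_latent(self, features: np.ndarray) -> np.ndarray:
        """Latent codes, rows x LV, each entry in [0, 1] (sigmoid latent)."""
        X = _check_features(features, self.spec.input_dim)
        return self._net.encoder.forward(X, train=False)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        X = _check_features(features, self.spec.input_dim)
        z = self._net.encoder.forward(X, train=False)
        return _nn.softmax(self._net.classifier.forward(z, train=False))

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-row (probability pair, hard label); softmax ties go negative."""
        proba = self.predict_proba(features)
        labels = (proba[:, 1] > proba[:, 0]).astype(np.int64)
        return proba, labels

    def reconstruct(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Decoded matrix X' = Dec(Enc(X)) and residual X - X'."""
        X = _check_features(features, self.spec.input_dim)
        z = self._net.encoder.forward(X, train=False)
        decoded = self._net.decoder.forward(z, train=False)
        return decoded, X - decoded

    # ---- reporting ----

    def evaluate(self, features: np.ndarray, labels: Sequence[int]):
        """MetricReport on an evaluation split."""
        _, pred = self.predict(features)
        return compute_metrics(compute_confusion(np.asarray(labels), pred))

    def reconstruction_db(self, features: np.ndarray) -> float:
        decoded, _ = self.reconstruct(features)
        return mse_db(np.asarray(features), decoded)

    def n_parameters(self) -> int:
        return self._net.n_parameters()

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Joint latent-space encoding model",
            "=" * 48,
            f"input dim        {self.spec.input_dim}  (CKSAAP k={cfg.k})",
            f"encoder widths   {' -> '.join(map(str, self.spec.encoder_widths))}",
            f"decoder widths   {' -> '.join(map(str, self.spec.decoder_widths))}",
            f"classifier       {' -> '.join(map(str, self.spec.classifier_widths))}",
            f"parameters       {self.n_parameters()}",
            f"lambda           {cfg.lam}",
            f"epochs run       {len(self.history)} (best epoch {self.best_epoch})",
        ]
        if len(self.history):
            last_best = self.history.iloc[self.best_epoch]
            lines.append(f"best val loss    {last_best['val_combined_loss']:.6f}")
        return "\n".join(lines)

    # ---- persistence ----

    def save(self, path: Union[str, Path]) -> None:
        save_checkpoint(self, path)


# ------------------------- functional wrappers -------------------------


def train(features: np.ndarray, labels: Sequence[int], config: ModelConfig,
          verbose: bool = False) -> DeepLSEResults:
    """Fit a model on a feature matrix (see :class:`DeepLSE`)."""
    return DeepLSE(features, labels, config).fit(verbose=verbose)


def encode_latent(results: DeepLSEResults, features: np.ndarray) -> np.ndarray:
    return results.encode_latent(features)


def predict(results: DeepLSEResults, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return results.predict(features)


def reconstruct(results: DeepLSEResults, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return results.reconstruct(features)


# ------------------------- checkpoints -------------------------


def save_checkpoint(results: DeepLSEResults, path: Union[str, Path]) -> None:
    """Self-describing checkpoint: flat npz of arrays + embedded JSON config."""
    arrays = {}
    for mod_name, mod_state in results._net.state().items():
        for i, layer_state in enumerate(mod_state):
            for key, arr in layer_state.items():
                arrays[f"{mod_name}/{i}/{key}"] = arr
    meta = {
        "format_version": 1,
        "config": asdict(replace(results.config)),
        "best_epoch": int(results.best_epoch),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: Union[str, Path]) -> DeepLSEResults:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["classifier_hidden"] = tuple(cfg_dict["classifier_hidden"])
    config = ModelConfig(**cfg_dict)
    spec = build_model(config)
    rng = np.random.default_rng(config.seed)
    net = _nn.JointNet(spec.encoder_widths, spec.decoder_widths, spec.classifier_widths,
                       config.dropout_rate, rng)
    state = net.state()
    for mod_name, mod_state in state.items():
        for i, layer_state in enumerate(mod_state):
            for key in layer_state:
                layer_state[key] = data[f"{mod_name}/{i}/{key}"]
    net.load_state(state)
    return DeepLSEResults(net=net, config=config, spec=spec,
                          history=pd.DataFrame(), best_epoch=meta["best_epoch"])
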