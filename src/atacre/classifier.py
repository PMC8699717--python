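"""Dual-branch convolutional classifier for cis-RE functional classes.

Architecture
------------
A deep branch consumes the 10x600 peak encoding with positions as the
convolution axis and the 10 rows as channels.  It stacks four convolutional
blocks, each: 1-D conv (kernel 19, stride 1) -> batch norm -> 1-D conv
(kernel 19, stride 1) -> max pool (2) -> batch norm, with ReLU activations on
the convolutions; the first two blocks use 256 filters, the last two 512.
An auxiliary branch consumes the standardized 19-feature vector.  Each branch
has its own 2048-unit dense head.  Branch outputs are concatenated into a
512-unit dense layer followed by a 4-way softmax over (promoter, enhancer,
insulator, other).

Training is staged: each branch is first trained separately under a temporary
softmax head (the two branches overfit at different rates), then the unified
model — concatenation plus joint dense layers — is trained in a final round.
All stages use Adam (learning rate 0.001) with batch size 32 and early
stopping on validation loss.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import nn
from .encoder import EncodingStats
from .features import FeatureStats
from .genomic_io import CLASS_NAMES

# hyperparameter search space explored during model tuning
TUNING_GRID = {
    "conv_kernel": (9, 11, 19, 21),
    "conv_blocks": (3, 4, 5),
    "branch_dense": (1024, 2048, 4096),
    "base_filters": (32, 128, 256),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings (defaults are the tuned values).

    ``filters_per_block`` follows the tuned pattern: the first two blocks at
    the base filter count, the remaining blocks doubled.
    """

    window_len: int = 600
    n_channels: int = 10
    n_aux_features: int = 19
    conv_kernel: int = 19
    conv_blocks: int = 4
    filters_per_block: tuple = (256, 256, 512, 512)
    pool_size: int = 2
    branch_dense: int = 2048
    joint_dense: int = 512
    n_classes: int = 4
    batch_size: int = 32
    learning_rate: float = 0.001
    branch_epochs: int = 20
    joint_epochs: int = 20
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd")
        if self.n_classes != 4:
            raise ValueError("the classifier is a 4-class model")
        if len(self.filters_per_block) != self.conv_blocks:
            raise ValueError(
                f"filters_per_block has {len(self.filters_per_block)} entries "
                f"for {self.conv_blocks} blocks"
            )
        for name in (
            "window_len", "n_channels", "n_aux_features", "conv_blocks",
            "pool_size", "branch_dense", "joint_dense", "batch_size",
            "branch_epochs", "joint_epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(f < 1 for f in self.filters_per_block):
            raise ValueError("all filter counts must be >= 1")
        self.deep_flat_size()  # raises if the window collapses

    def deep_flat_size(self) -> int:
        """Flattened deep-branch output size implied by the architecture."""
        L = self.window_len
        for f in self.filters_per_block:
            for _ in range(2):
                if L < self.conv_kernel:
                    raise ValueError(
                        "window collapses below the kernel size; reduce "
                        "conv_blocks or conv_kernel"
                    )
                L = L - self.conv_kernel + 1
            L = L // self.pool_size
        if L < 1:
            raise ValueError("window collapses to zero length after pooling")
        return L * self.filters_per_block[-1]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def small_config(**overrides) -> ModelConfig:
    """A reduced architecture for CPU-scale experiments on synthetic data."""
    defaults = dict(
        conv_kernel=9,
        conv_blocks=2,
        filters_per_block=(16, 32),
        branch_dense=64,
        joint_dense=32,
        branch_epochs=10,
        joint_epochs=8,
        early_stopping_patience=3,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _build_deep_branch(config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    channels = config.n_channels
    for f in config.filters_per_block:
        layers += [
            nn.Conv1D(channels, f, config.conv_kernel, rng),
            nn.ReLU(),
            nn.BatchNorm(f),
            nn.Conv1D(f, f, config.conv_kernel, rng),
            nn.ReLU(),
            nn.MaxPool1D(config.pool_size),
            nn.BatchNorm(f),
        ]
        channels = f
    layers += [
        nn.Flatten(),
        nn.Dense(config.deep_flat_size(), config.branch_dense, rng),
        nn.ReLU(),
    ]
    return nn.Sequential(layers)


def _build_aux_branch(config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        [nn.Dense(config.n_aux_features, config.branch_dense, rng), nn.ReLU()]
    )


def _build_joint(config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Dense(2 * config.branch_dense, config.joint_dense, rng),
            nn.ReLU(),
            nn.Dense(config.joint_dense, config.n_classes, rng),
        ]
    )


class CisREClassifier:
    """The dual-branch model plus everything prediction needs (architecture,
    learned parameters, training history, and the standardization statistics
    fitted on the training dataset)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.deep_branch = _build_deep_branch(config, rng)
        self.aux_branch = _build_aux_branch(config, rng)
        self.joint = _build_joint(config, rng)
        self._deep_head = nn.Dense(config.branch_dense, config.n_classes, rng)
        self._aux_head = nn.Dense(config.branch_dense, config.n_classes, rng)
        self.encoding_stats: Optional[EncodingStats] = None
        self.feature_stats: Optional[FeatureStats] = None
        self.history: dict[str, list] = {}
        self.trained = False

    # -- introspection ------------------------------------------------------

    def describe(self) -> list[dict]:
        """Flat description of the deep branch, one dict per layer."""
        out = []
        for layer in self.deep_branch.layers:
            if isinstance(layer, nn.Conv1D):
                out.append(
                    {"type": "conv1d", "kernel": layer.kernel, "stride": 1,
                     "filters": layer.filters}
                )
            elif isinstance(layer, nn.BatchNorm):
                out.append({"type": "batch_norm"})
            elif isinstance(layer, nn.MaxPool1D):
                out.append({"type": "max_pool", "pool": layer.pool})
            elif isinstance(layer, nn.Dense):
                out.append({"type": "dense", "units": layer.out_features})
            elif isinstance(layer, nn.ReLU):
                out.append({"type": "relu"})
            elif isinstance(layer, nn.Flatten):
                out.append({"type": "flatten"})
        return out

    # -- forward passes -----------------------------------------------------

    def _forward_joint(self, X: np.ndarray, F: np.ndarray, training: bool) -> np.ndarray:
        d = self.deep_branch.forward(X, training)
        a = self.aux_branch.forward(F, training)
        return self.joint.forward(np.concatenate([d, a], axis=1), training)

    def _backward_joint(self, grad: np.ndarray) -> None:
        g = self.joint.backward(grad)
        gd, ga = np.split(g, [self.config.branch_dense], axis=1)
        self.deep_branch.backward(gd)
        self.aux_branch.backward(ga)

    # -- persistence --------------------------------------------------------

    def _all_params(self) -> list[nn.Param]:
        return (
            self.deep_branch.params()
            + self.aux_branch.params()
            + self.joint.params()
        )

    def _bn_layers(self) -> list[nn.BatchNorm]:
        return [
            layer
            for seq in (self.deep_branch, self.aux_branch, self.joint)
            for layer in seq.layers
            if isinstance(layer, nn.BatchNorm)
        ]

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "config": asdict(self.config),
            "config_digest": self.config.digest(),
            "trained": self.trained,
            "history": self.history,
            "encoding_stats": self.encoding_stats.to_dict()
            if self.encoding_stats
            else None,
            "feature_stats": self.feature_stats.to_dict()
            if self.feature_stats
            else None,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(manifest, fh)
        arrays = {}
        for i, p in enumerate(self._all_params()):
            arrays[f"param_{i}"] = p.value
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        np.savez_compressed(os.path.join(directory, "params.npz"), **arrays)

    @classmethod
    def load(cls, directory: str) -> "CisREClassifier":
        with open(os.path.join(directory, "model.json")) as fh:
            manifest = json.load(fh)
        cfg_d = manifest["config"]
        cfg_d["filters_per_block"] = tuple(cfg_d["filters_per_block"])
        config = ModelConfig(**cfg_d)
        if config.digest() != manifest["config_digest"]:
            raise ValueError("model manifest config digest mismatch")
        model = cls(config)
        arrays = np.load(os.path.join(directory, "params.npz"))
        for i, p in enumerate(model._all_params()):
            p.value[...] = arrays[f"param_{i}"]
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean[...] = arrays[f"bn_mean_{i}"]
            bn.running_var[...] = arrays[f"bn_var_{i}"]
        model.trained = manifest["trained"]
        model.history = manifest["history"]
        if manifest["encoding_stats"]:
            model.encoding_stats = EncodingStats.from_dict(manifest["encoding_stats"])
        if manifest["feature_stats"]:
            model.feature_stats = FeatureStats.from_dict(manifest["feature_stats"])
        return model


def build_model(config: ModelConfig = ModelConfig()) -> CisREClassifier:
    """Construct the (untrained) dual-branch model from its configuration."""
    return CisREClassifier(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_label_indices(labels: Sequence) -> np.ndarray:
    idx = []
    for lab in labels:
        value = getattr(lab, "value", lab)
        if isinstance(value, str):
            if value not in CLASS_NAMES:
                raise ValueError(f"label {value!r} outside the 4 classes")
            idx.append(CLASS_NAMES.index(value))
        else:
            i = int(value)
            if not 0 <= i < 4:
                raise ValueError(f"label index {i} outside the 4 classes")
            idx.append(i)
    return np.array(idx, dtype=int)


def _batches(n: int, batch_size: int, order: np.ndarray):
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _eval_loss_acc(forward, data, batch_size: int) -> tuple[float, float]:
    X, F, y = data
    losses, hits, n = [], 0, len(y)
    for idx in _batches(n, batch_size, np.arange(n)):
        probs = nn.softmax(forward(X[idx], F[idx], training=False))
        losses.append(nn.cross_entropy(probs, y[idx]) * len(idx))
        hits += int((probs.argmax(axis=1) == y[idx]).sum())
    return float(np.sum(losses) / n), hits / n


def _fit(
    forward,
    backward,
    params: list[nn.Param],
    train_data,
    val_data,
    epochs: int,
    config: ModelConfig,
    rng: np.random.Generator,
) -> list[dict]:
    opt = nn.Adam(params, config.learning_rate)
    Xtr, Ftr, ytr = train_data
    n = len(ytr)
    best_val = np.inf
    best_snap = nn.snapshot_params(params)
    patience = 0
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for idx in _batches(n, config.batch_size, order):
            opt.zero_grad()
            probs = nn.softmax(forward(Xtr[idx], Ftr[idx], training=True))
            batch_losses.append(nn.cross_entropy(probs, ytr[idx]))
            backward(nn.softmax_xent_grad(probs, ytr[idx]))
            opt.step()
        val_loss, val_acc = _eval_loss_acc(forward, val_data, config.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_snap = nn.snapshot_params(params)
            patience = 0
        else:
            patience += 1
            if patience > config.early_stopping_patience:
                break
    nn.restore_params(params, best_snap)
    return history


def train_staged(
    encodings: np.ndarray,
    features: np.ndarray,
    labels: Sequence,
    splits: Sequence[str],
    config: ModelConfig = ModelConfig(),
    model: Optional[CisREClassifier] = None,
) -> CisREClassifier:
    """Staged training on standardized inputs.

    ``encodings`` is (n, 10, window_len), ``features`` (n, 19), ``labels``
    class names/enums/indices, ``splits`` per-example 'train'/'validation'
    markers.  Stage 1 trains each branch separately under a temporary softmax
    head; stage 2 trains the unified (concatenated) model end to end.
    """
    y = _as_label_indices(labels)
    splits = np.asarray(splits)
    X = np.ascontiguousarray(np.transpose(np.asarray(encodings), (0, 2, 1)))
    F = np.asarray(features, dtype=float)
    tr = splits == "train"
    va = splits == "validation"
    if not va.any():
        raise ValueError("a validation split is required for staged training")
    if not tr.any():
        raise ValueError("a train split is required")
    train_data = (X[tr], F[tr], y[tr])
    val_data = (X[va], F[va], y[va])

    if model is None:
        model = CisREClassifier(config)
    config = model.config
    rng = np.random.default_rng(config.seed + 1)

    # stage 1a: deep branch with temporary head
    def fwd_deep(Xb, Fb, training):
        return model._deep_head.forward(
            model.deep_branch.forward(Xb, training), training
        )

    def bwd_deep(grad):
        model.deep_branch.backward(model._deep_head.backward(grad))

    model.history["deep_branch"] = _fit(
        fwd_deep,
        bwd_deep,
        model.deep_branch.params() + model._deep_head.params(),
        train_data,
        val_data,
        config.branch_epochs,
        config,
        rng,
    )

    # stage 1b: auxiliary branch with temporary head
    def fwd_aux(Xb, Fb, training):
        return model._aux_head.forward(
            model.aux_branch.forward(Fb, training), training
        )

    def bwd_aux(grad):
        model.aux_branch.backward(model._aux_head.backward(grad))

    model.history["aux_branch"] = _fit(
        fwd_aux,
        bwd_aux,
        model.aux_branch.params() + model._aux_head.params(),
        train_data,
        val_data,
        config.branch_epochs,
        config,
        rng,
    )

    # stage 2: unified model (branches concatenated, all parameters trained)
    model.history["joint"] = _fit(
        model._forward_joint,
        model._backward_joint,
        model._all_params(),
        train_data,
        val_data,
        config.joint_epochs,
        config,
        rng,
    )
    model.trained = True
    return model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(
    model: CisREClassifier,
    encodings: np.ndarray,
    features: np.ndarray,
    batch_size: int = 64,
    require_stats: bool = True,
) -> np.ndarray:
    """Per-peak class probabilities (n, 4) ordered (promoter, enhancer,
    insulator, other).  Inputs must be standardized with the model's stored
    statistics; results are batch-size independent (inference uses running
    batch-norm statistics)."""
    if not model.trained:
        raise ValueError("model is untrained")
    if require_stats and (model.encoding_stats is None or model.feature_stats is None):
        raise ValueError(
            "standardization statistics are not attached to this model"
        )
    X = np.asarray(encodings)
    if X.ndim != 3 or X.shape[1] != model.config.n_channels or X.shape[2] != model.config.window_len:
        raise ValueError(
            f"encodings must be (n, {model.config.n_channels}, "
            f"{model.config.window_len}), got {X.shape}"
        )
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[1] != model.config.n_aux_features:
        raise ValueError(
            f"features must be (n, {model.config.n_aux_features}), got {F.shape}"
        )
    X = np.ascontiguousarray(np.transpose(X, (0, 2, 1)))
    out = []
    for i in range(0, len(X), batch_size):
        logits = model._forward_joint(X[i : i + batch_size], F[i : i + batch_size], False)
        out.append(nn.softmax(logits))
    return np.concatenate(out, axis=0)
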