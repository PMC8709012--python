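"""The residual CNN+LSTM feature extractor and its training harness.

The architecture is a convolutional stem followed by a stack of residual
blocks (two 3x3 convolutional units with batch normalisation, skip-added and
rectified), spatially downsampled every second block.  The final feature map
is unfolded row-wise into a sequence and read by an LSTM whose last hidden
state feeds a fully connected layer; the activations of that first fully
connected layer (FC1, width 350 by default) are the "deep features" handed
to the downstream feature-selection and classification stages.  A softmax
head on top closes the network for end-to-end training with cross-entropy
and SGD with momentum.

Four ablation variants are supported: ``cnn`` (no skips, no LSTM),
``cnn_lstm`` (no skips), ``rcnn`` (skips, flatten instead of LSTM), and the
full ``rcnn_lstm``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

VARIANTS = ("cnn", "cnn_lstm", "rcnn", "rcnn_lstm")


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture constants.

    Defaults give the full-size network: six residual blocks, 100 LSTM
    units, a 350-wide first fully connected layer, 125x125 RGB inputs.
    """

    n_residual_blocks: int = 6
    stem_filters: int = 8
    block_filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    kernel_size: int = 3
    lstm_units: int = 100
    fc1_width: int = 350
    n_classes: int = 8
    dropout_rate: float = 0.2
    input_size: int = 125
    variant: str = "rcnn_lstm"

    def __post_init__(self) -> None:
        self.block_filters = tuple(self.block_filters)
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.fc1_width < 1:
            raise ConfigurationError("fc1_width must be positive")
        if self.n_residual_blocks < 1:
            raise ConfigurationError("at least one block is required")
        if len(self.block_filters) != self.n_residual_blocks:
            raise ConfigurationError(
                f"block_filters has {len(self.block_filters)} entries for "
                f"{self.n_residual_blocks} blocks"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @property
    def uses_skip(self) -> bool:
        return self.variant in ("rcnn", "rcnn_lstm")

    @property
    def uses_lstm(self) -> bool:
        return self.variant in ("cnn_lstm", "rcnn_lstm")

    def block_strides(self) -> list[int]:
        # downsample at the stem and every second block
        return [2 if (i + 1) % 2 == 0 else 1 for i in range(self.n_residual_blocks)]

    def spatial_schedule(self) -> list[int]:
        """Feature-map side length after the stem and after each block."""

        def out(h: int, k: int, s: int) -> int:
            return (h + 2 * (k // 2) - k) // s + 1

        sizes = [out(self.input_size, self.kernel_size, 2)]
        for s in self.block_strides():
            sizes.append(out(sizes[-1], self.kernel_size, s))
        return sizes


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.001
    max_epochs: int = 150
    momentum: float = 0.9
    seed: int = 0
    # loss is fixed: softmax cross-entropy

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


@dataclass
class History:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"loss": self.loss, "accuracy": self.accuracy}))


@dataclass
class DeepFeatureSet:
    matrix: np.ndarray
    sample_ids: list
    source: str

    def to_csv(self, path: str | Path, labels: np.ndarray | None = None) -> None:
        from .synthdata import save_feature_table

        if labels is None:
            labels = np.zeros(self.matrix.shape[0], dtype=int)
        save_feature_table(path, self.matrix, labels)


def fold_to_sequence(feature_map: np.ndarray) -> np.ndarray:
    """Unfold an H x W x C map into H timesteps of length W*C (W-major, then C).

    Accepts a single map or a batch (B, H, W, C) -> (B, H, W*C).
    """
    fm = np.asarray(feature_map)
    if fm.ndim == 3:
        H, W, C = fm.shape
        return fm.reshape(H, W * C)
    B, H, W, C = fm.shape
    return fm.reshape(B, H, W * C)


def refold_from_sequence(seq: np.ndarray, width: int, channels: int) -> np.ndarray:
    """Inverse of :func:`fold_to_sequence`."""
    sq = np.asarray(seq)
    if sq.ndim == 2:
        T = sq.shape[0]
        return sq.reshape(T, width, channels)
    B, T = sq.shape[:2]
    return sq.reshape(B, T, width, channels)


class Model:
    """A built network: layers plus the bookkeeping to train and probe it."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng([seed, 17])
        sizes = config.spatial_schedule()
        if sizes[-1] < 2:
            min_size = _minimum_input_size(config)
            raise ConfigurationError(
                f"input_size={config.input_size} collapses to a {sizes[-1]}-pixel map "
                f"under the downsampling schedule; minimum input size is {min_size}"
            )
        self.stem = nn.Conv2d(3, config.stem_filters, config.kernel_size, 2, rng, "stem")
        self.stem_bn = nn.BatchNorm2d(config.stem_filters, name="stem.bn")
        self.stem_relu = nn.ReLU()
        self.blocks: list[nn.ResidualBlock] = []
        in_ch = config.stem_filters
        for i, (f, s) in enumerate(zip(config.block_filters, config.block_strides())):
            self.blocks.append(
                nn.ResidualBlock(
                    in_ch, f, s, use_skip=config.uses_skip,
                    kernel_size=config.kernel_size, rng=rng, name=f"block{i + 1}",
                )
            )
            in_ch = f
        self.final_hw = sizes[-1]
        self.final_ch = in_ch
        if config.uses_lstm:
            seq_dim = self.final_hw * in_ch
            self.lstm = nn.LSTM(seq_dim, config.lstm_units, rng, "lstm")
            fc1_in = config.lstm_units
        else:
            self.lstm = None
            fc1_in = self.final_hw * self.final_hw * in_ch
        self.fc1 = nn.Dense(fc1_in, config.fc1_width, rng, "fc1")
        self.fc1_relu = nn.ReLU()
        self.dropout = nn.Dropout(config.dropout_rate, np.random.default_rng([seed, 23]))
        self.head = nn.Dense(config.fc1_width, config.n_classes, rng, "head")
        self.classes_: np.ndarray | None = None

    # ---- plumbing -------------------------------------------------------

    def params(self) -> list[nn.Param]:
        ps = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            ps += b.params()
        if self.lstm is not None:
            ps += self.lstm.params()
        return ps + self.fc1.params() + self.head.params()

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def _backbone(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.stem.forward(x, train)
        out = self.stem_bn.forward(out, train)
        out = self.stem_relu.forward(out, train)
        for b in self.blocks:
            out = b.forward(out, train)
        return out

    def _fc1_input(self, fmap: np.ndarray, train: bool) -> np.ndarray:
        if self.lstm is not None:
            return self.lstm.forward(fold_to_sequence(fmap), train)
        return fmap.reshape(fmap.shape[0], -1)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fmap = self._backbone(x, train)
        self._fmap_shape = fmap.shape
        h = self._fc1_input(fmap, train)
        a = self.fc1.forward(h, train)
        a = self.fc1_relu.forward(a, train)
        a = self.dropout.forward(a, train)
        return self.head.forward(a, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.fc1_relu.backward(d)
        d = self.fc1.backward(d)
        if self.lstm is not None:
            d = self.lstm.backward(d)
            B, H, W, C = self._fmap_shape
            d = refold_from_sequence(d.reshape(B, H, W * C) if d.ndim == 2 else d, W, C)
            # LSTM.backward already returns (B, T, W*C); reshape to the map
            d = d.reshape(B, H, W, C)
        else:
            d = d.reshape(self._fmap_shape)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem.backward(d)

    # ---- user-facing ----------------------------------------------------

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        images = _prepare_images(images, self.config.input_size)
        out = []
        for i in range(0, len(images), batch_size):
            logits = self.forward_logits(images[i : i + batch_size], train=False)
            out.append(nn.softmax_logits(logits))
        return np.vstack(out) if out else np.zeros((0, self.config.n_classes))

    def predict(self, images: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(images).argmax(axis=1)
        if self.classes_ is not None:
            return self.classes_[idx]
        return idx

    def fc1_activations(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Pre-ReLU activations of the first fully connected layer."""
        images = _prepare_images(images, self.config.input_size)
        rows = []
        for i in range(0, len(images), batch_size):
            fmap = self._backbone(images[i : i + batch_size], train=False)
            h = self._fc1_input(fmap, train=False)
            rows.append(self.fc1.forward(h, train=False))
        return np.vstack(rows) if rows else np.zeros((0, self.config.fc1_width))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {p.name: p.value for p in self.params()}
        for i, b in enumerate(self.blocks):
            arrays[f"block{i + 1}.bn1.running_mean"] = b.bn1.running_mean
            arrays[f"block{i + 1}.bn1.running_var"] = b.bn1.running_var
            arrays[f"block{i + 1}.bn2.running_mean"] = b.bn2.running_mean
            arrays[f"block{i + 1}.bn2.running_var"] = b.bn2.running_var
        arrays["stem.bn.running_mean"] = self.stem_bn.running_mean
        arrays["stem.bn.running_var"] = self.stem_bn.running_var
        if self.classes_ is not None:
            arrays["classes_"] = self.classes_
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"), allow_pickle=False)
        for p in model.params():
            p.value[...] = data[p.name]
        for i, b in enumerate(model.blocks):
            b.bn1.running_mean = data[f"block{i + 1}.bn1.running_mean"]
            b.bn1.running_var = data[f"block{i + 1}.bn1.running_var"]
            b.bn2.running_mean = data[f"block{i + 1}.bn2.running_mean"]
            b.bn2.running_var = data[f"block{i + 1}.bn2.running_var"]
        model.stem_bn.running_mean = data["stem.bn.running_mean"]
        model.stem_bn.running_var = data["stem.bn.running_var"]
        if "classes_" in data:
            model.classes_ = data["classes_"]
        return model


def _minimum_input_size(config: ModelConfig) -> int:
    for size in range(8, 4096):
        trial = ModelConfig(**{**asdict(config), "input_size": size})
        if trial.spatial_schedule()[-1] >= 2:
            return size
    raise ConfigurationError("no feasible input size found")  # pragma: no cover


def _prepare_images(images: np.ndarray, input_size: int) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    if images.shape[0] == 0:
        return images.reshape(0, input_size, input_size, 3)
    if images.shape[1] != input_size or images.shape[2] != input_size:
        from skimage.transform import resize

        warnings.warn(
            f"resizing images from {images.shape[1]}x{images.shape[2]} to "
            f"{input_size}x{input_size}",
            stacklevel=3,
        )
        images = np.stack(
            [resize(im, (input_size, input_size, 3), anti_aliasing=True) for im in images]
        )
    return images


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Assemble a network for the given architecture constants."""
    return Model(config, seed=seed)


def train_model(
    model: Model,
    images: np.ndarray,
    labels: np.ndarray,
    tc: TrainConfig,
) -> tuple[Model, History]:
    """Train in place with SGD-with-momentum on softmax cross-entropy.

    Labels may be strings or integers; the sorted unique values become the
    class order stored on the model.  History records the mean minibatch
    loss and the training accuracy of each epoch.  Deterministic for a fixed
    seed and data order.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    if classes.size != model.config.n_classes:
        raise ValueError(
            f"model has {model.config.n_classes} output classes but the data "
            f"contains {classes.size}"
        )
    model.classes_ = classes
    y = np.searchsorted(classes, labels)
    images = _prepare_images(images, model.config.input_size)

    history = History()
    if tc.max_epochs == 0:
        return model, history

    rng = np.random.default_rng([tc.seed, 31])
    opt = nn.SGDM(model.params(), tc.learning_rate, tc.momentum)
    n = len(images)
    for _epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, tc.batch_size):
            idx = order[i : i + tc.batch_size]
            xb, yb = images[idx], y[idx]
            opt.zero_grad()
            logits = model.forward_logits(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / n)
    return model, history


def extract_deep_features(
    model: Model, images: np.ndarray, sample_ids: list | None = None
) -> DeepFeatureSet:
    """One FC1 feature row per image, in input order."""
    matrix = model.fc1_activations(images)
    if sample_ids is None:
        sample_ids = list(range(matrix.shape[0]))
    return DeepFeatureSet(
        matrix=matrix,
        sample_ids=sample_ids,
        source=f"{model.config.variant}/fc1[{model.config.fc1_width}]",
    )
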