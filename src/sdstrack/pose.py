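"""Pose-estimation network: regress the larynx pixel position from RGBD.

The model is a deliberately small convolutional regressor: three
ConvBlocks (3x3 'same' convolution -> ReLU -> 2x2 max pool), a flatten,
and two fully connected layers producing the (x, y) prediction as
normalised coordinates in [0, 1] relative to the preprocessed input crop.
Training minimises the L1 loss with Adam (beta1 0.9, beta2 0.99, learning
rate 1e-3, mini-batches of 4) and keeps the epoch checkpoint with the
smallest validation L1.

Organisation follows the statsmodels convention: a
:class:`PoseEstimationModel` is built from (already preprocessed) training
and validation arrays, ``fit()`` returns a :class:`PoseEstimationResults`
carrying the selected weights, the per-epoch history and a ``summary()``;
tracking full sequences hangs off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .preprocess import ROI, CropTransform, NormalizationParams, fuse_rgbd
from .rgbd_io import PointLabel, RGBDFrame, SequenceMeta

__all__ = ["ModelConfig", "TrainingConfig", "Prediction", "build_model",
           "count_parameters", "PoseEstimationModel", "PoseEstimationResults",
           "prepare_training_arrays", "track_sequence"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture settings; defaults keep the network CPU-trainable."""

    in_channels: int = 4
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    pool: int = 2
    fc_hidden: int = 128
    out_dim: int = 2
    input_size: int = 254

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three ConvBlocks are required")
        if self.out_dim != 2:
            raise ValueError("out_dim must be 2 (an (x, y) prediction)")
        if self.pool != 2:
            raise ValueError("only 2x2 max pooling is supported")
        if self.input_size < 8:
            raise ValueError("input_size must be >= 8")

    @property
    def flat_features(self) -> int:
        s = self.input_size
        for _ in self.conv_channels:
            s //= 2
        return s * s * self.conv_channels[-1]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation protocol: L1 loss, Adam(0.9, 0.99), lr 1e-3, batch 4."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    batch_size: int = 4
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Prediction:
    """Tracked larynx position in one frame, full-frame pixel coordinates."""

    frame_index: int
    x: float
    y: float
    depth_mm: float
    valid: bool = True


def build_model(config: ModelConfig, seed: int = 0) -> nn.Sequential:
    """Instantiate the three-ConvBlock regression network."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    cin = config.in_channels
    for cout in config.conv_channels:
        layers += [nn.Conv2D(cin, cout, config.kernel_size, rng),
                   nn.ReLU(), nn.MaxPool2()]
        cin = cout
    layers += [nn.Flatten(),
               nn.Dense(config.flat_features, config.fc_hidden, rng),
               nn.ReLU(),
               nn.Dense(config.fc_hidden, config.out_dim, rng)]
    return nn.Sequential(layers)


def count_parameters(config: ModelConfig) -> int:
    """Parameter count of the architecture (weights + biases)."""
    total = 0
    cin = config.in_channels
    for cout in config.conv_channels:
        total += cout * (cin * config.kernel_size ** 2 + 1)
        cin = cout
    total += config.fc_hidden * (config.flat_features + 1)
    total += config.out_dim * (config.fc_hidden + 1)
    return total


def prepare_training_arrays(sequences: list[tuple[list[RGBDFrame], list[PointLabel]]],
                            roi: ROI, target_size: int,
                            params: NormalizationParams = NormalizationParams()
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Fuse labeled frames into model input/target arrays.

    Returns inputs of shape (N, 4, S, S) float32 and crop-normalised
    targets (N, 2).  Labels outside the crop raise a ValueError.
    """
    inputs, targets = [], []
    for frames, labels in sequences:
        by_index = {f.index: f for f in frames}
        for lab in labels:
            frame = by_index.get(lab.frame_index)
            if frame is None:
                continue
            if not roi.contains(lab.x, lab.y):
                raise ValueError(
                    f"label ({lab.x:.1f}, {lab.y:.1f}) at frame "
                    f"{lab.frame_index} lies outside the crop {roi}")
            fused, transform = fuse_rgbd(frame, roi, target_size, params)
            inputs.append(fused.transpose(2, 0, 1))
            targets.append(transform.to_normalized(lab.x, lab.y))
    if not inputs:
        raise ValueError("no labeled frames: training set is empty")
    return (np.ascontiguousarray(np.stack(inputs), dtype=np.float32),
            np.asarray(targets, dtype=np.float32))


class PoseEstimationModel:
    """Larynx-position regressor over preprocessed RGBD crops.

    Parameters
    ----------
    train_inputs, train_targets : (N, 4, S, S) float32 and (N, 2)
        crop-normalised coordinates, e.g. from
        :func:`prepare_training_arrays`.
    val_inputs, val_targets : the validation split, same layout.
    config : architecture settings; ``config.input_size`` must match S.
    """

    def __init__(self, train_inputs: np.ndarray, train_targets: np.ndarray,
                 val_inputs: np.ndarray, val_targets: np.ndarray,
                 config: ModelConfig | None = None) -> None:
        if len(train_inputs) == 0:
            raise ValueError("training set is empty")
        s = train_inputs.shape[-1]
        self.config = config or ModelConfig(input_size=s)
        if self.config.input_size != s:
            raise ValueError(f"config.input_size {self.config.input_size} "
                             f"does not match data size {s}")
        self.train_inputs = np.asarray(train_inputs, dtype=np.float32)
        self.train_targets = np.asarray(train_targets, dtype=np.float32)
        self.val_inputs = np.asarray(val_inputs, dtype=np.float32)
        self.val_targets = np.asarray(val_targets, dtype=np.float32)

    @classmethod
    def from_sequences(cls, train_sequences, val_sequences, roi: ROI,
                       config: ModelConfig,
                       params: NormalizationParams = NormalizationParams()
                       ) -> "PoseEstimationModel":
        """Build from labeled (frames, labels) sequence pairs."""
        xt, yt = prepare_training_arrays(train_sequences, roi,
                                         config.input_size, params)
        xv, yv = prepare_training_arrays(val_sequences, roi,
                                         config.input_size, params)
        return cls(xt, yt, xv, yv, config)

    def _epoch_val_loss(self, net: nn.Sequential, batch: int = 64) -> float:
        losses, n = 0.0, 0
        for i in range(0, len(self.val_inputs), batch):
            xb = self.val_inputs[i:i + batch]
            pred = net.forward(xb)
            losses += float(np.abs(pred - self.val_targets[i:i + batch]).sum())
            n += pred.size
        return losses / n

    def fit(self, tc: TrainingConfig = TrainingConfig(),
            verbose: bool = False) -> "PoseEstimationResults":
        """Train with Adam/L1 and return the minimum-validation-loss epoch.

        Fully seeded: weight initialisation and the per-epoch shuffling both
        derive from ``tc.seed``, so repeated fits are bit-identical.
        """
        net = build_model(self.config, seed=tc.seed)
        opt = nn.Adam(net.params, lr=tc.learning_rate,
                      beta1=tc.beta1, beta2=tc.beta2)
        shuffle_rng = np.random.default_rng(tc.seed + 1)
        n = len(self.train_inputs)
        history = []
        best_val, best_weights, best_epoch = np.inf, None, -1
        for epoch in range(tc.max_epochs):
            order = shuffle_rng.permutation(n)
            train_loss_sum, train_count = 0.0, 0
            for i in range(0, n, tc.batch_size):
                idx = order[i:i + tc.batch_size]
                xb, yb = self.train_inputs[idx], self.train_targets[idx]
                pred = net.forward(xb)
                loss, grad = nn.l1_loss(pred, yb)
                net.backward(grad)
                opt.step(net.grads)
                train_loss_sum += loss * pred.size
                train_count += pred.size
            val_loss = (self._epoch_val_loss(net)
                        if len(self.val_inputs) else np.nan)
            train_loss = train_loss_sum / train_count
            history.append({"epoch": epoch, "train_l1": train_loss,
                            "val_l1": val_loss})
            if verbose:
                logger.info("epoch %d train L1 %.5f val L1 %.5f",
                            epoch, train_loss, val_loss)
            select_loss = val_loss if np.isfinite(val_loss) else train_loss
            if select_loss < best_val:
                best_val, best_epoch = select_loss, epoch
                best_weights = net.get_weights()
        net.set_weights(best_weights)
        return PoseEstimationResults(
            model=self, network=net, config=self.config, training_config=tc,
            history=pd.DataFrame(history), best_epoch=best_epoch,
            best_val_l1=best_val)


@dataclass
class PoseEstimationResults:
    """Fitted pose-estimation network plus its training history."""

    model: PoseEstimationModel | None
    network: nn.Sequential
    config: ModelConfig
    training_config: TrainingConfig
    history: pd.DataFrame
    best_epoch: int
    best_val_l1: float

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters

    def predict(self, inputs: np.ndarray, batch: int = 64) -> np.ndarray:
        """Forward pass -> crop-normalised (N, 2) predictions."""
        out = []
        for i in range(0, len(inputs), batch):
            out.append(self.network.forward(
                np.asarray(inputs[i:i + batch], dtype=np.float32)))
        return np.concatenate(out, axis=0)

    def summary(self) -> str:
        lines = [
            "Pose Estimation Model (3 ConvBlocks + 2 FC)",
            "=" * 47,
            f"input size:        {self.config.input_size} x {self.config.input_size} x {self.config.in_channels}",
            f"conv channels:     {list(self.config.conv_channels)}",
            f"parameters:        {self.n_parameters:,}",
            f"epochs run:        {len(self.history)}",
            f"selected epoch:    {self.best_epoch} (min validation L1)",
            f"validation L1:     {self.best_val_l1:.5f} (normalised units)",
            f"final train L1:    {self.history['train_l1'].iloc[-1]:.5f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        """Persist weights + configs to an .npz checkpoint."""
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.network.get_weights())}
        np.savez(path, best_epoch=self.best_epoch, best_val_l1=self.best_val_l1,
                 input_size=self.config.input_size,
                 conv_channels=np.asarray(self.config.conv_channels),
                 fc_hidden=self.config.fc_hidden,
                 kernel_size=self.config.kernel_size,
                 **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PoseEstimationResults":
        data = np.load(path)
        config = ModelConfig(
            conv_channels=tuple(int(c) for c in data["conv_channels"]),
            kernel_size=int(data["kernel_size"]),
            fc_hidden=int(data["fc_hidden"]),
            input_size=int(data["input_size"]))
        net = build_model(config, seed=0)
        weights = [data[f"w{i}"] for i in range(len(net.params))]
        net.set_weights(weights)
        return cls(model=None, network=net, config=config,
                   training_config=TrainingConfig(),
                   history=pd.DataFrame(), best_epoch=int(data["best_epoch"]),
                   best_val_l1=float(data["best_val_l1"]))

    def track_sequence(self, frames: list[RGBDFrame], roi: ROI,
                       meta: SequenceMeta,
                       params: NormalizationParams = NormalizationParams()
                       ) -> list[Prediction]:
        """Track a full sequence -> per-frame :class:`Prediction` list."""
        return track_sequence(self, frames, roi, meta, params)


def _sample_depth(depth: np.ndarray, x: float, y: float,
                  radius: int = 3) -> float | None:
    """Depth (mm) at the rounded pixel; nearest valid pixel within
    ``radius`` if the exact pixel reads 0 ("no return")."""
    h, w = depth.shape
    xi = int(round(x))
    yi = int(round(y))
    xi = min(max(xi, 0), w - 1)
    yi = min(max(yi, 0), h - 1)
    if depth[yi, xi] > 0:
        return float(depth[yi, xi])
    y0, y1 = max(yi - radius, 0), min(yi + radius + 1, h)
    x0, x1 = max(xi - radius, 0), min(xi + radius + 1, w)
    patch = depth[y0:y1, x0:x1]
    ys, xs = np.nonzero(patch > 0)
    if len(ys) == 0:
        return None
    d2 = (ys + y0 - yi) ** 2 + (xs + x0 - xi) ** 2
    k = int(np.argmin(d2))
    return float(patch[ys[k], xs[k]])


def track_sequence(results: PoseEstimationResults, frames: list[RGBDFrame],
                   roi: ROI, meta: SequenceMeta,
                   params: NormalizationParams = NormalizationParams()
                   ) -> list[Prediction]:
    """Run the fitted network over every frame of a sequence.

    Per frame: preprocess -> forward pass -> map the crop-normalised output
    back to full-frame pixels -> sample the depth at the rounded predicted
    pixel (nearest valid pixel within 3 px if that reading is invalid).
    Frames with no valid depth nearby are flagged invalid.
    """
    inputs = []
    transform: CropTransform | None = None
    for frame in frames:
        fused, transform = fuse_rgbd(frame, roi, results.config.input_size, params)
        inputs.append(fused.transpose(2, 0, 1))
    norm = results.predict(np.stack(inputs))
    xs, ys = transform.to_fullframe(norm[:, 0], norm[:, 1])
    preds: list[Prediction] = []
    for frame, x, y in zip(frames, xs, ys):
        d = _sample_depth(frame.depth, float(x), float(y))
        if d is None:
            logger.warning("frame %d: no valid depth within 3 px of "
                           "(%.1f, %.1f); prediction flagged invalid",
                           frame.index, x, y)
            preds.append(Prediction(frame.index, float(x), float(y), 0.0,
                                    valid=False))
        else:
            preds.append(Prediction(frame.index, float(x), float(y), d))
    return preds
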