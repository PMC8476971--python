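"""Training of the segmentation U-Net.

The regime is plain stochastic gradient descent on the mean-squared error
between the network output and the signed ground-truth mask: one iteration
= minibatch sampling (uniform with replacement, default size 12) ->
forward propagation -> loss evaluation -> backpropagation -> weight update.
There is no early stopping; the iteration count is configuration.  The
learning rate and momentum are not dictated by the regime and default to
the conventional 0.01 / 0.9; both are recorded in the checkpoint.

Data are always split at *patient* granularity, so no patient contributes
slices to both the training and the test set.
"""

from __future__ import annotations

import time
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dicom_io, preprocess
from .unet import UNetModel

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    minibatch_size: int = 12
    iterations: int = 600
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0
    eval_every: int = 0  # 0 = no periodic evaluation
    sampling: str = "replacement"  # or "epoch"

    def validate(self) -> None:
        if self.minibatch_size < 1 or self.iterations < 1:
            raise ValueError("minibatch_size and iterations must be >= 1")
        if self.sampling not in ("replacement", "epoch"):
            raise ValueError("sampling must be 'replacement' or 'epoch'")


@dataclass
class TrainLog:
    losses: list[float] = field(default_factory=list)
    seconds_per_iteration: list[float] = field(default_factory=list)
    eval_iterations: list[int] = field(default_factory=list)
    eval_mean_iou: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"iteration": np.arange(1, len(self.losses) + 1),
             "loss": self.losses,
             "seconds": self.seconds_per_iteration}
        ).to_csv(path, index=False)


@dataclass
class SliceDataset:
    """Preprocessed slices with patient labels, ready for the network."""

    images: np.ndarray  # (n, H, W) float32 in [-1, 1)
    targets: np.ndarray  # (n, H, W) float32 in {-1, +1}
    patient_ids: np.ndarray  # (n,) str
    slice_index: np.ndarray | None = None  # position within each patient's stack

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "SliceDataset":
        return SliceDataset(
            self.images[idx],
            self.targets[idx],
            self.patient_ids[idx],
            None if self.slice_index is None else self.slice_index[idx],
        )


def split_by_patient(dataset: SliceDataset, train_fraction: float, seed: int
                     ) -> tuple[SliceDataset, SliceDataset]:
    """Split slices into train/test sets at patient granularity.

    Deterministic for a fixed seed; the number of training patients is
    round(train_fraction * n_patients).
    """
    patients = np.unique(dataset.patient_ids)
    if len(patients) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_patients = set(patients[order[:n_train]])
    is_train = np.array([p in train_patients for p in dataset.patient_ids])
    return dataset.subset(is_train), dataset.subset(~is_train)


def mse_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Mean over all elements of the squared difference."""
    prediction = np.asarray(prediction)
    target = np.asarray(target)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch {prediction.shape} vs {target.shape}")
    d = prediction.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(d * d))


def _mean_iou(model: UNetModel, images: np.ndarray, targets: np.ndarray,
              batch: int = 12) -> float:
    from .evaluate import iou

    vals = []
    for i in range(0, len(images), batch):
        out = model.forward(images[i : i + batch], train=False)[:, 0]
        pred = out > 0
        truth = targets[i : i + batch] > 0
        for p, t in zip(pred, truth):
            vals.append(iou(p, t))
    return float(np.mean(vals))


def train(
    model: UNetModel,
    train_set: SliceDataset,
    config: TrainConfig,
    eval_set: SliceDataset | None = None,
) -> tuple[UNetModel, TrainLog]:
    """Run the SGD training loop; returns the model and the loss log.

    Aborts with a diagnostic on NaN loss.  Fixed seed implies an identical
    minibatch sequence and loss trajectory on the same hardware class.
    """
    config.validate()
    if train_set.images.shape[1] != model.config.input_size_px:
        raise ValueError("dataset slice size does not match model input size")
    rng = np.random.default_rng(config.seed)
    n = len(train_set)
    velocity = {name: np.zeros_like(p.value) for name, p in model.named_params()}
    tlog = TrainLog()
    epoch_order: np.ndarray | None = None
    epoch_pos = 0

    for it in range(1, config.iterations + 1):
        t0 = time.perf_counter()
        if config.sampling == "replacement":
            idx = rng.integers(0, n, size=config.minibatch_size)
        else:
            take = []
            while len(take) < config.minibatch_size:
                if epoch_order is None or epoch_pos >= n:
                    epoch_order = rng.permutation(n)
                    epoch_pos = 0
                take.append(epoch_order[epoch_pos])
                epoch_pos += 1
            idx = np.asarray(take)
        x = train_set.images[idx]
        t = train_set.targets[idx][:, None]
        model.zero_grad()
        out = model.forward(x, train=True)
        loss = mse_loss(out, t)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {it} "
                f"(learning_rate={config.learning_rate}); aborting"
            )
        model.backward(2.0 * (out - t) / out.size)
        for name, p in model.named_params():
            g = p.grad
            if config.weight_decay:
                g = g + config.weight_decay * p.value
            v = velocity[name]
            v *= config.momentum
            v -= config.learning_rate * g
            p.value += v
        tlog.losses.append(loss)
        tlog.seconds_per_iteration.append(time.perf_counter() - t0)
        if config.eval_every and eval_set is not None and it % config.eval_every == 0:
            miou = _mean_iou(model, eval_set.images, eval_set.targets)
            tlog.eval_iterations.append(it)
            tlog.eval_mean_iou.append(miou)
            log.info("iteration %d: loss %.4f, eval mean IoU %.3f", it, loss, miou)
    return model, tlog


# ---------------------------------------------------------------------------
# Corpus loading
# ---------------------------------------------------------------------------


def load_manifest(
    manifest_csv,
    params: preprocess.PreprocessParams | None = None,
) -> SliceDataset:
    """Load a training manifest (patient_id, image_path, roi_path, cohort).

    ``image_path`` is a DICOM series directory; ``roi_path`` is either a
    polygon-JSON file or a directory of per-slice PNG masks.  Every slice is
    preprocessed and paired with its signed target.  Prone acquisitions are
    rotated to supine orientation before preprocessing.
    """
    manifest = pd.read_csv(manifest_csv)
    base = Path(manifest_csv).parent
    images, targets, pids, sidx = [], [], [], []
    for _, row in manifest.iterrows():
        image_path = base / row["image_path"]
        roi_path = base / row["roi_path"]
        volume = dicom_io.read_dicom_series(image_path)
        if roi_path.is_dir():
            mask = dicom_io.read_mask_pngs(roi_path)
        else:
            contour = dicom_io.read_roi(roi_path, n_slices=volume.shape[0])
            mask = dicom_io.contour_to_mask(contour, volume.shape)
        volume, mask = dicom_io.orient_supine(volume, mask)
        hu = volume.hu()
        for k in range(hu.shape[0]):
            pre = preprocess.preprocess_slice(hu[k], mask[k], params)
            images.append(pre.image)
            targets.append(pre.target)
            pids.append(str(row["patient_id"]))
            sidx.append(k)
    return SliceDataset(
        np.stack(images), np.stack(targets), np.asarray(pids), np.asarray(sidx)
    )
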