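"""Training loop, inference wrapper, and checkpointing for SegModel.

The optimizer recipe follows the field calibration this package targets:
Adam with learning rate 0.001 and momentum-decay coefficients
beta1 = 0.9, beta2 = 0.98 (note the unusually low beta2 — it is honored as
the default), per-pixel cross-entropy on softmax scores, a fixed number of
epochs, and best-checkpoint selection by test-set mean IoU.

Two working profiles are used in practice:

* paper profile — 300 x 300 tiles (padded to 320 for the 5-stage nets),
  base_width 64, batch 64, 50 epochs;
* desk profile — 64 x 64 tiles, base_width 16, batch 8, a few epochs;
  this is what the test-suite benchmarks run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics, nn
from .models import SegModel, SegModelSpec, build_model
from .synthetic import LabeledTile
from .tiling import DatasetSplit

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.98
    seed: int = 0
    device: str = "cpu"
    loss: str = "cross_entropy"
    foreground_weight: float | None = None  # optional class imbalance weight

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")


@dataclass
class TrainResult:
    model: SegModel
    history: pd.DataFrame  # epoch, loss, miou, recall, precision, f1
    best_epoch: int
    best_miou: float


def _to_arrays(tiles: Sequence[LabeledTile]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([t.image for t in tiles]).astype(np.float32)
    x = imgs.transpose(0, 3, 1, 2) / 255.0 - 0.5
    y = np.stack([t.mask for t in tiles]).astype(np.int64)
    bad = np.setdiff1d(np.unique(y), [0, 1])
    if bad.size:
        raise ValueError(f"labels outside {{0,1}}: {bad.tolist()}")
    return x, y


def _evaluate(model: SegModel, x: np.ndarray, y: np.ndarray, batch: int) -> metrics.MetricReport:
    preds = []
    for i in range(0, x.shape[0], batch):
        p = model.predict_proba(x[i : i + batch])
        preds.append(p.argmax(axis=1).astype(np.uint8))
    pred = np.concatenate(preds)
    return metrics.evaluate_dataset(list(pred), list(y.astype(np.uint8)), mode="pooled")


def train(model: SegModel, split: DatasetSplit, config: TrainConfig) -> TrainResult:
    """Train on ``split.train``; track pooled test mIoU; keep the best weights.

    Fully reproducible for a fixed seed, model initialization and data:
    the seed drives only the minibatch order (weights are seeded at
    ``build_model`` time).
    """
    if len(split.train) == 0:
        raise ValueError("training set is empty")
    x_tr, y_tr = _to_arrays(split.train)
    have_test = len(split.test) > 0
    if have_test:
        x_te, y_te = _to_arrays(split.test)

    weights = None
    if config.foreground_weight is not None:
        weights = np.array([1.0, config.foreground_weight], dtype=np.float32)

    opt = nn.Adam(
        model.params(), lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2
    )
    rng = np.random.default_rng(config.seed)
    rows = []
    best_state, best_miou, best_epoch = None, -1.0, -1
    n = x_tr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            logits = model.forward(x_tr[sel], train=True)
            loss, dlogits = nn.cross_entropy(logits, y_tr[sel], class_weights=weights)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if have_test:
            rep = _evaluate(model, x_te, y_te, config.batch_size)
            row.update(
                miou=rep.miou, recall=rep.recall, precision=rep.cpa, f1=rep.f1
            )
            if rep.miou > best_miou:
                best_miou, best_epoch = rep.miou, epoch
                best_state = model.state_dict()
        rows.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    else:  # no test set: keep final weights
        best_epoch, best_miou = config.epochs - 1, float("nan")
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_miou=best_miou,
    )


def _pad_to_multiple(image: np.ndarray, factor: int) -> tuple[np.ndarray, int, int]:
    h, w = image.shape[:2]
    ph, pw = (-h) % factor, (-w) % factor
    if ph or pw:
        pad = ((0, ph), (0, pw)) + ((0, 0),) * (image.ndim - 2)
        image = np.pad(image, pad, mode="reflect")
    return image, h, w


def predict_mask(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Segment one RGB image into a {0, 1} boll mask.

    Inputs whose sides are not divisible by 2^n_stages are reflect-padded on
    the bottom/right for the forward pass and the prediction is cropped back,
    so the returned mask always matches the input size.
    """
    factor = 2**model.spec.n_stages
    img, h, w = _pad_to_multiple(np.asarray(image), factor)
    x = img.astype(np.float32).transpose(2, 0, 1)[None] / 255.0 - 0.5
    proba = model.predict_proba(x)
    return proba.argmax(axis=1)[0, :h, :w].astype(np.uint8)


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    """Write weights plus the embedded model spec (npz container)."""
    state = model.state_dict()
    np.savez(path, __spec__=np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> SegModel:
    with np.load(path) as data:
        spec = SegModelSpec.from_json(bytes(data["__spec__"]).decode())
        model = build_model(spec)
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model
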