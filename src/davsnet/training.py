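"""Training objective and protocol.

The loss is a median-frequency-balanced weighted cross-entropy: vessel
pixels are heavily outnumbered by background (typically <1:10 inside the
field of view), so each class's contribution is weighted by
``median(class frequencies) / frequency(class)``.  Optimisation uses
Adam with a constant learning rate of 1e-3, first-moment decay 0.9
(second-moment decay 0.999) and mini-batches of 10 images; the
leave-one-out protocol trains on n-1 samples and holds out each sample
exactly once.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import DavsNet, predict_mask

__all__ = [
    "ClassWeights",
    "TrainingConfig",
    "SplitPlan",
    "TrainingResult",
    "TrainingDiverged",
    "median_frequency_weights",
    "weighted_cross_entropy",
    "leave_one_out_splits",
    "Adam",
    "train",
]

#: floor inside log() so an exactly-zero probability cannot produce a
#: non-finite loss
LOG_FLOOR = 1e-12


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights for the (vessel, background) classes."""

    vessel: float
    background: float

    def __post_init__(self) -> None:
        for name in ("vessel", "background"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"ClassWeights.{name} must be finite and > 0, got {v}")

    def as_array(self, dtype=np.float64) -> np.ndarray:
        return np.array([self.vessel, self.background], dtype=dtype)


@dataclass
class TrainingConfig:
    """Optimiser and batching settings.

    Defaults follow the published recipe: Adam, initial learning rate
    1e-3, first-moment (exponential) decay 0.9, mini-batch of 10 images.
    The epoch count is problem-dependent and carries no published
    default.  ``restrict_loss_to_fov`` excludes pixels outside the field
    of view from the loss (off by default: all pixels contribute).
    """

    learning_rate: float = 1e-3
    first_moment_decay: float = 0.9
    second_moment_decay: float = 0.999
    batch_size: int = 10
    epochs: int = 1
    seed: int = 0
    restrict_loss_to_fov: bool = False
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 < self.first_moment_decay < 1 or not 0 < self.second_moment_decay < 1:
            raise ValueError("moment decays must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def median_frequency_weights(masks: Sequence[np.ndarray] | np.ndarray) -> ClassWeights:
    """Median frequency balancing over a collection of binary vessel masks.

    For each class ``c``, ``freq_c`` is the number of class-``c`` pixels
    divided by the total pixel count of the masks in which ``c`` occurs;
    the weight is ``median(freqs) / freq_c`` (the median of two
    frequencies being their midpoint).  Raises if a class never occurs.
    """
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks]
    pixels = np.zeros(2)
    present_total = np.zeros(2)
    for m in masks:
        m = np.asarray(m)
        nv = int((m == 1).sum())
        nb = int((m == 0).sum())
        for c, n in enumerate((nv, nb)):
            if n:
                pixels[c] += n
                present_total[c] += m.size
    names = ("vessel", "background")
    for c in range(2):
        if pixels[c] == 0:
            raise ValueError(f"class {names[c]!r} is absent from every mask; "
                             "median frequency balancing is undefined")
    freq = pixels / present_total
    med = float(np.median(freq))
    return ClassWeights(vessel=med / freq[0], background=med / freq[1])


def weighted_cross_entropy(
    probs: np.ndarray,
    target: np.ndarray,
    weights: ClassWeights,
    fov: Optional[np.ndarray] = None,
) -> float:
    """Mean over (selected) pixels of ``-w_c(p) * log P_c(p)``.

    ``probs`` has a trailing (vessel, background) channel pair; ``target``
    is the binary vessel mask.  Probabilities are floored at
    :data:`LOG_FLOOR` inside the log.  Zero exactly when the prediction
    is one-hot correct everywhere.
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    if probs.shape[:-1] != target.shape:
        raise ValueError(f"probs {probs.shape} and target {target.shape} do not align")
    p_true = np.where(target == 1, probs[..., 0], probs[..., 1])
    w = np.where(target == 1, weights.vessel, weights.background)
    per_pixel = -w * np.log(np.maximum(p_true, LOG_FLOOR))
    if fov is not None:
        sel = np.asarray(fov) == 1
        if not sel.any():
            raise ValueError("empty field of view: no pixels to evaluate")
        return float(per_pixel[sel].mean())
    return float(per_pixel.mean())


@dataclass(frozen=True)
class SplitPlan:
    """Ordered (training ids, held-out ids) pairs."""

    folds: tuple[tuple[tuple, tuple], ...]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def leave_one_out_splits(ids: Sequence) -> SplitPlan:
    """Leave-one-out plan: n folds, each training on n-1 samples.

    Every id is held out exactly once, in input order.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError(f"leave-one-out needs at least 2 samples, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    folds = tuple(
        (tuple(x for x in ids if x != held), (held,))
        for held in ids
    )
    return SplitPlan(folds=folds)


class Adam:
    """Adam optimiser over the nested parameter dict of :class:`DavsNet`.

    Batch-norm running statistics carry no gradient and are never
    touched.  A zero learning rate leaves every parameter unchanged.
    """

    def __init__(self, config: TrainingConfig):
        self.lr = config.learning_rate
        self.b1 = config.first_moment_decay
        self.b2 = config.second_moment_decay
        self.eps = config.epsilon
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for lname, garrs in grads.items():
            for pname, g in garrs.items():
                key = (lname, pname)
                m = self._m.get(key)
                if m is None:
                    m = self._m[key] = np.zeros_like(g, dtype=np.float64)
                    self._v[key] = np.zeros_like(g, dtype=np.float64)
                v = self._v[key]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * np.square(g)
                upd = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                arr = params[lname][pname]
                arr -= upd.astype(arr.dtype)


@dataclass
class TrainingResult:
    """Outcome of a training run.

    ``history`` holds one ``(iteration, loss, learning_rate)`` triple per
    optimisation step; the fitted parameters live on the model itself.
    """

    model: DavsNet
    history: list[tuple[int, float, float]]
    class_weights: ClassWeights
    config: TrainingConfig
    stopped_early: bool = False
    final_accuracy: Optional[float] = None

    @property
    def losses(self) -> np.ndarray:
        return np.array([h[1] for h in self.history])

    def write_loss_log(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "loss", "learning_rate"])
            w.writerows(self.history)

    def summary(self) -> str:
        lines = [
            "Training summary",
            "----------------",
            f"iterations          {len(self.history)}",
            f"learning rate       {self.config.learning_rate:g}",
            f"batch size          {self.config.batch_size}",
            f"class weights       vessel={self.class_weights.vessel:.4f} "
            f"background={self.class_weights.background:.4f}",
            f"first loss          {self.history[0][1]:.6f}" if self.history else "no steps taken",
        ]
        if self.history:
            lines.append(f"final loss          {self.history[-1][1]:.6f}")
        if self.final_accuracy is not None:
            lines.append(f"training accuracy   {self.final_accuracy:.4f}")
        lines.append(f"stopped early       {self.stopped_early}")
        return "\n".join(lines)


def _training_accuracy(model: DavsNet, x: np.ndarray, masks: np.ndarray,
                       fovs: Optional[np.ndarray]) -> float:
    """In-FOV pixel accuracy of the current model over the training arrays."""
    pred = predict_mask(model.forward(x))
    ok = pred == masks
    if fovs is not None:
        sel = fovs == 1
        return float(ok[sel].mean())
    return float(ok.mean())


def train(
    model: DavsNet,
    images,
    masks,
    fovs=None,
    config: Optional[TrainingConfig] = None,
    class_weights: Optional[ClassWeights] = None,
    max_iterations: Optional[int] = None,
    target_accuracy: Optional[float] = None,
    eval_every: int = 10,
) -> TrainingResult:
    """Optimise the model's parameters on image/mask pairs.

    ``images`` is ``(N, H, W, 3)`` (uint8 or float in [0, 1]); ``masks``
    and optional ``fovs`` are ``(N, H, W)`` binary.  Class weights
    default to median frequency balancing over ``masks``.  The loop is
    fully reproducible from ``config.seed``.  Optionally stops early
    once in-FOV training accuracy (checked every ``eval_every``
    iterations) reaches ``target_accuracy``; aborts with
    :class:`TrainingDiverged` if the loss becomes non-finite.
    """
    if config is None:
        config = TrainingConfig()
    images = np.asarray(images)
    masks = np.asarray(masks)
    if images.ndim != 4 or masks.ndim != 3 or images.shape[:3] != masks.shape:
        raise ValueError(f"images {images.shape} / masks {masks.shape} do not align")
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if fovs is not None:
        fovs = np.asarray(fovs)
        if fovs.shape != masks.shape:
            raise ValueError("fov masks must match ground-truth masks in shape")
    if images.dtype == np.uint8:
        images = images.astype(model.dtype) / 255.0

    if class_weights is None:
        class_weights = median_frequency_weights(list(masks))
    w_arr = class_weights.as_array(dtype=model.dtype)

    rng = np.random.default_rng(config.seed)
    optim = Adam(config)
    history: list[tuple[int, float, float]] = []
    iteration = 0
    stopped = False
    if max_iterations is not None:
        budget = max_iterations
    else:
        budget = config.epochs * int(np.ceil(n / config.batch_size))

    done = False
    while not done:
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb = images[sel]
            yb = masks[sel]
            fb = fovs[sel] if (fovs is not None and config.restrict_loss_to_fov) else None

            acts, indices = model.runtime.forward(
                model.params, {"input": xb}, training=True
            )
            probs = acts["softmax"]
            loss = weighted_cross_entropy(probs, yb, class_weights, fov=fb)
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"loss became non-finite ({loss}) at iteration {iteration}"
                )

            # fused softmax + weighted cross-entropy gradient at the logits
            onehot = np.stack([yb == 1, yb == 0], axis=-1).astype(model.dtype)
            w_pix = np.where(yb == 1, w_arr[0], w_arr[1])[..., None]
            if fb is not None:
                w_pix = w_pix * (fb == 1)[..., None]
                count = float((fb == 1).sum())
            else:
                count = float(yb.size)
            dlogits = (w_pix * (probs - onehot) / count).astype(model.dtype)
            grads = model.runtime.backward(
                model.params, {model.LOGIT_LAYER: dlogits}, acts, indices
            )
            optim.step(model.params, grads)

            iteration += 1
            history.append((iteration, loss, config.learning_rate))

            if target_accuracy is not None and iteration % eval_every == 0:
                acc = _training_accuracy(model, images, masks, fovs)
                if acc >= target_accuracy:
                    stopped = True
                    done = True
                    break
            if iteration >= budget:
                done = True
                break

    final_acc = _training_accuracy(model, images, masks, fovs) if target_accuracy is not None else None
    return TrainingResult(
        model=model,
        history=history,
        class_weights=class_weights,
        config=config,
        stopped_early=stopped,
        final_accuracy=final_acc,
    )
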