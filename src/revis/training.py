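"""Fine-tuning regimen and Top-1 evaluation for the model zoo.

The regimen mirrors the benchmark's two-phase cycles: within each cycle the
first epochs train only the classifier head plus the last convolutional
layer before it (preserving earlier features), and the remaining epochs
train the full model.  Defaults are 3 cycles x 9 epochs (6 head-only + 3
full, 27 epochs total), Adam with cross-entropy, and a pluggable
learning-rate policy queried once per cycle (the default halves a base rate
each cycle; the regimen's statistics must not depend on the policy's
internals).

Everything operates on plain ndarray batches (N, 3, H, W) and is
deterministic given the schedule seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import nn
from .behaviour import AnalysisError, ConfusionMatrix
from .models import Model
from .stimuli import BACKGROUND_GREY, ParameterError


class DivergenceError(RuntimeError):
    """Training loss became non-finite; carries the offending epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class StructureError(ValueError):
    pass


def default_lr_policy(cycle: int) -> float:
    """Constant-then-decay stand-in for a learning-rate finder: a fixed base
    rate halved at each new cycle."""
    return 1e-3 * (0.5 ** cycle)


@dataclass
class FinetuneSchedule:
    """Staged freeze/unfreeze schedule of the fine-tuning phase."""

    n_cycles: int = 3
    epochs_per_cycle: int = 9
    head_only_epochs: int = 6
    full_epochs: int = 3
    lr_policy: Callable[[int], float] = default_lr_policy
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.head_only_epochs + self.full_epochs != self.epochs_per_cycle:
            raise ParameterError(
                "head_only_epochs + full_epochs must equal epochs_per_cycle")

    @property
    def total_epochs(self) -> int:
        return self.n_cycles * self.epochs_per_cycle


@dataclass(frozen=True)
class FinetuneDatasetPlan:
    """Per-category layout of the fine-tune set: equal cells over the
    background (original vs neutral grey) x colour (colour vs greyscale)
    design."""

    images_per_category: int

    @property
    def cell_size(self) -> int:
        return self.images_per_category // 4

    @property
    def cells(self) -> list[tuple[str, str, int]]:
        return [(bg, col, self.cell_size)
                for bg in ("original", "neutral_grey")
                for col in ("colour", "greyscale")]


def build_finetune_plan(images_per_category: int) -> FinetuneDatasetPlan:
    """Split a per-category budget into four equal background x colour cells
    (the benchmark's 4,000-per-category layout at full scale)."""
    if images_per_category % 4:
        raise ParameterError(
            f"images_per_category={images_per_category} not divisible by 4")
    return FinetuneDatasetPlan(images_per_category)


# ---------------------------------------------------------------------------
# Parameter freezing
# ---------------------------------------------------------------------------


def trainable_mask(model: Model, phase: str) -> set[str]:
    """Names of the parameters trained in a phase.

    ``head_and_last_conv`` covers the decoder plus the final block's final
    convolution; ``full`` covers everything."""
    names = [n for n, _ in model.named_parameters()]
    if phase == "full":
        return set(names)
    if phase != "head_and_last_conv":
        raise ParameterError(f"unknown phase {phase!r}")
    head = model.head_parameter_names()
    if not head:
        raise StructureError("model has no identifiable decoder")
    return set(head) | set(model.last_conv_parameter_names())


# ---------------------------------------------------------------------------
# The fine-tune loop
# ---------------------------------------------------------------------------


@dataclass
class LabeledImages:
    """A labelled image set; images (N, 3, H, W) in [0, 1]."""

    images: np.ndarray
    labels: np.ndarray
    categories: list[str]


def run_finetune(model: Model, dataset: LabeledImages,
                 schedule: FinetuneSchedule) -> list[dict]:
    """Execute the staged fine-tune schedule in place; returns the loss log.

    Each cycle queries ``schedule.lr_policy`` once, trains
    ``head_only_epochs`` epochs on the head + last-conv mask and then
    ``full_epochs`` on all parameters, with Adam and cross-entropy.  The log
    carries one entry per epoch (cycle, epoch, phase, lr, mean loss).
    """
    rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, 77]))
    x = np.asarray(dataset.images, dtype=float)
    labels = np.asarray(dataset.labels)
    n = x.shape[0]
    log: list[dict] = []
    params = dict(model.named_parameters())
    epoch_index = 0
    model.train()
    for cycle in range(schedule.n_cycles):
        lr = schedule.lr_policy(cycle)
        for phase, n_epochs in (("head_and_last_conv", schedule.head_only_epochs),
                                ("full", schedule.full_epochs)):
            if n_epochs == 0:
                continue
            mask = trainable_mask(model, phase)
            opt = nn.Adam([(k, params[k]) for k in sorted(mask)], lr=lr)
            grad_from = (len(model.blocks) - 1
                         if phase == "head_and_last_conv" else 0)
            for _ in range(n_epochs):
                order = rng.permutation(n)
                losses = []
                for start in range(0, n, schedule.batch_size):
                    idx = order[start:start + schedule.batch_size]
                    opt.zero_grad()
                    model.zero_grad()
                    trace_states = [None] * len(model.blocks)
                    srcs = [None] * len(model.blocks)
                    xt = nn.Tensor(x[idx])
                    for _t in range(model.spec.timesteps):
                        out, trace_states, srcs = model.forward_pass(
                            xt, trace_states, srcs, grad_from=grad_from)
                    loss = nn.cross_entropy(out, labels[idx])
                    if not np.isfinite(loss.data):
                        raise DivergenceError(epoch_index)
                    loss.backward()
                    opt.step()
                    losses.append(float(loss.data))
                log.append({"cycle": cycle, "epoch": epoch_index,
                            "phase": phase, "lr": lr,
                            "loss": float(np.mean(losses))})
                epoch_index += 1
    return log


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def predict_top1(model: Model, images: np.ndarray,
                 timesteps: int | None = None,
                 batch_size: int = 32) -> np.ndarray:
    """Predicted class indices: argmax of the final-timestep logits
    (ties break to the lowest class index)."""
    model.eval()
    preds = []
    with nn.no_grad():
        for start in range(0, images.shape[0], batch_size):
            batch = np.asarray(images[start:start + batch_size], dtype=float)
            trace = model.unroll(batch, timesteps)
            preds.append(trace.final.argmax(axis=1))
    return np.concatenate(preds) if preds else np.zeros(0, dtype=int)


def evaluate_top1(model: Model, images: np.ndarray, labels: Sequence[int],
                  categories: Sequence[str], timesteps: int | None = None,
                  batch_size: int = 32) -> tuple[np.ndarray, ConfusionMatrix]:
    """Top-1 evaluation: per-item correctness plus the stimulus x response
    confusion matrix (row sums equal presented counts)."""
    labels = np.asarray(labels)
    if labels.max(initial=-1) >= len(categories) or labels.min(initial=0) < 0:
        raise AnalysisError("label outside the category set")
    pred = predict_top1(model, images, timesteps, batch_size)
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for t, p in zip(labels, pred):
        counts[t, p] += 1
    return pred == labels, ConfusionMatrix(list(categories), counts)


def model_trial_table(model_name: str, seed: int, conditions: Sequence[str],
                      true_labels: Sequence[str], correct: np.ndarray,
                      responses: Sequence[str]) -> pd.DataFrame:
    """Model evaluation results in the shared human/model trial schema."""
    return pd.DataFrame({
        "subject": f"model:{model_name}:{seed}",
        "condition": list(conditions),
        "masked": False,
        "true": list(true_labels),
        "response": list(responses),
        "rt": np.nan,
        "correct": np.asarray(correct, dtype=bool),
    })


# ---------------------------------------------------------------------------
# Image plumbing
# ---------------------------------------------------------------------------


def to_model_input(pixels: np.ndarray, size: int) -> np.ndarray:
    """Greyscale image -> (3, size, size) model input."""
    img = np.asarray(pixels, dtype=float)
    if img.shape != (size, size):
        img = _sk_resize(img, (size, size), anti_aliasing=True,
                         preserve_range=True)
    return np.repeat(img[None], 3, axis=0)


def realize_finetune_dataset(silhouettes, scenes, images_per_category: int,
                             size: int, seed: int = 0) -> LabeledImages:
    """Desk-scale fine-tune set per the background-split plan.

    Half of each category's images keep an "original" (scene surrogate)
    background, half sit on neutral grey; the pipeline is greyscale, so the
    colour/greyscale halves of the full-scale design coincide here.
    """
    plan = build_finetune_plan(images_per_category)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 311]))
    by_cat: dict[str, list] = {}
    for s in silhouettes:
        by_cat.setdefault(s.category, []).append(s)
    categories = sorted(by_cat)
    xs, ys = [], []
    for ci, cat in enumerate(categories):
        pool = by_cat[cat]
        for i in range(plan.images_per_category):
            sil = pool[int(rng.integers(len(pool)))]
            if i < plan.images_per_category // 2 and scenes:
                bg = scenes[int(rng.integers(len(scenes)))]
                if bg.shape != sil.pixels.shape:
                    bg = _sk_resize(bg, sil.pixels.shape, anti_aliasing=True,
                                    preserve_range=True)
                px = np.where(sil.object_mask, sil.pixels, bg)
            else:
                px = np.where(sil.object_mask, sil.pixels, BACKGROUND_GREY)
            xs.append(to_model_input(px, size))
            ys.append(ci)
    return LabeledImages(images=np.stack(xs), labels=np.array(ys),
                         categories=categories)
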