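"""Two-member ensemble classification: combination, ranking, quality factor.

Each member produces 5-way logits; the ensemble output is the arithmetic
mean of the member softmax probabilities (optionally: mean of logits then
softmax). The quality factor Q = round(p1/p2) over the top-2 combined
probabilities is the report's one-number confidence indicator: Q = 1 flags
a borderline case, large Q a confident one. Under the logit-mean option
the ratio equals exp(z1 - z2) on the combined pre-softmax scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from drgrade.backbones import BackboneContract
from drgrade.dataset import AugmentationSpec, ImageLoader, apply_augmentation, record_seed
from drgrade.io import DatasetManifest, FundusImage, N_CLASSES
from drgrade.nn import Adam, softmax_cross_entropy
from drgrade.preprocess import resize_array

logger = logging.getLogger("drgrade")


def softmax(logits: Sequence[float]) -> np.ndarray:
    """Numerically stable softmax; rejects non-finite input."""
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def combine(member_probs: Sequence[Sequence[float]], mode: str = "mean_prob") -> np.ndarray:
    """Merge member outputs into one probability vector.

    ``mean_prob``: arithmetic mean of member probabilities, renormalized.
    ``mean_logit``: softmax of the mean log-probabilities (equivalent to
    averaging the members' logits up to per-member constants).
    """
    arr = np.asarray(member_probs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one member probability vector")
    lengths = {len(p) for p in member_probs}
    if len(lengths) != 1:
        raise ValueError("member probability vectors differ in length")
    if mode == "mean_prob":
        merged = arr.mean(axis=0)
    elif mode == "mean_logit":
        merged = np.exp(np.log(np.clip(arr, 1e-300, None)).mean(axis=0))
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return merged / merged.sum()


def rank_classes(combined_probs: Sequence[float]) -> tuple[np.ndarray, int, int]:
    """Classes by descending probability; ties break toward the lower index."""
    p = np.asarray(combined_probs, dtype=np.float64)
    ranking = np.argsort(-p, kind="stable")
    return ranking, int(ranking[0]), int(ranking[1])


def quality_factor(combined_probs: Sequence[float]) -> int:
    """Q = round(p_top1 / p_top2), clamped to [1, 99]; p_top2 = 0 gives 99."""
    _, top1, top2 = rank_classes(combined_probs)
    p = np.asarray(combined_probs, dtype=np.float64)
    if p[top2] <= 0:
        return 99
    return int(np.clip(np.rint(p[top1] / p[top2]), 1, 99))


@dataclass
class EnsemblePrediction:
    """Per-member and combined class probabilities with ranking and Q."""

    member_probs: dict[str, np.ndarray]
    combined_probs: np.ndarray
    ranking: np.ndarray
    top1: int
    top2: int
    Q: int

    def __post_init__(self) -> None:
        for name, p in self.member_probs.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-6:
                raise ValueError(f"member {name!r} probabilities do not sum to 1")
        if abs(float(np.sum(self.combined_probs)) - 1.0) > 1e-6:
            raise ValueError("combined probabilities do not sum to 1")
        if sorted(self.ranking.tolist()) != list(range(N_CLASSES)):
            raise ValueError("ranking must be a permutation of 0..4")
        if self.Q < 1:
            raise ValueError("quality factor must be >= 1")


def _member_input(member: BackboneContract, image: FundusImage) -> np.ndarray:
    px = image.pixels
    if px.shape[:2] != (member.input_side, member.input_side):
        px = np.clip(np.rint(resize_array(px.astype(np.float64), member.input_side,
                                          member.input_side)), 0, 255).astype(np.uint8)
    return member.preprocess(px)[None]


def predict(image: FundusImage, members: Sequence[BackboneContract],
            mode: str = "mean_prob") -> EnsemblePrediction:
    """Run every member on one image and merge into an EnsemblePrediction."""
    if not members:
        raise ValueError("need at least one ensemble member")
    member_probs: dict[str, np.ndarray] = {}
    for member in members:
        try:
            _, logits = member.forward(_member_input(member, image))
        except Exception as exc:
            raise RuntimeError(f"backbone {member.name!r} failed: {exc}") from exc
        member_probs[member.name] = softmax(logits[0])
    combined = combine(list(member_probs.values()), mode=mode)
    ranking, top1, top2 = rank_classes(combined)
    return EnsemblePrediction(member_probs=member_probs, combined_probs=combined,
                              ranking=ranking, top1=top1, top2=top2,
                              Q=quality_factor(combined))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale training hyperparameters (conventional defaults)."""

    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    dynamic_augmentation: bool = True
    aug_spec: AugmentationSpec = field(default_factory=AugmentationSpec)


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    train_acc: float
    val_acc: float


def _prepare_split(manifest: DatasetManifest, loader: ImageLoader, split: str,
                   side: int) -> tuple[list, np.ndarray]:
    """Resolve a split's records to uint8 arrays at the network side."""
    records = [r for r in manifest.records if r.split == split]
    entries = []
    for rec in records:
        img = loader.load(rec)
        px = img.pixels
        if px.shape[:2] != (side, side):
            px = np.clip(np.rint(resize_array(px.astype(np.float64), side, side)),
                         0, 255).astype(np.uint8)
        entries.append((rec, px))
    labels = np.array([rec.grade for rec, _ in entries], dtype=np.int64)
    return entries, labels


def _batch_tensor(member: BackboneContract, arrays: list[np.ndarray]) -> np.ndarray:
    return np.stack([member.preprocess(px) for px in arrays])


def evaluate_accuracy(member_list, entries, labels, batch_size: int = 32,
                      mode: str = "mean_prob") -> tuple[float, np.ndarray]:
    """Ensemble accuracy and predicted grades on prepared entries."""
    preds = []
    for start in range(0, len(entries), batch_size):
        chunk = entries[start : start + batch_size]
        probs = []
        for member in member_list:
            x = _batch_tensor(member, [px for _, px in chunk])
            _, logits = member.forward(x)
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            probs.append(ez / ez.sum(axis=1, keepdims=True))
        merged = np.stack(probs).mean(axis=0) if mode == "mean_prob" else np.exp(
            np.log(np.clip(np.stack(probs), 1e-300, None)).mean(axis=0))
        preds.append(merged.argmax(axis=1))
    predicted = np.concatenate(preds) if preds else np.empty(0, dtype=int)
    acc = float((predicted == labels).mean()) if len(labels) else float("nan")
    return acc, predicted


def train(manifest: DatasetManifest, members: Sequence[BackboneContract],
          config: TrainConfig, loader: ImageLoader) -> dict[str, list[EpochLog]]:
    """Train each member independently on the dynamically augmented stream.

    Every epoch visits each static train record once, freshly perturbed
    (flip/rotation/channel shift) when dynamic augmentation is on; the
    validation split is scored un-perturbed after every epoch. Fully
    seeded: identical seeds give identical weights and logs.
    """
    train_records = [r for r in manifest.records if r.split == "train"]
    if not train_records:
        raise ValueError("empty train split")
    history: dict[str, list[EpochLog]] = {}
    for m_idx, member in enumerate(members):
        m_seed = record_seed(config.seed, member.name, "member")
        rng = np.random.default_rng(m_seed)
        entries, labels = _prepare_split(manifest, loader, "train", member.input_side)
        val_entries, val_labels = _prepare_split(manifest, loader, "val", member.input_side)
        optimizer = Adam(member.parameters(), lr=config.learning_rate)
        logs: list[EpochLog] = []
        for epoch in range(config.epochs):
            order = rng.permutation(len(entries))
            losses, correct = [], 0
            for start in range(0, len(order), config.batch_size):
                idx = order[start : start + config.batch_size]
                batch_px = []
                for i in idx:
                    rec, px = entries[i]
                    if config.dynamic_augmentation:
                        img = FundusImage(pixels=px, grade=rec.grade, origin=rec.origin,
                                          id=rec.id)
                        img = apply_augmentation(
                            img, config.aug_spec,
                            record_seed(m_seed, rec.id, f"ep{epoch}"))
                        batch_px.append(img.pixels)
                    else:
                        batch_px.append(px)
                x = _batch_tensor(member, batch_px)
                y = labels[idx]
                _, logits = member.forward(x)
                loss, dlogits = softmax_cross_entropy(logits, y)
                member.backward_from_logits(dlogits.astype(np.float32))
                optimizer.step()
                losses.append(loss)
                correct += int((logits.argmax(axis=1) == y).sum())
            train_acc = correct / len(entries)
            val_acc, _ = evaluate_accuracy([member], val_entries, val_labels) if len(
                val_entries) else (float("nan"), None)
            log = EpochLog(epoch=epoch, train_loss=float(np.mean(losses)),
                           train_acc=train_acc, val_acc=val_acc)
            logs.append(log)
            logger.info("member=%s epoch=%d loss=%.4f train_acc=%.3f val_acc=%.3f",
                        member.name, epoch, log.train_loss, log.train_acc, log.val_acc)
        history[member.name] = logs
    return history
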