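"""Dataset assembly: capping, splitting, balancing, merging and accounting.

The assembly order matters clinically and statistically: the primary data
is capped per class, split 80/20 into train/validation *before* any
augmentation (so no derived image ever leaks across the split boundary),
then the training side is topped up with compatible auxiliary images and
flip/rotate/channel-shift copies until each class reaches a common target,
and finally every record (both splits) is expanded into its three
Gaussian-blend variants. During training a dynamic stream re-perturbs
every static record once per epoch.

All of this is bookkept in the manifest; derived records are lazy (the
pixels are rendered on demand from the parent via a per-record seed), so
the full accounting of the assembly is recomputable from records alone.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from drgrade.io import (
    DERIVED_ORIGINS,
    DatasetManifest,
    FundusImage,
    ManifestRecord,
    N_CLASSES,
    SOURCE_ORIGINS,
    read_image,
)
from drgrade.preprocess import BlurSpec, gaussian_blend

logger = logging.getLogger("drgrade")


class OrderingError(RuntimeError):
    """Raised when assembly stages are applied out of order."""


@dataclass(frozen=True)
class AugmentationSpec:
    """Random flip / rotation / RGB channel-shift perturbation.

    horizontal_flip
        Probability of a left-right flip.
    rotation_range
        Rotation drawn uniformly in [-range, +range] degrees; exposed
        corners fill with black (the fundus background).
    channel_shift
        Per-channel integer offset drawn uniformly in [-shift, +shift]
        gray levels (0-255 scale), clipped.
    """

    horizontal_flip: float = 0.5
    rotation_range: float = 10.0
    channel_shift: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        if not (0 <= int(self.channel_shift) <= 255):
            raise ValueError("channel_shift must be an integer in [0, 255]")


@dataclass(frozen=True)
class AssemblyPlan:
    """Targets and quotas of the dataset assembly.

    Defaults mirror the study protocol: cap each class at 150 primary
    images, split 80/20, add per-class auxiliary quotas of
    {40, 40, 40, 70, 80} to training, balance every class's training pool
    to 160 images, and train for 30 epochs of dynamic augmentation.
    """

    per_class_cap: int = 150
    val_fraction: float = 0.2
    train_class_target: int = 160
    auxiliary_quota: tuple[int, ...] = (40, 40, 40, 70, 80)
    epochs: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.per_class_cap < 1:
            raise ValueError("per_class_cap must be >= 1")
        if len(self.auxiliary_quota) != N_CLASSES:
            raise ValueError("auxiliary_quota must have five entries")


def record_seed(stage_seed: int, record_id: str, extra: str = "") -> int:
    """Deterministic per-record seed below 2**31."""
    return int(zlib.crc32(f"{stage_seed}:{record_id}:{extra}".encode()) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def class_fractions(counts: Sequence[int]) -> pd.DataFrame:
    """Per-class percentages of a count vector at exact, 2-decimal and
    integer precision (the two precisions used when reporting the class
    distribution of an imbalanced dataset)."""
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("total count must be > 0")
    pct = 100.0 * counts / total
    return pd.DataFrame(
        {
            "count": counts,
            "percent": pct,
            "percent_2dec": np.round(pct, 2),
            "percent_int": np.round(pct).astype(int),
        }
    )


@dataclass
class AccountingTable:
    """Per-class assembly accounting, recomputed from manifest records."""

    per_class: pd.DataFrame
    fractions: pd.DataFrame
    artificial_per_real: float
    epochs: int

    @property
    def dynamic_train_total(self) -> int:
        return int(self.per_class["dynamic_train_total"].sum())

    @property
    def dynamic_val_total(self) -> int:
        return int(self.per_class["dynamic_val_total"].sum())


def accounting(manifest: DatasetManifest, plan: AssemblyPlan | None = None) -> AccountingTable:
    """Recompute every assembly count from the record set alone.

    ``available``/``selected`` are the source-origin records (what
    survives capping); train/val splits, auxiliary, augmented and
    blur-variant counts come from origin and split fields; dynamic totals
    multiply the static (blur) counts by the planned epochs. The
    artificial-per-real ratio is what full balancing of the rarest class
    to the most populated one would require: (max - min) / min.
    """
    plan = plan or AssemblyPlan()
    rows = []
    for c in range(N_CLASSES):
        recs = [r for r in manifest.records if r.grade == c]
        source = [r for r in recs if r.origin in SOURCE_ORIGINS]
        aux = [r for r in recs if r.origin == "auxiliary"]
        augmented = [r for r in recs if r.origin == "augmented"]
        blur = [r for r in recs if r.origin == "blur_variant"]
        blur_train = sum(1 for r in blur if r.split == "train")
        blur_val = sum(1 for r in blur if r.split == "val")
        rows.append(
            {
                "class": manifest.class_labels[c],
                "available": len(source),
                "selected": len(source),
                "orig_train": sum(1 for r in source if r.split == "train"),
                "orig_val": sum(1 for r in source if r.split == "val"),
                "auxiliary_train": sum(1 for r in aux if r.split == "train"),
                "augmented_train": sum(1 for r in augmented if r.split == "train"),
                "blur_train": blur_train,
                "blur_val": blur_val,
                "dynamic_train_total": blur_train * plan.epochs,
                "dynamic_val_total": blur_val * plan.epochs,
            }
        )
    per_class = pd.DataFrame(rows)
    avail = per_class["available"].to_numpy()
    if avail.sum() > 0:
        fractions = class_fractions(avail)
    else:
        fractions = pd.DataFrame(
            {"count": avail, "percent": 0.0, "percent_2dec": 0.0, "percent_int": 0}
        )
    positive = avail[avail > 0]
    ratio = float((positive.max() - positive.min()) / positive.min()) if positive.size else 0.0
    return AccountingTable(per_class=per_class, fractions=fractions,
                           artificial_per_real=ratio, epochs=plan.epochs)


# ---------------------------------------------------------------------------
# Selection and splitting
# ---------------------------------------------------------------------------

def select_balanced(manifest: DatasetManifest, plan: AssemblyPlan, seed: int) -> DatasetManifest:
    """Uniformly subsample every class above the per-class cap to the cap."""
    bad = [r for r in manifest.records if r.origin not in SOURCE_ORIGINS]
    if bad:
        raise OrderingError("select_balanced expects only primary-origin records")
    rng = np.random.default_rng(seed)
    kept: list[ManifestRecord] = []
    for c in range(N_CLASSES):
        recs = [r for r in manifest.records if r.grade == c]
        if not recs:
            logger.warning("class %s is empty before selection", manifest.class_labels[c])
            continue
        if len(recs) > plan.per_class_cap:
            idx = np.sort(rng.choice(len(recs), size=plan.per_class_cap, replace=False))
            recs = [recs[i] for i in idx]
        kept.extend(recs)
    order = {r.id: i for i, r in enumerate(manifest.records)}
    kept.sort(key=lambda r: order[r.id])
    return DatasetManifest(kept, manifest.class_labels)


def stratified_split(manifest: DatasetManifest, val_fraction: float, seed: int) -> DatasetManifest:
    """Assign train/val per class, validation = round(fraction * n), half-up.

    Must run before any augmentation: derived records present is an
    ordering violation (it would leak shared parents across the split).
    """
    if any(r.origin in DERIVED_ORIGINS for r in manifest.records):
        raise OrderingError("stratified_split must run before augmentation")
    if any(r.split != "unassigned" for r in manifest.records):
        raise OrderingError("manifest already carries split assignments")
    rng = np.random.default_rng(seed)
    assigned: dict[str, str] = {}
    for c in range(N_CLASSES):
        recs = [r for r in manifest.records if r.grade == c]
        n = len(recs)
        n_val = int(np.floor(val_fraction * n + 0.5))  # round half-up
        perm = rng.permutation(n)
        val_ids = {recs[i].id for i in perm[:n_val]}
        for r in recs:
            assigned[r.id] = "val" if r.id in val_ids else "train"
    return DatasetManifest(
        [r.with_(split=assigned[r.id]) for r in manifest.records], manifest.class_labels
    )


# ---------------------------------------------------------------------------
# Auxiliary-image compatibility and merging
# ---------------------------------------------------------------------------

def is_compatible(image: FundusImage) -> bool:
    """Auxiliary-image selection rule.

    Accept iff (a) the non-background region is a full circle, with
    diameter at least 0.95 x min(H, W), that touches no frame border
    (horizontally clipped fundus views fail this), and (b) a bright,
    approximately square connected component with side between 1% and 5%
    of the width sits in the first quadrant (top-right).
    """
    px = image.pixels
    h, w = px.shape[:2]
    fg = px.max(axis=2) > 20
    labels, n = ndimage.label(fg)
    if n == 0:
        return False
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    main = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(labels == main)
    bb_h = rows.max() - rows.min() + 1
    bb_w = cols.max() - cols.min() + 1
    if max(bb_h, bb_w) < 0.95 * min(h, w):
        return False
    if rows.min() == 0 or rows.max() == h - 1 or cols.min() == 0 or cols.max() == w - 1:
        return False  # circle clipped by the frame
    # roughly circular: fill fraction of the bounding box near pi/4
    fill = len(rows) / float(bb_h * bb_w)
    if not (0.6 <= fill <= 0.95):
        return False

    bright = px.min(axis=2) > 245
    labels, n = ndimage.label(bright)
    for k in range(1, n + 1):
        rows, cols = np.nonzero(labels == k)
        sh = rows.max() - rows.min() + 1
        sw = cols.max() - cols.min() + 1
        side = max(sh, sw)
        if not (0.01 * w <= side <= 0.05 * w):
            continue
        if not (0.75 <= sh / sw <= 1.33):
            continue
        if len(rows) / float(sh * sw) < 0.75:
            continue  # not filled: not a square
        cy, cx = rows.mean(), cols.mean()
        if cy < h / 2 and cx >= w / 2:
            return True
    return False


def compatibility_filter(images: Iterable[FundusImage]) -> list[FundusImage]:
    """Keep only auxiliary images passing the compatibility rule."""
    return [im for im in images if is_compatible(im)]


def merge_auxiliary(manifest: DatasetManifest, auxiliary: DatasetManifest,
                    plan: AssemblyPlan, seed: int) -> DatasetManifest:
    """Add the per-class auxiliary quota to the training split.

    Auxiliary images never enter validation; every class with a positive
    quota receives exactly that many records, sampled uniformly.
    """
    rng = np.random.default_rng(seed)
    existing = {r.id for r in manifest.records}
    added: list[ManifestRecord] = []
    for c in range(N_CLASSES):
        quota = int(plan.auxiliary_quota[c])
        if quota == 0:
            continue
        pool = [r for r in auxiliary.records if r.grade == c]
        if quota > len(pool):
            raise ValueError(
                f"auxiliary quota {quota} exceeds available {len(pool)} "
                f"for class {manifest.class_labels[c]!r}"
            )
        idx = np.sort(rng.choice(len(pool), size=quota, replace=False))
        for i in idx:
            rec = pool[i]
            new_id = rec.id if rec.id not in existing else f"aux__{rec.id}"
            existing.add(new_id)
            added.append(rec.with_(id=new_id, split="train", origin="auxiliary"))
    return manifest.extended(added)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def apply_augmentation(image: FundusImage, spec: AugmentationSpec, seed: int) -> FundusImage:
    """Random horizontal flip, rotation and RGB channel shift (seeded)."""
    rng = np.random.default_rng(seed)
    px = image.pixels
    if rng.random() < spec.horizontal_flip:
        px = px[:, ::-1, :]
    angle = float(rng.uniform(-spec.rotation_range, spec.rotation_range))
    if spec.rotation_range > 0:
        px = ndimage.rotate(px.astype(np.float64), angle, axes=(1, 0), reshape=False,
                            order=1, mode="constant", cval=0.0)
    else:
        px = px.astype(np.float64)
    shift = rng.integers(-spec.channel_shift, spec.channel_shift + 1, size=3)
    px = px + shift[None, None, :]
    pixels = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels, grade=image.grade, origin="augmented",
                       id=image.id, parent_id=image.parent_id)


def balance_augment(manifest: DatasetManifest, spec: AugmentationSpec,
                    plan: AssemblyPlan) -> DatasetManifest:
    """Append augmented copies until each class's train pool reaches target.

    Parents are train-split source images of the same class (auxiliary
    images are never augmented); parents are cycled in seeded random
    order so coverage is even. Classes already at target gain nothing.
    """
    if any(r.split == "unassigned" for r in manifest.records):
        raise OrderingError("balance_augment requires split assignment first")
    rng = np.random.default_rng(spec.seed)
    added: list[ManifestRecord] = []
    for c in range(N_CLASSES):
        if not any(r.grade == c for r in manifest.records):
            logger.warning("class %s is empty; skipping balancing", manifest.class_labels[c])
            continue
        train = [r for r in manifest.records if r.grade == c and r.split == "train"]
        need = plan.train_class_target - len(train)
        if need <= 0:
            continue
        parents = [r for r in train if r.origin in SOURCE_ORIGINS]
        if not parents:
            raise ValueError(
                f"class {manifest.class_labels[c]!r} has no train originals to augment"
            )
        order = rng.permutation(len(parents))
        for k in range(need):
            parent = parents[order[k % len(parents)]]
            added.append(
                ManifestRecord(
                    id=f"{parent.id}__aug{k // len(parents)}",
                    path="",
                    grade=parent.grade,
                    split="train",
                    origin="augmented",
                    parent_id=parent.id,
                )
            )
    return manifest.extended(added)


def expand_blur_variants(manifest: DatasetManifest, spec: BlurSpec | None = None) -> DatasetManifest:
    """Replace every record (train and validation) by its three
    Gaussian-blend variants; per-split and per-class counts triple."""
    spec = spec or BlurSpec()
    out: list[ManifestRecord] = []
    for rec in manifest.records:
        for k in range(3):
            out.append(
                ManifestRecord(
                    id=f"{rec.id}__s{k}",
                    path="",
                    grade=rec.grade,
                    split=rec.split,
                    origin="blur_variant",
                    parent_id=rec.id,
                )
            )
    return DatasetManifest(out, manifest.class_labels)


# ---------------------------------------------------------------------------
# Lazy pixel resolution and dynamic streaming
# ---------------------------------------------------------------------------

class ImageLoader:
    """Resolve any manifest record to pixels, rendering derived records.

    ``lineage`` maps every record id ever created (including intermediate
    records dropped by blur expansion) to its record, so that an
    augmented or blur-variant record can be rebuilt from its parent with
    the deterministic per-record seed.
    """

    def __init__(self, lineage: dict[str, ManifestRecord],
                 images: Optional[dict[str, FundusImage]] = None,
                 aug_spec: Optional[AugmentationSpec] = None,
                 blur_spec: Optional[BlurSpec] = None):
        self.lineage = dict(lineage)
        self.images = images or {}
        self.aug_spec = aug_spec or AugmentationSpec()
        self.blur_spec = blur_spec or BlurSpec()
        self._cache: dict[str, FundusImage] = {}

    def load(self, record: ManifestRecord) -> FundusImage:
        return self._resolve(record.id)

    def _resolve(self, rec_id: str) -> FundusImage:
        if rec_id in self._cache:
            return self._cache[rec_id]
        rec = self.lineage.get(rec_id)
        if rec is None:
            if rec_id in self.images:
                return self.images[rec_id]
            raise KeyError(f"unknown record id {rec_id!r}")
        if rec.origin in SOURCE_ORIGINS or rec.origin == "auxiliary":
            img = self.images.get(rec_id)
            if img is None:
                img = read_image(rec.path)
                img.grade = rec.grade
                img.id = rec.id
            out = img
        elif rec.origin == "augmented":
            parent = self._resolve(rec.parent_id)
            out = apply_augmentation(parent, self.aug_spec,
                                     record_seed(self.aug_spec.seed, rec.id, "aug"))
            out.id = rec.id
            out.parent_id = rec.parent_id
        elif rec.origin == "blur_variant":
            parent = self._resolve(rec.parent_id)
            k = int(rec.id.rsplit("__s", 1)[1]) if "__s" in rec.id else 0
            out = gaussian_blend(parent, self.blur_spec.sigmas[k], self.blur_spec)
            out.origin = "blur_variant"
            out.id = rec.id
            out.parent_id = rec.parent_id
        else:  # pragma: no cover - origins are validated upstream
            raise ValueError(f"cannot resolve origin {rec.origin!r}")
        self._cache[rec_id] = out
        return out


def dynamic_stream(manifest: DatasetManifest, spec: AugmentationSpec, epochs: int,
                   seed: int, loader: ImageLoader) -> tuple[Iterator[tuple[int, ManifestRecord, FundusImage]], int]:
    """Per-epoch stream of freshly perturbed images over the static records.

    Every epoch yields one flip/rotate/shift perturbation of each static
    record; the total number of images yielded is ``len(manifest) * epochs``.
    Fully determined by ``seed``.
    """
    if epochs <= 0:
        raise ValueError("epochs must be >= 1")
    total = len(manifest) * epochs

    def gen():
        for epoch in range(epochs):
            for rec in manifest.records:
                base = loader.load(rec)
                img = apply_augmentation(base, spec, record_seed(seed, rec.id, f"ep{epoch}"))
                img.id = f"{rec.id}__ep{epoch}"
                yield epoch, rec, img

    return gen(), total


# ---------------------------------------------------------------------------
# Leakage check and one-call assembly
# ---------------------------------------------------------------------------

def _root_key(rec: ManifestRecord, by_id: dict[str, ManifestRecord]) -> str:
    cur = rec
    while cur.parent_id is not None:
        nxt = by_id.get(cur.parent_id)
        if nxt is None:
            # Parent dropped from the manifest (blur expansion removes its
            # inputs); derived ids are suffixed, so strip back to the root.
            return cur.parent_id.split("__")[0]
        cur = nxt
    return cur.id.split("__")[0]


def check_leakage(manifest: DatasetManifest) -> bool:
    """True iff no source image contributes to both train and validation."""
    by_id = manifest.by_id()
    split_of_root: dict[str, set[str]] = {}
    for rec in manifest.records:
        if rec.split == "unassigned":
            continue
        split_of_root.setdefault(_root_key(rec, by_id), set()).add(rec.split)
    return all(len(s) == 1 for s in split_of_root.values())


@dataclass
class AssemblyResult:
    """Final manifest plus everything needed to render its pixels."""

    manifest: DatasetManifest
    loader: ImageLoader
    plan: AssemblyPlan
    table: AccountingTable
    stages: dict[str, DatasetManifest] = field(default_factory=dict)


def assemble_dataset(primary: DatasetManifest, plan: AssemblyPlan, aug_spec: AugmentationSpec,
                     seed: int, images: Optional[dict[str, FundusImage]] = None,
                     auxiliary: Optional[DatasetManifest] = None,
                     aux_images: Optional[dict[str, FundusImage]] = None,
                     blur_spec: Optional[BlurSpec] = None,
                     expand_blur: bool = True) -> AssemblyResult:
    """Run the full assembly: cap, split, merge auxiliary, balance, expand."""
    rng = np.random.default_rng(seed)
    s_select, s_split, s_merge = (int(rng.integers(2**31 - 1)) for _ in range(3))
    stages: dict[str, DatasetManifest] = {"input": primary}
    m = select_balanced(primary, plan, s_select)
    stages["selected"] = m
    m = stratified_split(m, plan.val_fraction, s_split)
    stages["split"] = m
    if auxiliary is not None:
        m = merge_auxiliary(m, auxiliary, plan, s_merge)
        stages["merged"] = m
    m = balance_augment(m, aug_spec, plan)
    stages["balanced"] = m
    lineage = {r.id: r for r in m.records}
    if expand_blur:
        m = expand_blur_variants(m, blur_spec)
        for r in m.records:
            lineage[r.id] = r
    stages["final"] = m
    all_images = dict(images or {})
    if aux_images:
        all_images.update(aux_images)
    loader = ImageLoader(lineage, all_images, aug_spec, blur_spec)
    return AssemblyResult(manifest=m, loader=loader, plan=plan,
                          table=accounting(m, plan), stages=stages)
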