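"""Images, dataset manifests, run configuration and logging.

The manifest is the bookkeeping backbone of the pipeline: every derived
image (balancing augmentation, Gaussian-blend variant) is a record with a
``parent_id`` pointing at its source, so split assignment, leakage freedom
and all per-class accounting are recomputable from the record set alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

#: ICDR severity grades 0-4.
ICDR_CLASS_NAMES = ("No DR", "Mild", "Moderate", "Severe", "Proliferative")

#: Number of ICDR grades.
N_CLASSES = 5

VALID_SPLITS = ("train", "val", "unassigned")
#: 'primary' and 'synthetic' are source images; 'auxiliary' are compatible
#: images merged from a second acquisition campaign; 'augmented' and
#: 'blur_variant' are derived and must carry a parent.
VALID_ORIGINS = ("primary", "auxiliary", "augmented", "blur_variant", "synthetic")
SOURCE_ORIGINS = ("primary", "synthetic")
DERIVED_ORIGINS = ("augmented", "blur_variant")

MANIFEST_COLUMNS = ("id", "path", "grade", "split", "origin", "parent_id")


class ManifestError(ValueError):
    """Raised when a manifest violates its structural invariants."""


@dataclass
class FundusImage:
    """An RGB fundus photograph held as an H x W x 3 uint8 array."""

    pixels: np.ndarray
    grade: Optional[int] = None
    origin: str = "primary"
    id: str = ""
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have height and width >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.grade is not None and self.grade not in range(N_CLASSES):
            raise ValueError(f"grade must be in 0..4, got {self.grade}")
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    """One image entry: identity, label, split assignment and lineage."""

    id: str
    path: str
    grade: int
    split: str = "unassigned"
    origin: str = "primary"
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ManifestError("record id must be non-empty")
        if self.grade not in range(N_CLASSES):
            raise ManifestError(f"grade must be in 0..4, got {self.grade!r}")
        if self.split not in VALID_SPLITS:
            raise ManifestError(f"unknown split {self.split!r}")
        if self.origin not in VALID_ORIGINS:
            raise ManifestError(f"unknown origin {self.origin!r}")
        if self.origin in DERIVED_ORIGINS and not self.parent_id:
            raise ManifestError(f"{self.origin} record {self.id!r} must carry parent_id")

    def with_(self, **changes) -> "ManifestRecord":
        return replace(self, **changes)


@dataclass
class DatasetManifest:
    """An ordered record set with the five ICDR class labels."""

    records: list[ManifestRecord] = field(default_factory=list)
    class_labels: tuple[str, ...] = ICDR_CLASS_NAMES

    def __post_init__(self) -> None:
        self.records = list(self.records)
        self.validate()

    def validate(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ManifestError(f"duplicate record id {dup!r}")
        by_id = {r.id: r for r in self.records}
        # Parent chains must terminate and never cycle.
        for rec in self.records:
            seen: set[str] = set()
            cur = rec
            while cur.parent_id is not None:
                if cur.parent_id in seen or cur.parent_id == cur.id:
                    raise ManifestError(f"cyclic parent chain at {rec.id!r}")
                seen.add(cur.id)
                nxt = by_id.get(cur.parent_id)
                if nxt is None:
                    break  # parent outside this manifest (e.g. after subsetting)
                cur = nxt

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, ManifestRecord]:
        return {r.id: r for r in self.records}

    def root_id(self, record_id: str) -> str:
        """Follow the parent chain to the original source image id."""
        by_id = self.by_id()
        cur = by_id[record_id]
        while cur.parent_id is not None and cur.parent_id in by_id:
            cur = by_id[cur.parent_id]
        return cur.parent_id if cur.parent_id is not None else cur.id

    def class_counts(
        self, split: Optional[str] = None, origins: Optional[Sequence[str]] = None
    ) -> np.ndarray:
        counts = np.zeros(N_CLASSES, dtype=int)
        for rec in self.records:
            if split is not None and rec.split != split:
                continue
            if origins is not None and rec.origin not in origins:
                continue
            counts[rec.grade] += 1
        return counts

    def subset(self, predicate) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if predicate(r)], self.class_labels)

    def extended(self, new_records: Iterable[ManifestRecord]) -> "DatasetManifest":
        return DatasetManifest(self.records + list(new_records), self.class_labels)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "path": r.path,
                "grade": r.grade,
                "split": r.split,
                "origin": r.origin,
                "parent_id": "" if r.parent_id is None else r.parent_id,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def read_image(path: str | Path) -> FundusImage:
    """Decode a PNG or JPEG file into a 3-channel fundus image.

    Grayscale inputs are replicated across the three channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise ValueError(f"cannot decode image {path}: {exc}") from exc
    return FundusImage(pixels=pixels, id=path.stem)


def write_image(image: FundusImage, path: str | Path) -> Path:
    """Write an image to disk; PNG is lossless and is the pipeline default.

    JPEG is permitted only for rendered report figures.
    """
    path = Path(path)
    if image.pixels.size == 0:
        raise ValueError("refusing to write a zero-sized image")
    suffix = path.suffix.lower()
    if suffix not in {".png", ".jpg", ".jpeg"}:
        raise ValueError(f"unsupported image format {suffix!r}; use PNG (or JPEG for reports)")
    im = Image.fromarray(image.pixels, mode="RGB")
    im.save(path)
    return path


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Serialize a manifest to a six-column CSV (byte-stable for fixed input)."""
    path = Path(path)
    frame = manifest.to_frame()
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV, validating grades, splits, origins and id uniqueness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    frame = pd.read_csv(path, dtype={"id": str, "path": str, "parent_id": str}, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        try:
            grade = int(row.grade)
        except (TypeError, ValueError):
            raise ManifestError(f"non-integer grade {row.grade!r} for id {row.id!r}")
        records.append(
            ManifestRecord(
                id=str(row.id),
                path=str(row.path),
                grade=grade,
                split=str(row.split) if row.split else "unassigned",
                origin=str(row.origin) if row.origin else "primary",
                parent_id=str(row.parent_id) if row.parent_id else None,
            )
        )
    return DatasetManifest(records)


def load_config(path: str | Path) -> dict:
    """Load a nested key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError("run configuration must be a mapping at top level")
    return dict(cfg)


def setup_logger(log_path: Optional[str | Path] = None, config: Optional[Mapping] = None) -> logging.Logger:
    """Create the pipeline logger; echoes the configuration verbatim at startup."""
    logger = logging.getLogger("drgrade")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler: logging.Handler
    if log_path is not None:
        handler = logging.FileHandler(log_path, mode="w")
    else:
        handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if config is not None:
        logger.info("run configuration:\n%s", yaml.safe_dump(dict(config), sort_keys=True).rstrip())
    return logger


def log_stage_counts(logger: logging.Logger, stage: str, manifest: DatasetManifest) -> None:
    """One line per pipeline stage with per-class counts, as the run log requires."""
    counts = manifest.class_counts()
    per_class = ", ".join(f"{n}={c}" for n, c in zip(manifest.class_labels, counts))
    logger.info("stage=%s total=%d [%s]", stage, len(manifest), per_class)
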