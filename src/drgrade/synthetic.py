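"""Seeded synthetic fundus images graded on the ICDR scale, with ground truth.

The generator draws a reddish-orange circular fundus field on black, dark
branching vessels and a bright optic disc, then adds the lesions that define
each ICDR grade: microaneurysms (small dark dots), haemorrhages (larger dark
blots), hard exudates (sharp bright yellowish deposits), soft exudates (pale
fuzzy patches) and, for proliferative disease, tortuous thin new-vessel
strokes. Grades 3-4 spread microaneurysms and haemorrhages across all four
quadrants, mirroring the clinical definition of severe disease.

Realism is not the goal: the images only need grade-dependent, learnable
structure plus an exact per-lesion ground truth so that classification,
explanation and dataset-assembly code can be exercised end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from drgrade.io import DatasetManifest, FundusImage, ManifestRecord, write_image

#: (lo, hi) inclusive count ranges per grade; quadrant_spread forces
#: microaneurysm/haemorrhage coverage of all four quadrants (grades 3-4).
DEFAULT_GRADE_PROFILES: dict[int, dict] = {
    0: dict(micro=(0, 0), haem=(0, 0), hard_ex=(0, 0), soft_ex_quadrants=(0, 0),
            neovessels=(0, 0), quadrant_spread=False),
    1: dict(micro=(1, 3), haem=(0, 0), hard_ex=(0, 0), soft_ex_quadrants=(0, 0),
            neovessels=(0, 0), quadrant_spread=False),
    2: dict(micro=(8, 15), haem=(2, 5), hard_ex=(2, 6), soft_ex_quadrants=(0, 1),
            neovessels=(0, 0), quadrant_spread=False),
    3: dict(micro=(16, 24), haem=(8, 12), hard_ex=(4, 8), soft_ex_quadrants=(2, 4),
            neovessels=(0, 0), preretinal=(0, 0), quadrant_spread=True),
    4: dict(micro=(18, 28), haem=(12, 16), hard_ex=(4, 8), soft_ex_quadrants=(2, 4),
            neovessels=(3, 5), preretinal=(1, 2), quadrant_spread=True),
}
for _g in (0, 1, 2):
    DEFAULT_GRADE_PROFILES[_g]["preretinal"] = (0, 0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Rendering parameters for the synthetic fundus generator.

    side
        Image side in pixels; lesion sizes scale linearly with it.
    grade_profiles
        Per-grade lesion count ranges (see ``DEFAULT_GRADE_PROFILES``).
    vessel_count
        Number of background vessel walks radiating from the optic disc.
    add_square_mark
        Draw the small bright square mark in the first quadrant that tags
        images from the auxiliary acquisition campaign.
    clip_horizontal
        Render a fundus wider than the frame so its left/right edges are
        cut off (an incompatible-image fixture for the selection filter).
    """

    side: int = 256
    grade_profiles: dict[int, dict] = field(default_factory=lambda: DEFAULT_GRADE_PROFILES)
    vessel_count: int = 8
    add_square_mark: bool = False
    clip_horizontal: bool = False

    def __post_init__(self) -> None:
        prof = self.grade_profiles
        if any(prof[0][k] != (0, 0) for k in ("micro", "haem", "hard_ex", "neovessels", "preretinal")):
            raise ValueError("grade-0 lesion count ranges must all be zero")
        for key in ("micro", "haem"):
            for g in range(4):
                if prof[g + 1][key][0] < prof[g][key][0] or prof[g + 1][key][1] < prof[g][key][1]:
                    raise ValueError(f"{key} count range must be non-decreasing with grade")


@dataclass(frozen=True)
class Lesion:
    """Ground truth for one drawn lesion."""

    type: str  # microaneurysm | haemorrhage | hard_exudate | soft_exudate | neovessel
    center: tuple[float, float]  # (row, col)
    radius: float
    quadrant: int  # 1 top-right, 2 top-left, 3 bottom-left, 4 bottom-right


def _quadrant_of(row: float, col: float, cy: float, cx: float) -> int:
    if row < cy:
        return 1 if col >= cx else 2
    return 3 if col < cx else 4


#: angular sectors (radians, math convention: angle 0 = +col, positive = up)
_QUADRANT_ANGLES = {1: (0.0, np.pi / 2), 2: (np.pi / 2, np.pi),
                    3: (np.pi, 3 * np.pi / 2), 4: (3 * np.pi / 2, 2 * np.pi)}


def _stamp_disk(canvas: np.ndarray, row: float, col: float, radius: float,
                color: np.ndarray, softness: float = 0.8, strength: float = 1.0) -> None:
    """Alpha-blend an anti-aliased disk onto the float canvas in place."""
    h, w = canvas.shape[:2]
    r0 = max(int(np.floor(row - radius - 2)), 0)
    r1 = min(int(np.ceil(row + radius + 2)) + 1, h)
    c0 = max(int(np.floor(col - radius - 2)), 0)
    c1 = min(int(np.ceil(col + radius + 2)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dist = np.sqrt((yy - row) ** 2 + (xx - col) ** 2)
    alpha = np.clip((radius + softness / 2 - dist) / softness, 0.0, 1.0) * strength
    patch = canvas[r0:r1, c0:c1]
    patch += alpha[:, :, None] * (color[None, None, :] - patch)


def _stamp_blob(canvas: np.ndarray, row: float, col: float, sigma: float,
                color: np.ndarray, strength: float = 0.85) -> None:
    """Gaussian-profile blob (soft exudate) blended in place."""
    h, w = canvas.shape[:2]
    ext = int(np.ceil(3 * sigma))
    r0, r1 = max(int(row) - ext, 0), min(int(row) + ext + 1, h)
    c0, c1 = max(int(col) - ext, 0), min(int(col) + ext + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    alpha = strength * np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2 * sigma**2))
    patch = canvas[r0:r1, c0:c1]
    patch += alpha[:, :, None] * (color[None, None, :] - patch)


def _stamp_walk(canvas: np.ndarray, rng: np.random.Generator, start: tuple[float, float],
                direction: float, steps: int, step_len: float, thickness: float,
                wiggle: float, color: np.ndarray, inside_radius: float,
                center: tuple[float, float], taper: bool = False) -> np.ndarray:
    """Stamp a random-walk stroke; returns the visited points (n x 2)."""
    cy, cx = center
    row, col = start
    pts = []
    for i in range(steps):
        direction += rng.normal(0.0, wiggle)
        row -= step_len * np.sin(direction)
        col += step_len * np.cos(direction)
        if (row - cy) ** 2 + (col - cx) ** 2 > inside_radius**2:
            break
        t = thickness * (1.0 - 0.6 * i / steps) if taper else thickness
        _stamp_disk(canvas, row, col, max(t, 0.6), color, softness=1.0)
        pts.append((row, col))
    return np.asarray(pts) if pts else np.empty((0, 2))


def _sample_point(rng: np.random.Generator, cy: float, cx: float, r_max: float,
                  quadrant: Optional[int] = None) -> tuple[float, float]:
    lo, hi = _QUADRANT_ANGLES[quadrant] if quadrant else (0.0, 2 * np.pi)
    theta = rng.uniform(lo, hi)
    radius = r_max * np.sqrt(rng.uniform(0.02, 1.0))
    return cy - radius * np.sin(theta), cx + radius * np.cos(theta)


def generate_fundus(grade: int, spec: SyntheticSpec | None = None,
                    seed: int = 0) -> tuple[FundusImage, list[Lesion]]:
    """Render one graded synthetic fundus image with lesion ground truth.

    Deterministic given ``(grade, spec, seed)``.
    """
    if grade not in range(5):
        raise ValueError(f"grade must be in 0..4, got {grade}")
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    side = spec.side
    canvas = np.zeros((side, side, 3), dtype=np.float64)
    cy = cx = (side - 1) / 2.0
    fundus_r = 0.48 * side * (1.25 if spec.clip_horizontal else 1.0)

    # Fundus field: radial colour gradient plus grain.
    yy, xx = np.mgrid[:side, :side]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    inside = dist <= fundus_r
    t = np.clip(dist / fundus_r, 0, 1)
    base_in = np.array([195.0, 102.0, 48.0])
    base_out = np.array([150.0, 66.0, 30.0])
    grad = base_in[None, None, :] + t[:, :, None] * (base_out - base_in)[None, None, :]
    noise = rng.normal(0.0, 4.0, size=(side, side, 1))
    canvas[inside] = (grad + noise)[inside]

    # Optic disc: bright ellipse offset toward one side (kept below the
    # white level so only the auxiliary square mark saturates).
    disc_row = cy + rng.uniform(-0.06, 0.06) * side
    disc_col = cx + rng.choice([-1, 1]) * rng.uniform(0.22, 0.3) * side
    ax_r, ax_c = 0.055 * side, 0.07 * side
    ell = ((yy - disc_row) / ax_r) ** 2 + ((xx - disc_col) / ax_c) ** 2
    disc_alpha = np.clip(1.2 - ell, 0, 1)
    disc_color = np.array([232.0, 206.0, 148.0])
    canvas += (disc_alpha * inside)[:, :, None] * (disc_color[None, None, :] - canvas)

    # Vessels: dark branching walks radiating from the optic disc.
    vessel_color = np.array([112.0, 38.0, 24.0])
    for _ in range(spec.vessel_count):
        direction = rng.uniform(0, 2 * np.pi)
        _stamp_walk(canvas, rng, (disc_row, disc_col), direction,
                    steps=int(0.5 * side), step_len=0.012 * side,
                    thickness=0.008 * side, wiggle=0.18, color=vessel_color,
                    inside_radius=0.95 * fundus_r, center=(cy, cx), taper=True)

    unit = side / 256.0
    prof = spec.grade_profiles[grade]
    lesions: list[Lesion] = []
    place_r = 0.9 * min(fundus_r, 0.48 * side)

    def place(kind: str, count: int, spread: bool) -> list[tuple[float, float, int]]:
        spots = []
        for i in range(count):
            quad = (i % 4) + 1 if spread and i < 4 else None
            row, col = _sample_point(rng, cy, cx, place_r, quadrant=quad)
            spots.append((row, col, _quadrant_of(row, col, cy, cx)))
        return spots

    # Microaneurysms: small dark dots.
    n = rng.integers(prof["micro"][0], prof["micro"][1] + 1)
    for row, col, quad in place("micro", int(n), prof["quadrant_spread"]):
        radius = rng.uniform(2.5, 4.0) * unit
        _stamp_disk(canvas, row, col, radius, np.array([70.0, 25.0, 20.0]))
        lesions.append(Lesion("microaneurysm", (row, col), radius, quad))

    # Haemorrhages: larger dark blots.
    n = rng.integers(prof["haem"][0], prof["haem"][1] + 1)
    for row, col, quad in place("haem", int(n), prof["quadrant_spread"]):
        radius = rng.uniform(5.0, 9.0) * unit
        _stamp_disk(canvas, row, col, radius, np.array([86.0, 20.0, 18.0]), softness=1.5)
        lesions.append(Lesion("haemorrhage", (row, col), radius, quad))

    # Hard exudates: sharp bright yellowish deposits.
    n = rng.integers(prof["hard_ex"][0], prof["hard_ex"][1] + 1)
    for row, col, quad in place("hard_ex", int(n), False):
        radius = rng.uniform(2.5, 5.0) * unit
        _stamp_disk(canvas, row, col, radius, np.array([238.0, 216.0, 90.0]), softness=0.5)
        lesions.append(Lesion("hard_exudate", (row, col), radius, quad))

    # Soft exudates: pale fuzzy patches, one or two per chosen quadrant.
    q_lo, q_hi = prof["soft_ex_quadrants"]
    n_quads = int(rng.integers(q_lo, q_hi + 1))
    for quad in rng.permutation([1, 2, 3, 4])[:n_quads]:
        row, col = _sample_point(rng, cy, cx, place_r, quadrant=int(quad))
        sigma = rng.uniform(4.0, 7.0) * unit
        _stamp_blob(canvas, row, col, sigma, np.array([210.0, 200.0, 178.0]))
        lesions.append(Lesion("soft_exudate", (row, col), 2.0 * sigma, int(quad)))

    # Preretinal haemorrhage: the large boat-shaped bleed in front of the
    # retina that marks proliferative disease — rendered as a big dark blot.
    n = rng.integers(prof["preretinal"][0], prof["preretinal"][1] + 1)
    for _ in range(int(n)):
        row, col = _sample_point(rng, cy, cx, 0.75 * place_r)
        radius = rng.uniform(11.0, 17.0) * unit
        _stamp_disk(canvas, row, col, radius, np.array([60.0, 12.0, 12.0]), softness=2.5)
        lesions.append(Lesion("preretinal_haemorrhage", (row, col), radius,
                              _quadrant_of(row, col, cy, cx)))

    # Neovascularisation: tortuous thin strokes near the optic disc.
    n = rng.integers(prof["neovessels"][0], prof["neovessels"][1] + 1)
    for _ in range(int(n)):
        start_row = disc_row + rng.uniform(-0.1, 0.1) * side
        start_col = disc_col + rng.uniform(-0.1, 0.1) * side
        pts = _stamp_walk(canvas, rng, (start_row, start_col), rng.uniform(0, 2 * np.pi),
                          steps=40, step_len=1.6 * unit, thickness=1.6 * unit,
                          wiggle=0.55, color=np.array([120.0, 28.0, 24.0]),
                          inside_radius=place_r, center=(cy, cx))
        if len(pts):
            center = pts.mean(axis=0)
            radius = float(np.max(np.linalg.norm(pts - center, axis=1))) + 1.2 * unit
            lesions.append(Lesion("neovessel", (float(center[0]), float(center[1])), radius,
                                  _quadrant_of(center[0], center[1], cy, cx)))

    canvas = np.clip(canvas, 0, 244)  # only the auxiliary mark reaches white

    # Auxiliary-campaign emulation: bright square mark in the first quadrant,
    # on the black background near the fundus rim.
    if spec.add_square_mark:
        mark_side = max(int(round(0.03 * side)), 2)
        r0 = int(round(0.07 * side))
        c0 = int(round(0.85 * side)) - mark_side
        canvas[r0 : r0 + mark_side, c0 : c0 + mark_side] = 255.0

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = FundusImage(pixels=pixels, grade=grade, origin="synthetic",
                        id=f"syn_g{grade}_seed{seed}")
    return image, lesions


def _image_seed(base_seed: int, grade: int, index: int) -> int:
    mix = zlib.crc32(f"{base_seed}:{grade}:{index}".encode())
    return int(mix % (2**31 - 1))


def generate_dataset(per_class_counts, spec: SyntheticSpec | None = None, seed: int = 0,
                     out_dir: str | Path | None = None) -> tuple[DatasetManifest, dict[str, FundusImage]]:
    """Generate a graded synthetic dataset: manifest plus images.

    Images are returned in memory keyed by record id; when ``out_dir`` is
    given they are also written as PNG and the manifest paths point there.
    """
    counts = [int(c) for c in per_class_counts]
    if len(counts) != 5 or any(c < 0 for c in counts):
        raise ValueError("per_class_counts must be five non-negative integers")
    spec = spec or SyntheticSpec()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    records, images = [], {}
    for grade, count in enumerate(counts):
        for idx in range(count):
            img_seed = _image_seed(seed, grade, idx)
            image, _ = generate_fundus(grade, spec, seed=img_seed)
            rec_id = f"syn_g{grade}_{idx:04d}"
            image.id = rec_id
            path = ""
            if out_path is not None:
                path = str(out_path / f"{rec_id}.png")
                write_image(image, path)
            records.append(ManifestRecord(id=rec_id, path=path, grade=grade,
                                          split="unassigned", origin="synthetic"))
            images[rec_id] = image
    return DatasetManifest(records), images
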