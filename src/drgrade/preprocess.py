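"""Fundus image preprocessing: circle crop, resize, weighted Gaussian blend.

The enhancement step is the weighted blend popularised in retinopathy
image competitions: ``out = clip(alpha * I + beta * G_sigma(I) + gamma)``.
With ``alpha = 4, beta = -4, gamma = 128`` it acts as a high-boost filter
that flattens illumination gradients and emphasises vessels and lesions.
Three blend variants per image, one per kernel width sigma, expand the
static dataset threefold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from drgrade.io import FundusImage


@dataclass(frozen=True)
class BlurSpec:
    """Parameters of the weighted Gaussian-blend enhancement.

    sigmas
        Exactly three Gaussian kernel standard deviations (pixels); one
        enhanced variant is produced per sigma. Defaults scale with the
        working resolution: side/60, side/30, side/15 at side=600.
    weight_image, weight_blur, offset
        The blend coefficients alpha, beta and the gray-level offset gamma.
    """

    sigmas: tuple[float, float, float] = (10.0, 20.0, 40.0)
    weight_image: float = 4.0
    weight_blur: float = -4.0
    offset: float = 128.0

    def __post_init__(self) -> None:
        if len(self.sigmas) != 3:
            raise ValueError("BlurSpec requires exactly three sigmas")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all sigmas must be > 0")

    @classmethod
    def for_side(cls, side: int, **kwargs) -> "BlurSpec":
        """Default sigma triple scaled to an image side length."""
        return cls(sigmas=(side / 60.0, side / 30.0, side / 15.0), **kwargs)


def crop_to_circle(image: FundusImage) -> FundusImage:
    """Zero every pixel outside the largest centered inscribed circle.

    The circle is centered on the image center with diameter min(H, W);
    the inside test uses pixel centers (0-based row/column indices).
    Idempotent, and a fixed point for anything already circular.
    """
    h, w = image.height, image.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    pixels = np.where(mask[:, :, None], image.pixels, 0).astype(np.uint8)
    return FundusImage(pixels=pixels, grade=image.grade, origin=image.origin,
                       id=image.id, parent_id=image.parent_id)


def _central_square(pixels: np.ndarray) -> np.ndarray:
    h, w = pixels.shape[:2]
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return pixels[r0 : r0 + side, c0 : c0 + side]


def resize_array(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample with the pixel-center convention.

    Output pixel (i, j) samples the source at
    ``((i + 0.5) * H/out_h - 0.5, (j + 0.5) * W/out_w - 0.5)``,
    clamped to the source grid, interpolated bilinearly.
    """
    h, w = pixels.shape[:2]
    if (out_h, out_w) == (h, w):
        return pixels.copy()
    rows = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    rows = np.clip(rows, 0, h - 1)
    cols = np.clip(cols, 0, w - 1)
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    planes = pixels if pixels.ndim == 3 else pixels[:, :, None]
    out = np.stack(
        [
            ndimage.map_coordinates(planes[:, :, k].astype(np.float64), [grid_r, grid_c], order=1, mode="nearest")
            for k in range(planes.shape[2])
        ],
        axis=-1,
    )
    return out if pixels.ndim == 3 else out[:, :, 0]


def resize(image: FundusImage, side: int) -> FundusImage:
    """Resize to ``side x side x 3`` with bilinear interpolation.

    Non-square inputs are first cropped to the central square (the fundus
    pipeline always circle-crops first, so only black border is lost).
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    square = _central_square(image.pixels)
    out = resize_array(square.astype(np.float64), side, side)
    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels, grade=image.grade, origin=image.origin,
                       id=image.id, parent_id=image.parent_id)


def gaussian_blend(image: FundusImage, sigma: float, spec: BlurSpec | None = None) -> FundusImage:
    """Weighted Gaussian blend: clip(alpha*I + beta*G_sigma(I) + gamma, 0, 255)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    spec = spec or BlurSpec()
    img = image.pixels.astype(np.float64)
    blurred = np.stack(
        [ndimage.gaussian_filter(img[:, :, k], sigma=sigma, mode="nearest") for k in range(3)],
        axis=-1,
    )
    out = spec.weight_image * img + spec.weight_blur * blurred + spec.offset
    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return FundusImage(pixels=pixels, grade=image.grade, origin=image.origin,
                       id=image.id, parent_id=image.parent_id)


def make_blur_variants(image: FundusImage, spec: BlurSpec | None = None) -> list[FundusImage]:
    """Produce the three enhanced variants of one image, one per sigma.

    Each output carries origin='blur_variant' and a parent_id linking it
    to the input; ids append a ``__s{k}`` suffix.
    """
    spec = spec or BlurSpec()
    variants = []
    for k, sigma in enumerate(spec.sigmas):
        out = gaussian_blend(image, sigma, spec)
        out.origin = "blur_variant"
        out.parent_id = image.id or None
        out.id = f"{image.id}__s{k}" if image.id else f"__s{k}"
        variants.append(out)
    return variants
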