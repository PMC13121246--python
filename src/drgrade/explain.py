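"""Grad-CAM explanations, ensemble heatmap averaging and clinician reports.

Grad-CAM weights each channel of a convolutional feature map by the
spatial mean of the class-score gradient, combines the channels, rectifies
and upsamples: ``L^c = upsample(ReLU(sum_k alpha_k A^k))`` with
``alpha_k = (1/Z) sum_ij d y^c / d A^k_ij``. Members with two summed head
stages contribute the average of their two stage heatmaps; the ensemble
heatmap is the pixel-wise average over members. All maps are min-max
normalized to [0, 1] after averaging (identically-zero maps stay zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from drgrade.backbones import BackboneContract
from drgrade.ensemble import EnsemblePrediction, _member_input
from drgrade.io import FundusImage, ICDR_CLASS_NAMES
from drgrade.preprocess import resize_array

logger = logging.getLogger("drgrade")

HEATMAP_SOURCES = ("ensemble", "member_A", "member_B", "member_B_stage1", "member_B_stage2")


@dataclass
class Heatmap:
    """Relevance map in [0, 1]: raw resolution plus image-aligned version."""

    values: np.ndarray
    upsampled: np.ndarray
    target_class: int
    source: str

    def __post_init__(self) -> None:
        for arr in (self.values, self.upsampled):
            if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
                raise ValueError("heatmap values must lie in [0, 1]")


def _minmax(arr: np.ndarray) -> np.ndarray:
    top = arr.max()
    if top <= 0:
        return np.zeros_like(arr)
    lo = arr.min()
    return (arr - lo) / (top - lo) if top > lo else np.ones_like(arr)


def grad_cam(member: BackboneContract, image: FundusImage, target_class: int,
             layer: Optional[str] = None) -> Heatmap:
    """Grad-CAM heatmap of one member layer for one class.

    The raw map is computed at the layer's resolution, rectified,
    bilinearly upsampled to the image size and min-max normalized; a map
    that is identically zero after ReLU stays all-zero.
    """
    layer = layer or member.target_layers[0]
    if layer not in member.target_layers:
        raise ValueError(f"unknown target layer {layer!r} for member {member.name!r}")
    x = _member_input(member, image)
    maps, _ = member.forward(x)
    grads = member.class_gradients(x, target_class)
    a = maps[layer][0]        # (K, h, w)
    da = grads[layer][0]
    alpha = da.mean(axis=(1, 2))  # (K,)
    raw = np.maximum((alpha[:, None, None] * a).sum(axis=0), 0.0)
    values = _minmax(raw)
    up = resize_array(raw.astype(np.float64), image.height, image.width)
    upsampled = _minmax(np.maximum(up, 0.0))
    return Heatmap(values=values, upsampled=upsampled, target_class=target_class,
                   source=f"{member.name}:{layer}")


def stage_average(stage_maps: Sequence[Heatmap]) -> Heatmap:
    """Average the heatmaps of one member's summed head stages."""
    if len({m.target_class for m in stage_maps}) != 1:
        raise ValueError("stage heatmaps target different classes")
    shapes = {m.upsampled.shape for m in stage_maps}
    if len(shapes) != 1:
        raise ValueError("stage heatmaps differ in upsampled size")
    mean = np.mean([m.upsampled for m in stage_maps], axis=0)
    values = _minmax(mean)
    source = stage_maps[0].source.split(":")[0]
    return Heatmap(values=values, upsampled=values,
                   target_class=stage_maps[0].target_class, source=source)


def ensemble_heatmap(member_maps: Sequence[Heatmap]) -> Heatmap:
    """Pixel-wise average of per-member heatmaps, re-normalized."""
    if len({m.target_class for m in member_maps}) != 1:
        raise ValueError("member heatmaps target different classes")
    shapes = {m.upsampled.shape for m in member_maps}
    if len(shapes) != 1:
        raise ValueError("member heatmaps differ in upsampled size")
    mean = np.mean([m.upsampled for m in member_maps], axis=0)
    values = _minmax(mean)
    return Heatmap(values=values, upsampled=values,
                   target_class=member_maps[0].target_class, source="ensemble")


def member_heatmap(member: BackboneContract, image: FundusImage,
                   target_class: int) -> Heatmap:
    """One member's explanation: Grad-CAM per target layer, stage-averaged
    when the member sums several head stages."""
    maps = [grad_cam(member, image, target_class, layer) for layer in member.target_layers]
    if len(maps) == 1:
        out = maps[0]
        out.source = member.name
        return out
    return stage_average(maps)


def explanation_heatmaps(members: Sequence[BackboneContract], image: FundusImage,
                         target_class: int) -> dict[str, Heatmap]:
    """All available explanation panels for one image and class."""
    available: dict[str, Heatmap] = {}
    member_maps = []
    for member in members:
        for layer in member.target_layers:
            hm = grad_cam(member, image, target_class, layer)
            if len(member.target_layers) > 1:
                available[f"{member.name}_{layer}"] = hm
        hm = member_heatmap(member, image, target_class)
        available[member.name] = hm
        member_maps.append(hm)
    available["ensemble"] = ensemble_heatmap(member_maps)
    return available


def overlay(image: FundusImage, heatmap: Heatmap, opacity: float = 0.4,
            colormap: str = "inferno") -> FundusImage:
    """Alpha-blend a color-mapped heatmap over the image.

    ``out = (1 - opacity) * image + opacity * colormap(heat)``; opacity 0
    returns the image unchanged.
    """
    if not (0.0 <= opacity <= 1.0):
        raise ValueError("opacity must be in [0, 1]")
    if heatmap.upsampled.shape != image.pixels.shape[:2]:
        raise ValueError("heatmap and image sizes are not aligned")
    if opacity == 0.0:
        return FundusImage(pixels=image.pixels.copy(), grade=image.grade,
                           origin=image.origin, id=image.id)
    mapped = matplotlib.colormaps[colormap](heatmap.upsampled)[:, :, :3] * 255.0
    blended = (1.0 - opacity) * image.pixels.astype(np.float64) + opacity * mapped
    return FundusImage(pixels=np.clip(np.rint(blended), 0, 255).astype(np.uint8),
                       grade=image.grade, origin=image.origin, id=image.id)


@dataclass
class DiagnosticReport:
    """The clinician-facing result: top-2 diagnoses, Q, heatmap panels."""

    top1: tuple[str, float]
    top2: tuple[str, float]
    Q: int
    panels: list[tuple[str, FundusImage]]
    confidence_line: str
    low_confidence: bool

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("report must contain at least one panel")


#: Panel label convention: M:0 is the ensemble average, M:1.. individual sources.
def _panel_label(idx: int, source: str) -> str:
    return f"M: {idx} ({source})"


def compose_report(prediction: EnsemblePrediction, heatmaps: dict[str, Heatmap],
                   selection: Optional[Sequence[str]] = None,
                   image: Optional[FundusImage] = None,
                   opacity: float = 0.4,
                   class_names: Sequence[str] = ICDR_CLASS_NAMES,
                   out_path: Optional[str | Path] = None,
                   low_q_threshold: int = 2) -> DiagnosticReport:
    """Assemble the configurable report: top-2 suggestions, Q, chosen panels.

    The default selection is the ensemble panel; an empty selection falls
    back to it with a warning. ``image`` enables rendered overlays (and,
    with ``out_path``, a saved figure); without it panels carry the plain
    heatmaps as grayscale images.
    """
    if selection is None:
        selection = ["ensemble"]
    selection = list(selection)
    if not selection:
        warnings.warn("empty panel selection; defaulting to the ensemble panel")
        selection = ["ensemble"]
    unknown = [s for s in selection if s not in heatmaps]
    if unknown:
        raise ValueError(f"unknown heatmap panels requested: {unknown}")

    p = prediction.combined_probs
    top1 = (class_names[prediction.top1], float(p[prediction.top1]))
    top2 = (class_names[prediction.top2], float(p[prediction.top2]))
    low = prediction.Q <= low_q_threshold
    confidence = (
        f"Suggested: {top1[0]} (p={top1[1]:.2f}); alternative: {top2[0]} "
        f"(p={top2[1]:.2f}); quality factor Q={prediction.Q}."
    )
    if low:
        confidence += " Low confidence: borderline case, expert review advised."

    panels: list[tuple[str, FundusImage]] = []
    for idx, name in enumerate(selection):
        hm = heatmaps[name]
        if image is not None:
            panel_img = overlay(image, hm, opacity=opacity)
        else:
            gray = np.clip(np.rint(hm.upsampled * 255.0), 0, 255).astype(np.uint8)
            panel_img = FundusImage(pixels=np.stack([gray] * 3, axis=-1), id=name)
        panels.append((_panel_label(0 if name == "ensemble" else idx + 1, name), panel_img))

    report = DiagnosticReport(top1=top1, top2=top2, Q=prediction.Q, panels=panels,
                              confidence_line=confidence, low_confidence=low)
    if out_path is not None:
        render_report(report, out_path)
    return report


def render_report(report: DiagnosticReport, out_path: str | Path) -> Path:
    """Render the report to a PNG figure (panels side by side plus text)."""
    out_path = Path(out_path)
    n = len(report.panels)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.8), squeeze=False)
    for ax, (label, img) in zip(axes[0], report.panels):
        ax.imshow(img.pixels)
        ax.set_title(label, fontsize=9)
        ax.axis("off")
    fig.suptitle(report.confidence_line, fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
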