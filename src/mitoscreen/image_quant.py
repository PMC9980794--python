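"""Quantification of mitophagy and organelle read-outs from cell images.

Works on two- or three-channel stacks of a tandem mCherry-GFP mitochondrial
reporter (mitoQC): healthy mitochondria fluoresce in both channels, while
mitochondria delivered to acidic lysosomes lose GFP and appear as red-only
puncta.  An optional third channel carries a neutral-lipid (lipid droplet)
or other structure stain.

Read-outs per cell: red-only punctum count, mitophagic classification
(strictly more than ``k`` puncta), red-only area as % of mitochondrial
area, circularity-filtered structure area as % of cell area, and Manders
colocalization coefficients M1/M2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_li

from .errors import ConfigError, QuantError

__all__ = [
    "ImageStack",
    "QuantConfig",
    "Punctum",
    "PunctaSet",
    "CellQuant",
    "segment_cells",
    "detect_red_only_puncta",
    "classify_mitophagic",
    "red_only_area_fraction",
    "area_fraction",
    "manders",
    "quantify_cells",
]

RATIO_EPS = 1.0  # intensity-unit stabilizer in (mCherry+eps)/(GFP+eps)


@dataclass
class ImageStack:
    """Multi-channel raster with optional per-cell label mask.

    ``channels`` maps channel name (e.g. "GFP", "mCherry", "LD") to a 2-D
    non-negative intensity array; all channels and the label mask share one
    shape.  Pixel coordinates are row-major and 0-based.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    cell_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("ImageStack needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ConfigError(f"channel shapes differ: {shapes}")
        if self.cell_labels is not None:
            if self.cell_labels.shape != next(iter(shapes)):
                raise ConfigError("cell_labels shape differs from channels")
            if np.any(self.cell_labels < 0):
                raise ConfigError("cell_labels must be non-negative integers")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise QuantError(f"missing channel {name!r}")
        return self.channels[name]


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and filters of the image pipeline.

    ``puncta_cutoff`` is the mitophagic-cell rule: a cell is mitophagic iff
    its red-only punctum count is strictly greater than this value.
    """

    mito_threshold: float = 50.0
    ratio_threshold: float = 2.0
    min_punctum_area: int = 4
    max_punctum_area: int = 400
    puncta_cutoff: int = 5
    circularity_min: float = 0.6
    ld_threshold: float = 40.0
    structure_threshold: float = 40.0

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 1:
            raise ConfigError("ratio_threshold must be > 1")
        if not 0 < self.min_punctum_area <= self.max_punctum_area:
            raise ConfigError("require 0 < min_punctum_area <= max_punctum_area")
        if self.puncta_cutoff < 0:
            raise ConfigError("puncta_cutoff must be >= 0")
        if not 0 < self.circularity_min <= 1:
            raise ConfigError("circularity_min must be in (0, 1]")


@dataclass(frozen=True)
class Punctum:
    centroid: tuple[float, float]
    area: int
    mean_ratio: float


# cell_id -> list of detected red-only puncta
PunctaSet = dict


@dataclass(frozen=True)
class CellQuant:
    cell_id: int
    red_only_count: int
    red_only_area_pct: float
    mitophagic: bool
    structure_area_pct: float | None = None
    manders_m1: float | None = None
    manders_m2: float | None = None


def segment_cells(stack: ImageStack, channel: str = "GFP") -> np.ndarray:
    """Cell label raster; provided masks pass through unchanged.

    Without provided labels: global threshold on the cytoplasmic channel
    (Li's minimum cross-entropy, which keeps dim cytoplasm above a dark
    background where Otsu would latch onto the bright organelle mode),
    hole filling, connected components, labels 1..n by descending area.
    """
    if stack.cell_labels is not None:
        return stack.cell_labels
    img = stack.channel(channel)
    if img.max() == img.min():
        raise QuantError("no cells found")
    mask = ndi.binary_fill_holes(img > threshold_li(img))
    labels, n = ndi.label(mask)
    if n == 0:
        raise QuantError("no cells found")
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(-areas)  # descending area
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[1 + order] = np.arange(1, n + 1)
    return relabel[labels]


def detect_red_only_puncta(
    stack: ImageStack, cells: np.ndarray, config: QuantConfig
) -> PunctaSet:
    """Red-only (mitolysosome) puncta per cell.

    Candidate pixels satisfy mCherry >= mito_threshold and
    (mCherry + 1)/(GFP + 1) >= ratio_threshold; 4-connected components
    within each cell are kept if their area lies in the configured bounds.
    """
    mcherry = stack.channel("mCherry").astype(float)
    gfp = stack.channel("GFP").astype(float)
    ratio = (mcherry + RATIO_EPS) / (gfp + RATIO_EPS)
    candidate = (mcherry >= config.mito_threshold) & (ratio >= config.ratio_threshold)
    out: PunctaSet = {}
    for cell_id in np.unique(cells):
        if cell_id == 0:
            continue
        mask = candidate & (cells == cell_id)
        labels = measure.label(mask, connectivity=1)
        puncta = []
        for region in measure.regionprops(labels, intensity_image=ratio):
            if config.min_punctum_area <= region.area <= config.max_punctum_area:
                puncta.append(
                    Punctum(
                        centroid=tuple(region.centroid),
                        area=int(region.area),
                        mean_ratio=float(region.intensity_mean),
                    )
                )
        out[int(cell_id)] = puncta
    return out


def classify_mitophagic(puncta_count: int, config: QuantConfig) -> bool:
    """A cell is mitophagic iff its red-only punctum count exceeds the cutoff."""
    if puncta_count < 0:
        raise ConfigError("puncta_count must be >= 0")
    return puncta_count > config.puncta_cutoff


def red_only_area_fraction(puncta: Sequence[Punctum], mito_mask_area: int) -> float:
    """Red-only punctum area as a percentage of mitochondrial mask area.

    The mitochondrial mask is the set of pixels at or above the mCherry
    threshold and therefore includes the red-only pixels themselves.
    """
    if mito_mask_area <= 0:
        raise QuantError("zero mitochondrial mask area")
    total = sum(p.area for p in puncta)
    return float(np.clip(100.0 * total / mito_mask_area, 0.0, 100.0))


def _circularity(region) -> float:
    perim = region.perimeter_crofton
    if perim == 0:
        return 1.0  # single-pixel / degenerate object: treat as circular
    return 4.0 * np.pi * region.area / perim**2


def area_fraction(
    structure_mask: np.ndarray, cell_mask: np.ndarray, config: QuantConfig
) -> float:
    """Circularity-filtered structure area as % of cell area.

    Objects are 4-connected components of the thresholded structure channel
    inside the cell; those with circularity 4*pi*A/P^2 (Crofton perimeter)
    below ``circularity_min`` are discarded.
    """
    cell_area = int(np.count_nonzero(cell_mask))
    if cell_area == 0:
        raise QuantError("zero cell area")
    labels = measure.label(structure_mask & cell_mask.astype(bool), connectivity=1)
    kept = sum(
        r.area for r in measure.regionprops(labels) if _circularity(r) >= config.circularity_min
    )
    return 100.0 * kept / cell_area


def manders(
    ld_channel: np.ndarray,
    mito_channel: np.ndarray,
    mito_mask: np.ndarray,
    ld_mask: np.ndarray,
) -> tuple[float, float]:
    """Manders colocalization coefficients.

    M1 = fraction of structure (LD) intensity inside ``ld_mask`` that falls
    on mitochondrial pixels; M2 = fraction of mitochondrial intensity inside
    ``mito_mask`` that falls on structure pixels.  Both lie in [0, 1].
    """
    if ld_channel.shape != mito_mask.shape or ld_channel.shape != ld_mask.shape:
        raise ConfigError("masks must match the channel shape")
    ld_mask = ld_mask.astype(bool)
    mito_mask = mito_mask.astype(bool)
    ld_total = float(ld_channel[ld_mask].sum())
    mito_total = float(mito_channel[mito_mask].sum())
    if ld_total == 0 or mito_total == 0:
        raise QuantError("zero total intensity in a mask")
    overlap = ld_mask & mito_mask
    m1 = float(ld_channel[overlap].sum()) / ld_total
    m2 = float(mito_channel[overlap].sum()) / mito_total
    return m1, m2


def quantify_cells(
    stack: ImageStack,
    config: QuantConfig | None = None,
    structure_channel: str = "LD",
) -> tuple[pd.DataFrame, dict]:
    """Per-cell mitophagy and structure read-outs plus a run-level summary.

    Returns a table with one row per cell (cell_id, red_only_count,
    mitophagic, red_only_area_pct, and, when a structure channel is present,
    structure_area_pct, manders_m1, manders_m2) and a summary dict with the
    percentage of mitophagic cells and mean area fractions.
    """
    config = config or QuantConfig()
    cells = segment_cells(stack)
    puncta = detect_red_only_puncta(stack, cells, config)
    mcherry = stack.channel("mCherry")
    mito_mask = mcherry >= config.mito_threshold
    has_structure = structure_channel in stack.channels
    if has_structure:
        structure = stack.channel(structure_channel)
        structure_mask = structure >= config.ld_threshold

    rows = []
    for cell_id in sorted(puncta):
        cell_mask = cells == cell_id
        cell_puncta = puncta[cell_id]
        mito_area = int(np.count_nonzero(mito_mask & cell_mask))
        red_pct = (
            red_only_area_fraction(cell_puncta, mito_area) if mito_area else 0.0
        )
        quant = {
            "cell_id": cell_id,
            "red_only_count": len(cell_puncta),
            "mitophagic": classify_mitophagic(len(cell_puncta), config),
            "red_only_area_pct": red_pct,
        }
        if has_structure:
            quant["structure_area_pct"] = area_fraction(
                structure_mask, cell_mask, config
            )
            sm = structure_mask & cell_mask
            mm = mito_mask & cell_mask
            if sm.any() and mm.any():
                m1, m2 = manders(structure, mcherry, mm, sm)
            else:
                m1 = m2 = np.nan
            quant["manders_m1"] = m1
            quant["manders_m2"] = m2
        rows.append(quant)
    table = pd.DataFrame(rows)
    summary = {
        "n_cells": len(rows),
        "pct_mitophagic": 100.0 * float(table["mitophagic"].mean()) if rows else 0.0,
        "mean_red_only_area_pct": float(table["red_only_area_pct"].mean()) if rows else 0.0,
    }
    if has_structure and rows:
        summary["mean_structure_area_pct"] = float(table["structure_area_pct"].mean())
        summary["mean_manders_m1"] = float(np.nanmean(table["manders_m1"]))
        summary["mean_manders_m2"] = float(np.nanmean(table["manders_m2"]))
    return table, summary
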