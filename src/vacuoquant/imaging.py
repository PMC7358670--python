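"""Per-cell LAMP-1 image quantification for imaging-flow-cytometry exports.

The pipeline mirrors a custom post-processing of channel-separated 8-bit
single-cell frames: a whole-cell mask is obtained by Otsu thresholding of the
surface CD4 channel (never the LAMP-1 channel, to avoid circularity in the
LAMP-1 statistics), and per cell the mean intracellular LAMP-1 intensity and
a *sliding-threshold curve* are computed — for each grayscale level ``k`` in
0..255 the percentage of masked cell area with LAMP-1 intensity greater than
or equal to ``k``.  Population percentile bands of those curves (median,
interquartile and 2.5-97.5 ranges) summarise the LAMP-1 distribution of a
cell population.

A useful self-consistency identity links the two statistics: every pixel of
intensity ``v`` is counted at exactly the ``v`` levels ``1..v``, so
``sum(pct_at_level[1:]) / 100 == mean_lamp1`` exactly (up to float error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .synth import CellImagePair, SeverityClass

__all__ = [
    "CellMask",
    "CellQuant",
    "SlidingThresholdCurve",
    "PopulationBands",
    "otsu_threshold",
    "segment_cell",
    "quantify_cell",
    "population_bands",
    "compare_classes",
]


@dataclass
class CellMask:
    """Whole-cell boolean mask derived from the CD4 channel only."""

    mask: np.ndarray
    area_px: int
    otsu_threshold: int
    source_channel: str = "CD4"


@dataclass
class CellQuant:
    """Scalar per-cell LAMP-1 summary."""

    cell_id: str
    mean_lamp1: float
    area_px: int
    class_label: SeverityClass | str | None = None


@dataclass
class SlidingThresholdCurve:
    """256-point curve: % of cell area with LAMP-1 >= level, level = 0..255."""

    cell_id: str
    pct_at_level: np.ndarray


@dataclass
class PopulationBands:
    """Per-level order statistics of sliding-threshold curves across cells."""

    levels: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    p2_5: np.ndarray
    p97_5: np.ndarray
    n_cells: int = 0


def otsu_threshold(pixels: np.ndarray) -> int:
    """Otsu threshold of an 8-bit array, as a level ``t`` in 1..255.

    The returned level splits pixels into background ``< t`` and foreground
    ``>= t`` so as to maximize the between-class variance of the 256-bin
    histogram.  Ties are broken toward the lowest maximizing level.  Raises
    ``ValueError`` for constant input (no threshold separates anything).
    """
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise ValueError("empty pixel array")
    flat = arr.ravel()
    if np.issubdtype(flat.dtype, np.floating):
        if not np.all(flat == np.rint(flat)):
            raise ValueError("pixels must be integers in 0..255")
        flat = flat.astype(np.int64)
    else:
        flat = flat.astype(np.int64)
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("pixels must be within 0..255")
    hist = np.bincount(flat, minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    p = hist / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    # candidate thresholds t = 1..255; class 0 holds levels 0..t-1
    omega0 = omega[:-1]
    mu0 = mu[:-1]
    valid = (omega0 > 0) & (omega0 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu0) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b = np.where(valid, sigma_b, -np.inf)
    return int(np.argmax(sigma_b)) + 1  # argmax returns first (lowest) maximizer


def segment_cell(
    image: CellImagePair | np.ndarray,
    connectivity: int = 2,
    fill_holes: bool = True,
) -> CellMask:
    """Whole-cell mask from the CD4 channel.

    Otsu-threshold the CD4 channel, keep the largest 8-connected foreground
    component, and fill interior holes.  ``connectivity`` follows the
    scikit-image convention (2 = 8-connectivity in 2-D).
    """
    cd4 = image.cd4_channel if isinstance(image, CellImagePair) else np.asarray(image)
    t = otsu_threshold(cd4)
    binary = cd4 >= t
    if not binary.any():
        raise ValueError("empty foreground after thresholding")
    labels = measure.label(binary, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return CellMask(mask=mask, area_px=int(mask.sum()), otsu_threshold=t)


def quantify_cell(
    image: CellImagePair, mask: CellMask
) -> tuple[CellQuant, SlidingThresholdCurve]:
    """Mean LAMP-1 and the sliding-threshold curve over the masked cell area."""
    lamp = image.lamp1_channel
    m = mask.mask
    if lamp.shape != m.shape:
        raise ValueError(
            f"shape mismatch: LAMP-1 {lamp.shape} vs mask {m.shape}"
        )
    vals = lamp[m].astype(np.int64)
    if vals.size == 0:
        raise ValueError("empty mask")
    area = int(vals.size)
    counts = np.bincount(vals, minlength=256)
    # pct_at_level[k] = 100 * #{pixels >= k} / area  (">= k" taken literally)
    tail = counts[::-1].cumsum()[::-1].astype(float)
    pct = 100.0 * tail / area
    quant = CellQuant(
        cell_id=image.cell_id,
        mean_lamp1=float(vals.mean()),
        area_px=area,
        class_label=image.class_label,
    )
    return quant, SlidingThresholdCurve(cell_id=image.cell_id, pct_at_level=pct)


def population_bands(curves: Sequence[SlidingThresholdCurve]) -> PopulationBands:
    """Median, quartile and 2.5/97.5 percentile bands across cells per level.

    Quantiles use the linear-interpolation definition (numpy default), which
    the band shapes depend on and is therefore fixed here.
    """
    if len(curves) == 0:
        raise ValueError("no curves supplied")
    stack = np.vstack([np.asarray(c.pct_at_level, dtype=float) for c in curves])
    q = np.percentile(stack, [2.5, 25.0, 50.0, 75.0, 97.5], axis=0)
    return PopulationBands(
        levels=np.arange(256),
        p2_5=q[0],
        q25=q[1],
        median=q[2],
        q75=q[3],
        p97_5=q[4],
        n_cells=stack.shape[0],
    )


def compare_classes(
    quants_by_class: Mapping[str, Sequence[CellQuant]]
) -> pd.DataFrame:
    """Per-class cell counts, mean of per-cell means, and mean-LAMP-1 deciles.

    Deciles (10th-90th percentile of per-cell mean LAMP-1, linear
    interpolation) describe the within-population spread the way one would
    pick representative example cells across the distribution.
    """
    if not quants_by_class:
        raise ValueError("no classes supplied")
    rows = []
    for label, quants in quants_by_class.items():
        means = np.array([q.mean_lamp1 for q in quants], dtype=float)
        if means.size == 0:
            raise ValueError(f"class {label!r} has no cells")
        row = {"class": str(label), "n_cells": means.size,
               "mean_of_means": float(means.mean())}
        for d in range(10, 100, 10):
            row[f"p{d}"] = float(np.percentile(means, d))
        rows.append(row)
    return pd.DataFrame(rows)
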