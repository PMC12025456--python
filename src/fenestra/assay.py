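"""Cell-count and endocytosis arithmetic.

Nuclei are counted by simple global threshold segmentation (connected
components above an intensity threshold, size-filtered), mirroring how
stained-nuclei images are commonly quantified; total endocytosed activity
(cell-associated + degraded) is normalized per counted cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "WellRecord",
    "count_nuclei",
    "measure_areas",
    "normalize_endocytosis",
]


@dataclass
class WellRecord:
    """One culture well of an endocytosis assay (activity in arbitrary
    units; n_cells from nuclei counting)."""

    cell_associated: float
    degraded: float
    n_cells: int
    substrate_label: str = ""

    def __post_init__(self) -> None:
        if self.cell_associated < 0 or self.degraded < 0:
            raise ValueError("activities must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


def count_nuclei(
    image: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 20,
) -> int:
    """Count nuclei by global thresholding and connected components.

    ``threshold=None`` falls back to Otsu's automatic threshold.  Touching
    nuclei merge into one component (a documented limitation of simple
    threshold segmentation).  Blank or saturated images yield a warning
    and a zero count.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.ptp(image) < 1e-12:
        warnings.warn("blank or saturated image: returning a zero count")
        return 0
    thr = threshold_otsu(image) if threshold is None else float(threshold)
    mask = image > thr
    if not mask.any() or mask.all():
        warnings.warn("threshold leaves no foreground/background split; count is 0")
        return 0
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())[1:]
    return int((counts >= min_area_px).sum())


def measure_areas(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, pixel_size_nm: float
) -> tuple[float, float]:
    """Projected cell and nucleus areas in µm² from aligned masks."""
    if cell_mask.shape != nucleus_mask.shape:
        raise ValueError("masks must be aligned")
    factor = pixel_size_nm**2 / 1e6
    cell = float(cell_mask.sum()) * factor
    nuc = float(nucleus_mask.sum()) * factor
    if cell == 0 or nuc == 0:
        warnings.warn("empty mask: zero area reported")
    return cell, nuc


def normalize_endocytosis(wells: list[WellRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-well normalized endocytosis: (cell_associated + degraded) / n_cells.

    Wells with zero cells are excluded with a warning.  Returns the
    per-well table; group summaries by substrate label are obtained with
    ``df.groupby("substrate_label")["normalized_total"].agg(["mean", "std"])``.
    """
    if isinstance(wells, pd.DataFrame):
        df = wells.copy()
        if "substrate_label" not in df:
            df["substrate_label"] = ""
    else:
        df = pd.DataFrame(
            {
                "cell_associated": [w.cell_associated for w in wells],
                "degraded": [w.degraded for w in wells],
                "n_cells": [w.n_cells for w in wells],
                "substrate_label": [w.substrate_label for w in wells],
            }
        )
    if (df["n_cells"] <= 0).any():
        warnings.warn("wells with zero cells excluded from normalization")
        df = df[df["n_cells"] > 0].copy()
    df["total"] = df["cell_associated"] + df["degraded"]
    df["normalized_total"] = df["total"] / df["n_cells"]
    return df
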