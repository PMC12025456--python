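"""Fenestration morphometry on reconstructed height maps.

Detects transcellular pores, computes porosity (fenestrations per µm² of
projected cell area, excluding the nuclear "labyrinth" region) and the
load-dependent deformability statistic: the per-pore fold change between
the diameters measured at a high and a low imaging force (300/170 pN),
matched one-to-one between the two reconstructions of the same scan.

Diameters are measured along the fast scan axis through the pore, by
default at half of the pore's apparent depth (threshold-stable under
noise); the criterion is configurable and is recorded on every record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .reconstruction import HeightMap

__all__ = [
    "PoreRecord",
    "PorosityResult",
    "DeformabilityPair",
    "DeformabilitySummary",
    "flatten",
    "segment_cell",
    "detect_nuclear_region",
    "detect_pores",
    "compute_porosity",
    "match_pores",
    "deformability_summary",
    "assign_sieve_plates",
]


@dataclass
class PoreRecord:
    """One detected pore on a height map at a given load force."""

    centroid_x_nm: float
    centroid_y_nm: float
    diameter_fast_axis_nm: float
    depth_nm: float
    area_nm2: float
    circularity: float
    in_nuclear_region: bool = False
    sieve_plate_id: int | None = None
    criterion: str = "half-depth"
    load_force_pn: float | None = None


@dataclass
class PorosityResult:
    n_fenestrations: int
    cell_area_um2: float
    porosity_per_um2: float
    n_excluded_nuclear: int


@dataclass
class DeformabilityPair:
    """A pore matched between the low- and high-force reconstructions."""

    pore_low: PoreRecord
    pore_high: PoreRecord
    fold_change: float
    pixel_size: float
    centroid_distance_nm: float


@dataclass
class DeformabilitySummary:
    mean_fold_change: float
    sd_fold_change: float
    percent_enlargement: float
    n_pairs: int


# ---------------------------------------------------------------------------
# pre-processing


def _fill_invalid(heights: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return heights.astype(float)
    if not valid.any():
        raise ValueError("height map is fully invalid")
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return heights[tuple(idx)].astype(float)


def _substrate_offset(h: np.ndarray) -> float:
    """Median of the low cluster (substrate + pore bottoms), or the global
    median when the map has no discernible low plateau."""
    finite = h[np.isfinite(h)]
    if finite.size == 0:
        raise ValueError("height map is fully invalid")
    if np.ptp(finite) < 1e-9:
        return float(np.median(finite))
    try:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(finite)
    except ValueError:
        return float(np.median(finite))
    low = finite[finite < thr]
    if low.size < 0.05 * finite.size:
        return float(np.median(finite))
    return float(np.median(low))


def _mode_center(values: np.ndarray, bin_width: float = 20.0) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < bin_width:
        return float(np.median(values))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    j = int(np.argmax(counts))
    sel = values[(values >= edges[j]) & (values < edges[j + 1] + 1e-12)]
    return float(np.median(sel)) if sel.size else float(np.median(values))


def _detrend_row(row: np.ndarray, x: np.ndarray, order: int, halfwidth: float = 40.0):
    """Remove the non-constant polynomial trend of one scan line, fitted to
    the line's dominant plateau only (mode window, iterated) so that the
    cell body, nuclear bulge and pores cannot tilt the fit."""
    resid = row.copy()
    trend = np.zeros_like(row)
    use = np.abs(resid - _mode_center(resid)) < halfwidth
    for _ in range(3):
        if use.sum() < order + 2:
            return row
        coef = np.polyfit(x[use], resid[use], order)
        step = np.polyval(coef, x)
        trend = trend + step
        resid = row - trend
        use = np.abs(resid - _mode_center(resid)) < halfwidth
    return resid + (np.median(trend[use]) if use.any() else np.median(trend))


def flatten(hmap: HeightMap, order: int = 1) -> HeightMap:
    """Line-wise levelling of a height map.

    Row offsets are aligned by cumulative medians of row-to-row
    differences (robust to pores and the cell plateau); for order >= 1 a
    sigma-clipped polynomial of the given order is fitted per scan line
    and its non-constant part subtracted.  Finally the substrate median is
    set to zero.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if not hmap.valid_mask.any():
        raise ValueError("height map is fully invalid")
    h = _fill_invalid(hmap.heights, hmap.valid_mask)
    ny, nx = h.shape
    # scan lines run along the fast axis; operate row-wise for fast_axis=x
    work = h if hmap.fast_axis == "x" else h.T
    def _align_rows(w: np.ndarray) -> np.ndarray:
        diffs = np.median(np.diff(w, axis=0), axis=1)
        offsets = np.concatenate([[0.0], np.cumsum(diffs)])
        return w - offsets[:, None]

    work = _align_rows(work)
    if order >= 1:
        x = np.arange(work.shape[1], dtype=float)
        for i in range(work.shape[0]):
            work[i] = _detrend_row(work[i], x, order)
        # detrending fixes each line's constant to its own plateau; re-align
        work = _align_rows(work)
    out = work if hmap.fast_axis == "x" else work.T
    out = out - _substrate_offset(out)
    heights = np.where(hmap.valid_mask, out, np.nan)
    return HeightMap(
        heights=heights,
        valid_mask=hmap.valid_mask.copy(),
        pixel_size=hmap.pixel_size,
        load_force=hmap.load_force,
        fast_axis=hmap.fast_axis,
        metadata={**hmap.metadata, "flatten_order": order},
    )


def segment_cell(hmap: HeightMap, height_threshold: float) -> tuple[np.ndarray, float]:
    """Cell mask (largest connected region above the threshold, pores
    filled) and its projected area in µm²."""
    h = _fill_invalid(hmap.heights, hmap.valid_mask)
    raw = h > height_threshold
    if not raw.any():
        raise ValueError("no pixels above the cell height threshold")
    raw = ndimage.binary_fill_holes(raw)
    labels = measure.label(raw, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    area_um2 = float(mask.sum()) * hmap.pixel_size**2 / 1e6
    return mask, area_um2


def detect_nuclear_region(hmap: HeightMap, bulge_threshold: float) -> np.ndarray:
    """Contiguous nuclear bulge above the threshold, morphologically
    closed; empty masks are allowed (flat cells have no bulge)."""
    h = _fill_invalid(hmap.heights, hmap.valid_mask)
    raw = h > bulge_threshold
    if not raw.any():
        return np.zeros_like(raw)
    closed = ndimage.binary_closing(raw, structure=morphology.disk(3))
    closed = ndimage.binary_fill_holes(closed)
    labels = measure.label(closed, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


# ---------------------------------------------------------------------------
# pore detection


def _crossing(row: np.ndarray, start: int, level: float, step: int) -> float:
    """Sub-pixel column index where the row rises through ``level`` walking
    from ``start`` in direction ``step``; the map edge clips the walk."""
    j = start
    n = row.size
    while 0 <= j + step < n and not row[j + step] > level:
        j += step
    nxt = j + step
    if not 0 <= nxt < n:
        return float(j) + 0.5 * step
    lo, hi = row[j], row[nxt]
    frac = (level - lo) / (hi - lo) if hi > lo else 0.5
    return j + step * float(np.clip(frac, 0.0, 1.0))


def _fast_axis_diameter(
    heights: np.ndarray, comp_mask: np.ndarray, level: float, pixel_size: float
) -> float:
    """Extent of a pore along the fast axis at the given height level,
    through the scan line containing the component's centroid."""
    ys, xs = np.nonzero(comp_mask)
    iy = int(round(ys.mean()))
    cols = xs[ys == iy]
    if cols.size == 0:  # centroid row outside the component (odd shapes)
        deepest = np.argmin(heights[ys, xs])
        iy, ix = int(ys[deepest]), int(xs[deepest])
    else:
        ix = int(cols[np.argmin(heights[iy, cols])])
    row = heights[iy]
    left = _crossing(row, ix, level, -1)
    right = _crossing(row, ix, level, +1)
    return max(right - left, 0.5) * pixel_size


def detect_pores(
    hmap: HeightMap,
    cell_mask: np.ndarray,
    depth_threshold: float | None = None,
    d_range: tuple[float, float] = (50.0, 350.0),
    min_circularity: float = 0.3,
    criterion: str = "half-depth",
    nuclear_mask: np.ndarray | None = None,
) -> list[PoreRecord]:
    """Detect pores as connected components deeper than a threshold below
    the local cell surface.

    The local surface is a grey-scale closing wide enough to bridge the
    largest admissible pore.  ``depth_threshold`` defaults to half the
    local membrane height above the substrate (which is at 0 after
    :func:`flatten`).  Components are filtered by fast-axis diameter range
    and circularity; ``criterion`` selects the level at which the diameter
    is read (``half-depth`` | ``fixed-depth`` | ``full-width``).
    """
    if criterion not in ("half-depth", "fixed-depth", "full-width"):
        raise ValueError(f"unknown diameter criterion {criterion!r}")
    h = _fill_invalid(hmap.heights, hmap.valid_mask)
    px = hmap.pixel_size
    size = max(3, 2 * int(np.ceil(d_range[1] / px)) + 1)
    surface = ndimage.grey_closing(h, size=(size, size), mode="nearest")
    depth = surface - h
    if depth_threshold is None:
        thr_map = 0.5 * np.clip(surface, 0.0, None)
    else:
        if depth_threshold <= 0:
            warnings.warn("depth_threshold at or below the noise floor")
        thr_map = np.full_like(h, float(depth_threshold))
    candidate = (depth > thr_map) & cell_mask & np.isfinite(hmap.heights)
    labels = measure.label(candidate, connectivity=2)
    records: list[PoreRecord] = []
    for region in measure.regionprops(labels):
        comp = labels == region.label
        comp_depth = float(depth[comp].max())
        cy, cx = region.centroid
        local_surface = float(surface[int(round(cy)), int(round(cx))])
        if criterion == "half-depth":
            level = local_surface - comp_depth / 2.0
        elif criterion == "fixed-depth":
            level = local_surface - float(thr_map[int(round(cy)), int(round(cx))])
        else:  # full-width at the detection threshold
            level = local_surface - float(thr_map[int(round(cy)), int(round(cx))])
        diameter = _fast_axis_diameter(h, comp, level, px)
        if not d_range[0] <= diameter <= d_range[1]:
            continue
        perim = region.perimeter if region.perimeter > 0 else 1.0
        circ = min(4.0 * np.pi * region.area / perim**2, 1.0)
        if circ < min_circularity:
            continue
        in_nuc = bool(
            nuclear_mask is not None and nuclear_mask[int(round(cy)), int(round(cx))]
        )
        records.append(
            PoreRecord(
                centroid_x_nm=(cx + 0.5) * px,
                centroid_y_nm=(cy + 0.5) * px,
                diameter_fast_axis_nm=float(diameter),
                depth_nm=comp_depth,
                area_nm2=float(region.area) * px**2,
                circularity=float(circ),
                in_nuclear_region=in_nuc,
                criterion=criterion,
                load_force_pn=hmap.load_force,
            )
        )
    return records


def assign_sieve_plates(pores: list[PoreRecord], linkage_nm: float = 1500.0) -> None:
    """Group pores into sieve plates by single-linkage clustering of their
    centroids (reporting only; plays no role in inclusion rules)."""
    n = len(pores)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(
                pores[i].centroid_x_nm - pores[j].centroid_x_nm,
                pores[i].centroid_y_nm - pores[j].centroid_y_nm,
            )
            if d <= linkage_nm:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    for i, p in enumerate(pores):
        r = find(i)
        roots.setdefault(r, len(roots))
        p.sieve_plate_id = roots[r]


def compute_porosity(
    pores: list[PoreRecord],
    cell_mask: np.ndarray,
    nuclear_mask: np.ndarray | None,
    pixel_size: float,
) -> PorosityResult:
    """Fenestrations per µm² of projected cell area, with pores over the
    nuclear bulge (fenestrae labyrinths, not transcellular) excluded."""
    area_um2 = float(cell_mask.sum()) * pixel_size**2 / 1e6
    if area_um2 <= 0:
        raise ValueError("cell area is zero")
    excluded = 0
    kept = 0
    for p in pores:
        ix = int(round(p.centroid_x_nm / pixel_size - 0.5))
        iy = int(round(p.centroid_y_nm / pixel_size - 0.5))
        in_nuc = p.in_nuclear_region
        if nuclear_mask is not None:
            iy = int(np.clip(iy, 0, nuclear_mask.shape[0] - 1))
            ix = int(np.clip(ix, 0, nuclear_mask.shape[1] - 1))
            in_nuc = in_nuc or bool(nuclear_mask[iy, ix])
            p.in_nuclear_region = in_nuc
        if in_nuc:
            excluded += 1
        else:
            kept += 1
    return PorosityResult(
        n_fenestrations=kept,
        cell_area_um2=area_um2,
        porosity_per_um2=kept / area_um2,
        n_excluded_nuclear=excluded,
    )


# ---------------------------------------------------------------------------
# deformability


def match_pores(
    pores_low: list[PoreRecord],
    pores_high: list[PoreRecord],
    max_centroid_dist: float,
) -> tuple[list[DeformabilityPair], list[PoreRecord], list[PoreRecord]]:
    """Greedy nearest-centroid one-to-one matching between the low- and
    high-force pore lists; candidate pairs are processed in order of
    centroid distance, which makes the outcome order-stable.

    Returns (pairs, unmatched_low, unmatched_high)."""
    cand = []
    for i, pl in enumerate(pores_low):
        for j, ph in enumerate(pores_high):
            d = np.hypot(
                pl.centroid_x_nm - ph.centroid_x_nm, pl.centroid_y_nm - ph.centroid_y_nm
            )
            if d <= max_centroid_dist:
                cand.append((d, i, j))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_low: set[int] = set()
    used_high: set[int] = set()
    pairs: list[DeformabilityPair] = []
    for d, i, j in cand:
        if i in used_low or j in used_high:
            continue
        used_low.add(i)
        used_high.add(j)
        pl, ph = pores_low[i], pores_high[j]
        pairs.append(
            DeformabilityPair(
                pore_low=pl,
                pore_high=ph,
                fold_change=ph.diameter_fast_axis_nm / pl.diameter_fast_axis_nm,
                pixel_size=0.0,
                centroid_distance_nm=float(d),
            )
        )
    unmatched_low = [p for i, p in enumerate(pores_low) if i not in used_low]
    unmatched_high = [p for j, p in enumerate(pores_high) if j not in used_high]
    return pairs, unmatched_low, unmatched_high


def deformability_summary(pairs: list[DeformabilityPair]) -> DeformabilitySummary:
    """Mean ± sd fold change over matched pores and the equivalent percent
    enlargement, (mean − 1) × 100."""
    if not pairs:
        raise ValueError("no matched pore pairs")
    folds = np.array([p.fold_change for p in pairs])
    mean = float(folds.mean())
    sd = float(folds.std(ddof=1)) if folds.size > 1 else 0.0
    return DeformabilitySummary(
        mean_fold_change=mean,
        sd_fold_change=sd,
        percent_enlargement=(mean - 1.0) * 100.0,
        n_pairs=int(folds.size),
    )
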