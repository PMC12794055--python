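"""Illumination correction, segmentation and nucleus-cell relation.

The analysis core follows the assay's pipeline: (1) correct the smooth
multiplicative illumination bias of the alpha-actinin channel; (2) segment
nuclei on DAPI with optional distance-transform watershed declumping;
(3) classify each nucleus as cardiomyocyte (CM) or non-CM by its overlap
with the alpha-actinin foreground; (4) partition the alpha-actinin
foreground into cells by a watershed seeded from CM nuclei, with a
merged-basin rule so that a binucleated CM — two nuclei in one continuous
bright body with no intensity valley between them — stays ONE cell
(the failure mode of plain propagation-based segmentation); (5) relate
nuclei to cells as parent/child objects, which defines nuclearity and the
mononucleated subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

from .config import AssayConfig


class DegenerateInputError(ValueError):
    """Raster has no structure to operate on (e.g. constant image)."""


@dataclass
class NucleusRecord:
    nucleus_id: int
    centroid: tuple[float, float]
    area_px: int
    is_cm_nucleus: bool
    parent_cell_id: int | None
    touches_border: bool


@dataclass
class CellRecord:
    cell_id: int
    nuclearity: int
    child_nucleus_ids: list[int]
    area_px: int
    touches_border: bool


# ---------------------------------------------------------------------------
# Illumination correction
# ---------------------------------------------------------------------------

def _poly_terms(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            cols.append((x**i) * (y**j))
    return np.stack(cols, axis=-1)


def correct_illumination(
    raster: np.ndarray,
    surface_order: int = 2,
    robust_fraction: float = 0.1,
    grid_blocks: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit and divide out a smooth multiplicative illumination surface.

    Background is sampled as the ``robust_fraction`` quantile of each block
    of a ``grid_blocks`` x ``grid_blocks`` grid; a polynomial surface of the
    given order is least-squares fitted to the samples with one outlier-
    rejection pass (blocks dominated by bright objects are discarded by
    their fit residual).  The raster is divided by the surface and rescaled
    so the median background level is unchanged.

    Returns ``(corrected, surface)``; the surface is strictly positive and
    normalized to mean 1.

    Raises :class:`DegenerateInputError` for a constant raster.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise DegenerateInputError("raster must be 2-D")
    if not np.all(np.isfinite(raster)):
        raise DegenerateInputError("raster contains non-finite values")
    if np.ptp(raster) == 0:
        raise DegenerateInputError("constant raster: illumination undefined")

    nr, nc = raster.shape
    rb = max(nr // grid_blocks, 4)
    cb = max(nc // grid_blocks, 4)
    xs, ys, vals = [], [], []
    for r0 in range(0, nr - rb + 1, rb):
        for c0 in range(0, nc - cb + 1, cb):
            block = raster[r0 : r0 + rb, c0 : c0 + cb]
            xs.append((r0 + rb / 2.0) / nr * 2 - 1)
            ys.append((c0 + cb / 2.0) / nc * 2 - 1)
            vals.append(np.quantile(block, robust_fraction))
    x = np.asarray(xs)
    y = np.asarray(ys)
    v = np.asarray(vals)

    A = _poly_terms(x, y, surface_order)
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ coef
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3.0 * 1.4826 * mad
        if keep.sum() >= A.shape[1]:
            coef, *_ = np.linalg.lstsq(A[keep], v[keep], rcond=None)

    rows, cols = np.mgrid[0:nr, 0:nc]
    xg = (rows + 0.5) / nr * 2 - 1
    yg = (cols + 0.5) / nc * 2 - 1
    surface = _poly_terms(xg.ravel(), yg.ravel(), surface_order) @ coef
    surface = surface.reshape(nr, nc)
    floor = max(1e-6, 0.05 * float(np.median(np.abs(surface))))
    surface = np.maximum(surface, floor)
    surface = surface / surface.mean()

    corrected = raster / surface
    # Rescale so the median background level is preserved.
    bg = corrected <= np.quantile(corrected, 0.5)
    med_pre = float(np.median(raster[bg]))
    med_post = float(np.median(corrected[bg]))
    if med_post > 0:
        corrected = corrected * (med_pre / med_post)
    return corrected, surface


# ---------------------------------------------------------------------------
# Thresholding helpers
# ---------------------------------------------------------------------------

def _threshold(raster: np.ndarray, method: str, value: float) -> float:
    if method == "otsu":
        return float(threshold_otsu(raster))
    if method == "percentile":
        return float(np.percentile(raster, value))
    if method == "fixed":
        return float(value)
    raise ValueError(f"unknown threshold method {method!r}")


# ---------------------------------------------------------------------------
# Nucleus segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    dapi: np.ndarray,
    threshold_method: str = "otsu",
    threshold_value: float = 0.5,
    min_area_px: int = 30,
    declump: bool = True,
    smooth_sigma: float = 1.0,
    declump_min_distance_px: int = 5,
) -> np.ndarray:
    """Segment DAPI nuclei into a label map (0 = background).

    Touching nuclei are split by a watershed on the distance transform when
    *declump* is on; objects below *min_area_px* are removed.  An empty or
    constant image yields an all-zero map.
    """
    dapi = np.asarray(dapi, dtype=float)
    if np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=np.int32)
    smoothed = ndimage.gaussian_filter(dapi, smooth_sigma) if smooth_sigma > 0 else dapi
    mask = smoothed > _threshold(smoothed, threshold_method, threshold_value)
    mask = ndimage.binary_fill_holes(mask)
    if min_area_px > 0:
        comps = cc_label(mask, connectivity=1)
        counts = np.bincount(comps.ravel())
        small = np.flatnonzero(counts < min_area_px)
        mask &= ~np.isin(comps, small[small > 0])
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    if not declump:
        labels = cc_label(mask, connectivity=1)
    else:
        dist = ndimage.distance_transform_edt(mask)
        peaks = peak_local_max(
            dist,
            min_distance=declump_min_distance_px,
            labels=cc_label(mask, connectivity=1),
            exclude_border=False,
        )
        if len(peaks) == 0:
            labels = cc_label(mask, connectivity=1)
        else:
            markers = np.zeros(mask.shape, dtype=np.int32)
            for i, (r, c) in enumerate(peaks, start=1):
                markers[r, c] = i
            labels = watershed(-dist, markers=markers, mask=mask)
    if min_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
    labels, *_ = relabel_sequential(labels)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# Nucleus classification by alpha-actinin colocalization
# ---------------------------------------------------------------------------

def actinin_foreground(
    actinin_corrected: np.ndarray,
    threshold_method: str = "otsu",
    threshold_value: float = 0.5,
) -> np.ndarray:
    """Binary alpha-actinin foreground mask on the corrected channel."""
    raster = np.asarray(actinin_corrected, dtype=float)
    if np.ptp(raster) == 0:
        return np.zeros(raster.shape, dtype=bool)
    mask = raster > _threshold(raster, threshold_method, threshold_value)
    return ndimage.binary_fill_holes(mask)


def classify_nuclei(
    nuclei: np.ndarray,
    actinin_mask: np.ndarray,
    overlap_fraction: float = 0.5,
) -> dict[int, bool]:
    """Flag each nucleus CM iff its overlap with the actinin foreground is
    at least *overlap_fraction* of its area.  Every nucleus gets exactly
    one flag."""
    if nuclei.shape != actinin_mask.shape:
        raise ValueError("label map and mask shapes differ")
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return {}
    areas = ndimage.sum_labels(np.ones_like(nuclei), nuclei, ids)
    overlaps = ndimage.sum_labels(actinin_mask.astype(float), nuclei, ids)
    return {
        int(i): bool(o / a >= overlap_fraction)
        for i, a, o in zip(ids, areas, overlaps)
    }


# ---------------------------------------------------------------------------
# Cardiomyocyte segmentation (seeded watershed + merged-basin rule)
# ---------------------------------------------------------------------------

def _adjacent_ridge_minima(
    labels: np.ndarray, intensity: np.ndarray, interior: np.ndarray
) -> dict[tuple[int, int], float]:
    """Minimum intensity on the interior ridge between each adjacent pair.

    Ridge pixels near the object boundary (outside *interior*) are ignored:
    the merge decision concerns the valley *between* nuclei, not the
    intensity falloff at the cell edge.
    """
    minima: dict[tuple[int, int], float] = {}
    for axis in (0, 1):
        a = labels.take(range(labels.shape[axis] - 1), axis=axis)
        b = labels.take(range(1, labels.shape[axis]), axis=axis)
        ia = intensity.take(range(labels.shape[axis] - 1), axis=axis)
        ib = intensity.take(range(1, labels.shape[axis]), axis=axis)
        inta = interior.take(range(labels.shape[axis] - 1), axis=axis)
        intb = interior.take(range(1, labels.shape[axis]), axis=axis)
        sel = (a > 0) & (b > 0) & (a != b) & inta & intb
        if not sel.any():
            continue
        lo = np.minimum(a[sel], b[sel])
        hi = np.maximum(a[sel], b[sel])
        val = np.minimum(ia[sel], ib[sel])
        for i, j, v in zip(lo, hi, val):
            key = (int(i), int(j))
            if key not in minima or v < minima[key]:
                minima[key] = float(v)
    return minima


class _UnionFind:
    def __init__(self, items: Sequence[int]):
        self.parent = {i: i for i in items}

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # Deterministic: smaller root wins.
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def segment_cardiomyocytes(
    actinin_corrected: np.ndarray,
    nuclei: np.ndarray,
    cm_seed_ids: Sequence[int],
    threshold_method: str = "otsu",
    threshold_value: float = 0.5,
    min_area_px: int = 200,
    ridge_fraction: float = 0.6,
) -> np.ndarray:
    """Partition the alpha-actinin foreground into CM cells.

    A watershed on the inverted corrected intensity is seeded from the CM
    nuclei in *cm_seed_ids*.  Basins whose shared ridge shows no intensity
    valley — minimum interior ridge intensity >= *ridge_fraction* times the
    mean intensity of the two basins — are merged into one cell, which is
    what lets a binucleated CM remain a single object.  Cells below
    *min_area_px* are removed.  An empty seed list yields an empty map.
    """
    actinin_corrected = np.asarray(actinin_corrected, dtype=float)
    if actinin_corrected.shape != nuclei.shape:
        raise ValueError("raster and nucleus label map shapes differ")
    out = np.zeros(actinin_corrected.shape, dtype=np.int32)
    seeds = [int(s) for s in cm_seed_ids]
    if not seeds:
        return out
    fg = actinin_foreground(actinin_corrected, threshold_method, threshold_value)
    if not fg.any():
        return out

    markers = np.where(np.isin(nuclei, seeds), nuclei, 0).astype(np.int32)
    markers[~fg] = 0
    if not markers.any():
        return out
    basins = watershed(-actinin_corrected, markers=markers, mask=fg)

    interior = ndimage.binary_erosion(fg, iterations=2)
    ridge_min = _adjacent_ridge_minima(basins, actinin_corrected, interior)
    ids = np.unique(basins)
    ids = ids[ids > 0]
    means = dict(
        zip(
            (int(i) for i in ids),
            ndimage.mean(actinin_corrected, basins, ids),
        )
    )
    uf = _UnionFind([int(i) for i in ids])
    for (i, j), vmin in ridge_min.items():
        pair_mean = 0.5 * (means[i] + means[j])
        if pair_mean > 0 and vmin >= ridge_fraction * pair_mean:
            uf.union(i, j)

    merged = basins.copy()
    for i in ids:
        root = uf.find(int(i))
        if root != int(i):
            merged[basins == i] = root

    if min_area_px > 0:
        counts = np.bincount(merged.ravel())
        small = np.flatnonzero(counts < min_area_px)
        merged[np.isin(merged, small[small > 0])] = 0
    merged, *_ = relabel_sequential(merged)
    return merged.astype(np.int32)


# ---------------------------------------------------------------------------
# Nucleus-to-cell relation
# ---------------------------------------------------------------------------

def _touches_border(labels: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(int(i) for i in np.unique(edge) if i > 0)


def relate_nuclei_to_cells(
    nuclei: np.ndarray,
    cells: np.ndarray,
    is_cm: Mapping[int, bool] | None = None,
) -> tuple[list[NucleusRecord], list[CellRecord]]:
    """Assign nuclei to cells as child objects and derive nuclearity.

    Each CM-flagged nucleus becomes a child of the cell covering the
    majority of its pixels (ties broken by the lower cell id).  Cells left
    with zero nuclei are dropped as segmentation artifacts; CM nuclei whose
    parent cell vanished are reclassified non-CM so the CM/non-CM partition
    stays exact.  When *is_cm* is None, any nucleus overlapping a cell is
    treated as a candidate CM nucleus.
    """
    if nuclei.shape != cells.shape:
        raise ValueError("label map shapes differ")
    nuc_ids = [int(i) for i in np.unique(nuclei) if i > 0]
    cell_ids = [int(i) for i in np.unique(cells) if i > 0]
    nuc_border = _touches_border(nuclei)
    cell_border = _touches_border(cells)

    # Joint histogram of (nucleus, cell) pixel overlaps.
    sel = nuclei > 0
    pairs: dict[int, dict[int, int]] = {i: {} for i in nuc_ids}
    if sel.any():
        n_flat = nuclei[sel].ravel()
        c_flat = cells[sel].ravel()
        key = n_flat.astype(np.int64) * (max(cell_ids, default=0) + 1) + c_flat
        uniq, counts = np.unique(key, return_counts=True)
        base = max(cell_ids, default=0) + 1
        for k, cnt in zip(uniq, counts):
            nid, cid = int(k // base), int(k % base)
            if cid > 0:
                pairs[nid][cid] = int(cnt)

    areas = dict(
        zip(
            nuc_ids,
            ndimage.sum_labels(np.ones_like(nuclei), nuclei, nuc_ids).astype(int),
        )
    ) if nuc_ids else {}
    centroids = (
        dict(zip(nuc_ids, ndimage.center_of_mass(np.ones_like(nuclei), nuclei, nuc_ids)))
        if nuc_ids
        else {}
    )
    cell_areas = dict(
        zip(
            cell_ids,
            ndimage.sum_labels(np.ones_like(cells), cells, cell_ids).astype(int),
        )
    ) if cell_ids else {}

    children: dict[int, list[int]] = {c: [] for c in cell_ids}
    parent: dict[int, int | None] = {}
    for nid in nuc_ids:
        flagged = is_cm.get(nid, False) if is_cm is not None else bool(pairs[nid])
        cand = pairs[nid]
        if flagged and cand:
            best = max(cand.values())
            cid = min(c for c, v in cand.items() if v == best)
            parent[nid] = cid
            children[cid].append(nid)
        else:
            parent[nid] = None

    cell_records = []
    surviving = set()
    for cid in cell_ids:
        if not children[cid]:
            continue  # cell with no nucleus: segmentation artifact, dropped
        surviving.add(cid)
        cell_records.append(
            CellRecord(
                cell_id=cid,
                nuclearity=len(children[cid]),
                child_nucleus_ids=sorted(children[cid]),
                area_px=cell_areas[cid],
                touches_border=cid in cell_border,
            )
        )

    nucleus_records = []
    for nid in nuc_ids:
        pid = parent[nid]
        if pid is not None and pid not in surviving:
            pid = None
        nucleus_records.append(
            NucleusRecord(
                nucleus_id=nid,
                centroid=tuple(float(x) for x in centroids[nid]),
                area_px=areas[nid],
                is_cm_nucleus=pid is not None,
                parent_cell_id=pid,
                touches_border=nid in nuc_border,
            )
        )
    return nucleus_records, cell_records


def filter_border_objects(records: Sequence) -> tuple[list, list]:
    """Split records into (interior, border-touching).

    Border-touching objects are excluded from morphometric statistics but
    remain available for raw counts.
    """
    interior = [r for r in records if not r.touches_border]
    border = [r for r in records if r.touches_border]
    return interior, border


# ---------------------------------------------------------------------------
# Whole-field convenience
# ---------------------------------------------------------------------------

@dataclass
class FieldSegmentation:
    """All segmentation products for one field."""

    nuclei: np.ndarray
    cells: np.ndarray
    actinin_corrected: np.ndarray
    illumination_surface: np.ndarray
    actinin_mask: np.ndarray
    nucleus_records: list[NucleusRecord]
    cell_records: list[CellRecord]


def segment_field(dapi: np.ndarray, actinin: np.ndarray, config: AssayConfig) -> FieldSegmentation:
    """Run the full segmentation stage on one two-channel field."""
    config.validate()
    corrected, surface = correct_illumination(
        actinin,
        surface_order=config.surface_order,
        robust_fraction=config.robust_fraction,
        grid_blocks=config.illum_grid_blocks,
    )
    nuclei = segment_nuclei(
        dapi,
        threshold_method=config.nucleus_threshold_method,
        threshold_value=config.nucleus_threshold_value,
        min_area_px=config.nucleus_min_area_px,
        declump=config.declump,
        smooth_sigma=config.nucleus_smooth_sigma,
        declump_min_distance_px=config.declump_min_distance_px,
    )
    mask = actinin_foreground(
        corrected, config.actinin_threshold_method, config.actinin_threshold_value
    )
    flags = classify_nuclei(nuclei, mask, config.overlap_fraction)
    seeds = [i for i, f in flags.items() if f]
    cells = segment_cardiomyocytes(
        corrected,
        nuclei,
        seeds,
        threshold_method=config.actinin_threshold_method,
        threshold_value=config.actinin_threshold_value,
        min_area_px=config.cell_min_area_px,
        ridge_fraction=config.ridge_fraction,
    )
    nucleus_records, cell_records = relate_nuclei_to_cells(nuclei, cells, flags)
    return FieldSegmentation(
        nuclei=nuclei,
        cells=cells,
        actinin_corrected=corrected,
        illumination_surface=surface,
        actinin_mask=mask,
        nucleus_records=nucleus_records,
        cell_records=cell_records,
    )
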