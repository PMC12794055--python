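"""Per-object morphology, intensity and co-occurrence texture features.

Intensity features are measured on the illumination-corrected
alpha-actinin raster for both nuclei and cells — the correction exists
precisely so intensities are comparable across a field.  Texture is
classical gray-level co-occurrence (GLCM): intensities are min-max scaled
to ``gray_levels`` within each object, pixel pairs are counted only when
both pixels lie inside the object's mask, the matrix is symmetrized and
normalized, and features are averaged over the four principal directions
(0, 45, 90, 135 degrees) at each configured offset.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

TEXTURE_FEATURES = ("asm", "contrast", "correlation", "entropy")

# Direction vectors (row, col) for 0, 45, 90, 135 degrees.
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


class ConsistencyError(ValueError):
    """Object-table id spaces are inconsistent (e.g. dangling parent)."""


def measure_morphology(labels: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Area, centroid, perimeter and eccentricity per labeled object.

    Area is the exact pixel count; ``area_um2 = area_px * pixel_size_um**2``.
    """
    rows = []
    for p in regionprops(np.asarray(labels)):
        rows.append(
            {
                "object_id": int(p.label),
                "area_px": int(p.area),
                "area_um2": float(p.area) * pixel_size_um**2,
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
                "perimeter_px": float(p.perimeter),
                "eccentricity": float(p.eccentricity),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "area_px",
            "area_um2",
            "centroid_row",
            "centroid_col",
            "perimeter_px",
            "eccentricity",
        ],
    )


def measure_intensity(labels: np.ndarray, raster: np.ndarray) -> pd.DataFrame:
    """Mean, integrated, sd and upper-decile-mean intensity per object.

    Statistics are taken over exactly the labeled pixels; background is
    excluded.  ``integrated = mean * area`` holds to machine precision.
    """
    labels = np.asarray(labels)
    raster = np.asarray(raster, dtype=float)
    if labels.shape != raster.shape:
        raise ValueError("label map and raster shapes differ")
    rows = []
    for i in (int(v) for v in np.unique(labels) if v > 0):
        vals = raster[labels == i]
        mean = float(vals.mean())
        decile = float(np.quantile(vals, 0.9))
        rows.append(
            {
                "object_id": i,
                "mean_intensity": mean,
                "integrated_intensity": mean * vals.size,
                "intensity_sd": float(vals.std(ddof=0)),
                "upper_decile_mean_intensity": float(vals[vals >= decile].mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "mean_intensity",
            "integrated_intensity",
            "intensity_sd",
            "upper_decile_mean_intensity",
        ],
    )


def _quantize(vals: np.ndarray, gray_levels: int) -> np.ndarray:
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros(vals.shape, dtype=np.int64)
    q = np.floor((vals - lo) / (hi - lo) * gray_levels).astype(np.int64)
    return np.minimum(q, gray_levels - 1)


def _glcm(
    quant: np.ndarray, mask: np.ndarray, offset: int, gray_levels: int
) -> np.ndarray | None:
    """Symmetric normalized GLCM over within-mask pixel pairs, averaged over
    the four principal directions.  None when no valid pair exists."""
    acc = np.zeros((gray_levels, gray_levels), dtype=float)
    total = 0
    nr, nc = mask.shape
    for dr, dc in _DIRECTIONS:
        dr_, dc_ = dr * offset, dc * offset
        r0, r1 = max(0, -dr_), min(nr, nr - dr_)
        c0, c1 = max(0, -dc_), min(nc, nc - dc_)
        m1 = mask[r0:r1, c0:c1]
        m2 = mask[r0 + dr_ : r1 + dr_, c0 + dc_ : c1 + dc_]
        both = m1 & m2
        if not both.any():
            continue
        a = quant[r0:r1, c0:c1][both]
        b = quant[r0 + dr_ : r1 + dr_, c0 + dc_ : c1 + dc_][both]
        np.add.at(acc, (a, b), 1.0)
        np.add.at(acc, (b, a), 1.0)  # symmetric
        total += 2 * a.size
    if total == 0:
        return None
    return acc / total


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """ASM, contrast, correlation and entropy of a normalized GLCM."""
    g = p.shape[0]
    i, j = np.mgrid[0:g, 0:g]
    asm = float((p**2).sum())
    contrast = float((p * (i - j) ** 2).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    sd_i = math.sqrt(float((p * (i - mu_i) ** 2).sum()))
    sd_j = math.sqrt(float((p * (j - mu_j) ** 2).sum()))
    if sd_i > 0 and sd_j > 0:
        corr = float((p * (i - mu_i) * (j - mu_j)).sum()) / (sd_i * sd_j)
    else:
        corr = 1.0  # degenerate single-level object: perfectly correlated
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"asm": asm, "contrast": contrast, "correlation": corr, "entropy": entropy}


def measure_texture(
    labels: np.ndarray,
    raster: np.ndarray,
    offsets_px: Sequence[int] = (1, 4),
    gray_levels: int = 8,
    min_area_px: int = 25,
) -> pd.DataFrame:
    """Per-object GLCM texture features at each offset.

    Objects below *min_area_px* (or with no valid within-mask pair at an
    offset) get NaN for that offset's features rather than an error.
    Column names are ``<feature>_o<offset>``.
    """
    labels = np.asarray(labels)
    raster = np.asarray(raster, dtype=float)
    if labels.shape != raster.shape:
        raise ValueError("label map and raster shapes differ")
    cols = ["object_id"] + [
        f"{feat}_o{off}" for off in offsets_px for feat in TEXTURE_FEATURES
    ]
    rows = []
    slices = ndimage.find_objects(labels)
    for i in (int(v) for v in np.unique(labels) if v > 0):
        sl = slices[i - 1]
        sub_mask = labels[sl] == i
        row: dict[str, float] = {"object_id": i}
        if int(sub_mask.sum()) < min_area_px:
            for off in offsets_px:
                for feat in TEXTURE_FEATURES:
                    row[f"{feat}_o{off}"] = float("nan")
            rows.append(row)
            continue
        quant = _quantize(raster[sl][sub_mask], gray_levels)
        qimg = np.zeros(sub_mask.shape, dtype=np.int64)
        qimg[sub_mask] = quant
        for off in offsets_px:
            p = _glcm(qimg, sub_mask, int(off), gray_levels)
            feats = (
                glcm_features(p)
                if p is not None
                else {f: float("nan") for f in TEXTURE_FEATURES}
            )
            for feat in TEXTURE_FEATURES:
                row[f"{feat}_o{off}"] = feats[feat]
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def assemble_object_table(
    nucleus_records,
    cell_records,
    nucleus_features: Sequence[pd.DataFrame],
    cell_features: Sequence[pd.DataFrame],
    well_id: str = "",
    field_index: int = 0,
) -> pd.DataFrame:
    """Combine records and feature frames into one row-per-object table.

    Raises :class:`ConsistencyError` on a dangling parent cell id.
    """
    cell_ids = {c.cell_id for c in cell_records}
    for n in nucleus_records:
        if n.parent_cell_id is not None and n.parent_cell_id not in cell_ids:
            raise ConsistencyError(
                f"nucleus {n.nucleus_id} references missing cell {n.parent_cell_id}"
            )

    def merged(records, frames, make_row):
        base = pd.DataFrame([make_row(r) for r in records])
        for f in frames:
            if not f.empty:
                base = base.merge(f, on="object_id", how="left")
        return base

    nuc = merged(
        nucleus_records,
        nucleus_features,
        lambda n: {
            "well_id": well_id,
            "field_index": field_index,
            "object_id": n.nucleus_id,
            "object_class": "cm_nucleus" if n.is_cm_nucleus else "noncm_nucleus",
            "parent_cell_id": n.parent_cell_id if n.parent_cell_id is not None else -1,
            "touches_border": n.touches_border,
            "nuclearity": np.nan,
        },
    )
    cell = merged(
        cell_records,
        cell_features,
        lambda c: {
            "well_id": well_id,
            "field_index": field_index,
            "object_id": c.cell_id,
            "object_class": "cm_cell",
            "parent_cell_id": -1,
            "touches_border": c.touches_border,
            "nuclearity": c.nuclearity,
        },
    )
    if nuc.empty and cell.empty:
        return pd.DataFrame(
            columns=[
                "well_id",
                "field_index",
                "object_id",
                "object_class",
                "parent_cell_id",
                "touches_border",
                "nuclearity",
            ]
        )
    return pd.concat([cell, nuc], ignore_index=True)
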