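"""Domain types and file I/O: two-channel fields, plate layouts, tables.

Images are single-channel TIFFs, one per channel per field, named
``<well>_f<field>_<channel>.tif`` by default (channel in {dapi, actinin}).
Intensities are processed as floats normalized by the source bit-depth
maximum so that thresholds transfer between 8- and 16-bit acquisitions;
the original bit depth is kept in provenance metadata.

Tables (plate layout, compound annotations, object tables, well summaries)
are RFC-4180 CSV with '.' decimal; floats are written with full repr
precision so write/read round-trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

VALID_ROLES = ("vehicle", "stimulated", "stimulated+compound")


class ValidationError(ValueError):
    """Input data violates a contract (duplicate wells, no vehicle, ...)."""


class DimensionError(ValidationError):
    """Channel rasters disagree in shape."""


@dataclass
class FieldImage:
    """Two registered single-channel rasters for one field of one well.

    ``dapi`` marks all nuclei; ``actinin`` marks sarcomeric alpha-actinin,
    i.e. cardiomyocyte bodies.  Intensities are floats on [0, ~1]
    (normalized by the source bit-depth maximum).
    """

    well_id: str
    field_index: int
    dapi: np.ndarray
    actinin: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dapi = np.asarray(self.dapi, dtype=float)
        self.actinin = np.asarray(self.actinin, dtype=float)
        if self.dapi.ndim != 2 or self.actinin.ndim != 2:
            raise DimensionError("channel rasters must be 2-D")
        if self.dapi.shape != self.actinin.shape:
            raise DimensionError(
                f"channel shapes differ: dapi {self.dapi.shape} vs "
                f"actinin {self.actinin.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        for name, arr in (("dapi", self.dapi), ("actinin", self.actinin)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValidationError(f"{name} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape


@dataclass
class PlateLayout:
    """Well-to-treatment map for one plate."""

    table: pd.DataFrame

    REQUIRED = ("well_id", "treatment_label", "concentration_uM", "role")
    OPTIONAL = ("stimulant_label", "compound_label")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"layout missing columns: {missing}")
        for c in self.OPTIONAL:
            if c not in t.columns:
                t[c] = ""
        t["stimulant_label"] = t["stimulant_label"].fillna("")
        t["compound_label"] = t["compound_label"].fillna("")
        if t["well_id"].duplicated().any():
            dups = sorted(t.loc[t["well_id"].duplicated(), "well_id"].unique())
            raise ValidationError(f"duplicate well_id(s): {dups}")
        bad_roles = set(t["role"]) - set(VALID_ROLES)
        if bad_roles:
            raise ValidationError(f"unknown role(s): {sorted(bad_roles)}")
        if (t["concentration_uM"] < 0).any():
            raise ValidationError("concentrations must be >= 0")
        if not (t["role"] == "vehicle").any():
            raise ValidationError(
                "layout has no vehicle well; percent-of-control "
                "normalization would be undefined"
            )

    @property
    def wells(self) -> list[str]:
        return list(self.table["well_id"])

    @property
    def vehicle_wells(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "vehicle", "well_id"])

    def row(self, well_id: str) -> pd.Series:
        sel = self.table[self.table["well_id"] == well_id]
        if sel.empty:
            raise KeyError(f"well {well_id!r} not in layout")
        return sel.iloc[0]

    def wells_for(self, treatment_label: str) -> list[str]:
        t = self.table
        return list(t.loc[t["treatment_label"] == treatment_label, "well_id"])


@dataclass
class CompoundAnnotation:
    """Biochemical annotation for one compound.

    pIC50 values are -log10(molar IC50) against the named kinase;
    ``clogp`` is the calculated octanol-water partition coefficient.
    Missing values are represented as NaN.
    """

    compound_label: str
    pic50_grk5: float = float("nan")
    pic50_grk2: float = float("nan")
    pic50_grk6: float = float("nan")
    clogp: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("pic50_grk5", "pic50_grk2", "pic50_grk6"):
            v = getattr(self, name)
            if np.isfinite(v) and not (2.0 <= v <= 12.0):
                raise ValidationError(f"{name}={v} outside plausible [2, 12]")


def _normalize_raster(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Cast an integer/float raster to normalized floats; return bit depth."""
    if raw.dtype == np.uint8:
        depth = 8
    elif raw.dtype == np.uint16:
        depth = 16
    elif np.issubdtype(raw.dtype, np.floating):
        return np.asarray(raw, dtype=float), 0  # already-normalized float source
    else:
        raise ValidationError(f"unsupported TIFF dtype {raw.dtype}")
    return raw.astype(float) / float(2**depth - 1), depth


def read_field_image(
    dapi_path: str | Path,
    actinin_path: str | Path,
    well_id: str,
    field_index: int,
    pixel_size_um: float,
) -> FieldImage:
    """Read a DAPI/alpha-actinin TIFF pair into a :class:`FieldImage`."""
    rasters = []
    depths = []
    for p in (dapi_path, actinin_path):
        try:
            raw = tifffile.imread(str(p))
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read TIFF {p}: {exc}") from exc
        if raw.ndim != 2:
            raise DimensionError(f"{p} is not a single-channel 2-D image")
        arr, depth = _normalize_raster(raw)
        rasters.append(arr)
        depths.append(depth)
    return FieldImage(
        well_id=well_id,
        field_index=field_index,
        dapi=rasters[0],
        actinin=rasters[1],
        pixel_size_um=pixel_size_um,
        bit_depth=max(depths),
        provenance={
            "dapi_path": str(dapi_path),
            "actinin_path": str(actinin_path),
            "dapi_bit_depth": depths[0],
            "actinin_bit_depth": depths[1],
        },
    )


def write_field_image(image: FieldImage, dapi_path: str | Path, actinin_path: str | Path) -> None:
    """Write the two channels as 16-bit TIFFs (clipped to [0, 1])."""
    for arr, path in ((image.dapi, dapi_path), (image.actinin, actinin_path)):
        scaled = np.clip(arr, 0.0, 1.0) * 65535.0
        tifffile.imwrite(str(path), np.round(scaled).astype(np.uint16))


def field_paths(
    directory: str | Path, well_id: str, field_index: int
) -> tuple[Path, Path]:
    """Default filename convention ``<well>_f<field>_<channel>.tif``."""
    d = Path(directory)
    return (
        d / f"{well_id}_f{field_index}_dapi.tif",
        d / f"{well_id}_f{field_index}_actinin.tif",
    )


def _infer_role(row: pd.Series) -> str:
    def _text(v) -> str:
        return "" if pd.isna(v) else str(v)

    stim = _text(row.get("stimulant_label", ""))
    comp = _text(row.get("compound_label", ""))
    if not stim:
        return "vehicle"
    if comp:
        return "stimulated+compound"
    return "stimulated"


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Read and validate a plate-layout CSV.

    Required columns: well_id, treatment_label, concentration_uM.  The
    ``role`` column is inferred from stimulant/compound columns when absent.
    """
    t = pd.read_csv(path, dtype={"well_id": str, "treatment_label": str})
    if "concentration_uM" not in t.columns:
        t["concentration_uM"] = 0.0
    t["concentration_uM"] = pd.to_numeric(t["concentration_uM"]).fillna(0.0)
    if "role" not in t.columns:
        t["role"] = t.apply(_infer_role, axis=1)
    return PlateLayout(t)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.table.to_csv(path, index=False)


def read_compound_annotations(path: str | Path) -> list[CompoundAnnotation]:
    t = pd.read_csv(path)
    out = []
    for _, r in t.iterrows():
        out.append(
            CompoundAnnotation(
                compound_label=str(r["compound_label"]),
                pic50_grk5=float(r.get("pic50_grk5", np.nan)),
                pic50_grk2=float(r.get("pic50_grk2", np.nan)),
                pic50_grk6=float(r.get("pic50_grk6", np.nan)),
                clogp=float(r.get("clogp", np.nan)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Object tables and label maps
# ---------------------------------------------------------------------------

OBJECT_TABLE_KEY_COLUMNS = [
    "well_id",
    "field_index",
    "object_id",
    "object_class",
    "parent_cell_id",
]


def write_object_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an object table as CSV with stable column order.

    Key columns come first in documented order; remaining feature columns
    follow in sorted order.  Floats use repr precision, so a write/read
    round trip preserves every value bit-for-bit.
    """
    cols = [c for c in OBJECT_TABLE_KEY_COLUMNS if c in table.columns]
    cols += sorted(c for c in table.columns if c not in cols)
    table[cols].to_csv(path, index=False, float_format=None)


def read_object_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: the fast default can be 1 ulp off, breaking the
    # lossless write/read contract.
    return pd.read_csv(path, float_precision="round_trip")


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label map as 16-bit TIFF (lossless for <65536 ids)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 65535:
        raise ValidationError("label map exceeds 16-bit id range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def find_field_files(
    directory: str | Path, wells: Iterable[str], fields_per_well: int
) -> list[tuple[str, int, Path, Path]]:
    """Locate (well, field, dapi, actinin) TIFF tuples under *directory*."""
    out = []
    for well in wells:
        for f in range(fields_per_well):
            dapi, act = field_paths(directory, well, f)
            if dapi.exists() and act.exists():
                out.append((well, f, dapi, act))
    return out
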