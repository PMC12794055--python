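"""Synthetic two-channel cardiac-culture fields with exact ground truth.

The generator emulates the statistical structure of the mixed-culture
hypertrophy assay: a field contains cardiomyocytes (CMs) — large
alpha-actinin-positive bodies with sinusoidal striation texture, each
holding one or two DAPI nuclei — plus alpha-actinin-negative cells
represented only by their DAPI nuclei, in roughly 44/56 proportion.
Hypertrophy is applied as multiplicative effects on CM body area, CM
nuclear area and alpha-actinin amplitude.  A smooth multiplicative
illumination surface and Gaussian read noise plus scaled-Poisson shot
noise corrupt the rendered field; ground truth records the pre-noise,
pre-illumination values.

All per-cell properties are drawn *before* placement from a fixed-length
random stream, so two runs with the same seed and different effect
multipliers share identical base draws and differ exactly by the
multiplier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConfigError, SynthParams
from .io import FieldImage, PlateLayout, field_paths, write_field_image


class PackingError(RuntimeError):
    """Objects could not be placed without overlap after bounded retries."""


TRUTH_COLUMNS = [
    "well_id",
    "field_index",
    "cell_id",
    "is_cm",
    "nuclearity",
    "nucleus_ids",
    "true_cell_area_px",
    "cell_mask_px",
    "true_nuclear_areas_px",
    "true_mean_actinin_intensity",
    "centroid_row",
    "centroid_col",
]


@dataclass
class GroundTruth:
    """Exact per-cell truth plus the noiseless label rasters for one field.

    ``cells`` has one row per cell (see TRUTH_COLUMNS).  ``nucleus_labels``
    and ``cell_labels`` assign every pixel its true nucleus/cell id (0 =
    background); non-CM cells appear only in ``nucleus_labels``.
    """

    well_id: str
    field_index: int
    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray

    def background_mask(self) -> np.ndarray:
        """Pixels belonging to no object in either channel."""
        return (self.nucleus_labels == 0) & (self.cell_labels == 0)

    def nucleus_is_cm(self) -> dict[int, bool]:
        """Map nucleus id -> whether its parent is a cardiomyocyte."""
        out: dict[int, bool] = {}
        for _, row in self.cells.iterrows():
            for nid in _parse_ids(row["nucleus_ids"]):
                out[nid] = bool(row["is_cm"])
        return out

    @property
    def n_cm(self) -> int:
        return int(self.cells["is_cm"].sum())


def _parse_ids(s: str | float) -> list[int]:
    if isinstance(s, float) and np.isnan(s):
        return []
    s = str(s)
    return [int(x) for x in s.split(";") if x]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return float(max(mean, lo * 1.01))


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
) -> np.ndarray:
    """Boolean mask of an ellipse with semi-axes a (along theta) and b."""
    r0 = max(int(np.floor(center[0] - a - 2)), 0)
    r1 = min(int(np.ceil(center[0] + a + 2)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - a - 2)), 0)
    c1 = min(int(np.ceil(center[1] + a + 2)) + 1, shape[1])
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dr = rows - center[0]
    dc = cols - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def linear_gradient_surface(shape: tuple[int, int], total_gradient: float) -> np.ndarray:
    """Diagonal multiplicative surface rising from 1 to 1 + total_gradient.

    ``total_gradient=0.3`` gives a 30% corner-to-corner illumination bias.
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    t = (rows + cols) / float(shape[0] + shape[1] - 2)
    return 1.0 + total_gradient * t


def random_polynomial_surface(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth order-2 multiplicative surface with range ~[1-A, 1+A]."""
    if amplitude == 0:
        return np.ones(shape)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = 2.0 * cols / max(shape[1] - 1, 1) - 1.0
    y = 2.0 * rows / max(shape[0] - 1, 1) - 1.0
    coeffs = rng.normal(size=5)
    raw = coeffs[0] * x + coeffs[1] * y + coeffs[2] * x * y + coeffs[3] * x * x + coeffs[4] * y * y
    peak = np.abs(raw).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * raw / peak


@dataclass
class _CellSpec:
    is_cm: bool
    binucleated: bool
    cell_area: float  # analytic area, effect applied (CMs only)
    nuc_areas: list[float]
    amplitude: float  # actinin amplitude, effect applied
    dapi_amp: float
    aspect: float
    theta: float
    phase: float


def _draw_cell_specs(params: SynthParams, rng: np.random.Generator) -> list[_CellSpec]:
    specs = []
    for _ in range(params.cells_per_field):
        is_cm = bool(rng.random() < params.cm_fraction)
        binuc = bool(rng.random() < params.binucleated_cm_fraction)
        base_cell_area = _trunc_normal(
            rng, params.cm_area_px_mean, params.cm_area_px_sd, params.cm_area_px_mean / 3
        )
        base_cm_nuc = [
            _trunc_normal(
                rng,
                params.cm_nucleus_area_px_mean,
                params.cm_nucleus_area_px_sd,
                params.cm_nucleus_area_px_mean / 3,
            )
            for _ in range(2)
        ]
        noncm_nuc = _trunc_normal(
            rng,
            params.noncm_nucleus_area_px_mean,
            params.noncm_nucleus_area_px_sd,
            params.noncm_nucleus_area_px_mean / 3,
        )
        amp = _trunc_normal(
            rng, params.actinin_intensity_mean, params.actinin_intensity_sd, 0.05
        )
        dapi_amp = _trunc_normal(
            rng, params.dapi_intensity_mean, params.dapi_intensity_sd, 0.1
        )
        aspect = float(rng.uniform(1.0, params.cm_aspect_max))
        theta = float(rng.uniform(0.0, np.pi))
        phase = float(rng.uniform(0.0, 2 * np.pi))
        if is_cm:
            n_nuc = 2 if binuc else 1
            if binuc:
                # Binucleated CMs are larger and more elongated, which also
                # guarantees both nuclei fit inside the body.
                base_cell_area *= 1.35
                aspect = max(aspect, 1.3)
            specs.append(
                _CellSpec(
                    is_cm=True,
                    binucleated=binuc,
                    cell_area=base_cell_area * params.effect_area,
                    nuc_areas=[a * params.effect_nuc_area for a in base_cm_nuc[:n_nuc]],
                    amplitude=amp * params.effect_intensity,
                    dapi_amp=dapi_amp,
                    aspect=aspect,
                    theta=theta,
                    phase=phase,
                )
            )
        else:
            specs.append(
                _CellSpec(
                    is_cm=False,
                    binucleated=False,
                    cell_area=noncm_nuc,
                    nuc_areas=[noncm_nuc],
                    amplitude=0.0,
                    dapi_amp=dapi_amp,
                    aspect=min(aspect, 1.4),
                    theta=theta,
                    phase=phase,
                )
            )
    return specs


def generate_field(
    params: SynthParams,
    well_id: str,
    field_index: int,
    rng: np.random.Generator,
    illumination_surface: np.ndarray | None = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its exact ground truth.

    Placement uses rejection sampling on bounding circles so no two objects
    overlap; after 400 failed tries per object a :class:`PackingError` is
    raised.  If *illumination_surface* is given it overrides the random
    order-2 surface (pass ``np.ones(shape)`` for flat illumination).
    """
    params.validate()
    shape = tuple(params.field_shape)
    specs = _draw_cell_specs(params, rng)

    # Semi-axes of each object's outer ellipse (CM body, or the nucleus
    # itself for non-CMs).
    axes = []
    for s in specs:
        area = s.cell_area if s.is_cm else s.nuc_areas[0]
        a = float(np.sqrt(area * s.aspect / np.pi))
        b = float(np.sqrt(area / (np.pi * s.aspect)))
        axes.append((a, b))

    # Rejection-sampling placement on an occupancy raster with true ellipse
    # footprints (dilated by a 1.5 px margin so rendered objects never
    # touch).  Largest objects go first — sequential packing at the
    # coverage a stimulated field reaches fails in random order but
    # succeeds reliably size-sorted.  Properties were drawn before
    # placement, so ordering does not perturb the per-cell truth stream.
    order = sorted(range(len(specs)), key=lambda i: -axes[i][0])
    for a, _ in axes:
        if 2 * (a + 2.0) >= min(shape):
            raise PackingError(
                f"object with semi-axis {a:.1f}px cannot fit a "
                f"{shape[0]}x{shape[1]} field"
            )

    # A dense sequential packing occasionally jams; retry the whole
    # configuration with fresh positions before giving up.
    centers_by_index: dict[int, tuple[float, float]] = {}
    for attempt in range(6):
        centers_by_index.clear()
        occupancy = np.zeros(shape, dtype=bool)
        jammed = False
        for i in order:
            a, b = axes[i]
            margin = a + 2.0
            placed = False
            for _ in range(1000):
                cr = rng.uniform(margin, shape[0] - margin)
                cc = rng.uniform(margin, shape[1] - margin)
                foot = _ellipse_mask(shape, (cr, cc), a + 1.5, b + 1.5, specs[i].theta)
                if not (occupancy & foot).any():
                    occupancy |= foot
                    centers_by_index[i] = (cr, cc)
                    placed = True
                    break
            if not placed:
                jammed = True
                break
        if not jammed:
            break
    else:
        raise PackingError(
            f"could not place {len(specs)} objects in a "
            f"{shape[0]}x{shape[1]} field after 6 packing attempts; "
            "reduce cells_per_field or object sizes"
        )
    centers = [centers_by_index[i] for i in range(len(specs))]

    dapi = np.full(shape, params.dapi_background, dtype=float)
    actinin = np.full(shape, params.actinin_background, dtype=float)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)

    rows_g, cols_g = np.mgrid[0 : shape[0], 0 : shape[1]]
    records = []
    next_nucleus_id = 1
    for cell_id, (spec, center) in enumerate(zip(specs, centers), start=1):
        if spec.is_cm:
            a = np.sqrt(spec.cell_area * spec.aspect / np.pi)
            b = np.sqrt(spec.cell_area / (np.pi * spec.aspect))
            body = _ellipse_mask(shape, center, a, b, spec.theta)
            cell_labels[body] = cell_id
            # Striations run perpendicular to the long axis, as sarcomeres do.
            u = (rows_g - center[0]) * np.cos(spec.theta) + (cols_g - center[1]) * np.sin(
                spec.theta
            )
            stri = 1.0 + params.striation_depth * np.sin(
                2 * np.pi * u / params.striation_period_px + spec.phase
            )
            actinin[body] = params.actinin_background + spec.amplitude * stri[body]

            # Place nuclei on the major axis, fully inside the body.  For a
            # binucleated CM the two nuclei are rotated 90 deg to the cell
            # axis and separated by at least their own width plus a gap, so
            # their masks never touch; nuclei are shrunk (rarely) when the
            # drawn body is too small to hold them.
            n_nuc = len(spec.nuc_areas)
            nuc_ids, nuc_areas_px = [], []
            nuc_aspect = 1.2
            if n_nuc == 1:
                placements = [(0.0, spec.nuc_areas[0], spec.theta)]
            else:
                placements = []
                nb2 = max(
                    np.sqrt(A / (np.pi * nuc_aspect)) for A in spec.nuc_areas
                )  # semi-axis along the cell major axis (nucleus minor)
                sep = max(params.binucleate_min_sep_px, 2.0 * nb2 + 5.0)
                shrink = 1.0
                # Fit along the major axis and within the local half-width.
                if sep / 2.0 + nb2 > 0.92 * a:
                    shrink = max(0.5, ((0.92 * a - sep / 2.0) / nb2) if nb2 > 0 else 1.0)
                halfwidth = b * np.sqrt(max(1.0 - (sep / 2.0 / a) ** 2, 0.05))
                na_big = max(np.sqrt(A * nuc_aspect / np.pi) for A in spec.nuc_areas)
                if na_big > halfwidth - 1.0:
                    shrink = min(shrink, max(0.5, (halfwidth - 1.0) / na_big))
                for off, A in zip((-sep / 2.0, sep / 2.0), spec.nuc_areas):
                    placements.append((off, A * shrink**2, spec.theta + np.pi / 2.0))
            for off, nuc_area, nuc_theta in placements:
                nr = center[0] + off * np.cos(spec.theta)
                nc = center[1] + off * np.sin(spec.theta)
                na = np.sqrt(nuc_area * nuc_aspect / np.pi)
                nb = np.sqrt(nuc_area / (np.pi * nuc_aspect))
                nmask = _ellipse_mask(shape, (nr, nc), na, nb, nuc_theta) & body
                nucleus_labels[nmask] = next_nucleus_id
                dapi[nmask] = params.dapi_background + spec.dapi_amp
                nuc_ids.append(next_nucleus_id)
                nuc_areas_px.append(int(nmask.sum()))
                next_nucleus_id += 1
            records.append(
                {
                    "well_id": well_id,
                    "field_index": field_index,
                    "cell_id": cell_id,
                    "is_cm": True,
                    "nuclearity": n_nuc,
                    "nucleus_ids": ";".join(map(str, nuc_ids)),
                    "true_cell_area_px": spec.cell_area,
                    "cell_mask_px": int(body.sum()),
                    "true_nuclear_areas_px": ";".join(map(str, nuc_areas_px)),
                    "true_mean_actinin_intensity": spec.amplitude,
                    "centroid_row": center[0],
                    "centroid_col": center[1],
                }
            )
        else:
            nuc_area = spec.nuc_areas[0]
            na = np.sqrt(nuc_area * spec.aspect / np.pi)
            nb = np.sqrt(nuc_area / (np.pi * spec.aspect))
            nmask = _ellipse_mask(shape, center, na, nb, spec.theta)
            nucleus_labels[nmask] = next_nucleus_id
            dapi[nmask] = params.dapi_background + spec.dapi_amp
            records.append(
                {
                    "well_id": well_id,
                    "field_index": field_index,
                    "cell_id": cell_id,
                    "is_cm": False,
                    "nuclearity": 1,
                    "nucleus_ids": str(next_nucleus_id),
                    "true_cell_area_px": nuc_area,
                    "cell_mask_px": int(nmask.sum()),
                    "true_nuclear_areas_px": str(int(nmask.sum())),
                    "true_mean_actinin_intensity": 0.0,
                    "centroid_row": center[0],
                    "centroid_col": center[1],
                }
            )
            next_nucleus_id += 1

    truth = GroundTruth(
        well_id=well_id,
        field_index=field_index,
        cells=pd.DataFrame(records, columns=TRUTH_COLUMNS),
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
    )

    # Soften edges slightly so segmentation faces realistic boundaries.
    dapi = ndimage.gaussian_filter(dapi, 0.7)
    actinin = ndimage.gaussian_filter(actinin, 0.7)

    if illumination_surface is None:
        surface = random_polynomial_surface(
            shape, params.illumination_gradient_amplitude, rng
        )
    else:
        surface = np.asarray(illumination_surface, dtype=float)
        if surface.shape != shape:
            raise ConfigError("illumination surface shape mismatch")
    dapi = dapi * surface
    actinin = actinin * surface

    nm = params.noise_model
    for arr in (dapi, actinin):
        if nm.poisson_scaling > 0:
            arr[:] = rng.poisson(arr / nm.poisson_scaling) * nm.poisson_scaling
        if nm.gaussian_sd > 0:
            arr += rng.normal(0.0, nm.gaussian_sd, size=shape)
        np.clip(arr, 0.0, None, out=arr)

    image = FieldImage(
        well_id=well_id,
        field_index=field_index,
        dapi=dapi,
        actinin=actinin,
        pixel_size_um=0.65,
        provenance={"synthetic": True, "params": dataclasses.asdict(params)},
    )
    return image, truth


def field_rng(seed: int, well_index: int, field_index: int) -> np.random.Generator:
    """Deterministic per-field generator, independent of iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(well_index), int(field_index)])
    )


def generate_plate(
    layout: PlateLayout,
    condition_params: Mapping[str, SynthParams],
    base: SynthParams,
    out_dir: str | Path,
    seed: int,
    fields_per_well: int = 4,
) -> pd.DataFrame:
    """Render a whole plate to TIFF pairs plus one ground-truth CSV.

    Vehicle wells always use *base* (all effect multipliers forced to 1.0);
    other wells use ``condition_params[treatment_label]``.  Output is
    deterministic given (seed, layout): wells are processed in sorted
    well_id order with per-field seeds derived from (seed, well, field).

    Returns the manifest DataFrame (one row per written field) that is also
    saved as ``manifest.csv``; truth rows go to ``ground_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vehicle_params = base.with_effects(1.0, 1.0, 1.0)

    manifest_rows = []
    truth_frames = []
    wells = sorted(layout.wells)
    for wi, well in enumerate(wells):
        row = layout.row(well)
        if row["role"] == "vehicle":
            params = vehicle_params
        else:
            label = row["treatment_label"]
            if label not in condition_params:
                raise ConfigError(f"no SynthParams for treatment {label!r}")
            params = condition_params[label]
        for f in range(fields_per_well):
            rng = field_rng(seed, wi, f)
            image, truth = generate_field(params, well, f, rng)
            dapi_path, act_path = field_paths(out, well, f)
            write_field_image(image, dapi_path, act_path)
            truth_frames.append(truth.cells)
            manifest_rows.append(
                {
                    "well_id": well,
                    "field_index": f,
                    "treatment_label": row["treatment_label"],
                    "role": row["role"],
                    "concentration_uM": row["concentration_uM"],
                    "dapi_path": dapi_path.name,
                    "actinin_path": act_path.name,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "ground_truth.csv", index=False
    )
    return manifest


def dose_response_params(
    base_stimulated: SynthParams,
    i_max: float,
    ic50_uM: float,
    hill: float,
    dose_uM: float,
) -> SynthParams:
    """Interpolate effect multipliers along a logistic inhibition curve.

    The inhibited fraction is ``f = i_max / (1 + (ic50/dose)^hill)``
    (f = 0 at dose 0); each effect multiplier m becomes ``1 + (m-1)(1-f)``,
    so full inhibition (f = 1) restores vehicle conditions exactly.
    """
    if not (0.0 <= i_max <= 1.0):
        raise ConfigError("i_max must be in [0, 1]")
    if ic50_uM <= 0 or hill <= 0:
        raise ConfigError("ic50_uM and hill must be > 0")
    if dose_uM < 0:
        raise ConfigError("dose_uM must be >= 0")
    for name in ("effect_area", "effect_nuc_area", "effect_intensity"):
        if getattr(base_stimulated, name) < 1.0:
            raise ConfigError("base stimulated multipliers must be >= 1")
    f = 0.0 if dose_uM == 0 else i_max / (1.0 + (ic50_uM / dose_uM) ** hill)
    return base_stimulated.with_effects(
        1.0 + (base_stimulated.effect_area - 1.0) * (1.0 - f),
        1.0 + (base_stimulated.effect_nuc_area - 1.0) * (1.0 - f),
        1.0 + (base_stimulated.effect_intensity - 1.0) * (1.0 - f),
    )
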