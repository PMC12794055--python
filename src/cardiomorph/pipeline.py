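"""End-to-end orchestration: images -> object tables -> well scores.

Every run writes a manifest (config, seed, package versions, input
checksums) so results are reproducible from (seed, config) alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import AssayConfig, to_yaml
from .features import (
    assemble_object_table,
    measure_intensity,
    measure_morphology,
    measure_texture,
)
from .io import (
    FieldImage,
    PlateLayout,
    ValidationError,
    find_field_files,
    read_field_image,
    write_label_map,
    write_object_table,
)
from .scoring import (
    ScoreResult,
    WellSummary,
    aggregate_scores,
    aggregate_well,
    normalize_to_control,
    score_well,
    summaries_to_frame,
    toxicity_flag,
)
from .segment import segment_field


def analyze_field(image: FieldImage, config: AssayConfig) -> pd.DataFrame:
    """Segment one field and measure all per-object features."""
    seg = segment_field(image.dapi, image.actinin, config)
    nuc_morph = measure_morphology(seg.nuclei, image.pixel_size_um)
    nuc_inten = measure_intensity(seg.nuclei, seg.actinin_corrected)
    cell_morph = measure_morphology(seg.cells, image.pixel_size_um)
    cell_inten = measure_intensity(seg.cells, seg.actinin_corrected)
    cell_tex = measure_texture(
        seg.cells,
        seg.actinin_corrected,
        offsets_px=config.texture_offsets_px,
        gray_levels=config.texture_gray_levels,
        min_area_px=config.texture_min_area_px,
    )
    return assemble_object_table(
        seg.nucleus_records,
        seg.cell_records,
        [nuc_morph, nuc_inten],
        [cell_morph, cell_inten, cell_tex],
        well_id=image.well_id,
        field_index=image.field_index,
    )


def analyze_plate(
    images_dir: str | Path,
    layout: PlateLayout,
    config: AssayConfig,
    out_dir: str | Path | None = None,
    write_labels: bool = False,
) -> dict[str, list[pd.DataFrame]]:
    """Analyze all fields of all layout wells found under *images_dir*.

    Returns per-well lists of per-field object tables; optionally writes
    ``objects_<well>.csv`` (and label-map TIFFs) under *out_dir*.
    """
    files = find_field_files(images_dir, sorted(layout.wells), config.fields_per_well)
    if not files:
        raise ValidationError(f"no field images found under {images_dir}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, list[pd.DataFrame]] = {}
    for well, fidx, dapi_path, act_path in files:
        image = read_field_image(dapi_path, act_path, well, fidx, config.pixel_size_um)
        table = analyze_field(image, config)
        tables.setdefault(well, []).append(table)
        if out is not None and write_labels:
            seg = segment_field(image.dapi, image.actinin, config)
            write_label_map(seg.nuclei, out / f"{well}_f{fidx}_nuclei_labels.tif")
            write_label_map(seg.cells, out / f"{well}_f{fidx}_cell_labels.tif")
    if out is not None:
        for well in sorted(tables):
            write_object_table(
                pd.concat(tables[well], ignore_index=True), out / f"objects_{well}.csv"
            )
    return tables


def score_plate(
    tables: Mapping[str, Sequence[pd.DataFrame]],
    layout: PlateLayout,
    config: AssayConfig,
) -> tuple[list[WellSummary], list[ScoreResult], pd.DataFrame]:
    """Aggregate object tables to wells, normalize to vehicle and score.

    Returns (summaries, per-well score results, scores DataFrame).  Wells
    are toxicity-flagged against the vehicle-control mean counts.
    """
    summaries = []
    for well in sorted(tables):
        row = layout.row(well)
        summaries.append(aggregate_well(list(tables[well]), row, zero_cm_warning=True))
    summaries = normalize_to_control(summaries, layout)

    vehicle_ids = set(layout.vehicle_wells)
    veh = [s for s in summaries if s.well_id in vehicle_ids]
    ctrl_cm = float(np.mean([s.cm_count for s in veh]))
    ctrl_noncm = float(np.mean([s.noncm_nucleus_count for s in veh]))

    results = []
    for s in summaries:
        r = score_well(s)
        r.toxicity_flag = toxicity_flag(
            s, ctrl_cm, ctrl_noncm, config.toxicity_threshold_fraction
        )
        results.append(r)

    frame = pd.DataFrame(
        [
            {
                "well_id": r.label,
                "treatment_label": s.treatment_label,
                "role": s.role,
                "concentration_uM": s.concentration_uM,
                "hypertrophy_score": r.hypertrophy_score,
                "cm_area_pct": r.cm_area_pct,
                "nuc_area_pct": r.nuc_area_pct,
                "intensity_pct": r.intensity_pct,
                "toxicity_flag": r.toxicity_flag,
            }
            for s, r in zip(summaries, results)
        ]
    )
    return summaries, results, frame


def condition_scores(
    results: Sequence[ScoreResult],
    summaries: Sequence[WellSummary],
) -> dict[str, ScoreResult]:
    """Aggregate per-well scores into per-condition mean +/- SEM."""
    by_label: dict[str, list[ScoreResult]] = {}
    for s, r in zip(summaries, results):
        key = s.treatment_label or s.role
        by_label.setdefault(key, []).append(r)
    return {k: aggregate_scores(v, k) for k, v in by_label.items()}


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_run_manifest(
    out_dir: str | Path,
    config: AssayConfig,
    seed: int,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write the reproducibility manifest for a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = to_yaml(config)
    manifest = {
        "package": "cardiomorph",
        "version": __version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16],
        "config": cfg_yaml,
        "numpy": np.__version__,
        "inputs": {
            str(p): _checksum(Path(p)) for p in inputs if Path(p).is_file()
        },
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
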