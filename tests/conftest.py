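"""Shared fixtures: synthetic fields, segmented field batches, mini plates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cardiomorph.config import AssayConfig, SynthParams
from cardiomorph.io import PlateLayout
from cardiomorph.pipeline import analyze_plate, score_plate
from cardiomorph.segment import segment_field
from cardiomorph.synth import field_rng, generate_field, generate_plate


@pytest.fixture
def assay_config() -> AssayConfig:
    return AssayConfig()


@pytest.fixture
def synth_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def synthetic_field():
    """One default-condition field with its ground truth (fixed seed)."""
    img, truth = generate_field(SynthParams(), "A01", 0, field_rng(11, 0, 0))
    return img, truth


@pytest.fixture(scope="session")
def segmented_fields20():
    """20 default-SNR fields with ground truth and segmentation products.

    Shared by the classification-accuracy, CM-count-recovery and
    binucleation-recovery checks so the fields are rendered once.
    """
    cfg = AssayConfig()
    out = []
    for s in range(20):
        img, truth = generate_field(SynthParams(), "A01", s, field_rng(23, 0, s))
        seg = segment_field(img.dapi, img.actinin, cfg)
        out.append((img, truth, seg))
    return out


def make_layout(n_vehicle: int, conditions: dict[str, int]) -> PlateLayout:
    """Layout helper: n_vehicle DMSO wells plus replicate wells per label."""
    rows = []
    widx = 1
    for _ in range(n_vehicle):
        rows.append(
            {
                "well_id": f"A{widx:02d}",
                "treatment_label": "DMSO",
                "stimulant_label": "",
                "compound_label": "",
                "concentration_uM": 0.0,
                "role": "vehicle",
            }
        )
        widx += 1
    for label, n in conditions.items():
        for _ in range(n):
            rows.append(
                {
                    "well_id": f"B{widx:02d}",
                    "treatment_label": label,
                    "stimulant_label": label,
                    "compound_label": "",
                    "concentration_uM": 0.0,
                    "role": "stimulated",
                }
            )
            widx += 1
    return PlateLayout(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def mini_plate_scores(tmp_path_factory):
    """Small end-to-end plate (4 vehicle + 4 stimulated wells, 2 fields):
    generated, analyzed and scored once for the scoring-level tests."""
    d = tmp_path_factory.mktemp("mini_plate")
    layout = make_layout(4, {"PE-LIF": 4})
    base = SynthParams()
    stim = base.with_effects(1.5, 1.2, 1.3)
    generate_plate(layout, {"DMSO": base, "PE-LIF": stim}, base, d, seed=7, fields_per_well=2)
    cfg = AssayConfig(fields_per_well=2)
    tables = analyze_plate(d, layout, cfg)
    summaries, results, frame = score_plate(tables, layout, cfg)
    return {
        "layout": layout,
        "config": cfg,
        "tables": tables,
        "summaries": summaries,
        "results": results,
        "frame": frame,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
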