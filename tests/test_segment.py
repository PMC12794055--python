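"""Segmentation core: illumination, nuclei, CM watershed, relation."""

import numpy as np
import pytest
from scipy import ndimage

from cardiomorph.config import AssayConfig, SynthParams
from cardiomorph.segment import (
    CellRecord,
    DegenerateInputError,
    actinin_foreground,
    classify_nuclei,
    correct_illumination,
    filter_border_objects,
    relate_nuclei_to_cells,
    segment_cardiomyocytes,
    segment_field,
    segment_nuclei,
)
from cardiomorph.synth import field_rng, generate_field, linear_gradient_surface


# ---------------------------------------------------------------------------
# Illumination correction
# ---------------------------------------------------------------------------

def _noise_free_params(**kwargs):
    from cardiomorph.config import NoiseModel

    return SynthParams(
        illumination_gradient_amplitude=0.0,
        noise_model=NoiseModel(gaussian_sd=0.0, poisson_scaling=0.0),
        **kwargs,
    )


class TestIlluminationCorrection:
    def test_flat_field_is_near_identity(self):
        params = _noise_free_params()
        img, _ = generate_field(
            params, "A01", 0, field_rng(1, 0, 0),
            illumination_surface=np.ones(params.field_shape),
        )
        corrected, surface = correct_illumination(img.actinin)
        assert np.ptp(surface) / surface.mean() < 0.01
        rel = np.abs(corrected - img.actinin) / img.actinin.max()
        assert rel.max() < 0.01

    def test_gradient_background_cv_reduced_5x(self):
        """A 30% corner-to-corner multiplicative gradient must be flattened:
        background CV (via ground-truth masks) drops at least five-fold."""
        params = _noise_free_params()
        surface = linear_gradient_surface(params.field_shape, 0.30)
        img, truth = generate_field(
            params, "A01", 0, field_rng(1, 0, 0), illumination_surface=surface
        )
        corrected, _ = correct_illumination(img.actinin)
        bg = truth.background_mask()
        # stay away from blurred object rims
        bg = ndimage.binary_erosion(bg, iterations=3)
        cv_before = img.actinin[bg].std() / img.actinin[bg].mean()
        cv_after = corrected[bg].std() / corrected[bg].mean()
        assert cv_before / cv_after >= 5.0

    def test_idempotence_within_1pct(self):
        params = _noise_free_params()
        surface = linear_gradient_surface(params.field_shape, 0.30)
        img, _ = generate_field(
            params, "A01", 0, field_rng(1, 0, 0), illumination_surface=surface
        )
        once, _ = correct_illumination(img.actinin)
        twice, _ = correct_illumination(once)
        assert (np.abs(twice - once) / once.max()).max() < 0.01

    def test_constant_raster_rejected(self):
        with pytest.raises(DegenerateInputError):
            correct_illumination(np.full((64, 64), 3.0))

    def test_surface_strictly_positive(self):
        img, _ = generate_field(SynthParams(), "A01", 0, field_rng(2, 0, 0))
        _, surface = correct_illumination(img.actinin)
        assert (surface > 0).all()


# ---------------------------------------------------------------------------
# Nucleus segmentation
# ---------------------------------------------------------------------------

class TestSegmentNuclei:
    def test_blank_raster_empty_map(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_nuclei_recovered_with_iou(self):
        """50 DAPI-only nuclei at default SNR: one label each, IoU >= 0.7."""
        params = SynthParams(cm_fraction=0.0, cells_per_field=50)
        img, truth = generate_field(params, "A01", 0, field_rng(6, 0, 0))
        labels = segment_nuclei(img.dapi)
        n_true = int(truth.nucleus_labels.max())
        assert labels.max() == n_true
        matched = 0
        for nid in range(1, n_true + 1):
            tmask = truth.nucleus_labels == nid
            cand = np.bincount(labels[tmask].ravel()).argmax()
            if cand == 0:
                continue
            smask = labels == cand
            iou = (tmask & smask).sum() / (tmask | smask).sum()
            if iou >= 0.7:
                matched += 1
        assert matched == n_true

    def test_binucleate_pair_split_into_two_labels(self):
        """Two nuclei of a binucleated CM give two labels, not one."""
        params = SynthParams(cm_fraction=1.0, binucleated_cm_fraction=1.0,
                             cells_per_field=6)
        img, truth = generate_field(params, "A01", 0, field_rng(8, 0, 0))
        labels = segment_nuclei(img.dapi)
        for _, row in truth.cells.iterrows():
            nids = [int(x) for x in str(row.nucleus_ids).split(";")]
            assert len(nids) == 2
            seg_ids = set()
            for nid in nids:
                tmask = truth.nucleus_labels == nid
                lab = np.bincount(labels[tmask].ravel()).argmax()
                assert lab > 0
                seg_ids.add(int(lab))
            assert len(seg_ids) == 2


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class TestClassifyNuclei:
    def test_inside_and_outside(self):
        nuclei = np.zeros((20, 20), np.int32)
        nuclei[2:6, 2:6] = 1   # fully inside actinin body
        nuclei[12:16, 12:16] = 2  # zero overlap
        mask = np.zeros((20, 20), bool)
        mask[0:10, 0:10] = True
        flags = classify_nuclei(nuclei, mask, overlap_fraction=0.5)
        assert flags == {1: True, 2: False}

    def test_overlap_fraction_boundary(self):
        nuclei = np.zeros((10, 10), np.int32)
        nuclei[0:4, 0:4] = 1  # 16 px, 8 inside mask
        mask = np.zeros((10, 10), bool)
        mask[0:2, 0:4] = True
        assert classify_nuclei(nuclei, mask, 0.5) == {1: True}
        assert classify_nuclei(nuclei, mask, 0.51) == {1: False}


# ---------------------------------------------------------------------------
# Cardiomyocyte segmentation
# ---------------------------------------------------------------------------

def _binucleated_fixture():
    """One continuous bright body holding two nuclei (no interior valley)."""
    act = np.full((64, 64), 0.04)
    rr, cc = np.mgrid[0:64, 0:64]
    body = ((rr - 32) / 14.0) ** 2 + ((cc - 32) / 26.0) ** 2 <= 1
    act[body] = 0.4
    nuclei = np.zeros((64, 64), np.int32)
    nuclei[((rr - 32) / 5.0) ** 2 + ((cc - 20) / 5.0) ** 2 <= 1] = 1
    nuclei[((rr - 32) / 5.0) ** 2 + ((cc - 44) / 5.0) ** 2 <= 1] = 2
    return act, nuclei


class TestSegmentCardiomyocytes:
    def test_single_mononucleated_cell(self):
        act = np.full((40, 40), 0.04)
        rr, cc = np.mgrid[0:40, 0:40]
        body = (rr - 20) ** 2 + (cc - 20) ** 2 <= 14**2
        act[body] = 0.4
        nuclei = np.zeros((40, 40), np.int32)
        nuclei[(rr - 20) ** 2 + (cc - 20) ** 2 <= 5**2] = 1
        cells = segment_cardiomyocytes(act, nuclei, [1])
        assert cells.max() == 1
        assert (cells[nuclei == 1] == 1).all()

    def test_binucleated_body_stays_one_cell(self):
        """The failure mode of propagation methods: a binucleated CM must
        NOT be split into two cells."""
        act, nuclei = _binucleated_fixture()
        cells = segment_cardiomyocytes(act, nuclei, [1, 2])
        assert cells.max() == 1
        assert (cells[nuclei > 0] == 1).all()

    def test_adjacent_cells_with_dim_seam_split(self):
        """Two touching mononucleated CMs separated by a 2-px dim seam
        yield two cells."""
        act = np.full((64, 64), 0.04)
        rr, cc = np.mgrid[0:64, 0:64]
        left = ((rr - 32) / 14.0) ** 2 + ((cc - 19) / 12.0) ** 2 <= 1
        right = ((rr - 32) / 14.0) ** 2 + ((cc - 45) / 12.0) ** 2 <= 1
        act[left | right] = 0.4
        act[:, 31:33][(left | right)[:, 31:33]] = 0.06  # dim seam
        nuclei = np.zeros((64, 64), np.int32)
        nuclei[((rr - 32) / 5.0) ** 2 + ((cc - 19) / 5.0) ** 2 <= 1] = 1
        nuclei[((rr - 32) / 5.0) ** 2 + ((cc - 45) / 5.0) ** 2 <= 1] = 2
        cells = segment_cardiomyocytes(act, nuclei, [1, 2])
        assert cells.max() == 2
        lab1 = cells[nuclei == 1]
        lab2 = cells[nuclei == 2]
        assert set(lab1[lab1 > 0]) != set(lab2[lab2 > 0])

    def test_empty_seed_list_valid(self):
        act, nuclei = _binucleated_fixture()
        assert segment_cardiomyocytes(act, nuclei, []).max() == 0


# ---------------------------------------------------------------------------
# Relation and border filtering
# ---------------------------------------------------------------------------

class TestRelateNucleiToCells:
    def test_one_cell_one_nucleus(self):
        cells = np.zeros((16, 16), np.int32)
        cells[4:12, 4:12] = 1
        nuclei = np.zeros((16, 16), np.int32)
        nuclei[6:10, 6:10] = 1
        nrecs, crecs = relate_nuclei_to_cells(nuclei, cells, {1: True})
        assert crecs[0].nuclearity == 1
        assert nrecs[0].parent_cell_id == 1
        # oracle: areas and centroid by direct pixel counting
        assert nrecs[0].area_px == 16
        assert crecs[0].area_px == 64
        assert nrecs[0].centroid == (7.5, 7.5)

    def test_binucleated_cell_mononucleated_subpopulation_empty(self):
        cells = np.zeros((16, 16), np.int32)
        cells[2:14, 2:14] = 1
        nuclei = np.zeros((16, 16), np.int32)
        nuclei[4:7, 4:7] = 1
        nuclei[9:12, 9:12] = 2
        nrecs, crecs = relate_nuclei_to_cells(nuclei, cells, {1: True, 2: True})
        assert crecs[0].nuclearity == 2
        assert [c for c in crecs if c.nuclearity == 1] == []

    def test_cell_without_nucleus_dropped_and_flag_reset(self):
        cells = np.zeros((16, 16), np.int32)
        cells[1:5, 1:5] = 1  # no nucleus inside
        nuclei = np.zeros((16, 16), np.int32)
        nuclei[9:12, 9:12] = 1  # CM-flagged but overlaps no cell
        nrecs, crecs = relate_nuclei_to_cells(nuclei, cells, {1: True})
        assert crecs == []
        assert nrecs[0].is_cm_nucleus is False
        assert nrecs[0].parent_cell_id is None

    def test_majority_tie_broken_by_lower_cell_id(self):
        cells = np.zeros((8, 8), np.int32)
        cells[:, :4] = 2
        cells[:, 4:] = 1
        nuclei = np.zeros((8, 8), np.int32)
        nuclei[3:5, 3:5] = 1  # 2 px in each cell
        _, crecs = relate_nuclei_to_cells(nuclei, cells, {1: True})
        assert [c.cell_id for c in crecs] == [1]


def test_filter_border_objects_partition():
    recs = [
        CellRecord(1, 1, [1], 50, touches_border=False),
        CellRecord(2, 1, [2], 60, touches_border=True),
        CellRecord(3, 2, [3, 4], 80, touches_border=False),
    ]
    interior, border = filter_border_objects(recs)
    assert [c.cell_id for c in interior] == [1, 3]
    assert [c.cell_id for c in border] == [2]
    assert len(interior) + len(border) == len(recs)


# ---------------------------------------------------------------------------
# Field-level recovery against ground truth
# ---------------------------------------------------------------------------

class TestFieldRecovery:
    def test_partition_invariant_every_field(self, segmented_fields20):
        for _, _, seg in segmented_fields20:
            n_cm = sum(1 for n in seg.nucleus_records if n.is_cm_nucleus)
            n_non = sum(1 for n in seg.nucleus_records if not n.is_cm_nucleus)
            assert n_cm + n_non == len(seg.nucleus_records)
            assert sum(c.nuclearity for c in seg.cell_records) == n_cm

    def test_classification_accuracy(self, segmented_fields20):
        """CM/non-CM nucleus classification >= 95% against ground truth."""
        correct = total = 0
        for _, truth, seg in segmented_fields20:
            true_flag = truth.nucleus_is_cm()
            for n in seg.nucleus_records:
                r, c = (int(round(x)) for x in n.centroid)
                tid = int(truth.nucleus_labels[r, c])
                if tid > 0:
                    total += 1
                    correct += true_flag[tid] == n.is_cm_nucleus
            assert total > 0
        assert correct / total >= 0.95

    def test_cm_count_within_10pct(self, segmented_fields20):
        det = sum(len(seg.cell_records) for _, _, seg in segmented_fields20)
        true = sum(truth.n_cm for _, truth, _ in segmented_fields20)
        assert abs(det - true) / true <= 0.10

    def test_binucleated_fraction_recovered(self, segmented_fields20):
        binuc = sum(
            sum(1 for c in seg.cell_records if c.nuclearity == 2)
            for _, _, seg in segmented_fields20
        )
        total = sum(len(seg.cell_records) for _, _, seg in segmented_fields20)
        assert abs(binuc / total - 0.30) <= 0.05

    def test_segmentation_deterministic(self, synthetic_field):
        img, _ = synthetic_field
        cfg = AssayConfig()
        s1 = segment_field(img.dapi, img.actinin, cfg)
        s2 = segment_field(img.dapi, img.actinin, cfg)
        np.testing.assert_array_equal(s1.nuclei, s2.nuclei)
        np.testing.assert_array_equal(s1.cells, s2.cells)


def test_actinin_foreground_covers_cm_bodies(synthetic_field):
    img, truth = synthetic_field
    corrected, _ = correct_illumination(img.actinin)
    mask = actinin_foreground(corrected)
    body = truth.cell_labels > 0
    core = ndimage.binary_erosion(body, iterations=2)
    assert mask[core].mean() > 0.95
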