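# Data dictionary

## Object table (`objects_<well>.csv`)

One row per segmented object (cells first, then nuclei).

| column | type | meaning |
|---|---|---|
| `well_id` | text | plate well |
| `field_index` | int | 0-based field within the well |
| `object_id` | int | label id, unique within (field, object kind) |
| `object_class` | text | `cm_cell`, `cm_nucleus` or `noncm_nucleus` |
| `parent_cell_id` | int | owning cell id for CM nuclei; −1 otherwise |
| `touches_border` | bool | object touches a field edge (excluded from morphometrics, kept in counts) |
| `nuclearity` | int | nuclei per cell (cells only; NaN for nuclei) |
| `area_px` | int | exact pixel count |
| `area_um2` | float | `area_px × pixel_size_um²` |
| `centroid_row`, `centroid_col` | float | 0-based (row, col) centroid |
| `perimeter_px` | float | contour perimeter |
| `eccentricity` | float | 0 (circle) … 1 (line) |
| `mean_intensity` | float | mean corrected α-actinin intensity over the object |
| `integrated_intensity` | float | `mean_intensity × area_px` |
| `intensity_sd` | float | within-object SD |
| `upper_decile_mean_intensity` | float | mean of the brightest 10% of pixels |
| `asm_o<k>` | float | GLCM angular second moment at offset k px, ∈ (0, 1] |
| `contrast_o<k>` | float | GLCM contrast at offset k px, ≥ 0 |
| `correlation_o<k>` | float | GLCM correlation at offset k px, ∈ [−1, 1] |
| `entropy_o<k>` | float | GLCM entropy (bits) at offset k px |

Texture columns are NaN for objects below the minimum texture area.

## Well summary (`well_summary.csv`)

| column | meaning |
|---|---|
| `well_id`, `treatment_label`, `role`, `concentration_uM`, `n_fields` | layout metadata |
| `cm_count` | CM cells, all fields, border-inclusive |
| `cm_nucleus_count`, `noncm_nucleus_count`, `total_nucleus_count` | nucleus counts; total = CM + non-CM exactly |
| `mean_cm_area_um2` | mean CM cell area over interior cells |
| `mean_cm_nuclear_area_um2` | mean CM nuclear area over interior CM nuclei |
| `mean_cm_actinin_intensity` | mean corrected α-actinin intensity of interior CM cells |
| `mean_nuclearity` | mean nuclei per interior CM |
| `<parameter>_pct` | the above, as percent of the plate's vehicle-well mean |

## Scores (`scores.csv`)

| column | meaning |
|---|---|
| `hypertrophy_score` | (cm_area_pct + nuc_area_pct + intensity_pct) / 3 |
| `cm_area_pct`, `nuc_area_pct`, `intensity_pct` | the three components |
| `toxicity_flag` | `none`, `noncm_loss` or `cm_loss` (counts < 0.7 × control) |

## Efficacy (`efficacy.csv`)

| column | meaning |
|---|---|
| `i_8uM` | window-normalized inhibition at 8 μM (%) |
| `cellular_ic50_uM` | 4PL IC50; empty when the fit did not converge in range |
| `hill` | Hill slope of the fit |
| `converged` | fit accepted (IC50 inside [min dose/10, max dose×10]) |

## Ground truth (`ground_truth.csv`, synthetic plates)

| column | meaning |
|---|---|
| `cell_id`, `is_cm`, `nuclearity`, `nucleus_ids` | per-cell identity; nucleus ids are `;`-joined |
| `true_cell_area_px` | analytic ellipse area (effect multipliers apply exactly) |
| `cell_mask_px` | rendered pixel count of the body (nucleus for non-CMs) |
| `true_nuclear_areas_px` | exact rendered pixel counts, `;`-joined |
| `true_mean_actinin_intensity` | pre-noise α-actinin amplitude (0 for non-CMs) |
| `centroid_row`, `centroid_col` | placed center |
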