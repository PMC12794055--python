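# Methods

## Analysis pipeline

### Illumination correction

Fluorescence fields carry a smooth multiplicative shading surface
(vignetting, uneven excitation). `correct_illumination` estimates the
background on a grid of blocks (default 8×8) as the `robust_fraction`
(default 0.1) quantile of each block, fits a 2-D polynomial of order
`surface_order` (default 2) to these samples by least squares with one
MAD-based outlier-rejection pass (blocks dominated by bright cells are
discarded by their residual), divides the raster by the surface
(normalized to mean 1, floored strictly positive) and rescales so the
median background level is unchanged. The low quantile makes the
estimate robust to objects covering part of a block; the order-2 surface
matches the smooth, low-frequency character of real shading. Correction
is close to idempotent: once the background is flat, the refitted surface
is constant to within the fit noise.

Assumption: the bias is multiplicative and smooth at the block scale.
High-frequency shading or additive stray light is not modeled.

### Nucleus segmentation (DAPI)

Gaussian smoothing (σ = 1 px) → Otsu threshold (per field; percentile or
fixed thresholds available) → hole filling → removal of objects
< 30 px² → optional declumping by watershed on the Euclidean distance
transform seeded at distance peaks (minimum peak separation 5 px).
Declumping is what keeps the two nuclei of a binucleated CM as two
objects when blur bridges them.

### Nucleus classification

A nucleus is a CM nucleus iff ≥ `overlap_fraction` (default 0.5) of its
pixels lie inside the α-actinin foreground mask (Otsu on the corrected
channel). Every nucleus receives exactly one flag, so CM + non-CM counts
partition the total exactly — the invariant the toxicity readout relies
on.

### Cardiomyocyte segmentation and the merged-basin rule

The α-actinin foreground is partitioned by a watershed on the inverted
corrected intensity, seeded from the CM nuclei. Plain seeded watershed
would split a binucleated CM into two cells — the classic propagation
failure. We therefore merge two adjacent basins when there is **no
intensity valley** between them: the minimum corrected intensity along
their shared ridge (evaluated ≥ 2 px inside the foreground, so the
normal intensity falloff at the cell edge does not masquerade as a
valley) must reach `ridge_fraction` (default 0.6) of the mean intensity
of the two basins. Inside one continuous bright body the ridge stays
near the striation trough, ≈ (1 − striation depth) ≈ 0.8 of the body
mean, well above 0.6, so the basins merge; between two abutting cells a
dim seam drops the ridge minimum far below the criterion and the cells
stay separate. Merging uses a union–find with the smallest label as the
deterministic representative; cells < 200 px² are removed.

### Nucleus–cell relation

Each CM-flagged nucleus becomes a child of the cell covering the
majority of its pixels (ties to the lower cell id). Cells left without a
nucleus are dropped as artifacts; CM nuclei whose parent vanished are
reclassified non-CM so the partition invariant survives. A cell's
nuclearity is its child count; the mononucleated subpopulation is
`nuclearity == 1`. Objects touching the field border are excluded from
morphometric statistics but kept in raw counts with a flag.

### Features

* Morphology: exact pixel-count area (also in μm² via `pixel_size_um²`,
  default 0.65 μm/px), centroid, perimeter, eccentricity (scikit-image
  regionprops).
* Intensity (on the corrected α-actinin raster, for nuclei and cells):
  mean, integrated (= mean × area to machine precision), SD,
  upper-decile mean.
* Texture: per-object gray-level co-occurrence features (angular second
  moment, contrast, correlation, entropy). Intensities are min–max
  scaled to 8 gray levels within the object; pairs are counted only when
  both pixels are inside the object mask; the matrix is symmetrized and
  normalized and features are averaged over the four principal
  directions at offsets {1, 4} px. Objects below 25 px² get explicit
  missing markers. A constant object has ASM 1, contrast 0, entropy 0;
  its correlation is defined as 1 (degenerate single-level limit).

### Wells, normalization, score

Counts are summed over a well's fields (border-inclusive); phenotype
parameters are means over interior objects pooled across fields (not
means of field means — with four fields per well and varying cell counts
the pooled estimator weights every cell equally). Each parameter is then
divided by its mean over the plate's vehicle wells × 100, so vehicle
wells self-normalize to exactly 100 on average. The Hypertrophy Score is
the unweighted mean of CM-area %, CM-nuclear-area % and
α-actinin-intensity %; a missing component yields a missing score with a
warning, never a silent reweighting. Replicate wells aggregate to
mean ± SEM.

Mean (not integrated) α-actinin intensity enters the score: integrated
intensity is ∝ area × mean and would double-count the area component.

### Toxicity and efficacy

A well is flagged `cm_loss` / `noncm_loss` when its CM count / non-CM
nucleus count falls below `toxicity_threshold_fraction` (default 0.7) of
the vehicle mean; `cm_loss` dominates and such wells are excluded from
efficacy ranking (scores remain reported, marked). The inhibition
I(d) = 100·(S_stim − S_d)/(S_stim − S_vehicle) is undefined without a
positive hypertrophic window and errors in that case. **The I_8μM
definition is this package's own window-normalized formula** — the
metric's name fixes the dose, not the formula, and raw-score
alternatives exist; this choice makes 0 and 100 interpretable as
"no effect" and "full rescue".

Dose–response fitting uses a 4-parameter logistic on log10-dose with the
bottom fixed at 0 (untreated stimulated wells define zero inhibition by
construction) and top free up to 100, via least squares
(`scipy.optimize.curve_fit`, bounds: top ∈ (0, 100],
log-IC50 ∈ data range ± 2 decades, Hill ∈ [0.1, 10]). The IC50 is
reported only when the fit converges inside [min dose/10, max dose·10];
flat or non-converged series report no IC50. When the top tested dose is
below ~2× the IC50 the free top and the IC50 trade off; replicate
averaging (the assay's n = 3 wells/dose) keeps recovery within ±30%.

### Statistics

Conditions are compared to control by one-way-ANOVA-style many-to-one
Dunnett comparisons (`scipy.stats.dunnett`); exactly two groups fall
back to an unpaired t-test; unadjusted and Bonferroni variants are
config options. Stars follow * p ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001,
**** ≤ 0.0001. Potency–efficacy (pIC50 vs I_8μM) and
lipophilicity–efficacy (cLogP vs I_8μM) reports carry both Pearson and
Spearman coefficients; exclusion of toxic compounds is explicit,
reason-carrying configuration, never automatic.

## Synthetic-field generator

The generator emulates the statistical structure the analysis assumes,
with exact ground truth:

* **Composition**: each of `cells_per_field` (default 50, field
  256×256 px) cells is a CM with probability `cm_fraction`
  (default 0.44, the mixed-culture CM ratio); CMs are binucleated with
  probability `binucleated_cm_fraction` (default 0.30).
* **Geometry**: CM bodies are random ellipses (area ~ N(450, 90²) px²
  truncated, aspect U(1, 2)); binucleated bodies are 1.35× larger and at
  least 1.3:1 elongated (binucleated CMs are larger cells, and this
  guarantees both nuclei fit). Nuclei are ellipses (CM nuclei
  N(110, 22²) px², non-CM N(80, 16²) px²) placed fully inside the body;
  the two nuclei of a binucleated CM sit on the major axis, rotated 90°,
  separated by at least their own width + 5 px so naive
  one-nucleus-per-cell logic demonstrably fails while declumping can
  still separate them. Non-CMs are DAPI-only nuclei — fibroblast
  cytoplasm is invisible in both assay channels, matching a readout that
  counts non-CMs via nuclei alone.
* **Placement**: rejection sampling on an occupancy raster with true
  ellipse footprints dilated by 1.5 px (no overlaps, unambiguous truth),
  largest objects first; a `PackingError` is raised after bounded
  retries.
* **Intensities** (normalized [0, 1] scale): α-actinin body amplitude
  ~ N(0.35, 0.05²) modulated by a sinusoidal striation of period 6 px
  and depth 0.2 oriented along the sarcomere direction; DAPI amplitude
  ~ N(0.55, 0.08²); backgrounds 0.04/0.03. Hypertrophy multiplies CM
  body area (`effect_area`), CM nuclear area (`effect_nuc_area`) and
  α-actinin amplitude (`effect_intensity`) before rendering.
* **Corruption**: light Gaussian edge blur (σ 0.7), a multiplicative
  order-2 illumination surface of amplitude 0.15 (or any caller-supplied
  surface), scaled-Poisson shot noise (gain 0.002) plus Gaussian read
  noise (σ 0.01).
* **Truth**: recorded pre-noise/pre-illumination. Cell areas are stored
  as the analytic ellipse area (so effect multipliers scale truth
  exactly) alongside the rendered mask pixel count; nuclear areas are
  exact pixel counts. Per-cell properties are drawn from a fixed-length
  random stream *before* placement, so two runs differing only in effect
  multipliers share identical base draws.
* **Dose–response**: `dose_response_params` interpolates the effect
  multipliers toward vehicle with the logistic inhibited fraction
  f = i_max/(1 + (IC50/d)^h) (f = 0 at d = 0), giving plates a known
  cellular IC50 by construction.

Determinism: each (well, field) gets a `SeedSequence([seed, well_index,
field_index])` generator, so plates are byte-reproducible from the seed
and independent of iteration order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: irregular/concave CM shapes and touching or
overlapping cells, sarcomere ultrastructure beyond a plain sinusoid,
intensity heterogeneity within a cell, debris and staining artifacts,
out-of-focus fields, cell density gradients, and any plate-position
(edge) effects. Recovery numbers on synthetic plates are upper bounds on
real-data performance; the pipeline's parameters are exposed in
`AssayConfig` precisely because real material will need retuning.

## Numerical and design choices

* Default sizes/thresholds (nucleus min 30 px², cell min 200 px²,
  texture min 25 px²) are chosen for the default synthetic scale
  (0.65 μm/px, 256×256 fields) and are all configuration.
* Thresholding defaults to per-field Otsu — a neutral choice where the
  assay's original settings are unknown; fixed and percentile modes are
  provided for transfer across acquisitions.
* Intensities are processed as floats normalized by the source bit-depth
  maximum, making thresholds transferable between 8- and 16-bit sources;
  the bit depth is kept in provenance.
* Well-level pooling (objects pooled across fields, score per well,
  mean ± SEM across replicate wells) follows the replicate structure of
  plate assays; per-plate vehicle normalization absorbs plate effects —
  no cross-plate harmonization is attempted.
* Problem sizes used by the test suite and acceptance script (20-field
  recovery batches, an 8+8-well reference plate at 4 fields/well,
  500-run null simulations) are chosen so the whole suite runs in about
  a minute on a laptop core while keeping sampling error well inside the
  asserted tolerances.

## Known limitations

* The ridge-based merge rule assumes striation depth < 1 − ridge
  fraction; deeply modulated or fragmented α-actinin staining could
  break a true cell into pieces.
* Border objects are excluded from morphometrics but not corrected for
  size bias (large cells touch borders more often).
* The 4PL fit reports a single IC50 without a confidence interval;
  non-monotone dose series (as toxic compounds produce) are only caught
  via the toxicity flags.
* No deep-learning segmentation, 3-D, time-lapse, or vendor container
  formats (CZI/ND2); images are single-channel TIFFs per field.
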