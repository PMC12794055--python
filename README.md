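# cardiomorph

High-content analysis of cardiomyocyte (CM) hypertrophy in **mixed
neonatal cardiac cultures**, from two-channel fluorescence fields to a
single composite phenotype metric.

Primary cardiac cultures contain CMs (~44% of cells) alongside
fibroblasts, endothelial and other non-CM cells. Hypertrophy assays image
each well in two channels — DAPI (all nuclei) and sarcomeric α-actinin
(CM bodies) — and must solve three problems that defeat off-the-shelf
propagation segmentation:

1. **Cell-type mixing** — every nucleus must be classified CM vs non-CM
   by colocalization with the α-actinin signal;
2. **Binucleation** — neonatal CMs frequently carry two nuclei, so a
   one-nucleus-per-cell assumption splits cells and corrupts counts and
   per-cell morphology;
3. **Illumination bias** — smooth multiplicative shading across the field
   makes raw intensities incomparable.

`cardiomorph` re-implements this analysis as a library + CLI:
illumination correction, nucleus segmentation with declumping,
colocalization classification, binucleation-aware seeded-watershed CM
segmentation, parent/child nucleus–cell relation, multiparametric
morphology/intensity/GLCM-texture features, well-level aggregation, and a
synthetic-field generator with exact ground truth that makes every stage
testable without any microscope data.

## The Hypertrophy Score

Each phenotype parameter is expressed as **percent of the vehicle (DMSO)
control** of its plate. The three parameters most consistently altered by
hypertrophic stimulation are combined with equal weights:

```
Score = (CM area % + CM nuclear area % + α-actinin intensity %) / 3
```

Vehicle wells sit at 100 by construction. Inhibitor efficacy at dose *d*
is window-normalized inhibition

```
I(d) = 100 · (Score_stim − Score_d) / (Score_stim − Score_vehicle)
```

(0 = no effect, 100 = full return to baseline); I at 8 μM (I_8μM) serves
for cross-compound ranking and a four-parameter logistic fit of I vs
log-dose (bottom fixed at 0) yields the cellular IC50. Cardiotoxicity is
flagged from raw CM and non-CM nucleus counts versus control, because
shrinking, dying cells otherwise masquerade as an antihypertrophic
response.

## Worked example

Simulate a 4-well plate (2 DMSO vehicle wells, 2 wells stimulated with
effects 1.5/1.2/1.3 on CM area / nuclear area / α-actinin intensity),
analyze and score it:

```bash
cat > layout.csv <<EOF
well_id,treatment_label,stimulant_label,compound_label,concentration_uM
A01,DMSO,,,0
A02,DMSO,,,0
B01,PE-LIF,PE-LIF,,0
B02,PE-LIF,PE-LIF,,0
EOF
cat > conditions.yaml <<EOF
PE-LIF: {effect_area: 1.5, effect_nuc_area: 1.2, effect_intensity: 1.3}
DMSO: {}
EOF
cardiomorph simulate --layout layout.csv --out img --seed 1 \
    --conditions conditions.yaml --fields-per-well 4
cardiomorph analyze --images img --layout layout.csv --out obj --seed 1
cardiomorph score --objects obj --layout layout.csv --out scored --seed 1
```

`scored/scores.csv` then contains (this exact run):

```
well_id treatment_label       role  hypertrophy_score  cm_area_pct  nuc_area_pct  intensity_pct toxicity_flag
    A01            DMSO    vehicle               98.4         96.4          98.8          100.1          none
    A02            DMSO    vehicle              101.6        103.6         101.2          99.9           none
    B01          PE-LIF stimulated              134.0        151.2         124.2         126.5           none
    B02          PE-LIF stimulated              132.7        150.1         122.5         125.5           none
```

Vehicle wells average exactly 100; the stimulated wells recover the
simulated effects — component percents near (150, 120, 130) and a score
near the expected (150+120+130)/3 ≈ 133.3. `cardiomorph report` adds
group statistics (one-way ANOVA with Dunnett many-to-one comparison
against control, star banding * p≤0.05 ** ≤0.01 *** ≤0.001 **** ≤0.0001)
and, for dose plates, per-compound I_8μM and IC50 fits.

The library mirrors the CLI one-to-one: `generate_plate`,
`analyze_plate`, `score_plate`, `fit_dose_response`, `compare_groups`,
`correlate_efficacy` (see `docs/methods.md` for the science and
`docs/data_dictionary.md` for every output column).

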