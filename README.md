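# periostage

Automated measurement of alveolar bone loss on periapical radiographs and
rule-based periodontitis staging and grading — implemented end to end with a
built-in synthetic radiograph generator, so the whole pipeline is testable
without clinical data.

## Who this is for

Researchers in dental radiology and medical image analysis who want a
transparent, fully testable reference implementation of the radiographic
bone-loss workflow: segment the bone-loss (BL) area, locate the
cemento-enamel junction (CEJ) and the root apex, convert the geometry into a
bone-loss percentage, and map that percentage onto the 2017-workshop-style
stage and grade. Clinical radiographs of periodontitis patients are rarely
shareable; the package's synthetic generator emulates their geometry with
exactly known ground truth, which makes every stage of the pipeline
verifiable to the pixel.

## The method

1. **Segmentation.** A U-Net (encoder filters 64/128/256/528, a 1,024-filter
   bridge, decoder 512/256/128/64; Dice loss, Adam, batch 8, lr 1e-4,
   15 epochs) maps a 160×320 histogram-equalized radiograph to a binary BL
   mask. The training engine is pure NumPy with hand-written backpropagation,
   so desk-scale configurations (4/8/16/32 filters) train in minutes on one
   CPU.
2. **Apex detection.** Pluggable: any detector that emits YOLO-style text
   labels (`class x_c y_c w h`, normalized) can be used. A reference
   blob detector for the synthetic images is included.
3. **Geometry.** Connected-component analysis finds each BL region; the
   region's bounding-box height is the maximum BL height `h`. The CEJ center
   is the midpoint of the bounding-box border facing the crown (upper border
   for lower teeth, lower border for upper teeth). Root length `r` is the
   Euclidean distance from the CEJ center to the apex, and

   BL% = 100 · h / r.

   Regions whose BL height is ≤ 2 mm are within the physiological
   CEJ-to-crest distance and are dropped.
4. **Staging and grading.** Stage I: BL% < 15; stage II: 15–33;
   stage III/IV: > 33. Grade from BL%/age: A < 0.25, B 0.25–1, C > 1.
5. **Evaluation suite.** Pixel metrics (accuracy/precision/recall/F1,
   IoU, Dice), rank-based ROC-AUC, MAE/RMSE, ICC(2,1) (two-way random,
   single rater, absolute agreement, with F-based 95% CI), per-class
   classification reports, and detection mAP over IoU 0.50:0.05:0.95.

## Worked example

```python
from periostage import SyntheticConfig, generate_case, CalibrationConfig, assess_patient
from periostage.pipeline import measure_case

case = generate_case(SyntheticConfig(seed=7), case_id=0)
teeth = measure_case(case.mask, [b.center for b in case.apex_boxes],
                     case.jaw, CalibrationConfig(mm_per_px=0.1))
for m in teeth:
    print(f"tooth at CEJ ({m.cej_center.x:.0f}, {m.cej_center.y:.0f}): "
          f"max BL {m.max_bl_px:.0f} px ({m.max_bl_mm:.1f} mm), "
          f"root {m.root_length_px:.1f} px, BL% {m.bl_percent:.1f}")
assessment = assess_patient([m.bl_percent for m in teeth], age=case.age)
print(f"age {case.age}: stage {assessment.stage}, grade {assessment.grade} "
      f"(index {assessment.grade_index:.2f})")
```

prints

```
tooth at CEJ (169, 38): max BL 32 px (3.2 mm), root 65.0 px, BL% 49.2
age 56: stage III/IV, grade B (index 0.88)
```

One of the three generated teeth exceeds the 2 mm allowance; its 32 px BL
height over a 65 px root gives 49.2% bone loss, i.e. stage III/IV, and
49.2/56 ≈ 0.88 places the patient in grade B.

The same flow is available from the shell:

```bash
periostage generate --out data --n-cases 100 --seed 5
periostage measure  --in data --out measurements.csv
periostage stage    --measurements measurements.csv --manifest data/manifest.csv --out assessments.csv
periostage run-all  --out results --n-cases 50 --seed 5   # full pipeline + reports
```

Other subcommands: `prepare` (80:10:10 split + two-fold flip/rotate
augmentation), `train-seg` (U-Net training), `detect` (reference blob
detector), `evaluate` (mask metrics), `compare-raters` (pairwise
ICC/MAE/RMSE between measurement CSVs).

## Layout

- `src/periostage/synthetic.py` — synthetic radiograph generator with exact ground truth
- `src/periostage/image_io.py` — PNG I/O, preprocessing, splitting, augmentation
- `src/periostage/segmentation.py`, `_nn.py` — U-Net and the NumPy training engine
- `src/periostage/apex_detection.py` — YOLO-txt parsing, blob detector, matching
- `src/periostage/measurement.py` — regions, CEJ, root length, BL%
- `src/periostage/staging.py` — stage/grade rules
- `src/periostage/metrics.py` — full metric suite
- `src/periostage/pipeline.py`, `cli.py` — orchestration and the `periostage` command

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
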