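# thermoscreen

Automated analysis of frontal breast thermograms for cancer screening.
Infrared thermography maps skin surface temperature; inflammation and
tumour-driven angiogenesis raise local perfusion, which shows up as
focal warm spots and asymmetric vascular patterns between the two
breasts.  `thermoscreen` turns a raw temperature matrix into a single
**thermal score** and a binary screening call, and aggregates calls
over a cohort into standard screening statistics.

The pipeline, stage by stage:

1. **Segmentation** — the pseudo-color rendering is converted to
   grayscale (Rec. 601 luma) and a Sobel gradient is computed
   (`Mag(∇f) = √(Gx² + Gy²)`), binarized with Otsu's threshold.  The
   horizontal projection profile (white-pixel count per row) is scanned
   bottom-up: the infra-mammary fold produces the first dense row,
   taken as the lower limit *LL*.  The breast height is a fraction of
   the image height *m* switched on whether the fold lies within 26 %
   of the image bottom (`h = round(0.45·m)` or `round(0.35·m)`), giving
   the axillary upper limit `UL = LL − h`.  Outermost edge columns in
   `[UL, LL]` give the side limits, and their midpoint the central axis
   that splits the left and right breast regions.
2. **Vascularity** — the rendering is mapped to CIELAB; every pixel is
   assigned to the nearest chromaticity marker (red vs background) by
   Euclidean distance in the (a\*, b\*) plane.  The per-breast red-area
   fractions drive a discrete grade: 0 (no vascular pattern), 2
   (symmetric/moderate), 3 (significant asymmetry), 4 (asymmetry over
   at least one third of the breast area).
3. **Scoring** — ΔT is the temperature at the hottest in-breast pixel
   minus the temperature at its mirror site (same row, column reflected
   about the central axis) on the contralateral breast.  The thermal
   score is `grade + ΔT` (°C); scores ≥ 2.5 are called **anomaly**,
   below 2.5 **healthy**.
4. **Screening statistics** — cohort-level confusion counts,
   sensitivity / specificity / PPV / NPV (positive class = anomaly),
   and a ROC curve swept over score thresholds with trapezoidal AUC.

Because clinical thermograms are rarely shareable, the package ships a
**phantom generator**: synthetic frontal thermograms with a warm torso
on a 24 °C background, an infra-mammary fold line, branching vascular
trees, optional hotspots and sensor noise — all with exact ground truth
(fold row, midline, vessel masks, grade, ΔT, label), so every stage is
testable end to end.

## Worked example

Simulate one healthy and one tumour-bearing patient, then score the
tumour case:

```sh
thermoscreen simulate --n-healthy 1 --n-cancer 1 --seed 7 --outdir phantoms
thermoscreen score phantoms/P002.csv --rgb phantoms/P002.png
```

```json
{
  "asymmetry": 0.30941745625908657,
  "classification": "anomaly",
  "delta_t": 2.2826335334020555,
  "grade": 3,
  "hotspot": [103, 88],
  "left_fraction": 0.34235474006116207,
  "limits": {"central_axis": 100, "left": 40, "lower": 182, "right": 160, "upper": 74},
  "mirror_site": [103, 112],
  "right_fraction": 0.0329372838020755,
  "score": 5.2826335334020555,
  "threshold": 2.5
}
```

Reading this: the fold was detected at row 182 and the body midline at
column 100; 34 % of the left breast region classified as vascular
against 3 % of the right (asymmetry 0.31 → grade 3, significant); the
hotspot at (103, 88) is 2.28 °C warmer than its mirror site (103, 112),
so the thermal score is 3 + 2.28 = 5.28 ≥ 2.5 → anomaly.

Cohort statistics from the manifest the simulator wrote:

```sh
thermoscreen stats phantoms/cohort.csv
# {"auc": 1.0, "npv": 100.0, "ppv": 100.0, "sensitivity": 100.0, "specificity": 100.0}
```

The same works for real data: a CSV of °C values (one image row per
line) or a single-channel 16-bit TIFF with a scale/offset sidecar,
plus optionally the camera's own pseudo-color PNG.

In Python the same pipeline is three calls:

```python
from thermoscreen import read_thermogram, analyze_thermogram

t = read_thermogram("phantoms/P002.csv", "phantoms/P002.png")
result = analyze_thermogram(t)
print(result.score.score, result.score.classification)
```

## Layout

| module | contents |
| --- | --- |
| `thermoscreen.io` | `Thermogram` container, CSV/TIFF/PNG I/O, versioned palette, `render_rgb` |
| `thermoscreen.segmentation` | Sobel edge map, projection profiles, limit detection, breast masks |
| `thermoscreen.vascularity` | CIELAB conversion, marker classification, grading |
| `thermoscreen.scoring` | hotspot, mirror site, ΔT, thermal score, 2.5-threshold call |
| `thermoscreen.stats` | confusion counts, screening rates, ROC/AUC |
| `thermoscreen.phantom` | synthetic thermograms and cohorts with ground truth |
| `thermoscreen.pipeline` / `thermoscreen.cli` | end-to-end orchestration, `thermoscreen` command |

See `docs/methods.md` for the modelling choices, defaults, and what the
phantom does and does not emulate.
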