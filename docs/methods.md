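# Methods

## The screening model

The package implements a rule-based screening method for frontal breast
thermograms.  Two physiological signals are combined:

* **ΔT** — the surface temperature at the hottest point inside the
  breast regions minus the temperature at its *mirror site* on the
  contralateral breast, in °C.  Healthy breasts are thermally nearly
  symmetric; tumour-associated hypervascularity breaks that symmetry.
* **Vascularity grade** — a discrete ordinal {0, 2, 3, 4} describing
  the amount and asymmetry of vascular (red-rendered, i.e. hot) pattern:
  absence (0), symmetric or moderate pattern (2), significant asymmetry
  (3), asymmetry extending over at least one third of the breast area
  (4).  Only the one-third bound is quantitative in the source scale;
  the other cutoffs are configurable (see below).

The thermal score is their sum, `score = grade + ΔT`, and the binary
call is `anomaly ⇔ score ≥ 2.5`.  The threshold is inclusive on the
anomalous side and exposed as a parameter, since the ROC over score
thresholds is itself an output of interest.

## Segmentation assumptions and defaults

The segmentation assumes a single, roughly upright frontal torso
against a cooler background, with the infra-mammary fold visible as the
densest horizontal edge structure in the lower part of the image.
Parameters (YAML-configurable through `RunConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `edge_threshold` | `otsu` | gradient-magnitude binarization; a fixed value may be supplied |
| `hpp_threshold_frac` | 0.15 | fraction of image width a row's edge count must reach to be the fold line |
| `scan_region_frac` | 0.40 | fraction of rows, from the bottom, scanned for the fold |
| `c_small` / `c_large` | 0.45 / 0.35 | breast height as a fraction of image height; `c_small` applies when the fold is within 26 % of the bottom (small-breast framing), `c_large` otherwise |

The original height formulas exist only as figure content in the source
method, so the two coefficients are this package's own calibration,
chosen to reproduce the described qualitative behaviour (the
bottom-distance is large for small breasts) and left configurable.  The
fold-line preset count is likewise known only as "chosen by tests";
scaling it with image width keeps the default resolution-independent.
Tie-breaks follow the scan order: the bottom-most qualifying row wins
the fold scan, outermost columns win the side scan, and the central
axis is `left + floor((right − left + 1)/2)`.

Degenerate inputs: images smaller than 32×32 are rejected; a flat
gradient falls back to an empty edge set with a warning; a missing fold
line or missing lateral contour raises a `SegmentationError` naming the
structure.

## Color classification

The rendering is converted to CIELAB (sRGB, D65) and each pixel is
labelled by its nearest marker in the (a\*, b\*) plane; L\* is ignored
because the red-vs-background distinction is chromatic, not one of
brightness.  Distance ties go to background, which biases against false
vascular pixels.

Marker acquisition is automatic by default so the pipeline can run
unattended.  One subtlety matters: *blue* pixels carry large positive
a\* (sRGB blue is a\* ≈ +68), so ranking "redness" by a\* alone would
select the cold background.  The automatic red marker therefore ranks
pixels by a\* + b\* — red and orange are high on both axes, blue is
pulled far down by its negative b\* — and averages the top 2 % inside
the segmented torso rectangle.  Two background markers are used rather
than one: the mean chromaticity outside the rectangle (ambient) and the
mean over the rectangle's at-or-below-median-redness pixels (ordinary
skin).  With a single outside-only background marker, mid-palette skin
tones (greens/yellows) sit closer to the red marker than to the
ambient blue and would be misclassified as vascular.  Explicit sample
regions or marker coordinates can still be supplied, mirroring manual
region selection.

Grading thresholds: `t_absent = 0.01` (maximum red fraction below which
the pattern counts as absent) and `t_significant = 0.10` (asymmetry at
which grade 3 begins) are this package's defaults; only the ≥ 1/3 rule
for grade 4 is fixed by the scale.  Rules are evaluated in the order
absence → one-third → significant → moderate, which makes the grade
monotone in asymmetry whenever a pattern is present.

## ΔT measurement

The hotspot is the in-mask global temperature maximum (ties broken
toward the smallest row, then column, for deterministic output).  The
mirror site is the same row with the column reflected about the central
axis, clamped into the contralateral rectangle; a hotspot exactly on
the axis maps to itself and warns.  ΔT is clamped at zero — the
hotspot is a global maximum, so a negative difference can only arise
through clamping at asymmetric masks.  ΔT is computed from the stored
temperature matrix rather than by live camera readout, which makes the
measurement reproducible from archived data.

## Screening statistics

Sensitivity, specificity, PPV and NPV are kept at full precision;
*display* values use truncation (not rounding) to two decimals, the
convention under which 136/198 prints as 68.68 % and 8/70 as 11.42 %.
Zero-denominator statistics are reported as undefined rather than
raised.  The ROC sweeps the sorted unique scores (call = score ≥
threshold, positive class = anomaly), starts from an implicit +inf
threshold so the curve begins at (0, 0), and integrates AUC by the
trapezoid rule.  In tests the curve is cross-checked against an
exhaustive enumeration and scikit-learn's `roc_auc_score`.

## The phantom generator

The generator emulates the standardized acquisition setting: a 24 °C
controlled ambient, skin base 33.5 °C, Gaussian sensor noise of
0.07 °C (a typical uncooled-microbolometer thermal sensitivity), and a
geometry whose fold sits at 75 % of the image height and axilla at
30 % — the proportions the default height rule reconstructs.  Drawn
features and their ground truth:

* torso silhouette with a shoulder step at the axilla row;
* a cold crease line at the fold row spanning both breasts (the dense
  horizontal edge the fold scan keys on);
* slightly cooler smooth breast mounds (no spurious hard edges);
* branching vascular polylines, dilated to ~3 px and elevated 2.0 °C
  above local skin so the shipped palette renders them orange/red; a
  side's "density" d targets vessel coverage of 0.45·d of that
  half-chest, so d = 1 comfortably exceeds the grade-4 one-third bound;
* an optional Gaussian hotspot; the elevation layer is the pointwise
  *maximum* of hotspot and vessel elevations, so a vessel crossing a
  hotspot never overshoots the specified peak ΔT, and a small disk
  around the hotspot's mirror site is kept vessel-free so the measured
  ΔT reflects the specified value;
* healthy phantoms mirror the left vascular tree onto the right side
  exactly, making ΔT ≈ 0 by construction; cohort cancer cases draw
  peak ΔT from [1.5, 4.0] °C with strongly one-sided vasculature,
  healthy cases from [0, 0.8] °C with symmetric vasculature.

Default phantom and cohort images are 240×200; the full pipeline runs
in ~20 ms per phantom, so property tests sweep dozens of seeds cheaply.

What the phantom does **not** emulate: bioheat (Pennes) physics,
anatomical variability (posture, breast ptosis, arm position), camera
optics (vignetting, dead pixels, lens distortion), drafts or emissivity
variation, and non-tumour causes of thermal asymmetry (mastitis,
recent exercise).  Passing phantom tests therefore demonstrates that
the *algorithmic chain* is implemented correctly and is robust at the
stated noise level — not that the method achieves any particular
clinical accuracy; the clinical operating point can only be checked
against the printed cohort counts, which the statistics tests do.

## Known limitations

* The breast-height coefficients and fold preset are calibrated
  stand-ins (see above); on real data they should be tuned per camera
  geometry via the config file.
* Automatic marker acquisition assumes a rainbow-style palette with a
  red hot end; gray-scale or iron palettes need explicit markers.
* Frontal view only; one torso per image; no pose correction.
* The mirror site is a single pixel; a small neighbourhood average
  would be more robust to noise but would no longer reproduce the
  point-difference definition of ΔT.
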