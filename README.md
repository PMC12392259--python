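# luxpaper

Image-to-answer analysis for **bioluminescent paper water-toxicity
biosensors** photographed with a smartphone.

Paper sensors carrying immobilized *Aliivibrio fischeri* glow in the dark;
toxicants in a water sample dim that glow dose-dependently. A sensor is a
small paper disc with seven hydrophilic wells — six calibrator wells
(S0…S5, with S0 the zero-dose control) arranged around one central sample
well — photographed inside a dark box with a long-exposure smartphone
camera. Because the calibration is *on board* (same paper, same photo),
normalizing every well to the control cancels camera gain, exposure and
ambient effects, and the sample's toxicity-equivalent concentration can be
interpolated from the calibration curve of the very same image.

`luxpaper` implements the full analysis chain, plus a synthetic sensor
renderer so everything is testable without a laboratory:

1. **simulate** — render ground-truth-annotated sensor photographs under a
   parametric CMOS camera model (Poisson shot noise, Gaussian read noise,
   PSF blur, per-phone gain/exposure presets);
2. **detect** — find wells with a scale-searched circular matched filter
   whose normalized response is a confidence in [0, 1], filter at a
   probability threshold (default 0.67), and greedily suppress overlapping
   candidates (bounding-box IoU > 0.01);
3. **quantify** — per-well bioluminescence in relative light units (RLU):
   mean in-disc intensity minus the median of a local background annulus,
   then residual activity as % of the control;
4. **calibrate & infer** — fit the four-parameter logistic

   *y(c) = bottom + (top − bottom) / (1 + (c / EC₅₀)^h)*,

   compute limits of detection and quantification from blank statistics
   (LOD = mean(blank) − 3·SD, LOQ = mean(blank) − 10·SD, mapped to
   concentration through the closed-form curve inverse), interpolate the
   sample well, attach a bootstrap 95 % CI, and emit a **Toxic/Safe**
   verdict against a configurable decision threshold (default: the
   concentration at 20 % inhibition).

## Worked example

```python
import luxpaper as lp

# synthetic NaClO-like assay: calibrators 0-4.0 ppm, sample spiked at 1.5 ppm
img, layout, record = lp.make_assay_fixture(
    "NaClO", [0, 0.1, 0.5, 1.0, 2.0, 4.0], sample_conc=1.5,
    model=lp.InhibitionModel(ec50=1.0, hill=1.5),
    camera=lp.get_camera("oneplus6"), seed=7, cv=0.05,
)
report = lp.analyze_image(img, layout, seed=1)
```

prints (via the fields of `report`):

```
wells detected : 7
R^2            : 0.9997
EC50 (fitted)  : 0.926 ppm
LOD            : 0.083 ppm (signal 98.2 %)
sample estimate: 1.41 ppm  CI95 [1.31, 1.51]
status         : Toxic
```

All seven wells were found and assigned; the on-board calibration fits the
six calibrators nearly perfectly (R² = 0.9997); the blank statistics place
the detection limit below the lowest calibrator; and the 1.5 ppm spike is
recovered at 1.41 ppm (94 % recovery) with a 95 % confidence interval that
covers the truth — well above the 20 %-inhibition decision threshold, hence
**Toxic**.

The same pipeline is scriptable from the shell:

```sh
luxpaper simulate --config assay.yaml --n 3 --seed 7 --out fixtures/
luxpaper analyze fixtures/img_000.tiff --config assay.yaml --out report.json --overlay overlay.png
luxpaper study --manifest fixtures/manifest.json --config assay.yaml --out results.csv
```

Exit codes: 0 ok, 2 bad input, 3 assay invalid (missing wells, dead
control, no dose-response — each with a machine-readable error code in the
report), 4 internal.

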