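# Methods

## The measurement problem

A paper disc carries seven hydrophilic wells of immobilized *Aliivibrio
fischeri*, a marine bacterium whose lux-operon bioluminescence decreases
when cell viability is impaired. Six outer wells receive standard
solutions of increasing toxicant concentration (S0 = 0, the control) and
the central well receives the water sample. One long-exposure smartphone
photograph in a dark box captures all seven wells simultaneously, so a
calibration curve and the unknown are measured under identical optics,
camera settings and timing. The quantity of interest is the sample's
toxicity-equivalent concentration and a Toxic/Safe classification.

## Dose-response model

Residual activity (signal as % of control) follows a symmetric
four-parameter logistic in concentration,

    y(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill),

equivalent to the standard 4PL on log10-concentration. This form was
chosen because (i) it is the field-standard sigmoid for acute-toxicity
dose-response, (ii) it evaluates exactly to `top` at zero dose, so the
blank participates in the fit without a pseudo-log offset, and (iii) it
inverts in closed form,

    c(y) = ec50 * ((top - y) / (y - bottom))^(1/hill),

which the inference stage uses for LOD/LOQ mapping and sample
interpolation (a numeric root-finder is used only as a cross-check in the
test suite). Fitting is bounded trust-region least squares with a fixed,
deterministic initialization (top = max signal, bottom = min signal,
ec50 = geometric mean of the nonzero concentrations, hill = 1). Inputs
must contain the blank and at least four distinct concentrations; a
Spearman correlation > −0.5 between dose and signal, or flat signals,
raise a "no dose-response" failure rather than producing a meaningless
fit.

## Limits of detection and quantification

Because toxicity *decreases* signal, detectability is a decrease below the
blank: `LOD_signal = mean(blank) − 3·SD(blank)` and
`LOQ_signal = mean(blank) − 10·SD(blank)`, mapped to concentration through
the curve inverse. A limit whose signal falls outside the open interval
(bottom, top) is reported as out-of-range rather than extrapolated; a
limit *below the lowest calibrator* is still reported numerically, since
blank-based limits routinely sit below the working range. On a single
image there are no blank replicates, so the pipeline uses the standard
error of the control-ROI mean (pixel SD / √n) as the blank SD; with
replicate sensors, `compute_lod_loq` accepts the replicate control RLUs
directly. Which convention applies is the caller's choice; the single-image
default measures only shot/read noise, not between-sensor variability, and
therefore yields optimistic limits.

## Well detection

The published analysis used a served instance-segmentation model, with a
probability threshold of 0.67 and a non-maximum-suppression threshold of
0.01. The model itself is not available, so this package honours the same
contract with a classical, fully reproducible detector: candidate centres
and scales come from Laplacian-of-Gaussian maxima on the range-normalized
image, and each candidate's confidence is the Pearson correlation between
the local patch and an ideal disc template at the best radius (scanned on
a 25-point geometric grid, centre refined over a ±1 px neighbourhood).
Pearson correlation is exactly invariant under affine intensity maps, so
the 0.67 threshold transfers across cameras, and equals 1 only for a
perfect disc. NMS is greedy by decreasing confidence with ties broken by
image row then column; the overlap metric is IoU of the circles'
axis-aligned bounding boxes (common NMS practice; at threshold 0.01
essentially no overlap is tolerated). Equivalence with an exhaustive
subset-search oracle is tested on instances of up to 8 candidates.

Role assignment on the flower sensor: the detection nearest the centroid
is the sample; the outer six are binned to 60° slots measured from the
orientation cue. Without an explicit orientation, S0 is taken as the
brightest outer well — the control is uninhibited, so this holds whenever
the sample is at least slightly toxic and noise is moderate; for samples
brighter than the control (hormesis) the cue must be supplied. Two outer
wells within 5° of each other, or any unfilled slot, abort the assay with
the role named. The 3×6 array uses similarity registration (centroid,
RMS-radius scale, optional rotation) followed by optimal assignment, with
matches farther than one well radius treated as missing.

## Quantification

RLU is the *mean* background-subtracted in-disc pixel value (the
mean-gray-value convention; integrated intensity would be equivalent up to
the fixed disc area but more sensitive to radius jitter). Background is
the median of a concentric annulus at 1.2–1.6 well radii — median rather
than mean to resist glow tails from neighbouring wells. Negative
differences clamp to zero with a flag. The PSF leaks a few percent of rim
signal out of every disc; the leakage fraction is identical across
same-radius wells and cancels in control normalization, which is the
reason calibration is done in residual-activity space (control ≡ 100 %)
while blank statistics stay in raw RLU.

## Synthetic sensor generator

The generator emulates: disc-shaped wells with antialiased rims on a dark
paper, per-well photon flux proportional to residual activity (control
flux 40 photons/s/px, putting a 30 s exposure at ~15 % of 16-bit full
scale), faint stray-light background (0.2 photons/s/px), Gaussian PSF
(σ = 1.2 px at 0.2 mm/px), Poisson shot noise, affine gain, Gaussian read
noise, baseline offset and clipping, with six camera presets at their
reported integration times and gains chosen so the control lands at a
comparable exposure fraction on each. Multiplicative per-well flux jitter
(`cv`) models biological replicate scatter. The default NaClO-like assay
uses calibrators 0, 0.1, 0.5, 1.0, 2.0, 4.0 ppm with ec50 = 1.0 ppm and
hill = 1.5 — midpoint mid-range and a moderately steep slope typical of an
acute toxicant over ~1.5 decades.

It does **not** model paper texture, wax-boundary optics, hydrogel drying,
bacterial kinetics over incubation, vignetting, demosaicing or any phone
tone-mapping/night-mode stacking. Passing tests therefore demonstrate the
correctness and robustness of the *analysis chain* under realistic photon
statistics — not the wet-lab performance of a physical sensor; real-image
LODs and recoveries depend on the biology and optics that are outside this
package's scope.

## Decision rule and uncertainty

The sample estimate inverts the fitted curve at the sample's residual
activity. Samples at or above the blank-derived LOD signal report
"< LOD"; samples brighter than blank + 3·SD additionally flag stimulation
(hormesis) and classify Safe. The 95 % CI is a seeded parametric bootstrap
(default 500 resamples): calibrator signals are perturbed with the fit's
residual SD, the curve refitted, and an equally perturbed sample signal
inverted. The Toxic/Safe threshold defaults to the concentration at 20 %
inhibition on the fitted curve and is configurable — the cut-off is a
policy choice, not a property of the sensor.

## Study sizes and numerical choices

Seeded desk-scale studies (in `luxpaper.studies`) use: 100 noise
realizations for detection fidelity; 200 repeats for calibration quality
(2 % CV, triplicate wells) and for EC₅₀ recovery (5 % CV, triplicate
wells, median relative error); a 3-level × 3-replicate recovery panel at
5 % CV through the full image pipeline, with each level's recovery taken
as the mean of its triplicate estimates (matching the triplicate-sample
convention of recovery studies); and one fixed scene rendered under all
six camera presets for the invariance check. Images are 195×195 px at
0.2 mm/px. Tolerances: curve round-trip inversion is exact to closed form
(cross-checked against Brent root-finding at 1e−9 relative); detector
centres are required within 1 px of ground truth on noiseless renders;
photon-transfer variance is verified to 5 % on ≥10⁴-pixel regions.

## Known limitations

- The detector assumes one sensor per image, roughly paper-centred, with
  wells of similar radius; no perspective or lens-distortion correction.
- The brightest-well orientation fallback fails for strongly hormetic
  samples; pass the orientation explicitly in that case.
- Single-image LOD/LOQ rest on within-ROI noise only (see above).
- The bootstrap CI reflects calibration and sample signal noise, not
  detection/segmentation uncertainty (negligible at these SNRs).
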