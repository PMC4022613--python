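# echostruct

Quantification of left-ventricular myocardial microstructure from B-mode
echocardiographic images, built around the **signal-intensity coefficient
(SIC)**: the 25th-percentile intensity `p` of a pericardial region of
interest on an 8-bit frame, mapped to `SIC = 1 - p/256`. A darker
pericardial reflection (higher SIC) indicates attenuated transmission
through the overlying myocardium. The package also computes the
conventional linear echo measures (wall thickness, relative wall thickness,
Teichholz volumes/EF, LV mass, MAP, diastolic ratios) and the composite
**myocardial structural index** `MSI = SIC/0.13 + RWT/0.05`, plus the full
statistical evaluation pipeline and fully synthetic test surfaces (speckle
phantoms and simulated cohorts).

## Modules

| module | contents |
| --- | --- |
| `echostruct.imaging_io` | 8-bit frame reading (PNG/JPEG; DICOM via the optional `pydicom` extra), ROI JSON I/O, pixel-center even-odd polygon rasterization, pixel extraction |
| `echostruct.sic` | nearest-rank percentiles, distribution summaries, SIC and MSI |
| `echostruct.conventional` | LVWT, RWT, MAP, Teichholz volumes/EF, fractional shortening, LV mass, diastolic ratios |
| `echostruct.phantom` | layered Rayleigh-speckle phantoms with a disease-severity knob, gain transforms, ROI jitter |
| `echostruct.cohort` | truncated-Gaussian cohort simulator with optional SIC–DBP copula coupling; clinical and murine presets |
| `echostruct.stats` | pooled t, chi-square, standardized OLS/logistic regression, tertiles, rank trend test, Kruskal-Wallis, Pearson r, ICC(2,1), the full clinical analysis grid |
| `echostruct.cli` | `echostruct` command-line interface and batch measurement |

## CLI

```bash
# generate phantoms and measure them
echostruct phantom generate --theta 0.5 --seed 1 --n-seeds 4 --out-dir out/phantoms
echostruct measure --manifest out/phantoms/manifest.csv --out out/measurements.csv

# simulate a cohort and run the analysis grid
echostruct cohort simulate --preset clinical --seed 7 --out out/cohort.csv
echostruct stats compare --cohort out/cohort.csv --out out/comparison.csv
echostruct stats regress --cohort out/cohort.csv --out out/regressions.csv
echostruct stats trend   --cohort out/cohort.csv --out out/trend.csv

# everything at once (phantom severity panel + simulated clinical study)
echostruct demo --seed 7 --out-dir out/demo
```

ROI files are JSON lists of `{"label": "myocardial"|"pericardial",
"vertices": [[row, col], ...]}` polygons in 0-based pixel coordinates with
pixel centers at integer coordinates.

## Conventions worth knowing

- Percentiles are nearest-rank order statistics (no interpolation), so the
  SIC always lies on the lattice `{1 - k/256}`.
- The SIC divisor is 256 (as the method defines it), although 8-bit
  intensities top out at 255.
- RWT is total wall thickness (IVS + PW) over LVDD.
- Non-8-bit images are rejected unless explicitly rescaled
  (`read_frame(..., rescale=True)`).
- The Student t-test pools variances; regressions report coefficients per
  1-SD of the raw predictor; no multiple-testing adjustment is applied.
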