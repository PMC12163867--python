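# flimphasor

Phasor-plot analysis of TCSPC-FLIM decay cubes. The package turns per-pixel
photon arrival-time histograms into calibrated phasor coordinates, derives
phase / modulation / average lifetime maps, supports photon thresholds,
manual masks, sliding-window spatial binning and phasor-space ROI selection,
pools samples by experimental condition, and exports CSV tables, float32
TIFF maps and publication-style figures (phasor clouds, lifetime galleries,
violin plots).

## Method summary

Each pixel's decay `I(t_k)` (bin centers `t_k = (k + 0.5) · bin_width`) is
projected onto the first harmonic of the laser repetition rate:

```
G = Σ I(t_k) cos(ω t_k) / Σ I(t_k)      S = Σ I(t_k) sin(ω t_k) / Σ I(t_k)
```

with `ω = 2π · f · n` in rad/ns. A measured single-exponential reference dye
of known lifetime (e.g. Rhodamine 6G, 4 ns in water) defines a global
rotation + modulation-scale correction that moves its photon-weighted mean
phasor onto the theoretical position `(1/(1+(ωτ)²), ωτ/(1+(ωτ)²))`; applying
that transform to samples cancels the instrument response without
deconvolution. Lifetimes follow from the calibrated coordinates:
`τ_φ = tan(φ)/ω`, `τ_M = √(1/M² − 1)/ω`, `τ_avg = (τ_φ + τ_M)/2`.

## Input formats

* **`.sdt`** (Becker & Hickl) — image-mode histogram blocks; bin width and
  repetition rate from the header. A minimal, documented subset of the
  container is implemented in-repo (`flimphasor/_sdt.py`).
* **`.ptu`** (PicoQuant, PicoHarp-T3 TTTR) — photon records are binned per
  pixel using the file's frame/line markers and resolution tags
  (`flimphasor/_ptu.py`).
* **`.tif`** — one page per time bin. This format carries no timing
  metadata, so `--tif-bin-width` (ns) is required.

Images are indexed `(row, col)` with row 0 at the top; TIFF page order is
time order. Masks are image files whose nonzero pixels are kept. Condition
tables are CSV with `file_path,condition[,sample_id]` columns.

## CLI

```bash
# full pipeline on a two-condition dataset
flimphasor analyze \
    --conditions conditions.csv \
    --ref reference.sdt --ref-tau-ns 4.0 \
    --freq-mhz 80 --min-photons 50 --bin 1 \
    --out results/

# synthetic dataset with analytic ground truth
flimphasor simulate --spec examples/demo_spec.json --out sim/ --ref-tau-ns 4.0

# re-plot a phasor figure from exported per-pixel points
flimphasor render --points results/phasor_points.csv --mode contour --out phasor.png
```

`analyze` writes `summary.csv` (per-image / per-ROI / per-condition means),
per-image lifetime TIFFs (invalid pixels NaN), `phasor_points.csv`,
`phasor.png`, tau/intensity galleries, violin figures + CSVs, a run log with
pixel accounting, and `resolved_config.yaml` — re-running from that file
reproduces the run exactly. All parameters can also be given as a YAML
config (`--config run.yaml`) with flags taking precedence.

ROIs in phasor space are JSON: polygons (`vertices`) or ellipses
(`center`, `semi_axes`, `angle`), selected pixels are back-mapped onto the
lifetime image and summarized per ROI.

## Synthetic data

`flimphasor.synthetic` generates decay cubes with exact analytic ground
truth: wrapped (incomplete-decay) multi-exponentials, optional Gaussian IRF
(closed-form erfc convolution), optional per-bin Poisson noise, and
label-image patterns for multi-population scenes. `analytic_phasor` /
`analytic_lifetimes` give the continuous-model truth used throughout the
test suite.

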