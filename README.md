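# fetquant

Quantification toolkit for [18F]-FET PET monitoring of orthotopic
glioblastoma (GL261) in the mouse. Pre-clinical amino-acid PET faces
tumors of only a few mm³ on a scanner with ~1.2–1.7 mm resolution, so
naive SUV readouts are biased by partial volume effects and fixed
segmentation thresholds from clinical routine produce unreliable tumor
volumes. `fetquant` implements the full quantification chain for this
setting, for imaging scientists who need reproducible, scriptable analysis
of small-animal FET PET:

* **Uptake statistics** — SUVmean/BG and SUVmax/BG in a universal 88 mm³
  target VOI normalized to a 123 mm³ contralateral background VOI, with
  automated screening for bone spill-in at the VOI edge.
* **Partial volume correction** — Rousset-style geometric transfer matrix
  (GTM) over an 8-region mask: w<sub>ij</sub>, the fraction of region j's
  true signal observed in region i, is obtained by blurring region
  indicators with the scanner PSF (FWHM 1.20 × 1.20 × 1.72 mm); solving
  W t = m recovers true regional means t from measured means m.
* **Biological tumor volume (BTV)** — suprathreshold segmentation
  (SUV/BG ≥ θ, hot-connected "hot 3D VOI" mode), exact optimal-threshold
  search against a reference volume, and the individual-threshold
  calibration θ = 0.3215 · SUVmax/BG + 0.5654 that predicts each animal's
  segmentation threshold from its peak uptake alone.
* **Cavalieri volumetry** — stereological reference volumes from
  sectional ROI areas (V = Σ areas × thickness × interval; 16 µm
  sections, every 24th mounted ⇒ 0.384 mm spacing).
* **Longitudinal analysis** — linear/logarithmic/quadratic growth fits
  with correlation-based model selection and weekly cohort summaries.
* **Synthetic phantoms** — a seeded mouse-head phantom cohort generator
  (brain compartment, tumor of configurable volume and uptake ratio,
  Harderian glands, skull hot spot, anisotropic Gaussian blur,
  pseudo-Poisson noise) that provides ground truth for every stage.

Images and masks are NIfTI-1 (via nibabel); tables are CSV (pandas);
configuration and reports are JSON. See `docs/methods.md` for the model
details and assumptions.

## Worked example

```python
from fetquant import phantom, quant, btv, histology
from fetquant.pipeline import ExperimentConfig, run_calibration_round, \
    run_validation_round, default_search_region

# One synthetic animal: 40 mm^3 tumor at twice the background uptake
spec = phantom.default_spec(tumor_volume_mm3=40.0, uptake_ratio=2.0, seed=7)
image, truth = phantom.generate_brain_phantom(spec)

tumor_voi, bg_voi = phantom.default_universal_vois()
stats = quant.region_uptake_stats(image, tumor_voi, bg_voi)
print(f"SUVmean/BG = {stats.suv_mean_bg:.3f}, SUVmax/BG = {stats.suv_max_bg:.3f}")

series = histology.sample_section_areas(truth.masks["tumor"], spacing_mm=0.384)
reference = histology.cavalieri_volume(series)
theta, result = btv.find_optimal_threshold(
    image, stats.bg_mean, reference, default_search_region(tumor_voi))
print(f"optimal individual threshold = {theta:.4f}, BTV = {result.volume_mm3:.1f} mm^3")

# Two-round experiment: calibrate on 8 phantoms, validate on 15 fresh ones
config = ExperimentConfig(seed=0)
model, _ = run_calibration_round(config)
report = run_validation_round(config, model)
```

This prints:

```
SUVmean/BG = 1.385, SUVmax/BG = 2.132
optimal individual threshold = 1.4210, BTV = 38.3 mm^3
fitted calibration: theta = 0.4107 * SUVmax/BG + 0.5010 (rho = 0.988)
validation: RMSE individual = 13.1%, best fixed = 36.3%, rho(BTV, reference) = 0.996
```

Reading the numbers: the universal-VOI SUVmean/BG (1.385) sits well below
the true uptake ratio of 2 — partial volume loss plus dilution by healthy
tissue inside the fixed VOI — while the peak ratio survives better
(2.132 after noise). The exact threshold search finds the SUV/BG cutoff
(1.421) whose hot-connected volume matches the 38.3 mm³ Cavalieri
reference. Across the calibration cohort those optimal thresholds are
almost perfectly linear in SUVmax/BG (ρ = 0.988), and on the independent
validation cohort thresholds *predicted* from that line alone track the
reference volumes far better (RMSE 13.1%) than the best of the four fixed
clinical thresholds 1.4/1.6/1.8/2.0 (RMSE 36.3%).

The same pipeline is scriptable from the shell:

```sh
fetquant run --seed 0 --out-dir results/          # two-round experiment
fetquant phantom single --volume 40 --uptake 2 --seed 7 --out img.nii.gz
fetquant btv predict --suvmax-bg 2.0              # -> 1.2084
```

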