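# Methods

`fetquant` implements the quantification chain used for amino-acid PET
([18F]-FET) monitoring of orthotopic glioblastoma in the mouse: uptake
ratios in universal volumes of interest, geometric-transfer-matrix (GTM)
partial volume correction, threshold-based biological tumor volume (BTV)
segmentation with individually calibrated thresholds, Cavalieri reference
volumetry, and growth-curve fitting. Because no real scan data ship with
the package, a synthetic phantom generator provides the cohorts on which
every stage is validated end to end.

## Coordinate and volume conventions

Images live on regular grids with voxel-center world coordinates
(`world = origin + index * spacing`, mm). The axial direction is the third
array axis and carries the coarse 0.80 mm spacing of the reconstruction
grid (in-plane 0.39 mm). All volumes are voxel counts times the voxel
volume (0.12168 mm³ at the default spacing). NIfTI-1 is the on-disk
format; masks are 8-bit with 1 = member.

## Universal VOIs

Uptake is quantified in an 88 mm³ target VOI surrounding the stereotactic
inoculation site and a 123 mm³ background VOI in the tumor-free
contralateral hemisphere. Only the volumes and anatomical placement of
these VOIs are prescribed, not their shape, so they are built as
axis-aligned boxes: full axial slabs over a rectangular footprint with the
final slab filled from the center outward until the member count equals
`round(V / voxel_volume)`. This hits the requested volume to the nearest
achievable count (723 voxels = 87.97 mm³; 1011 voxels = 123.02 mm³) while
keeping membership trivially auditable. The background VOI uses a thin
3.2 × 7.0 mm footprint so that it fits inside the contralateral hemisphere
of the phantom's brain compartment.

All endpoints are ratios to the background VOI mean (SUVmean/BG,
SUVmax/BG), so the absolute SUV normalization by injected dose and body
weight cancels; an absolute-SUV helper exists but nothing downstream needs
it.

## Phantom model

Each synthetic animal is a piecewise-constant activity field:

* **Brain compartment** — ellipsoid with semi-axes 6.8 × 8.5 × 5.2 mm and
  unit activity. This is deliberately larger than a literal mouse brain:
  it stands for brain plus uniform peritumoral baseline tissue, sized so
  that the 123 mm³ background box and tumors up to ~150 mm³ fit wholly
  inside the uniform compartment (an ellipsoid of literal brain volume
  cannot host the anatomically irregular VOIs of a real hemisphere).
* **Tumor** — sphere at the stereotactic site (1.5 mm right, 1 mm anterior
  of the compartment center) with uptake ratio U relative to brain,
  painted last (it overwrites brain tissue). Cohort defaults draw volumes
  uniformly from 5–150 mm³ (the histologically observed range) and U from
  1.3–3.5 (the plausible FET contrast range).
* **Extracerebral structures** — two Harderian-gland ellipsoids (3× brain
  uptake) anterior to the brain, and an optional frontobasal skull hot
  spot (4×) for spill-in studies. These must not intersect the brain.

The field is blurred with the separable Gaussian system PSF
(FWHM 1.20 × 1.20 × 1.72 mm, the measured resolution of the small-animal
tomograph setup; σ = FWHM / 2√(2 ln 2)) and degraded with pseudo-Poisson
noise: `v → max(0, v + N(0, κ²·v))` with κ = 0.05 by default. The
reconstructed-image noise of the real scanner is unknown, so κ is a free
knob and validation relies on parameter recovery rather than absolute
noise realism. The default grid is a 96 × 96 × 64 crop of the full
256 × 256 × 159 reconstruction matrix: structures keep ≥ 3 PSF sigmas of
boundary margin (enforced), simulations stay fast, and the full grid
remains a configuration option.

**PSF discretization.** The blur kernel is the voxel-integrated Gaussian
(erf differences over voxel extents), not the sampled density. Voxels
integrate activity, so this is the faithful discretization; it conserves
total activity exactly away from the boundary and makes cumulative kernel
sums agree with the Gaussian CDF at voxel boundaries to machine precision
— the property the GTM coefficients inherit. Convolution uses zero
padding; the 3σ margin invariant keeps boundary losses below 0.1%.

What the phantom does **not** emulate: reconstruction artifacts
(OSEM/MAP convergence, correlated noise), attenuation/scatter residuals,
anatomical texture, infiltrative tumor margins, or co-registration error.
Passing tests therefore demonstrate the correctness of the quantification
chain under its own assumptions, not scanner-level accuracy on real mice.

## Spill-in screening

Cranium-bound [18F] fluoride occasionally contaminates the edge of the
universal target VOI. `screen_spill_in` automates the slice-by-slice
manual control: voxels in the outer rim (default width 1) whose SUV/BG
exceeds the interior maximum (factor 1.0) are flagged, and their
26-connected suprathreshold components intersected with the rim form a
*suggested* exclusion mask. Applying it remains an analyst decision,
mirroring manual masking practice. Under noise the screen is intentionally
sensitive (any rim voxel above the interior max); flags are warnings, not
exclusions.

## GTM partial volume correction

For disjoint regions R_1..R_n, blurring each indicator with the PSF and
averaging over every region gives w_ij, the fraction of region j's true
signal observed in region i. Measured means m then satisfy W t = m; t is
recovered with a linear solve (no explicit inverse) and the condition
number is always reported (error above 1e6 by default — thin regions can
make W near-singular). Negative corrected means are flagged as warnings
(tolerating −1e-9 of round-off on zero-activity regions).

The default 8-region mask mirrors the analysis design: the individual
tumor VOI (the optimal/predicted BTV), rest of cerebrum, two Harderian
glands, and four extracerebral boxes (frontal, spinal, superior, basal).
Voxels outside all regions are treated as zero activity; since ~10% of
total activity always diffuses out of the masked regions through the
brain surface, the mandatory coverage diagnostic warns only above 20%.
For noiseless images that are blurred piecewise-constant truth, the
correction is exact up to the solver tolerance; under noise it reduces the
tumor-mean error against the autoradiographic reference to a fraction of
the uncorrected bias (the −26% → −11% structure of the in-vivo result).

## BTV segmentation and the individual-threshold calibration

`segment_btv` includes search-region voxels with value/BG ≥ θ (inclusive,
matching the ≥1.4/1.6/1.8/2.0 notation). "Hot 3D VOI assignment" is read
as the 26-connected suprathreshold component containing the hottest voxel
of the search region; the plain suprathreshold set (`all-voxels`) is
retained for sensitivity analysis. The default search region is the
universal tumor VOI dilated by 2 voxels in-plane and 1 axially — large
enough for tumors outgrowing the VOI, small enough to exclude the
Harderian glands. The background mean always comes from the universal
background VOI, never from a local recomputation.

The optimal individual threshold for a known reference volume is found by
exact enumeration: candidate thresholds are the distinct value/BG ratios
in the search region (plus an empty-volume sentinel), and the candidate
minimizing |V(θ) − V_ref| wins, ties resolving to the smaller θ (the
larger volume — avoids clipping the tumor rim). Because V(θ) is a step
function of the candidates, no approximation gap exists; the search is
verified against brute-force enumeration.

Across a cohort the optimal threshold is nearly linear in SUVmax/BG; the
shipped default calibration is

    θ = 0.3215 · SUVmax/BG + 0.5654

(an 8-animal fit), and `fit_calibration` re-estimates it by OLS with
Pearson ρ and its t-test p-value. Predictions at or below SUV/BG = 1
(x ≲ 1.35 with the default line) trigger a plausibility warning. The
calibration fit in the pipeline includes only animals with
SUVmax/BG ≥ 1.2, mirroring the restriction to PET-positive tumors.

## Cavalieri reference volumetry

Histological reference volumes follow the Cavalieri estimator
V = Σ areas × thickness × interval, with 16 µm sections and every 24th
mounted (spacing 0.384 mm) by default. Mounting every k-th section is
treated as systematic uniform random sampling, so synthetic closed-loop
tests average over the section phase; partial end-sections get no special
handling (unweighted sum). An optional multiplicative shrinkage factor
(default 1.0, i.e. none) is exposed for tissue-preparation shrinkage.
`sample_section_areas` cuts sections from a phantom truth mask so the
pipeline's reference volumes carry the same measurement error as real
stereology.

## Longitudinal growth fitting

Linear, logarithmic (a + b ln t) and quadratic least-squares models are
fitted to (week, BTV) data — per animal or pooled. The selected model is
the one with the highest Pearson correlation between fitted and observed
values (which reduces to |r| for the 2-parameter models); ties within
1e-9 resolve toward fewer parameters, so data exactly on a line select
the linear, not the quadratic, model. The quadratic needs ≥ 4 points and
the logarithmic strictly positive times. Weekly summaries report mean,
sample SD (0 by convention for a single animal), min and max. Group
inference (ANOVA/post-hoc) is out of scope as off-the-shelf statistics.

## The two-round experiment

`run_calibration_round` (n = 8 by default) measures universal-VOI uptake,
determines optimal thresholds against Cavalieri references sampled from
the truth masks at a random phase, and fits the calibration line.
`run_validation_round` (n = 15) applies the fitted line to a fresh cohort
and compares the predicted-threshold BTVs and the four fixed-threshold
BTVs to the references (per-case percent error, group RMSE%, Pearson ρ).
Both rounds are pure functions of the config seed (child seeds are spawned
deterministically), so reports are bit-reproducible.

## Numerical choices and degenerate inputs

* Thresholding is ≥; equal values at the threshold are included.
* Optimal-threshold ties break toward the smaller threshold; argmax ties
  for the hottest voxel break toward the first voxel in array order.
* References smaller than one voxel degrade gracefully (warning, then the
  best single-voxel or empty solution).
* GTM solves refuse condition numbers above 1e6; the partial-slab VOI
  construction orders fill-in voxels by in-plane distance, then index.
* Noise is clamped at zero (activity concentrations cannot be negative);
  at κ = 0.05 the clamping is negligible everywhere except in air.

## Known limitations

* Box VOIs are a geometric idealization of the anatomically drawn VOIs.
* The ellipsoid head model has no skull shell, no ventricles, and
  spherical tumors only; infiltrative margins — exactly the case where
  threshold segmentation is weakest — are not represented.
* The GTM assumes uniform activity within each region; the tumor region
  of the mask is a segmented BTV, so region-model mismatch contributes to
  the corrected values under noise.
* Validation-round accuracy deteriorates for tumors near the detection
  limit (predicted thresholds can exceed the blurred peak, giving empty
  BTVs), which matches the behavior of the in-vivo method for
  PET-negative animals.
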