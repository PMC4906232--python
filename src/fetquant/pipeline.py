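"""End-to-end orchestration of the two-round experimental design on
synthetic cohorts.

Round 1 (calibration): generate a phantom cohort, measure SUVmax/BG in the
universal VOIs, determine each animal's 'optimal' individual threshold
against its Cavalieri reference volume (sampled from the truth mask the
way histological sections are), and fit the linear SUVmax/BG -> threshold
calibration.

Round 2 (validation): on a fresh cohort, predict individual thresholds
from SUVmax/BG alone, segment the BTVs, and compare them — together with
the four predefined clinical thresholds — to the Cavalieri reference
(per-case percent error, group RMSE%, Pearson rho).

Reference volumes are Cavalieri estimates on sampled truth sections, not
raw voxel counts, so the synthetic loop carries the same
reference-measurement error as the animal study. Everything is a pure
function of the config seed.
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import btv as btv_mod
from . import histology, pvec, quant
from .btv import CalibrationModel, STANDARD_THRESHOLDS
from .geometry import VOIMask
from .phantom import (
    DEFAULT_FWHM,
    default_universal_vois,
    generate_cohort,
    make_pvec_regions,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "default_search_region",
    "run_calibration_round",
    "run_validation_round",
    "run_experiment",
]

logger = logging.getLogger("fetquant.pipeline")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a two-round synthetic experiment.

    Defaults mirror the animal study: 8 calibration and 15 validation
    tumors, volumes across the histologically observed range, uptake
    ratios across the plausible FET contrast range, the measured scanner
    FWHM, the four clinical thresholds, and 0.384 mm section spacing.
    ``min_suvmax_bg`` restricts the calibration fit to PET-positive
    animals, as in the study.
    """

    n_calibration: int = 8
    n_validation: int = 15
    volume_range_mm3: tuple[float, float] = (5.0, 150.0)
    uptake_range: tuple[float, float] = (1.3, 3.5)
    noise_kappa: float = 0.05
    fwhm: tuple[float, float, float] = DEFAULT_FWHM
    thresholds: tuple[float, ...] = STANDARD_THRESHOLDS
    section_spacing_mm: float = 0.384
    min_suvmax_bg: float = 1.2
    mode: str = "hot-connected"
    seed: int = 0
    run_pvec: bool = True
    output_dir: str | None = None


@dataclass
class ExperimentReport:
    """Per-animal table plus recomputable group metrics and warnings."""

    table: pd.DataFrame
    metrics: dict
    warnings: list[str] = field(default_factory=list)


def default_search_region(tumor_voi: VOIMask) -> VOIMask:
    """Default BTV search region: the universal tumor VOI dilated by 2
    voxels in-plane and 1 voxel axially — admits tumors outgrowing the
    universal VOI while staying clear of the Harderian glands."""
    dilated = ndimage.binary_dilation(tumor_voi.members, structure=np.ones((5, 5, 3), dtype=bool))
    return VOIMask(tumor_voi.geometry, dilated, label="btv_search")


def _reference_volume(truth, spacing_mm: float, phase_mm: float) -> float:
    series = histology.sample_section_areas(
        truth.masks["tumor"], plane_axis=2, spacing_mm=spacing_mm, phase_mm=phase_mm
    )
    return histology.cavalieri_volume(series)


def _autorad_reference_ratio(truth) -> float:
    """Autoradiographic SUVmean/BG surrogate: slice-wise tumor and
    contralateral means from the unblurred truth field."""
    tumor = truth.masks["tumor"].members
    brain = truth.masks["brain"].members & ~tumor
    vals = truth.truth.values
    tumor_means, bg_means = [], []
    for k in range(vals.shape[2]):
        if tumor[:, :, k].any() and brain[:, :, k].any():
            tumor_means.append(float(vals[:, :, k][tumor[:, :, k]].mean()))
            bg_means.append(float(vals[:, :, k][brain[:, :, k]].mean()))
    if not tumor_means:
        return truth.uptake_ratio
    return quant.autorad_reference(tumor_means, bg_means).suv_mean_bg


def _pvec_tumor_ratio(image, truth, tumor_mask: VOIMask, fwhm) -> tuple[float, float, float]:
    """(corrected tumor/cerebrum ratio, GTM condition number, coverage)."""
    regions = make_pvec_regions(truth, tumor_region=tumor_mask)
    gtm = pvec.compute_gtm(regions, fwhm)
    measured = pvec.measure_region_means(image, regions)
    corrected = pvec.correct_regional_means(measured, gtm)
    idx = {label: i for i, label in enumerate(corrected.labels)}
    ratio = corrected.corrected[idx["tumor"]] / corrected.corrected[idx["cerebrum"]]
    coverage = pvec.coverage_fraction(image, regions)
    return float(ratio), gtm.condition_number, coverage


def _analyze_animal(
    animal_id: int,
    image,
    truth,
    config: ExperimentConfig,
    phase_mm: float,
    warnings_out: list[str],
) -> dict:
    geom = image.geometry
    tumor_voi, bg_voi = default_universal_vois(geom)
    search = default_search_region(tumor_voi)

    stats_u = quant.region_uptake_stats(image, tumor_voi, bg_voi)
    spill = quant.screen_spill_in(image, tumor_voi, bg_voi)
    if len(spill.flagged_voxels):
        warnings_out.append(
            f"animal {animal_id}: {len(spill.flagged_voxels)} rim voxel(s) flagged as possible spill-in"
        )
    reference = _reference_volume(truth, config.section_spacing_mm, phase_mm)

    row = {
        "id": animal_id,
        "true_volume_mm3": truth.true_volume_mm3,
        "uptake_ratio": truth.uptake_ratio,
        "reference_volume_mm3": reference,
        "bg_mean": stats_u.bg_mean,
        "suv_mean_bg": stats_u.suv_mean_bg,
        "suv_max_bg": stats_u.suv_max_bg,
        "spill_in_flags": int(len(spill.flagged_voxels)),
    }
    for theta in config.thresholds:
        res = btv_mod.segment_btv(image, stats_u.bg_mean, theta, search, config.mode)
        row[f"btv_fixed_{theta:g}_mm3"] = res.volume_mm3
    logger.info(
        "animal=%d stage=quant suv_max_bg=%.3f ref_volume=%.2f", animal_id, stats_u.suv_max_bg, reference
    )
    row["_search"] = search
    row["_stats"] = stats_u
    return row


def _add_pvec(row: dict, image, truth, tumor_mask: VOIMask, config: ExperimentConfig, warnings_out: list[str]) -> None:
    if not config.run_pvec:
        return
    tumor_voi, _ = default_universal_vois(image.geometry)
    effective = tumor_mask if tumor_mask.count else tumor_voi
    autorad_ref = _autorad_reference_ratio(truth)
    uncorrected = float(image.values[effective.members & truth.masks["brain"].members].mean()) if (
        effective.members & truth.masks["brain"].members
    ).any() else np.nan
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            ratio, cond, coverage = _pvec_tumor_ratio(image, truth, effective, config.fwhm)
        for c in caught:
            warnings_out.append(f"animal {row['id']}: {c.message}")
    except Exception as exc:  # pragma: no cover - diagnostic path
        warnings_out.append(f"animal {row['id']}: PVEC failed ({exc})")
        row.update(pvec_suv_mean_bg=np.nan, gtm_condition=np.nan, pvec_coverage=np.nan)
        return
    row["autorad_reference_ratio"] = autorad_ref
    row["uncorrected_tumor_mean_bg"] = uncorrected / row["bg_mean"]
    row["pvec_suv_mean_bg"] = ratio
    row["gtm_condition"] = cond
    row["pvec_coverage"] = coverage
    row["error_uncorrected_pct"] = quant.error_percent(row["uncorrected_tumor_mean_bg"], autorad_ref)
    row["error_pvec_pct"] = quant.error_percent(ratio, autorad_ref)
    # ~10% of activity always diffuses out of the masked regions through the
    # brain surface; warn only when substantially more is unmodeled.
    if coverage > 0.20:
        warnings_out.append(f"animal {row['id']}: {coverage:.1%} of activity outside the PVEC regions")


def run_calibration_round(config: ExperimentConfig) -> tuple[CalibrationModel, ExperimentReport]:
    """First experimental round: optimal thresholds and the calibration fit."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cohort_seed = int(rng.integers(0, 2**31 - 1))
    cohort, _ = generate_cohort(
        config.n_calibration,
        config.volume_range_mm3,
        config.uptake_range,
        seed=cohort_seed,
        noise_kappa=config.noise_kappa,
        psf_fwhm=config.fwhm,
    )
    warnings_out: list[str] = []
    rows = []
    for i, (image, truth) in enumerate(cohort):
        phase = float(rng.uniform(0, config.section_spacing_mm))
        row = _analyze_animal(i, image, truth, config, phase, warnings_out)
        theta, result = btv_mod.find_optimal_threshold(
            image, row["_stats"].bg_mean, row["reference_volume_mm3"], row["_search"], config.mode
        )
        row["optimal_threshold"] = theta
        row["optimal_btv_mm3"] = result.volume_mm3
        _add_pvec(row, image, truth, result.mask, config, warnings_out)
        logger.info("animal=%d stage=btv optimal_threshold=%.4f", i, theta)
        rows.append(row)

    table = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")} for r in rows])
    positive = table[table["suv_max_bg"] >= config.min_suvmax_bg]
    if len(positive) < len(table):
        warnings_out.append(
            f"{len(table) - len(positive)} animal(s) below SUVmax/BG {config.min_suvmax_bg} excluded from the fit"
        )
    pairs = list(zip(positive["suv_max_bg"], positive["optimal_threshold"]))
    model = btv_mod.fit_calibration(pairs)

    metrics = {
        "n_pairs": model.n,
        "calibration_slope": model.slope,
        "calibration_intercept": model.intercept,
        "calibration_rho": model.pearson_rho,
        "calibration_p": model.p_value,
    }
    for theta in config.thresholds:
        metrics[f"rmse_fixed_{theta:g}_pct"] = btv_mod.rms_percent_error(
            table[f"btv_fixed_{theta:g}_mm3"], table["reference_volume_mm3"]
        )
    return model, ExperimentReport(table=table, metrics=metrics, warnings=warnings_out)


def run_validation_round(config: ExperimentConfig, model: CalibrationModel) -> ExperimentReport:
    """Second round: predicted individual thresholds vs the fixed thresholds."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cohort_seed = int(rng.integers(0, 2**31 - 1))
    cohort, _ = generate_cohort(
        config.n_validation,
        config.volume_range_mm3,
        config.uptake_range,
        seed=cohort_seed,
        noise_kappa=config.noise_kappa,
        psf_fwhm=config.fwhm,
    )
    warnings_out: list[str] = []
    rows = []
    for i, (image, truth) in enumerate(cohort):
        phase = float(rng.uniform(0, config.section_spacing_mm))
        row = _analyze_animal(i, image, truth, config, phase, warnings_out)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            theta = btv_mod.predict_threshold(row["suv_max_bg"], model)
        for c in caught:
            warnings_out.append(f"animal {i}: {c.message}")
        result = btv_mod.segment_btv(image, row["_stats"].bg_mean, theta, row["_search"], config.mode)
        row["predicted_threshold"] = theta
        row["predicted_btv_mm3"] = result.volume_mm3
        _add_pvec(row, image, truth, result.mask, config, warnings_out)
        logger.info("animal=%d stage=btv predicted_threshold=%.4f btv=%.2f", i, theta, result.volume_mm3)
        rows.append(row)

    table = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")} for r in rows])
    metrics = {
        "rmse_individual_pct": btv_mod.rms_percent_error(
            table["predicted_btv_mm3"], table["reference_volume_mm3"]
        )
    }
    for theta in config.thresholds:
        metrics[f"rmse_fixed_{theta:g}_pct"] = btv_mod.rms_percent_error(
            table[f"btv_fixed_{theta:g}_mm3"], table["reference_volume_mm3"]
        )
    metrics["best_fixed_rmse_pct"] = min(
        metrics[f"rmse_fixed_{theta:g}_pct"] for theta in config.thresholds
    )
    rho, p = stats.pearsonr(table["predicted_btv_mm3"], table["reference_volume_mm3"])
    metrics["pearson_rho_btv_vs_reference"] = float(rho)
    metrics["pearson_p_btv_vs_reference"] = float(p)
    return ExperimentReport(table=table, metrics=metrics, warnings=warnings_out)


def run_experiment(config: ExperimentConfig) -> tuple[CalibrationModel, ExperimentReport, ExperimentReport]:
    """Both rounds; optionally writes report.csv, model.json and metrics.json."""
    model, calibration_report = run_calibration_round(config)
    validation_report = run_validation_round(config, model)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        calibration_report.table.to_csv(out / "calibration_report.csv", index=False)
        validation_report.table.to_csv(out / "validation_report.csv", index=False)
        with open(out / "model.json", "w") as fh:
            json.dump(asdict(model), fh, indent=2)
        with open(out / "metrics.json", "w") as fh:
            json.dump(
                {
                    "calibration": calibration_report.metrics,
                    "validation": validation_report.metrics,
                    "warnings": calibration_report.warnings + validation_report.warnings,
                },
                fh,
                indent=2,
            )
    return model, calibration_report, validation_report
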