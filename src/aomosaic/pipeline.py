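"""End-to-end orchestration: simulate → detect/measure → fit → report.

A run emulates the study design — a cohort of subjects imaged at regularly
spaced temporal eccentricities from the fovea outward — and pushes every
ROI through the full measurement chain: en-face rendering, cell detection,
Voronoi metrics, power-spectrum density, per-cone outer segment length
from a miniature volume, topographic model fits, and inter-session
reliability statistics.  Every stage communicates through serialized CSV /
JSON files so a run can be restarted at any stage, and all randomness
derives from the single seed recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import axial, detection, mosaic_metrics, reliability, synthetic, topography

log = logging.getLogger("aomosaic")

__all__ = ["RunConfig", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run.

    Defaults mirror the study design: 11 subjects, 13 ROIs from the fovea
    to 12° temporal at 1° spacing, cones quantified from 1° outward and RPE
    at every ROI including the fovea.
    """

    n_subjects: int = 11
    eccentricities_deg: tuple = tuple(range(13))
    window_um: float = 250.0
    jitter_frac: float = 0.10
    # rendering / detection
    spot_fwhm_um: float = 3.0
    noise_cv: float = 0.15
    threshold_quantile: float = 0.5
    n_vessels: int = 1
    vessel_width_um: float = 12.0
    # reliability sub-study
    n_repeat_subjects: int = 7
    n_sessions: int = 3
    seed: int = 0
    output_dir: str = "aomosaic_run"
    verbosity: str = "INFO"
    with_volumes: bool = True

    def __post_init__(self) -> None:
        if len(self.eccentricities_deg) == 0:
            raise ValueError("eccentricity list must not be empty")
        self.eccentricities_deg = tuple(sorted(float(e) for e in self.eccentricities_deg))
        if any(e < 0 for e in self.eccentricities_deg):
            raise ValueError("eccentricities must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.threshold_quantile < 1):
            raise ValueError("threshold_quantile must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def cohort_spec(self) -> synthetic.CohortSpec:
        return synthetic.CohortSpec(
            n_subjects=self.n_subjects,
            eccentricities_deg=self.eccentricities_deg,
            window_um=self.window_um,
            jitter_frac=self.jitter_frac,
            seed=self.seed,
        )


def measure_roi(
    roi: dict,
    config: RunConfig,
    rng: np.random.Generator,
    cone_model=synthetic.DEFAULT_CONE_MODEL,
    rpe_model=synthetic.DEFAULT_RPE_MODEL,
) -> dict:
    """Measure one ROI (cone + RPE mosaics, optional volume) end to end.

    Detection and the spectral ring search need a rough density prior; the
    normative topographic model value at the ROI's eccentricity is used
    (never the ROI's own ground truth).
    """
    ecc = roi["eccentricity_deg"]
    row = {"subject": roi["subject"], "eccentricity_deg": ecc}
    excluded = {"vessel_or_boundary": 0, "invalid_osl": 0}

    for cls, mosaic in (("pr", roi.get("cone_mosaic")), ("rpe", roi.get("rpe_mosaic"))):
        if mosaic is None:
            continue
        model_density = (
            float(synthetic.cone_density_model(max(ecc, 1.0), cone_model))
            if cls == "pr"
            else float(synthetic.rpe_density_model(ecc, rpe_model))
        )
        expected_spacing = synthetic.hex_spacing_um(model_density)
        if config.n_vessels and mosaic.vessel_mask is None:
            mosaic.vessel_mask = synthetic.generate_vessel_mask(
                mosaic.window,
                config.n_vessels,
                config.vessel_width_um,
                rng,
                mosaic.pixel_size_um,
            )
        # reflectance spots scale with cell aperture: cap at half the expected
        # spacing so foveal-adjacent cones stay resolved
        fwhm = min(config.spot_fwhm_um, 0.5 * expected_spacing)
        img = synthetic.render_enface(mosaic, fwhm, config.noise_cv, rng)
        det = detection.detect_cells(
            img,
            mosaic.pixel_size_um,
            expected_spacing,
            threshold_quantile=config.threshold_quantile,
            origin_um=(mosaic.window[0], mosaic.window[1]),
        )
        measured = synthetic.CellMosaic(
            points=det.points,
            cell_class=mosaic.cell_class,
            window=mosaic.window,
            pixel_size_um=mosaic.pixel_size_um,
            vessel_mask=mosaic.vessel_mask,
            eccentricity_deg=ecc,
        )
        try:
            metrics, per_cell = mosaic_metrics.voronoi_metrics(measured)
        except mosaic_metrics.InsufficientDataError as exc:
            log.warning("%s %s° %s: %s", roi["subject"], ecc, cls, exc)
            continue
        excluded["vessel_or_boundary"] += len(det) - metrics.n_cells_counted
        row[f"{cls}_density"] = metrics.density_cells_mm2
        row[f"{cls}_spacing"] = metrics.mean_spacing_um
        row[f"{cls}_area"] = metrics.mean_cell_area_um2
        row[f"{cls}_n_cells"] = metrics.n_cells_counted
        if cls == "pr":
            try:
                ps_density, _ = mosaic_metrics.power_spectrum_density(
                    img,
                    mosaic.pixel_size_um,
                    expected_density_mm2=model_density,
                    vessel_mask=mosaic.vessel_mask,
                )
                row["ps_density"] = ps_density
            except (mosaic_metrics.NoRingError, ValueError) as exc:
                log.warning("%s %s° ring: %s", roi["subject"], ecc, exc)

    if roi.get("volume") is not None:
        vol = roi["volume"]
        records = axial.measure_osl(
            vol,
            roi["volume_mosaic"].points,
            search_window_px=axial.outer_retina_window(vol),
        )
        summary = axial.summarize_osl(records)
        excluded["invalid_osl"] = summary["n_total"] - summary["n_valid"]
        row["osl_mean"] = summary["mean_um"]
        row["osl_sd"] = summary["sd_um"]
        row["osl_n"] = summary["n_valid"]
        row["osl_bimodal"] = summary["bimodal"]

    if row.get("pr_density") and row.get("rpe_density"):
        row["pr_rpe_ratio"] = topography.pr_rpe_ratio(row["pr_density"], row["rpe_density"])
    log.info(
        "%s %s°: excluded %d boundary/vessel cells, %d invalid OSL",
        roi["subject"],
        ecc,
        excluded["vessel_or_boundary"],
        excluded["invalid_osl"],
    )
    return row


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full synthetic run; returns the run directory.

    The directory contains ``roi_metrics.csv``, ``ground_truth.csv``,
    ``topography_summary.csv`` + ``topography_fits.json``,
    ``reliability.json`` and a ``manifest.json`` listing every file with
    the parameters and package version.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = config.cohort_spec()
    rois, gt = synthetic.generate_cohort(spec, with_volumes=config.with_volumes)
    gt.write(outdir)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for roi in rois:
        try:
            rows.append(measure_roi(roi, config, rng))
        except Exception as exc:  # keep the run going; log the ROI failure
            log.error("ROI %s %s° failed: %s", roi["subject"], roi["eccentricity_deg"], exc)
    roi_metrics = pd.DataFrame(rows).sort_values(["subject", "eccentricity_deg"])
    roi_metrics.to_csv(outdir / "roi_metrics.csv", index=False)

    summary, fits = topography.build_topography_table(roi_metrics)
    topography.write_topography_report(summary, fits, outdir)

    # inter-session reliability sub-study at the stated within-session CVs
    rel_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rel = {}
    rel_specs = {
        "pr_density": (float(synthetic.cone_density_model(7.5)), 0.016, 0.152),
        "osl": (float(synthetic.osl_model(7.5)), 0.020, 0.072),
        "rpe_density_fovea": (float(synthetic.rpe_density_model(0.0)), 0.023, 0.093),
        "rpe_density_7.5deg": (float(synthetic.rpe_density_model(7.5)), 0.023, 0.093),
    }
    for metric, (true_val, within_cv, between_cv) in rel_specs.items():
        table = synthetic.generate_repeat_sessions(
            true_val,
            k=config.n_sessions,
            within_cv=within_cv,
            n_subjects=config.n_repeat_subjects,
            between_cv=between_cv,
            seed=rel_rng,
        )
        icc = reliability.icc_absolute_agreement_k(table)
        rel[metric] = {
            "icc": icc.to_dict(),
            "normalized_sd": reliability.normalized_sd(table),
            "true_value": true_val,
            "within_cv": within_cv,
        }
        table.to_csv(outdir / f"sessions_{metric}.csv")
    (outdir / "reliability.json").write_text(json.dumps(rel, indent=2))

    try:
        version = _metadata.version("aomosaic")
    except _metadata.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "package_version": version,
        "seed": config.seed,
        "config": asdict(config),
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def report(run_dir: str | Path, show: bool = False) -> Path:
    """Render the human-readable summary figures for a completed run.

    Produces per-metric eccentricity panels (cohort mean ± SD with fit
    overlays read from the serialized fit block) and a reliability dot
    plot.  Raises if a required stage output is missing, naming it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    needed = ["topography_summary.csv", "topography_fits.json", "reliability.json"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing stage output: {name}")

    summary = pd.read_csv(run_dir / "topography_summary.csv")
    fits = json.loads((run_dir / "topography_fits.json").read_text())
    rel = json.loads((run_dir / "reliability.json").read_text())

    panels = [
        ("pr_density", "Cone density (cells/mm²)"),
        ("rpe_density", "RPE density (cells/mm²)"),
        ("osl_mean", "Outer segment length (µm)"),
        ("pr_rpe_ratio", "Cone/RPE ratio"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (metric, label) in zip(axes.ravel(), panels):
        sub = summary[summary["metric"] == metric].sort_values("eccentricity_deg")
        if sub.empty:
            ax.set_visible(False)
            continue
        e = sub["eccentricity_deg"]
        has_sd = sub["sd"].gt(0).any()
        ax.errorbar(e, sub["mean"], yerr=sub["sd"] if has_sd else None, fmt="ko", ms=4)
        if metric in fits:
            f = fits[metric]
            fit = topography.TopographyFit(
                f["model"], tuple(f["coefficients"]), f["r2_pearson"],
                f["r2_spearman"], f["p_value"], f["n"],
            )
            ee = np.linspace(max(e.min(), 0.25), e.max(), 200)
            if f["model"] == "power":
                ee = ee[ee >= 1]
            ax.plot(ee, fit.predict(ee), "k-", lw=1)
        ax.set_xlabel("Eccentricity (deg, temporal)")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(run_dir / "topography_panels.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(rel)
    iccs = [rel[m]["icc"]["estimate"] for m in names]
    lo = [rel[m]["icc"]["ci_low"] for m in names]
    hi = [rel[m]["icc"]["ci_high"] for m in names]
    ax.errorbar(
        iccs,
        range(len(names)),
        xerr=[np.array(iccs) - lo, np.array(hi) - iccs],
        fmt="o",
        color="k",
    )
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(names)
    ax.set_xlabel("ICC(A,k)")
    ax.set_xlim(0, 1.05)
    fig.tight_layout()
    fig.savefig(run_dir / "reliability_dots.png", dpi=150)
    plt.close(fig)
    return run_dir
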