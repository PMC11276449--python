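"""Eccentricity relationships of the photoreceptor–RPE complex.

Cone density follows a power law D = a·E^b with temporal eccentricity E
(degrees), RPE density declines linearly, per-cone outer segment length
follows a second-order polynomial, and the cone/RPE ratio again follows a
power law.  This module fits those families to per-eccentricity cohort
means and reports both Pearson and Spearman squared correlations between
observed and fitted values (conventions in the literature differ on which
is quoted, so both are labeled explicitly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["TopographyFit", "fit_model", "pr_rpe_ratio", "build_topography_table"]

_MODELS = ("power", "linear", "poly2")


@dataclass
class TopographyFit:
    """A fitted eccentricity model with goodness-of-fit."""

    model: str  # power | linear | poly2
    coefficients: tuple  # power: (a, b); linear: (intercept, slope); poly2: (c0, c1, c2)
    r2_pearson: float
    r2_spearman: float
    p_value: float
    n: int
    r2_spearman_raw: float = np.nan  # Spearman² of y on E directly
    degenerate: bool = False

    def predict(self, ecc_deg) -> np.ndarray:
        e = np.asarray(ecc_deg, dtype=float)
        if self.model == "power":
            a, b = self.coefficients
            return a * e**b
        if self.model == "linear":
            c0, c1 = self.coefficients
            return c0 + c1 * e
        c0, c1, c2 = self.coefficients
        return c0 + c1 * e + c2 * e**2

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coefficients": [float(c) for c in self.coefficients],
            "r2_pearson": float(self.r2_pearson),
            "r2_spearman": float(self.r2_spearman),
            "r2_spearman_raw": float(self.r2_spearman_raw),
            "p_value": float(self.p_value),
            "n": self.n,
            "degenerate": self.degenerate,
        }


def fit_model(ecc_deg, values, model: str) -> TopographyFit:
    """Least-squares fit of a density/length–eccentricity relationship.

    ``power`` fits y = a·E^b by nonlinear least squares initialized from a
    log–log regression (requires E > 0 and y > 0); ``linear`` and ``poly2``
    are ordinary polynomial least squares.  Goodness of fit is reported as
    the squared Pearson and squared Spearman correlation between observed
    and predicted values, with the two-sided p-value of the Pearson
    correlation.
    """
    e = np.asarray(ecc_deg, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(e) & np.isfinite(y)
    e, y = e[keep], y[keep]
    n = len(e)
    min_n = {"power": 3, "linear": 3, "poly2": 4}
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    if n < min_n[model]:
        raise ValueError(f"{model} fit needs >= {min_n[model]} points, got {n}")
    if len(np.unique(e)) < min_n[model]:
        raise ValueError("rank-deficient design: too few distinct eccentricities")

    if model == "power":
        if np.any(e <= 0) or np.any(y <= 0):
            raise ValueError("power model requires strictly positive E and y")
        slope, intercept = np.polyfit(np.log(e), np.log(y), 1)
        p0 = (np.exp(intercept), slope)
        coeffs, _ = optimize.curve_fit(lambda x, a, b: a * x**b, e, y, p0=p0, maxfev=10000)
        coeffs = tuple(float(c) for c in coeffs)
    elif model == "linear":
        c1, c0 = np.polyfit(e, y, 1)
        coeffs = (float(c0), float(c1))
    else:
        c2, c1, c0 = np.polyfit(e, y, 2)
        coeffs = (float(c0), float(c1), float(c2))

    fit = TopographyFit(model, coeffs, np.nan, np.nan, np.nan, n)
    pred = fit.predict(e)

    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        # constant data (or constant prediction): correlation undefined
        fit.degenerate = True
        return fit
    rp = stats.pearsonr(y, pred)
    rs = stats.spearmanr(y, pred)
    rs_raw = stats.spearmanr(y, e)
    fit.r2_pearson = float(rp.statistic**2)
    fit.r2_spearman = float(rs.statistic**2)
    fit.r2_spearman_raw = float(rs_raw.statistic**2)
    fit.p_value = float(rp.pvalue)
    return fit


def pr_rpe_ratio(pr_density, rpe_density):
    """Elementwise cone-to-RPE density ratio (cones per RPE cell)."""
    pr = np.asarray(pr_density, dtype=float)
    rpe = np.asarray(rpe_density, dtype=float)
    if np.any(rpe <= 0):
        raise ValueError("RPE density must be positive")
    out = pr / rpe
    return float(out) if out.ndim == 0 else out


def build_topography_table(
    roi_metrics: pd.DataFrame,
    fit_cone_from_deg: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, TopographyFit]]:
    """Cohort topography summary and model fits from per-ROI metrics.

    ``roi_metrics`` is a long table with at least the columns ``subject``,
    ``eccentricity_deg`` and any of ``pr_density``, ``rpe_density``,
    ``osl_mean``, ``pr_rpe_ratio``.  The summary gives the per-eccentricity
    cohort mean ± SD of each metric; fits use the standard family per
    metric: power for cone density and cone/RPE ratio (restricted to
    E ≥ ``fit_cone_from_deg``), linear for RPE density, second-order
    polynomial for OSL.  The ratio is fitted on per-subject ratios averaged
    per eccentricity (mean of ratios); the ratio of cohort mean densities
    is reported alongside in the summary.
    """
    df = roi_metrics.copy()
    if df["subject"].nunique() < 2:
        pass  # single-subject runs are allowed; SD columns will be 0/NaN
    if df["eccentricity_deg"].nunique() < 4:
        raise ValueError("need at least 4 eccentricities for the model fits")

    metrics = [
        c
        for c in ("pr_density", "rpe_density", "osl_mean", "pr_rpe_ratio", "ps_density")
        if c in df.columns
    ]
    if "pr_rpe_ratio" not in df.columns and {"pr_density", "rpe_density"} <= set(df.columns):
        df["pr_rpe_ratio"] = pr_rpe_ratio(
            df["pr_density"].to_numpy(), df["rpe_density"].to_numpy()
        )
        metrics.append("pr_rpe_ratio")

    rows = []
    for ecc, grp in df.groupby("eccentricity_deg"):
        for m in metrics:
            vals = grp[m].dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "metric": m,
                    "eccentricity_deg": float(ecc),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            )
    summary = pd.DataFrame(rows).sort_values(["metric", "eccentricity_deg"]).reset_index(drop=True)

    # ratio of cohort mean densities, for comparison with the mean of ratios
    piv = summary.pivot(index="eccentricity_deg", columns="metric", values="mean")
    if {"pr_density", "rpe_density"} <= set(piv.columns):
        rom = piv["pr_density"] / piv["rpe_density"]
        rom_rows = pd.DataFrame(
            {
                "metric": "pr_rpe_ratio_of_means",
                "eccentricity_deg": rom.index,
                "mean": rom.to_numpy(),
                "sd": np.nan,
                "n": np.nan,
            }
        ).dropna(subset=["mean"])
        summary = pd.concat([summary, rom_rows], ignore_index=True)

    fits: dict[str, TopographyFit] = {}
    mean_of = lambda m: summary[summary["metric"] == m].sort_values("eccentricity_deg")

    spec = {
        "pr_density": ("power", True),
        "pr_rpe_ratio": ("power", True),
        "rpe_density": ("linear", False),
        "osl_mean": ("poly2", True),
    }
    for metric, (family, cone_range) in spec.items():
        sub = mean_of(metric)
        if sub.empty:
            continue
        e = sub["eccentricity_deg"].to_numpy()
        y = sub["mean"].to_numpy()
        if cone_range:
            sel = e >= fit_cone_from_deg
            e, y = e[sel], y[sel]
        try:
            fits[metric] = fit_model(e, y, family)
        except ValueError:
            continue
    return summary, fits


def write_topography_report(
    summary: pd.DataFrame, fits: dict[str, TopographyFit], directory: str | Path
) -> None:
    """Serialize the cohort summary (CSV) and fit block (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary.to_csv(directory / "topography_summary.csv", index=False)
    (directory / "topography_fits.json").write_text(
        json.dumps({k: f.to_dict() for k, f in fits.items()}, indent=2)
    )
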