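"""Reproducibility and agreement statistics.

Inter-session reproducibility of a metric measured on the same subjects in
k sessions is summarized by the intraclass correlation coefficient for
absolute agreement of averaged measurements, ICC(A,k) in the McGraw–Wong
taxonomy, computed from the two-way ANOVA mean squares

    ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)

with rows = subjects (MS_R), columns = sessions (MS_C), and error MS_E.
Confidence intervals use the standard F-based interval.  Inter-grader
agreement of paired measurements is summarized by Lin's concordance
correlation coefficient, and session scatter by the mean per-subject
coefficient of variation (SD across sessions normalized to the subject
mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "icc_absolute_agreement_k",
    "lin_ccc",
    "normalized_sd",
    "reliability_label",
    "anova_mean_squares",
]


@dataclass
class ReliabilityResult:
    """A reliability estimate with its confidence interval and method label."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n: int
    label: str | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": float(self.estimate),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "method": self.method,
            "n": self.n,
            "label": self.label,
        }


def reliability_label(icc: float) -> str:
    """Conventional qualitative reliability bands for an ICC."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def _as_matrix(table) -> np.ndarray:
    data = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(
        table, dtype=float
    )
    if data.ndim != 2:
        raise ValueError("session table must be 2-D (subjects × sessions)")
    if np.any(~np.isfinite(data)):
        raise ValueError("session table must be complete (no missing cells)")
    return data


def anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (rows × columns, no replication) ANOVA mean squares.

    Returns (MS_rows, MS_cols, MS_error).
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_err)


def icc_absolute_agreement_k(table, confidence: float = 0.95) -> ReliabilityResult:
    """ICC for absolute agreement of k-session average measurements, ICC(A,k).

    ``table`` is a complete subjects × sessions matrix (DataFrame or array)
    with at least 3 subjects.  The F-based confidence interval follows the
    single-rater interval with a Spearman–Brown step-up to k raters.
    """
    data = _as_matrix(table)
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 sessions")
    msr, msc, mse = anova_mean_squares(data)
    denom = msr + (msc - mse) / n
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    icc_k = (msr - mse) / denom

    # F-based CI for ICC(A,1), then Spearman-Brown to the k-average form
    alpha = 1.0 - confidence
    icc_1_den = msr + (k - 1) * mse + k * (msc - mse) / n
    ci_low = ci_high = np.nan
    if icc_1_den > 0 and mse >= 0:
        icc_1 = (msr - mse) / icc_1_den
        a = k * icc_1 / (n * (1 - icc_1)) if icc_1 < 1 else np.inf
        b = 1 + k * icc_1 * (n - 1) / (n * (1 - icc_1)) if icc_1 < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
            l1 = n * (msr - f_u * mse) / (
                f_u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            u1 = n * (f_l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_l * msr
            )
            ci_low = l1 * k / (1 + l1 * (k - 1))
            ci_high = u1 * k / (1 + u1 * (k - 1))
        elif icc_1 >= 1:
            ci_low = ci_high = 1.0

    return ReliabilityResult(
        estimate=float(icc_k),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        method=f"ICC-A,{k}",
        n=n,
        label=reliability_label(icc_k),
    )


def lin_ccc(x, y, confidence: float = 0.95) -> ReliabilityResult:
    """Lin's concordance correlation coefficient between paired raters.

    ρc = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (n-divisor)
    moments; the confidence interval uses the Fisher z transform with the
    large-sample standard error of ẑ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx2 = np.var(x)
    sy2 = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("zero variance in both raters: concordance undefined")
    rho_c = 2 * sxy / denom

    ci_low = ci_high = np.nan
    if sx2 > 0 and sy2 > 0 and abs(rho_c) < 1:
        r = sxy / np.sqrt(sx2 * sy2)
        u = (x.mean() - y.mean()) / (sx2 * sy2) ** 0.25
        z = np.arctanh(rho_c)
        # Lin (1989) large-sample variance of the z-transformed estimate
        se_z = np.sqrt(
            (
                (1 - r**2) * rho_c**2 / ((1 - rho_c**2) * r**2)
                + 2 * rho_c**3 * (1 - rho_c) * u**2 / (r * (1 - rho_c**2) ** 2)
                - rho_c**4 * u**4 / (2 * r**2 * (1 - rho_c**2) ** 2)
            )
            / (n - 2)
        )
        zc = stats.norm.ppf(1 - (1 - confidence) / 2)
        ci_low = float(np.tanh(z - zc * se_z))
        ci_high = float(np.tanh(z + zc * se_z))

    return ReliabilityResult(
        estimate=float(rho_c),
        ci_low=ci_low,
        ci_high=ci_high,
        method="LCC",
        n=n,
    )


def normalized_sd(table) -> float:
    """Mean per-subject coefficient of variation across sessions.

    For each subject, the SD of its session measurements divided by its
    mean; averaged over subjects with equal weights.  Scale-invariant.
    """
    data = _as_matrix(table)
    means = data.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("zero subject mean: normalized SD undefined")
    sds = data.std(axis=1, ddof=1)
    return float(np.mean(sds / means))


def reliability_report_from_long(df: pd.DataFrame, confidence: float = 0.95) -> dict:
    """Reliability summary from a long table (subject, session, metric, value).

    Returns a dict keyed by metric with the ICC(A,k) result and the
    normalized SD.
    """
    out = {}
    for metric, grp in df.groupby("metric"):
        table = grp.pivot(index="subject", columns="session", values="value")
        icc = icc_absolute_agreement_k(table, confidence)
        out[metric] = {
            "icc": icc.to_dict(),
            "normalized_sd": normalized_sd(table),
            "k": int(table.shape[1]),
            "n_subjects": int(table.shape[0]),
        }
    return out
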