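"""Synthetic photoreceptor / RPE mosaics, en-face images and outer-retina volumes.

The generators here emulate the statistical structure of averaged AO-OCT
data of the photoreceptor–RPE complex, with ground truth recorded so every
downstream stage (cell detection, Voronoi metrics, outer-segment-length
measurement, topographic fits, reproducibility statistics) can be validated
by parameter recovery.

Cell mosaics are jittered hexagonal lattices rather than Poisson point
processes: cone and RPE mosaics are quasi-crystalline, and only a
quasi-regular arrangement produces the annular spectral peak (Yellott's
ring) that the power-spectrum density estimator relies on.

Default topographic models (all eccentricities E in degrees, temporal):

* cone density  D_pr(E)  = 53,329 · E^(−0.731)   cells/mm²   (valid E ≥ 1)
* RPE density   D_rpe(E) = 6,913 − 123 · E        cells/mm²
* outer segment length  OSL(E) = c0 + c1·E + c2·E²  µm, monotone decreasing
  on [1°, 12°] through 33.3 µm at 1° and 18.0 µm at 12°.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CellMosaic",
    "CohortSpec",
    "GroundTruth",
    "generate_mosaic",
    "generate_vessel_mask",
    "render_enface",
    "render_volume",
    "generate_cohort",
    "generate_repeat_sessions",
    "cone_density_model",
    "rpe_density_model",
    "osl_model",
    "DEFAULT_CONE_MODEL",
    "DEFAULT_RPE_MODEL",
    "DEFAULT_OSL_MODEL",
    "hex_spacing_um",
    "write_mosaic_csv",
    "read_mosaic_csv",
]

# ---------------------------------------------------------------------------
# Topographic model defaults (cells/mm², µm; E in degrees temporal)
# ---------------------------------------------------------------------------

#: Power-law (a, b) of cone density a·E^b; b anchored at the 1° and 12° means.
DEFAULT_CONE_MODEL = (53329.0, -0.731)

#: Linear (intercept, slope) of RPE density with eccentricity.
DEFAULT_RPE_MODEL = (6913.0, -123.0)


def _fit_default_osl_poly() -> tuple[float, float, float]:
    # Second-order polynomial through (1°, 33.3 µm) and (12°, 18.0 µm) with the
    # derivative vanishing at 12° — the minimal monotone-decreasing choice on
    # [1°, 12°] (decline steep near the fovea, flattening in the periphery).
    c2 = (33.3 - 18.0) / 121.0
    c1 = -24.0 * c2
    c0 = 33.3 - c1 - c2
    return (c0, c1, c2)


#: Polynomial (c0, c1, c2) of OSL in µm.
DEFAULT_OSL_MODEL = _fit_default_osl_poly()


def cone_density_model(ecc_deg, coeffs=DEFAULT_CONE_MODEL):
    """Cone density (cells/mm²) at eccentricity ``ecc_deg`` (power law)."""
    a, b = coeffs
    return a * np.asarray(ecc_deg, dtype=float) ** b


def rpe_density_model(ecc_deg, coeffs=DEFAULT_RPE_MODEL):
    """RPE density (cells/mm²) at eccentricity ``ecc_deg`` (linear)."""
    intercept, slope = coeffs
    return intercept + slope * np.asarray(ecc_deg, dtype=float)


def osl_model(ecc_deg, coeffs=DEFAULT_OSL_MODEL):
    """Mean outer segment length (µm) at eccentricity ``ecc_deg`` (poly2)."""
    c0, c1, c2 = coeffs
    e = np.asarray(ecc_deg, dtype=float)
    return c0 + c1 * e + c2 * e**2


def hex_spacing_um(density_cells_mm2: float) -> float:
    """Center-to-center spacing of a perfect hexagonal mosaic at a density.

    Inverts D = 2 / (√3 · a²) with D in cells/µm².
    """
    d_um2 = density_cells_mm2 * 1e-6
    return float(np.sqrt(2.0 / (np.sqrt(3.0) * d_um2)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CellMosaic:
    """A 2-D cell-center point set with physical scale.

    ``points`` is an (N, 2) array of (x, y) positions in µm inside the
    rectangular ``window`` (xmin, ymin, xmax, ymax, µm).  ``vessel_mask`` is
    an optional boolean raster at ``pixel_size_um`` pitch (True = excluded).
    """

    points: np.ndarray
    cell_class: str  # "cone" | "rpe"
    window: tuple[float, float, float, float]
    pixel_size_um: float = 1.0
    vessel_mask: np.ndarray | None = None
    eccentricity_deg: float = 0.0
    true_density_cells_mm2: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.cell_class not in ("cone", "rpe"):
            raise ValueError("cell_class must be 'cone' or 'rpe'")
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValueError("window must have positive extent")
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity_deg must be >= 0")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if x.min() < x0 or x.max() > x1 or y.min() < y0 or y.max() > y1:
                raise ValueError("all points must lie inside the window")

    @property
    def window_area_mm2(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0) * 1e-6

    @property
    def raster_shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.window
        return (
            int(round((y1 - y0) / self.pixel_size_um)),
            int(round((x1 - x0) / self.pixel_size_um)),
        )


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Between-subject variability is a per-metric multiplicative lognormal
    coefficient of variation; within-session CVs drive the repeat-session
    tables.  Defaults mirror an 11-subject design sampled at 13 ROIs from
    the fovea to 12° temporal, with cohort spreads matching the normative
    1° means (cone 8106/53329, RPE 681/7335, OSL 2.4/33.3).
    """

    n_subjects: int = 11
    eccentricities_deg: Sequence[float] = tuple(range(13))
    cone_model: tuple[float, float] = DEFAULT_CONE_MODEL
    rpe_model: tuple[float, float] = DEFAULT_RPE_MODEL
    osl_model: tuple[float, float, float] = DEFAULT_OSL_MODEL
    between_subject_cv: dict = field(
        default_factory=lambda: {"pr_density": 0.152, "rpe_density": 0.093, "osl": 0.072}
    )
    within_session_cv: dict = field(
        default_factory=lambda: {"pr_density": 0.016, "osl": 0.020, "rpe_density": 0.023}
    )
    window_um: float = 250.0
    jitter_frac: float = 0.10
    osl_cell_sd_um: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.eccentricities_deg) == 0:
            raise ValueError("eccentricity list must be non-empty")
        if any(v < 0 for v in self.between_subject_cv.values()):
            raise ValueError("between_subject_cv entries must be >= 0")
        if any(v < 0 for v in self.within_session_cv.values()):
            raise ValueError("within_session_cv entries must be >= 0")
        if self.cone_model[1] >= 0:
            raise ValueError("cone power-law exponent must be negative")
        if self.rpe_model[1] >= 0:
            raise ValueError("RPE density slope must be negative")


@dataclass
class GroundTruth:
    """True per-ROI values behind a generated cohort, for recovery testing."""

    table: pd.DataFrame  # columns: subject, eccentricity_deg, true_pr_density, ...
    seed: int
    params: dict

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "ground_truth.csv", index=False)
        manifest = {"seed": self.seed, "params": self.params}
        (directory / "ground_truth_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_jsonable)
        )

    @classmethod
    def read(cls, directory: str | Path) -> "GroundTruth":
        directory = Path(directory)
        table = pd.read_csv(directory / "ground_truth.csv")
        manifest = json.loads((directory / "ground_truth_manifest.json").read_text())
        return cls(table=table, seed=manifest["seed"], params=manifest["params"])


def _jsonable(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Mosaic generation
# ---------------------------------------------------------------------------


def generate_mosaic(
    density_cells_mm2: float,
    window: tuple[float, float, float, float] | float,
    jitter_frac: float = 0.10,
    seed: int | np.random.Generator = 0,
    cell_class: str = "cone",
    eccentricity_deg: float = 0.0,
    pixel_size_um: float = 1.0,
) -> CellMosaic:
    """Generate a jittered-hexagonal cell mosaic at a target density.

    Points are laid on a hexagonal lattice with spacing ``a = √(2/(√3·D))``,
    rotated by a seeded uniform random angle, and perturbed by isotropic
    Gaussian jitter of standard deviation ``jitter_frac · a``.

    Parameters
    ----------
    density_cells_mm2
        Target density in cells/mm²; the realized interior density is within
        ~3% for windows of 0.25 × 0.25 mm and larger.
    window
        (xmin, ymin, xmax, ymax) in µm, or a scalar side length for a square
        window anchored at the origin.
    jitter_frac
        Jitter SD as a fraction of the lattice spacing (0 = perfect lattice).
    seed
        Integer seed or a numpy Generator.
    """
    if np.isscalar(window):
        window = (0.0, 0.0, float(window), float(window))
    x0, y0, x1, y1 = window
    if density_cells_mm2 <= 0:
        raise ValueError("density must be positive")
    area_mm2 = (x1 - x0) * (y1 - y0) * 1e-6
    if density_cells_mm2 * area_mm2 < 20:
        raise ValueError(
            f"window too small: expected {density_cells_mm2 * area_mm2:.1f} cells (< 20)"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    a = hex_spacing_um(density_cells_mm2)
    row_pitch = a * np.sqrt(3.0) / 2.0
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    half_diag = 0.5 * np.hypot(x1 - x0, y1 - y0) + 3 * a

    n_cols = int(np.ceil(2 * half_diag / a)) + 2
    n_rows = int(np.ceil(2 * half_diag / row_pitch)) + 2
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    xs = (jj + 0.5 * (ii % 2)) * a - half_diag
    ys = ii * row_pitch - half_diag
    pts = np.column_stack([xs.ravel(), ys.ravel()])

    theta = rng.uniform(0, np.pi / 3)  # hex lattice has 60° symmetry
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = pts @ rot.T + [cx, cy]

    if jitter_frac > 0:
        pts = pts + rng.normal(0.0, jitter_frac * a, size=pts.shape)

    inside = (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
    return CellMosaic(
        points=pts[inside],
        cell_class=cell_class,
        window=window,
        pixel_size_um=pixel_size_um,
        eccentricity_deg=eccentricity_deg,
        true_density_cells_mm2=density_cells_mm2,
    )


def generate_vessel_mask(
    window: tuple[float, float, float, float] | float,
    n_vessels: int,
    width_um: float,
    seed: int | np.random.Generator = 0,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Boolean raster marking vessel-shadow bands to exclude (True = excluded).

    Each vessel is a smooth curvilinear band: a straight chord across the
    window with a low-frequency sinusoidal meander, dilated to ``width_um``.
    """
    if np.isscalar(window):
        window = (0.0, 0.0, float(window), float(window))
    x0, y0, x1, y1 = window
    w_px = int(round((x1 - x0) / pixel_size_um))
    h_px = int(round((y1 - y0) / pixel_size_um))
    if width_um >= min(x1 - x0, y1 - y0):
        raise ValueError("vessel width must be smaller than the window extent")
    mask = np.zeros((h_px, w_px), dtype=bool)
    if n_vessels == 0:
        return mask
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    centerline = np.zeros((h_px, w_px), dtype=bool)
    diag = np.hypot(w_px, h_px)
    for _ in range(n_vessels):
        theta = rng.uniform(0, np.pi)
        # anchor point somewhere in the window interior
        ax = rng.uniform(0.2, 0.8) * w_px
        ay = rng.uniform(0.2, 0.8) * h_px
        amp = rng.uniform(0.0, 0.06) * diag
        freq = rng.uniform(0.5, 1.5) * 2 * np.pi / diag
        phase = rng.uniform(0, 2 * np.pi)
        t = np.linspace(-diag, diag, int(4 * diag))
        dx, dy = np.cos(theta), np.sin(theta)
        # meander perpendicular to the chord direction
        off = amp * np.sin(freq * t + phase)
        px = ax + dx * t - dy * off
        py = ay + dy * t + dx * off
        ok = (px >= 0) & (px < w_px) & (py >= 0) & (py < h_px)
        centerline[py[ok].astype(int), px[ok].astype(int)] = True

    dist = ndimage.distance_transform_edt(~centerline, sampling=pixel_size_um)
    mask = dist <= width_um / 2.0
    return mask


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _splat_gaussians(
    shape: tuple[int, int],
    points_px: np.ndarray,
    sigma_px: float,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of unit-peak Gaussian spots at subpixel positions (vectorized stamps)."""
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    r = max(1, int(np.ceil(3 * sigma_px)))
    if amplitudes is None:
        amplitudes = np.ones(len(points_px))
    for (px, py), amp in zip(points_px, amplitudes):
        ix, iy = int(round(px)), int(round(py))
        xlo, xhi = max(ix - r, 0), min(ix + r + 1, w)
        ylo, yhi = max(iy - r, 0), min(iy + r + 1, h)
        if xlo >= xhi or ylo >= yhi:
            continue
        xs = np.arange(xlo, xhi) - px
        ys = np.arange(ylo, yhi) - py
        img[ylo:yhi, xlo:xhi] += amp * np.outer(
            np.exp(-(ys**2) / (2 * sigma_px**2)), np.exp(-(xs**2) / (2 * sigma_px**2))
        )
    return img


def render_enface(
    mosaic: CellMosaic,
    spot_fwhm_um: float = 3.0,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    vessel_attenuation: float = 0.15,
) -> np.ndarray:
    """Render a mosaic as a 2-D en-face intensity image in [0, 1].

    Each cell contributes a Gaussian spot of the given FWHM at its center;
    vessel-mask regions are attenuated, and multiplicative lognormal speckle
    of coefficient of variation ``noise_cv`` is applied.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h, w = mosaic.raster_shape
    sigma_px = spot_fwhm_um / 2.355 / mosaic.pixel_size_um
    if sigma_px < 0.5:
        import warnings

        warnings.warn(
            "raster pixel larger than spot FWHM; spots will be undersampled", stacklevel=2
        )
    x0, y0, _, _ = mosaic.window
    pts_px = (mosaic.points - [x0, y0]) / mosaic.pixel_size_um
    img = _splat_gaussians((h, w), pts_px, sigma_px)

    if mosaic.vessel_mask is not None:
        img = np.where(mosaic.vessel_mask, img * vessel_attenuation, img)

    if noise_cv > 0:
        sigma_log = np.sqrt(np.log(1 + noise_cv**2))
        img = img * rng.lognormal(-(sigma_log**2) / 2, sigma_log, size=img.shape)

    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


def render_volume(
    cone_mosaic: CellMosaic,
    osl_um: float | np.ndarray = 30.0,
    isos_depth_um: float = 40.0,
    rpe_depth_um: float = 90.0,
    axial_pixel_um: float = 1.0,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    osl_sd_um: float = 0.0,
    depth_um: float | None = None,
    axial_fwhm_um: float = 8.4,
    spot_fwhm_um: float = 3.0,
    cone_amplitude: float = 1.0,
    rpe_amplitude: float = 2.0,
    tilt_um: np.ndarray | Callable | None = None,
):
    """Render a miniature outer-retina volume for a cone mosaic.

    Each cone contributes a pair of axial Gaussian reflections — the IS/OS
    junction at ``isos_depth_um`` and the outer segment tip (COST) at
    ``isos_depth_um + OSL`` — localized laterally at its position; a
    continuous reflective band (the RPE) lies deeper at ``rpe_depth_um``.
    Per-cone OSL may be a scalar plus i.i.d. Gaussian scatter (``osl_sd_um``)
    or an explicit per-cone array.  ``tilt_um`` is an optional per-column
    axial displacement field (array of shape (ny, nx) or callable of x,y in
    µm) used to exercise volume flattening.

    Returns
    -------
    (volume, true_osl_um)
        ``volume`` is an :class:`~aomosaic.axial.AOVolume`; ``true_osl_um``
        the per-cone ground-truth outer segment lengths.
    """
    from .axial import AOVolume  # local import to avoid a hard cycle

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(cone_mosaic.points)
    osl = np.broadcast_to(np.asarray(osl_um, dtype=float), (n,)).copy()
    if osl_sd_um > 0:
        osl = osl + rng.normal(0.0, osl_sd_um, size=n)
    if np.any(isos_depth_um + osl >= rpe_depth_um):
        raise ValueError("layer order violated: IS/OS + OSL must lie above the RPE band")
    if np.any(osl <= 0):
        raise ValueError("outer segment lengths must be positive")
    if axial_pixel_um <= 0:
        raise ValueError("axial_pixel_um must be positive")

    if depth_um is None:
        depth_um = rpe_depth_um + 4 * axial_fwhm_um
    nz = int(round(depth_um / axial_pixel_um))
    h, w = cone_mosaic.raster_shape
    vol = np.zeros((nz, h, w), dtype=float)

    x0, y0, _, _ = cone_mosaic.window
    pts_px = (cone_mosaic.points - [x0, y0]) / cone_mosaic.pixel_size_um
    z_axis = np.arange(nz) * axial_pixel_um
    sig_z = axial_fwhm_um / 2.355
    sig_xy = spot_fwhm_um / 2.355 / cone_mosaic.pixel_size_um
    r = max(1, int(np.ceil(3 * sig_xy)))

    if tilt_um is None:
        tilt_map = np.zeros((h, w))
    elif callable(tilt_um):
        xx = x0 + (np.arange(w) + 0.5) * cone_mosaic.pixel_size_um
        yy = y0 + (np.arange(h) + 0.5) * cone_mosaic.pixel_size_um
        tilt_map = np.asarray(tilt_um(*np.meshgrid(xx, yy)))
    else:
        tilt_map = np.asarray(tilt_um, dtype=float)
        if tilt_map.shape != (h, w):
            raise ValueError("tilt_um array must match the lateral raster shape")

    for i, (px, py) in enumerate(pts_px):
        ix, iy = int(round(px)), int(round(py))
        xlo, xhi = max(ix - r, 0), min(ix + r + 1, w)
        ylo, yhi = max(iy - r, 0), min(iy + r + 1, h)
        if xlo >= xhi or ylo >= yhi:
            continue
        xs = np.arange(xlo, xhi) - px
        ys = np.arange(ylo, yhi) - py
        lat = np.outer(
            np.exp(-(ys**2) / (2 * sig_xy**2)), np.exp(-(xs**2) / (2 * sig_xy**2))
        )
        dz = tilt_map[min(max(iy, 0), h - 1), min(max(ix, 0), w - 1)]
        ax_profile = np.exp(
            -((z_axis - (isos_depth_um + dz)) ** 2) / (2 * sig_z**2)
        ) + np.exp(-((z_axis - (isos_depth_um + osl[i] + dz)) ** 2) / (2 * sig_z**2))
        vol[:, ylo:yhi, xlo:xhi] += cone_amplitude * ax_profile[:, None, None] * lat[None]

    # continuous RPE band, brightest layer of the complex
    rpe_z = rpe_depth_um + tilt_map  # (h, w)
    band = rpe_amplitude * np.exp(
        -((z_axis[:, None, None] - rpe_z[None]) ** 2) / (2 * sig_z**2)
    )
    vol += band

    if noise_cv > 0:
        sigma_log = np.sqrt(np.log(1 + noise_cv**2))
        vol = vol * rng.lognormal(-(sigma_log**2) / 2, sigma_log, size=vol.shape)

    volume = AOVolume(
        intensity=vol,
        axial_pixel_um=axial_pixel_um,
        lateral_pixel_um=cone_mosaic.pixel_size_um,
    )
    return volume, osl


# ---------------------------------------------------------------------------
# Cohort and repeat-session generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec, with_volumes: bool = True):
    """Generate a full synthetic cohort with recorded ground truth.

    For each subject a multiplicative lognormal effect per metric (CV =
    ``between_subject_cv``) scales the topographic model curves; mosaics are
    then generated at the resulting true densities.  Cones are generated only
    for eccentricities ≥ 1° (at the fovea individual cones are unresolved);
    RPE mosaics at all eccentricities.

    Returns
    -------
    (rois, ground_truth)
        ``rois`` is a list of dicts with keys ``subject``,
        ``eccentricity_deg``, ``cone_mosaic`` (or None at the fovea),
        ``rpe_mosaic``, ``volume`` / ``true_osl`` (if ``with_volumes``);
        ``ground_truth`` a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    eccs = sorted(spec.eccentricities_deg)

    def subject_effect(cv, rng):
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log(1 + cv**2))
        return float(rng.lognormal(-(sigma**2) / 2, sigma))

    rois = []
    gt_rows = []
    for s in range(spec.n_subjects):
        eff_pr = subject_effect(spec.between_subject_cv.get("pr_density", 0.0), rng)
        eff_rpe = subject_effect(spec.between_subject_cv.get("rpe_density", 0.0), rng)
        eff_osl = subject_effect(spec.between_subject_cv.get("osl", 0.0), rng)
        for e in eccs:
            true_pr = (
                float(cone_density_model(e, spec.cone_model)) * eff_pr if e >= 1 else np.nan
            )
            true_rpe = float(rpe_density_model(e, spec.rpe_model)) * eff_rpe
            true_osl_mean = float(osl_model(e, spec.osl_model)) * eff_osl if e >= 1 else np.nan

            roi = {"subject": f"S{s:02d}", "eccentricity_deg": float(e)}
            if e >= 1:
                roi["cone_mosaic"] = generate_mosaic(
                    true_pr,
                    spec.window_um,
                    spec.jitter_frac,
                    rng,
                    cell_class="cone",
                    eccentricity_deg=e,
                )
            else:
                roi["cone_mosaic"] = None
            roi["rpe_mosaic"] = generate_mosaic(
                true_rpe,
                spec.window_um,
                spec.jitter_frac,
                rng,
                cell_class="rpe",
                eccentricity_deg=e,
            )
            if with_volumes and e >= 1:
                # a small sub-window keeps the volume cheap while sampling ~100 cones
                sub_side = min(spec.window_um, 64.0)
                sub = generate_mosaic(
                    true_pr, sub_side, spec.jitter_frac, rng, cell_class="cone",
                    eccentricity_deg=e,
                )
                vol, true_osl = render_volume(
                    sub,
                    osl_um=true_osl_mean,
                    osl_sd_um=spec.osl_cell_sd_um,
                    noise_cv=0.15,
                    seed=rng,
                )
                roi["volume"] = vol
                roi["volume_mosaic"] = sub
                roi["true_osl"] = true_osl
            rois.append(roi)
            gt_rows.append(
                {
                    "subject": f"S{s:02d}",
                    "eccentricity_deg": float(e),
                    "true_pr_density": true_pr,
                    "true_rpe_density": true_rpe,
                    "true_osl_mean_um": (
                        float(np.mean(roi["true_osl"]))
                        if with_volumes and e >= 1
                        else true_osl_mean
                    ),
                    "true_osl_model_um": true_osl_mean,
                }
            )

    gt = GroundTruth(
        table=pd.DataFrame(gt_rows),
        seed=spec.seed,
        params={
            "cone_model": list(spec.cone_model),
            "rpe_model": list(spec.rpe_model),
            "osl_model": list(spec.osl_model),
            "n_subjects": spec.n_subjects,
            "eccentricities_deg": [float(e) for e in eccs],
            "window_um": spec.window_um,
        },
    )
    return rois, gt


def generate_repeat_sessions(
    true_value: float,
    k: int = 3,
    within_cv: float = 0.02,
    n_subjects: int = 7,
    between_cv: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Subject × session measurement table with between/within variability.

    Each subject's latent mean is ``true_value`` scaled by a lognormal effect
    of coefficient of variation ``between_cv``; each session measurement is
    the subject mean times ``(1 + N(0, within_cv))``.
    """
    if k < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if between_cv > 0:
        sigma = np.sqrt(np.log(1 + between_cv**2))
        subj_means = true_value * rng.lognormal(-(sigma**2) / 2, sigma, size=n_subjects)
    else:
        subj_means = np.full(n_subjects, float(true_value))
    if within_cv > 0:
        noise = rng.normal(0.0, within_cv, size=(n_subjects, k))
    else:
        noise = np.zeros((n_subjects, k))
    data = subj_means[:, None] * (1.0 + noise)
    return pd.DataFrame(
        data,
        index=[f"S{i:02d}" for i in range(n_subjects)],
        columns=[f"session{j + 1}" for j in range(k)],
    )


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_mosaic_csv(mosaic: CellMosaic, path: str | Path) -> None:
    """Write cell centers as CSV with columns (id, x_um, y_um)."""
    df = pd.DataFrame(
        {
            "id": np.arange(len(mosaic.points)),
            "x_um": mosaic.points[:, 0],
            "y_um": mosaic.points[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_mosaic_csv(
    path: str | Path,
    cell_class: str,
    window: tuple[float, float, float, float],
    **kwargs,
) -> CellMosaic:
    """Read a (id, x_um, y_um) CSV back into a :class:`CellMosaic`."""
    df = pd.read_csv(path)
    return CellMosaic(
        points=df[["x_um", "y_um"]].to_numpy(),
        cell_class=cell_class,
        window=window,
        **kwargs,
    )
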