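"""Volume operations: averaging, flattening, slab projection, per-cone OSL.

A cone photoreceptor appears in an outer-retina OCT volume as a pair of
bright axial reflections — the inner/outer segment junction (IS/OS) and the
cone outer segment tip (COST) — above the continuous RPE band.  Outer
segment length (OSL) is defined as the distance between the *peak
intensities* of the IS/OS and COST reflections (not band edges), measured
per cone after the volume has been flattened to the photoreceptor–RPE
complex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, signal

__all__ = [
    "AOVolume",
    "LayerSegmentation",
    "ConeRecord",
    "average_volumes",
    "flatten",
    "unflatten",
    "extract_enface",
    "measure_osl",
    "summarize_osl",
    "write_volume",
    "read_volume",
    "cone_records_to_frame",
]


@dataclass
class AOVolume:
    """3-D intensity raster indexed (z, y, x), z increasing posteriorly."""

    intensity: np.ndarray
    axial_pixel_um: float
    lateral_pixel_um: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3-D (z, y, x) array")
        if self.axial_pixel_um <= 0 or self.lateral_pixel_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass
class LayerSegmentation:
    """Per-(y, x) depth-index maps for the IS/OS, COST and RPE band centers."""

    isos: np.ndarray | None = None
    cost: np.ndarray | None = None
    rpe: np.ndarray | None = None
    slab_halfwidth_px: int = 1

    def __post_init__(self) -> None:
        maps = [m for m in (self.isos, self.cost, self.rpe) if m is not None]
        if not maps:
            raise ValueError("at least one layer map is required")
        shape = maps[0].shape
        if any(m.shape != shape for m in maps):
            raise ValueError("layer maps must share one lateral shape")
        if self.isos is not None and self.cost is not None:
            if not np.all(self.isos < self.cost):
                raise ValueError("IS/OS must lie above COST everywhere")
        if self.cost is not None and self.rpe is not None:
            if not np.all(self.cost < self.rpe):
                raise ValueError("COST must lie above the RPE band everywhere")


@dataclass
class ConeRecord:
    """One cone's lateral position, reflection depths, and OSL."""

    cone_id: int
    x_um: float
    y_um: float
    z_isos: float
    z_cost: float
    osl_um: float
    valid: bool = True


def cone_records_to_frame(records: list[ConeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.cone_id,
                "x_um": r.x_um,
                "y_um": r.y_um,
                "z_isos": r.z_isos,
                "z_cost": r.z_cost,
                "osl_um": r.osl_um,
                "valid": r.valid,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Averaging and flattening
# ---------------------------------------------------------------------------


def average_volumes(volumes: list[AOVolume]) -> AOVolume:
    """Voxel-wise mean of registered volumes with identical geometry."""
    if not volumes:
        raise ValueError("volume list is empty")
    first = volumes[0]
    for v in volumes[1:]:
        if v.shape != first.shape:
            raise ValueError("volumes must share one shape")
        if v.axial_pixel_um != first.axial_pixel_um or v.lateral_pixel_um != first.lateral_pixel_um:
            raise ValueError("volumes must share pixel sizes")
    mean = np.mean([v.intensity for v in volumes], axis=0)
    return AOVolume(mean, first.axial_pixel_um, first.lateral_pixel_um)


def flatten(
    volume: AOVolume,
    axial_smooth_um: float = 8.0,
    lateral_median_px: int = 5,
    reference_frac: float = 0.6,
):
    """Flatten a volume to the photoreceptor–RPE complex.

    The per-column reference depth is the argmax of the axially smoothed
    A-scan (in practice the bright RPE band), median-filtered laterally to
    suppress outlier columns; each column is then shifted by an integer
    number of pixels so the reference lies at a common depth
    (``reference_frac`` of the way down the volume).

    Returns
    -------
    (flat_volume, shift_px)
        ``shift_px`` is the per-column shift applied (positive = moved
        posteriorly); pass it to :func:`unflatten` to invert.
    """
    vol = volume.intensity
    nz = vol.shape[0]
    sigma_px = max(axial_smooth_um / volume.axial_pixel_um, 1.0)
    smooth = ndimage.gaussian_filter1d(vol, sigma_px, axis=0)
    ref = np.argmax(smooth, axis=0).astype(float)
    ref = ndimage.median_filter(ref, size=lateral_median_px)
    target = int(round(reference_frac * (nz - 1)))
    shift = np.round(target - ref).astype(int)

    flat = np.empty_like(vol)
    for iy in range(vol.shape[1]):
        for ix in range(vol.shape[2]):
            flat[:, iy, ix] = np.roll(vol[:, iy, ix], shift[iy, ix])
    return AOVolume(flat, volume.axial_pixel_um, volume.lateral_pixel_um), shift


def unflatten(volume: AOVolume, shift_px: np.ndarray) -> AOVolume:
    """Invert :func:`flatten` given its shift map."""
    vol = volume.intensity
    out = np.empty_like(vol)
    for iy in range(vol.shape[1]):
        for ix in range(vol.shape[2]):
            out[:, iy, ix] = np.roll(vol[:, iy, ix], -shift_px[iy, ix])
    return AOVolume(out, volume.axial_pixel_um, volume.lateral_pixel_um)


# ---------------------------------------------------------------------------
# Slab projection
# ---------------------------------------------------------------------------

_LAYERS = ("ISOS", "COST", "ISOS+COST", "RPE")


def extract_enface(
    volume: AOVolume,
    segmentation: LayerSegmentation,
    layer: str = "ISOS+COST",
    slab_px: int | None = None,
) -> np.ndarray:
    """Mean axial projection over a slab centered on a segmented layer.

    ``layer`` selects which depth map(s) the slab follows; ``ISOS+COST``
    averages the two cone-reflection slabs (the standard photoreceptor
    en-face projection).  ``slab_px`` is the half-width in pixels (defaults
    to the segmentation's).  Slabs clipped by the volume boundary are
    truncated.
    """
    if layer not in _LAYERS:
        raise ValueError(f"layer must be one of {_LAYERS}")
    if slab_px is None:
        slab_px = segmentation.slab_halfwidth_px

    def slab_mean(center: np.ndarray) -> np.ndarray:
        nz, h, w = volume.shape
        out = np.zeros((h, w))
        c = np.clip(np.round(center).astype(int), 0, nz - 1)
        lo = np.clip(c - slab_px, 0, nz - 1)
        hi = np.clip(c + slab_px, 0, nz - 1)
        zz = np.arange(nz)[:, None, None]
        sel = (zz >= lo[None]) & (zz <= hi[None])
        out = np.sum(volume.intensity * sel, axis=0) / np.sum(sel, axis=0)
        return out

    if layer == "ISOS":
        if segmentation.isos is None:
            raise ValueError("segmentation lacks an IS/OS map")
        return slab_mean(segmentation.isos)
    if layer == "COST":
        if segmentation.cost is None:
            raise ValueError("segmentation lacks a COST map")
        return slab_mean(segmentation.cost)
    if layer == "RPE":
        if segmentation.rpe is None:
            raise ValueError("segmentation lacks an RPE map")
        return slab_mean(segmentation.rpe)
    if segmentation.isos is None or segmentation.cost is None:
        raise ValueError("segmentation lacks IS/OS and COST maps")
    return 0.5 * (slab_mean(segmentation.isos) + slab_mean(segmentation.cost))


# ---------------------------------------------------------------------------
# Per-cone outer segment length
# ---------------------------------------------------------------------------


def outer_retina_window(volume: AOVolume, margin_um: float = 6.0) -> tuple[int, int]:
    """Axial search window above the RPE band, for cone-reflection peaks.

    The RPE band is located as the brightest axially smoothed peak of the
    volume-mean A-scan; the window ends ``margin_um`` above it so the band
    itself cannot be mistaken for a cone outer segment tip.
    """
    profile = volume.intensity.mean(axis=(1, 2))
    smooth = ndimage.gaussian_filter1d(profile, max(2.0 / volume.axial_pixel_um, 1.0))
    rpe_idx = int(np.argmax(smooth))
    z1 = max(1, rpe_idx - int(round(margin_um / volume.axial_pixel_um)))
    return (0, z1)


def _parabolic_refine(profile: np.ndarray, idx: int) -> float:
    """3-point parabolic sub-pixel refinement of a local maximum."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    return idx + 0.5 * (y0 - y2) / denom


def measure_osl(
    volume: AOVolume,
    cone_points_um: np.ndarray,
    search_window_px: tuple[int, int] | None = None,
    neighborhood_px: int = 1,
    min_separation_um: float = 5.0,
    min_prominence_frac: float = 0.1,
) -> list[ConeRecord]:
    """Measure outer segment length for each cone from its paired reflections.

    For each lateral cone position, the A-scans in a small neighborhood
    (default 3×3 px) are averaged to suppress speckle, the two most prominent
    local maxima inside ``search_window_px`` (exclusive of the RPE band) are
    taken as the IS/OS and COST reflections, each is refined to sub-pixel
    depth by 3-point parabolic interpolation, and
    ``OSL = (z_cost − z_isos) · axial_pixel_um``.

    Records with fewer than two distinct peaks, or peaks whose prominence is
    below ``min_prominence_frac`` of the window maximum, are flagged invalid
    rather than dropped.
    """
    nz, h, w = volume.shape
    if search_window_px is None:
        search_window_px = (0, nz)
    z0, z1 = search_window_px
    z0, z1 = max(0, z0), min(nz, z1)
    dist_px = max(1, int(round(min_separation_um / volume.axial_pixel_um)))

    records: list[ConeRecord] = []
    pts = np.asarray(cone_points_um, dtype=float)
    for i, (x_um, y_um) in enumerate(pts):
        # raster convention: index i lies at physical coordinate i * pixel_size
        ix = min(max(int(round(x_um / volume.lateral_pixel_um)), 0), w - 1)
        iy = min(max(int(round(y_um / volume.lateral_pixel_um)), 0), h - 1)
        xlo, xhi = max(ix - neighborhood_px, 0), min(ix + neighborhood_px + 1, w)
        ylo, yhi = max(iy - neighborhood_px, 0), min(iy + neighborhood_px + 1, h)
        ascan = volume.intensity[z0:z1, ylo:yhi, xlo:xhi].mean(axis=(1, 2))

        peaks, props = signal.find_peaks(
            ascan, distance=dist_px, prominence=min_prominence_frac * max(ascan.max(), 1e-12)
        )
        if len(peaks) < 2:
            records.append(ConeRecord(i, x_um, y_um, np.nan, np.nan, np.nan, valid=False))
            continue
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        top2.sort()
        z_isos = z0 + _parabolic_refine(ascan, int(top2[0]))
        z_cost = z0 + _parabolic_refine(ascan, int(top2[1]))
        osl = (z_cost - z_isos) * volume.axial_pixel_um
        records.append(ConeRecord(i, x_um, y_um, z_isos, z_cost, osl, valid=osl > 0))
    return records


def summarize_osl(records: list[ConeRecord]) -> dict:
    """Mean, SD, count and a bimodality flag for valid per-cone OSLs.

    The bimodality flag uses the sample bimodality coefficient
    b = (skew² + 1) / kurtosis; b above the uniform-distribution reference
    value 5/9 suggests a bimodal OSL distribution.
    """
    osl = np.array([r.osl_um for r in records if r.valid])
    n = len(osl)
    out = {"n_valid": n, "n_total": len(records)}
    if n == 0:
        out.update({"mean_um": np.nan, "sd_um": np.nan, "bimodal": False})
        return out
    out["mean_um"] = float(np.mean(osl))
    out["sd_um"] = float(np.std(osl, ddof=1)) if n > 1 else 0.0
    if n > 3 and out["sd_um"] > 0:
        from scipy import stats

        skew = stats.skew(osl)
        kurt = stats.kurtosis(osl, fisher=False)
        out["bimodal"] = bool((skew**2 + 1) / kurt > 5.0 / 9.0)
    else:
        out["bimodal"] = False
    return out


# ---------------------------------------------------------------------------
# Plain multi-page TIFF I/O with JSON sidecar
# ---------------------------------------------------------------------------


def write_volume(volume: AOVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, volume.intensity.astype(np.float32))
    sidecar = {
        "axial_pixel_um": volume.axial_pixel_um,
        "lateral_pixel_um": volume.lateral_pixel_um,
        "shape_zyx": list(volume.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_volume(path: str | Path) -> AOVolume:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return AOVolume(data, sidecar["axial_pixel_um"], sidecar["lateral_pixel_um"])
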