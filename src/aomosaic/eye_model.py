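"""Retinal magnification scaling from ocular biometry.

Densities and lengths measured on an angular raster (degrees of visual
field) must be converted to physical retinal units (µm, mm²) before they
can be compared across eyes of different axial length.  The conversion
used here is the small-angle Bennett schematic-eye relation

    q [mm/deg] = 0.01306 · (AL − 1.82)

where ``AL`` is the axial length in mm and 1.82 mm is the distance from
the posterior nodal point to the corneal vertex of the reduced eye.  A
2° field sampled with N A-scans then has a lateral pixel pitch of
``q · fov / N`` on the retina.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Bennett conversion constant, mm of retina per degree per mm of (AL - 1.82).
BENNETT_COEFF_MM_PER_DEG = 0.01306

#: Distance (mm) from posterior nodal point to corneal vertex in the reduced eye.
NODAL_OFFSET_MM = 1.82


class BiometryError(ValueError):
    """Raised for physically impossible biometry."""


@dataclass(frozen=True)
class EyeBiometry:
    """Ocular biometry needed to scale an angular raster to the retina.

    Parameters
    ----------
    axial_length_mm
        Axial length of the eye in mm; must exceed the 1.82 mm nodal offset.
    fov_deg
        Scan field of view in degrees.
    samples_per_fov
        Number of lateral A-scans across the field.
    """

    axial_length_mm: float
    fov_deg: float = 2.0
    samples_per_fov: int = 512

    def __post_init__(self) -> None:
        if self.axial_length_mm <= NODAL_OFFSET_MM:
            raise BiometryError(
                f"axial length {self.axial_length_mm} mm must exceed "
                f"{NODAL_OFFSET_MM} mm (posterior nodal distance would be <= 0)"
            )
        if self.fov_deg <= 0:
            raise BiometryError("fov_deg must be positive")
        if int(self.samples_per_fov) < 2 or self.samples_per_fov != int(self.samples_per_fov):
            raise BiometryError("samples_per_fov must be an integer >= 2")


def microns_per_degree(biometry: EyeBiometry) -> float:
    """Retinal distance subtended by one degree of visual angle, in µm/deg."""
    return 1000.0 * BENNETT_COEFF_MM_PER_DEG * (biometry.axial_length_mm - NODAL_OFFSET_MM)


def lateral_pixel_size(biometry: EyeBiometry) -> float:
    """Lateral pixel pitch on the retina, in µm/pixel."""
    return microns_per_degree(biometry) * biometry.fov_deg / biometry.samples_per_fov


def counts_to_density(cell_count: int, area_px2: float, pixel_size_um: float) -> float:
    """Convert a cell count over a pixel area to a density in cells/mm².

    ``area_px2`` is the analyzed area in squared pixels and ``pixel_size_um``
    the physical pixel pitch, so the physical area is
    ``area_px2 · pixel_size_um² · 1e-6`` mm².
    """
    if area_px2 <= 0:
        raise ValueError("area_px2 must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if cell_count < 0:
        raise ValueError("cell_count must be non-negative")
    area_mm2 = area_px2 * pixel_size_um**2 * 1e-6
    return cell_count / area_mm2


def load_biometry(path: str | Path) -> EyeBiometry:
    """Read biometry from a JSON or YAML config file.

    Expected keys: ``axial_length_mm`` (required), ``fov_deg`` and
    ``samples_per_fov`` (optional, defaulting to 2° / 512).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return EyeBiometry(
        axial_length_mm=float(raw["axial_length_mm"]),
        fov_deg=float(raw.get("fov_deg", 2.0)),
        samples_per_fov=int(raw.get("samples_per_fov", 512)),
    )
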