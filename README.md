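# aomosaic

Quantification of the photoreceptor–RPE complex from AO-OCT-style data:
cell-mosaic density metrics, per-cone outer segment length, retinal
magnification scaling, topographic model fits, and reproducibility
statistics — together with a synthetic-data generator that makes every
stage verifiable by parameter recovery.

## Who this is for

Cellular-resolution retinal imaging (adaptive optics OCT and SLO) resolves
the cone photoreceptor (PR) and retinal pigment epithelium (RPE) mosaics in
the living eye. Turning those images into normative numbers — cone density,
RPE density, cone outer segment length (OSL), cone/RPE ratio as functions of
eccentricity — requires a chain of well-defined measurement steps, each of
which can bias the result. `aomosaic` implements that chain as a tested
Python library for researchers developing or validating such metrics.

## The measurements

* **Magnification scaling** — visual angle is converted to retinal distance
  with the small-angle Bennett schematic-eye relation
  `q [mm/deg] = 0.01306 · (AL − 1.82)`, so densities and lengths are in
  physical units (cells/mm², µm) regardless of axial length AL.
* **Voronoi mosaic metrics** — cell centers are tessellated; polygons
  touching the window boundary or a vessel-shadow mask are excluded;
  density = included cells / summed included polygon area; cell-to-cell
  spacing is averaged over Voronoi-adjacent pairs.
* **Power-spectrum density** — the annular spectral peak of a quasi-regular
  mosaic (Yellott's ring) at radial frequency `f` (cycles/mm) gives an
  independent density estimate `D = (√3/2)·f²`.
* **Outer segment length** — each cone appears in an outer-retina volume as
  a pair of axial reflections, the inner/outer segment junction (IS/OS) and
  the cone outer segment tip (COST). OSL is the distance between the two
  *intensity peaks*, found per cone with a minimum-separation constraint
  and refined to sub-pixel depth by parabolic interpolation.
* **Topography** — cone density and cone/RPE ratio follow a power law
  `a·E^b` in eccentricity `E` (degrees), RPE density is linear, OSL is a
  second-order polynomial; fits report squared Pearson and Spearman
  correlations of observed vs predicted.
* **Reliability** — inter-session reproducibility via the absolute-agreement
  average-measures intraclass correlation ICC(A,k) with F-based confidence
  intervals, per-subject normalized SD, and inter-grader agreement via
  Lin's concordance correlation coefficient.

The synthetic generator produces jittered-hexagonal mosaics, vessel-shadow
masks, en-face images with multiplicative speckle, and miniature volumes
with paired IS/OS–COST reflections above an RPE band, all with recorded
ground truth, at the normative topographic defaults (cone
`53,329·E^−0.731`, RPE `6913 − 123·E` cells/mm², OSL from 33.3 µm at 1° to
18.0 µm at 12°).

## Worked example

```python
import aomosaic as am

# a 250 µm RPE mosaic at the 1° normative density, with speckle
mosaic = am.generate_mosaic(7335.0, 250.0, 0.10, seed=2, cell_class="rpe")
image = am.render_enface(mosaic, spot_fwhm_um=3.0, noise_cv=0.15, seed=1)

# detect cells, then measure the mosaic two independent ways
det = am.detect_cells(image, 1.0, am.hex_spacing_um(7335.0))
measured = am.CellMosaic(det.points, "rpe", mosaic.window)
metrics, _ = am.voronoi_metrics(measured)
ps_density, ring = am.power_spectrum_density(image, 1.0, 7335.0)

print(f"cells counted:        {metrics.n_cells_counted}")
print(f"Voronoi density:      {metrics.density_cells_mm2:.0f} cells/mm^2")
print(f"mean cell area:       {metrics.mean_cell_area_um2:.1f} um^2")
print(f"mean spacing:         {metrics.mean_spacing_um:.2f} um")
print(f"spectral ring:        {ring:.1f} cyc/mm -> {ps_density:.0f} cells/mm^2")
```

```
cells counted:        377
Voronoi density:      7304 cells/mm^2
mean cell area:       136.9 um^2
mean spacing:         12.68 um
spectral ring:        89.6 cyc/mm -> 6949 cells/mm^2
```

The Voronoi estimate lands within 0.5% of the generated 7,335 cells/mm²;
the spectral estimate sits a few percent lower — the expected windowing
bias of the ring method on finite images.

A full study-design run (11 subjects × 13 ROIs from the fovea to 12°
temporal, detection → Voronoi → OSL → fits → reliability) is one call:

```bash
aomosaic all --seed 0 --out my_run     # or: python -m aomosaic.cli …
```

which writes `roi_metrics.csv`, `topography_summary.csv` +
`topography_fits.json`, `reliability.json`, session tables, ground truth
and a manifest; `aomosaic report --run-dir my_run` renders the summary
figures. `simulate`, `analyze`, `topography` and `reliability` run the
stages individually on serialized files.

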