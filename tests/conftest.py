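import numpy as np
import pytest

import aomosaic as am


@pytest.fixture(scope="session")
def hex_mosaic_11547():
    """Jittered hex mosaic at 11,547 cells/mm² (10 µm lattice spacing)."""
    return am.generate_mosaic(11547.0, 250.0, 0.10, seed=2)


@pytest.fixture(scope="session")
def perfect_hex_mosaic():
    """Noise-free hexagonal lattice, 10 µm spacing, 250 µm window."""
    return am.generate_mosaic(11547.0, 250.0, 0.0, seed=1)


@pytest.fixture(scope="session")
def square_grid_mosaic():
    """5×5 square grid, 10 µm spacing: hand-computable Voronoi geometry."""
    xs, ys = np.meshgrid(np.arange(5) * 10.0, np.arange(5) * 10.0)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    return am.CellMosaic(points=pts, cell_class="rpe", window=(0.0, 0.0, 40.0, 40.0))


@pytest.fixture(scope="session")
def small_volume():
    """~200-cone volume with per-cone OSL scatter and speckle."""
    side = np.sqrt(200 / 11547.0) * 1000
    mosaic = am.generate_mosaic(11547.0, side, 0.10, seed=3)
    volume, true_osl = am.render_volume(
        mosaic, osl_um=33.3, osl_sd_um=2.4, noise_cv=0.15, seed=4
    )
    return mosaic, volume, true_osl
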