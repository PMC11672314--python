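import numpy as np
import pytest

from tesserakit import pipeline as pl
from tesserakit import rag as rg
from tesserakit import synthetic as syn


@pytest.fixture(scope="session")
def small_phantom():
    """Noisy slab-shell phantom small enough for per-test reuse."""
    return pl.default_phantom(extent=(500.0, 500.0), n_seeds=45, seed=3)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and blur-free phantom with lacunae: truth support == threshold."""
    return pl.default_phantom(
        extent=(500.0, 500.0), n_seeds=45, seed=3, noise_sd=0.0, blur_sigma=0.0
    )


@pytest.fixture(scope="session")
def zero_gap_phantom():
    """Gap-free, void-free, noise-free phantom: labels tile the whole shell."""
    return pl.default_phantom(
        extent=(400.0, 400.0), n_seeds=30, seed=11,
        gap_width=0.0, lacunae=(0, 0.0), noise_sd=0.0, blur_sigma=0.0,
    )


@pytest.fixture(scope="session")
def hex_tessellation():
    """Regular hexagonal tiling (spacing 1) on a plane; interior cells exact."""
    pts = syn.hexagonal_lattice_points(12, 12, 1.0) + np.array([1.2, 1.0, 0.0])
    surface = syn.SurfaceSpec("plane", extent=(14.0, 12.0))
    return syn.voronoi_tessellation(pts, surface)


@pytest.fixture(scope="session")
def hex_graph(hex_tessellation):
    return rg.graph_from_tessellation(hex_tessellation)


@pytest.fixture(scope="session")
def sphere_tessellation():
    surface = syn.SurfaceSpec("sphere", radius=500.0)
    pts = syn.sample_hardcore_points(surface, 400, 30.0, seed=2)
    return syn.voronoi_tessellation(pts, surface)


def hex_interior_ids(tess, graph):
    """Ids (1-based) of cells with the full 6-neighbour hexagonal fan."""
    return [
        i + 1
        for i in range(tess.n_cells)
        if not tess.boundary[i] and graph.degree(i + 1) == 6
    ]
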