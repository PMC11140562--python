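"""Shared fixtures: small grids, analytic edges and a miniature phantom."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import erf

import phantomiq as pq


@pytest.fixture(scope="session")
def small_grid() -> pq.Grid:
    return pq.Grid.centered((64, 64, 9), (0.25, 0.25, 0.5))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240524)


def analytic_edge_volume(sigma: float, pixel: float = 0.3125,
                         shape=(128, 96, 5), tilt_deg: float = 5.0,
                         hi: float = 424.0, lo: float = 40.0) -> tuple:
    """Volume holding an analytically Gaussian-blurred planar edge.

    The edge is tilted slightly in-plane so voxel projections sample the
    transition at sub-pixel pitch (slanted-edge practice).  Returns
    (volume, EdgeSpec).
    """
    g = pq.Grid.centered(shape, (pixel, pixel, 0.25))
    X, Y, Z = g.meshgrid(np.float64)
    th = np.radians(tilt_deg)
    n = (np.cos(th), np.sin(th), 0.0)
    d = X * n[0] + Y * n[1]
    vals = hi - (hi - lo) * 0.5 * (1.0 + erf(d / (sigma * np.sqrt(2.0))))
    vol = pq.VoxelVolume(np.broadcast_to(vals, g.shape).copy(), g)
    ext = g.world_extent()
    pad = 2 * pixel
    edge = pq.EdgeSpec(
        pq.PlanarEdge((0.0, 0.0, 0.0), n,
                      ((ext[0][0] + pad, ext[0][1] - pad),
                       (ext[1][0] + pad, ext[1][1] - pad))),
        band_halfwidth=max(6.0 * sigma + 0.5, 2.5),
        contrast=(hi, lo),
    )
    return vol, edge


@pytest.fixture(scope="session")
def mini_phantom():
    """A small, coarse phantom for fast geometry tests.

    16 mm of z on the full 1024 in-plane model grid is too slow for unit
    tests, so this uses a 256-matrix grid over a 160 mm FoV (0.625 mm
    pixels) without the sub-millimetre vessels.
    """
    spec = pq.PhantomSpec(
        vessels=(
            pq.VesselSpec("normal-3.2",
                          np.array([[35.0, 0.0, -8.0], [35.0, 0.0, 8.0]]), 3.2),
            pq.VesselSpec("curved-4.0",
                          np.stack([2.0 * np.sin(np.linspace(-np.pi / 2, np.pi / 2, 17)),
                                    np.full(17, -35.0),
                                    np.linspace(-8.0, 8.0, 17)], axis=1), 4.0),
        ),
        stent=None,
    )
    grid = pq.Grid.centered((256, 256, 33), (0.625, 0.625, 0.5))
    vol, truth = pq.build_digital_phantom(spec, grid)
    return spec, grid, vol, truth
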