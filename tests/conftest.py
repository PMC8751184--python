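"""Shared fixtures: small phantoms, analytic cylinder grids, solved fields.

Session-scoped where the underlying computation is deterministic and
reused across test modules.
"""

import numpy as np
import pytest

from pnstim.dielectrics import ConductivityMap
from pnstim.phantom import TissueGrid, make_layered_cylinder
from pnstim.spfd import ExposureSpec, solve_field


def circular_cylinder_grid(radius_mm=100.0, height_mm=20.0, voxel_mm=2.0,
                           label=3):
    """Homogeneous circular cylinder (axis z), centered on the origin."""
    n = int(np.ceil(2 * (radius_mm + voxel_mm) / voxel_mm))
    nz = max(1, int(round(height_mm / voxel_mm)))
    origin = np.array([-n / 2 * voxel_mm, -n / 2 * voxel_mm, 0.0])
    x = origin[0] + (np.arange(n) + 0.5) * voxel_mm
    X, Y = np.meshgrid(x, x, indexing="ij")
    sec = (X ** 2 + Y ** 2 <= radius_mm ** 2)
    lab = np.repeat(sec[:, :, None], nz, axis=2).astype(np.int16) * label
    return TissueGrid(labels=lab, voxel_size=voxel_mm, origin=origin)


def elliptic_cylinder_grid(ax_mm=30.0, ay_mm=45.0, height_mm=12.0,
                           voxel_mm=2.0, label=3):
    nx = int(np.ceil(2 * (ax_mm + voxel_mm) / voxel_mm))
    ny = int(np.ceil(2 * (ay_mm + voxel_mm) / voxel_mm))
    nz = max(1, int(round(height_mm / voxel_mm)))
    origin = np.array([-nx / 2 * voxel_mm, -ny / 2 * voxel_mm, 0.0])
    xs = origin[0] + (np.arange(nx) + 0.5) * voxel_mm
    ys = origin[1] + (np.arange(ny) + 0.5) * voxel_mm
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    sec = (X / ax_mm) ** 2 + (Y / ay_mm) ** 2 <= 1.0
    lab = np.repeat(sec[:, :, None], nz, axis=2).astype(np.int16) * label
    return TissueGrid(labels=lab, voxel_size=voxel_mm, origin=origin)


def uniform_conductivity(grid, sigma=0.2, f_hz=1000.0):
    return ConductivityMap(sigma=np.where(grid.labels > 0, sigma, 0.0),
                           frequency_hz=f_hz, grid=grid)


@pytest.fixture(scope="session")
def cylinder_field():
    """Solved axial-exposure field of the homogeneous circular cylinder.

    The analytic solution is purely azimuthal with |E| = pi f B r.
    """
    grid = circular_cylinder_grid(radius_mm=100.0, height_mm=20.0,
                                  voxel_mm=2.0)
    cond = uniform_conductivity(grid)
    expo = ExposureSpec(b_amplitude_t=3e-4, direction=(0, 0, 1),
                        frequency_hz=1000.0)
    return solve_field(cond, expo)


@pytest.fixture(scope="session")
def small_phantom():
    """Layered elliptical torso phantom at 2 mm voxels (test scale)."""
    return make_layered_cylinder(radius_mm=60.0, height_mm=24.0,
                                 layer_thicknesses={"skin": 2.0, "fat": 10.0},
                                 voxel_size_mm=2.0)


@pytest.fixture(scope="session")
def phantom_field(small_phantom):
    """Front-to-back 1 kHz exposure solved on the small phantom."""
    from pnstim.dielectrics import assign_conductivity, load_cole_cole_table
    cond = assign_conductivity(small_phantom, load_cole_cole_table(), 1000.0)
    expo = ExposureSpec(b_amplitude_t=3e-4, direction=(0, 1, 0),
                        frequency_hz=1000.0)
    return solve_field(cond, expo)
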