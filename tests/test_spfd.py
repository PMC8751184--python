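"""SPFD solver: vector potential, assembly, analytic oracles, invariants."""

import numpy as np
import pytest

from pnstim.dielectrics import ConductivityMap
from pnstim.phantom import TissueGrid
from pnstim.spfd import (ExposureSpec, assemble_system, solve_field,
                         vector_potential)

from conftest import (circular_cylinder_grid, elliptic_cylinder_grid,
                      uniform_conductivity)


def test_vector_potential_symmetric_gauge():
    expo = ExposureSpec(b_amplitude_t=2.0, direction=(0, 0, 1),
                        frequency_hz=50.0)
    a = vector_potential(expo, (10.0, 0.0, 0.0))        # mm
    assert np.allclose(a, [0.0, 1.0 * 0.01, 0.0])       # 0.5*B*x
    assert np.allclose(vector_potential(expo, (0.0, 0.0, 0.0)), 0.0)


def test_vector_potential_numeric_curl_reproduces_b():
    """Central-difference curl of sampled A0 equals B to near round-off."""
    expo = ExposureSpec(b_amplitude_t=0.7, direction=(0.3, -0.5, 0.8),
                        frequency_hz=1000.0)
    h = 1.0  # mm
    xs = np.arange(10) * h
    P = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1)
    A = vector_potential(expo, P, center_mm=(4.0, 4.0, 4.0))
    hm = h * 1e-3
    def d(comp, axis):
        return np.gradient(A[..., comp], hm, axis=axis)
    curl = np.stack([d(2, 1) - d(1, 2), d(0, 2) - d(2, 0),
                     d(1, 0) - d(0, 1)], axis=-1)
    b = expo.b_vector
    assert np.max(np.abs(curl - b)) < 1e-10 * np.linalg.norm(b)


def test_single_voxel_assembles_cube_laplacian():
    """One conductive voxel: the 8-node system is the cube graph-Laplacian
    scaled by the edge conductance sigma*delta/4 (each edge borders one of
    its four voxel slots)."""
    lab = np.ones((1, 1, 1), dtype=np.int16) * 3
    g = TissueGrid(labels=lab, voxel_size=2.0, origin=np.zeros(3))
    sigma = 0.4
    cond = ConductivityMap(sigma=np.full((1, 1, 1), sigma),
                           frequency_hz=1e3, grid=g)
    expo = ExposureSpec(b_amplitude_t=1e-3, direction=(0, 0, 1),
                        frequency_hz=1e3)
    L, b, meta = assemble_system(cond, expo)
    L = L.toarray()
    s = sigma * (2.0e-3) / 4.0
    # hand-built cube Laplacian: nodes indexed (ix*2+iy)*2+iz
    expect = np.zeros((8, 8))
    for ix in range(2):
        for iy in range(2):
            for iz in range(2):
                i = (ix * 2 + iy) * 2 + iz
                for jx, jy, jz in ((1 - ix, iy, iz), (ix, 1 - iy, iz),
                                   (ix, iy, 1 - iz)):
                    j = (jx * 2 + jy) * 2 + jz
                    expect[i, j] = -s
                    expect[i, i] += s
    assert np.allclose(L, expect)
    assert np.allclose(L.sum(axis=1), 0.0)
    assert b.sum() == pytest.approx(0.0, abs=1e-20)


def test_row_sums_zero_on_heterogeneous_grid(small_phantom):
    from pnstim.dielectrics import assign_conductivity, load_cole_cole_table
    cond = assign_conductivity(small_phantom, load_cole_cole_table(), 1e3)
    expo = ExposureSpec(b_amplitude_t=1e-3, direction=(0, 1, 0),
                        frequency_hz=1e3)
    L, b, meta = assemble_system(cond, expo)
    rs = np.abs(np.asarray(L.sum(axis=1))).max()
    assert rs < 1e-12 * np.abs(L.diagonal()).max()


def test_all_air_rejected():
    lab = np.ones((3, 3, 3), dtype=np.int16)
    g = TissueGrid(labels=lab, voxel_size=1.0)
    cond = ConductivityMap(sigma=np.zeros((3, 3, 3)), frequency_hz=1e3,
                           grid=g)
    with pytest.raises(ValueError, match="conductive"):
        assemble_system(cond, ExposureSpec(b_amplitude_t=1e-3,
                                           frequency_hz=1e3))


def test_axial_cylinder_matches_faraday_law(cylinder_field):
    """|E| = pi f B r within 2% in the homogeneous circular cylinder."""
    fld = cylinder_field
    g = fld.grid
    x = g.voxel_centers_axes()[0]
    X, Y = np.meshgrid(x, x, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2)
    zmid = g.shape[2] // 2
    emag = fld.e_mag[:, :, zmid]
    sel = (r > 20) & (r < 80)   # away from axis and staircase boundary
    exact = np.pi * 1000.0 * 3e-4 * r[sel] * 1e-3
    rel = np.abs(emag[sel] - exact) / exact
    assert rel.max() < 0.02
    # potential is constant (zero) by symmetry
    assert np.abs(fld.psi).max() < 1e-6 * np.abs(exact).max()


def test_elliptic_cylinder_matches_closed_form():
    """Axial exposure of an elliptical section: psi = k*x*y with
    k = (B/2)(b^2-a^2)/(a^2+b^2); E follows in closed form."""
    axm, aym = 30.0, 45.0
    g = elliptic_cylinder_grid(axm, aym, 12.0, 2.0)
    cond = uniform_conductivity(g, sigma=0.3)
    f, B = 1000.0, 1e-3
    expo = ExposureSpec(b_amplitude_t=B, direction=(0, 0, 1), frequency_hz=f)
    fld = solve_field(cond, expo)
    a = axm * 1e-3
    b = aym * 1e-3
    k = (B / 2.0) * (b ** 2 - a ** 2) / (a ** 2 + b ** 2)
    w = 2 * np.pi * f
    xs = g.voxel_centers_axes()[0]
    ys = g.voxel_centers_axes()[1]
    X, Y = np.meshgrid(xs * 1e-3, ys * 1e-3, indexing="ij")
    inside = (X / a) ** 2 + (Y / b) ** 2 <= 0.8 ** 2
    zmid = g.shape[2] // 2
    ex = -w * Y * (k - B / 2.0)
    ey = -w * X * (k + B / 2.0)
    exact = np.sqrt(ex ** 2 + ey ** 2)
    got = fld.e_mag[:, :, zmid]
    sel = inside & (exact > 0.2 * exact[inside].max())
    rel = np.abs(got[sel] - exact[sel]) / exact[sel]
    assert np.median(rel) < 0.02
    assert rel.max() < 0.08


def test_linearity_in_b_and_frequency():
    g = circular_cylinder_grid(radius_mm=40.0, height_mm=8.0, voxel_mm=4.0)
    cond = uniform_conductivity(g)
    base = solve_field(cond, ExposureSpec(b_amplitude_t=1e-3,
                                          direction=(0, 0, 1),
                                          frequency_hz=1e3))
    x2b = solve_field(cond, ExposureSpec(b_amplitude_t=2e-3,
                                         direction=(0, 0, 1),
                                         frequency_hz=1e3))
    x2f = solve_field(cond, ExposureSpec(b_amplitude_t=1e-3,
                                         direction=(0, 0, 1),
                                         frequency_hz=2e3))
    m = g.labels > 0
    assert np.allclose(x2b.e_vec[m], 2 * base.e_vec[m], rtol=1e-5,
                       atol=1e-12)
    assert np.allclose(x2f.e_vec[m], 2 * base.e_vec[m], rtol=1e-4,
                       atol=1e-12)


def test_current_conservation_and_gauge():
    g = circular_cylinder_grid(radius_mm=40.0, height_mm=8.0, voxel_mm=4.0)
    cond = uniform_conductivity(g)
    expo = ExposureSpec(b_amplitude_t=1e-3, direction=(1, 0, 0),
                        frequency_hz=1e3)
    fld = solve_field(cond, expo, tol=1e-8)
    L, b, meta = assemble_system(cond, expo)
    psi = fld.psi.ravel()
    imbalance = L @ psi - b
    act = meta["active"]
    scale = np.abs(b[act]).max()
    assert np.abs(imbalance[act]).max() < 1e-6 * scale
    assert fld.residual <= 1e-7 * 10


def test_grid_convergence_monotone():
    """Closed-form ellipse error decreases monotonically 4 -> 2 -> 1 mm."""
    errs = []
    for vs in (4.0, 2.0, 1.0):
        g = elliptic_cylinder_grid(30.0, 45.0, max(8.0, 2 * vs), vs)
        cond = uniform_conductivity(g, sigma=0.3)
        f, B = 1000.0, 1e-3
        fld = solve_field(cond, ExposureSpec(b_amplitude_t=B,
                                             direction=(0, 0, 1),
                                             frequency_hz=f))
        a, b = 30e-3, 45e-3
        k = (B / 2.0) * (b ** 2 - a ** 2) / (a ** 2 + b ** 2)
        w = 2 * np.pi * f
        xs, ys = (c * 1e-3 for c in g.voxel_centers_axes()[:2])
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        inside = (X / a) ** 2 + (Y / b) ** 2 <= 0.7 ** 2
        zmid = g.shape[2] // 2
        exact = np.hypot(-w * Y * (k - B / 2), -w * X * (k + B / 2))
        got = fld.e_mag[:, :, zmid]
        sel = inside & (exact > 0)
        errs.append(np.sqrt(np.mean(
            ((got[sel] - exact[sel]) / exact[sel].max()) ** 2)))
    assert errs[0] > errs[1] > errs[2], errs
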