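"""Fiber templates, streamline tracing, quasi-potential sampling."""

import numpy as np
import pytest

from pnstim.fibers import (FiberPath, curved_fiber, sample_quasipotential,
                           straight_fiber, surface_normal,
                           uniform_field_fiber)


class TestTemplate:
    def test_node_internode_alternation_and_length(self):
        f = uniform_field_fiber(20.0, n_nodes=21)
        assert f.is_node[0] and f.is_node[-1]
        assert f.n_nodes == 21
        assert len(f.is_node) == 41
        total = f.arclength_mm()[-1]
        assert total == pytest.approx(20 * 2.0)   # 20 internodes x 2 mm

    def test_internode_spacing_scales_with_diameter(self):
        f = uniform_field_fiber(10.0, n_nodes=5)
        assert f.arclength_mm()[-1] == pytest.approx(4 * 1.0)

    def test_alternation_enforced(self):
        with pytest.raises(ValueError):
            FiberPath(points=np.zeros((4, 3)),
                      is_node=np.array([True, False, True, False]),
                      diameter_um=20.0)


class TestStraightFiber:
    def test_theta_0_and_180_mirror(self):
        n = np.array([0.0, 1.0, 0.0])
        a = straight_fiber((0, 0, 0), 0.0, plane_normal=n, n_nodes=7)
        b = straight_fiber((0, 0, 0), 180.0, plane_normal=n, n_nodes=7)
        assert np.allclose(a.points, b.points[::-1], atol=1e-9)

    def test_seven_protocol_orientations_distinct(self):
        n = np.array([0.0, 1.0, 0.0])
        fibers = [straight_fiber((0, 0, 0), th, plane_normal=n, n_nodes=5)
                  for th in (0, 30, 60, 90, 120, 150, 180)]
        assert len(fibers) == 7
        dirs = [(f.points[-1] - f.points[0]) for f in fibers]
        dirs = np.array([d / np.linalg.norm(d) for d in dirs])
        # consecutive orientations are 30 degrees apart
        dots = np.einsum("ij,ij->i", dirs[:-1], dirs[1:])
        assert np.allclose(dots, np.cos(np.deg2rad(30.0)), atol=1e-9)

    def test_fiber_in_tangent_plane(self):
        n = np.array([1.0, 2.0, 0.5])
        f = straight_fiber((1, 2, 3), 40.0, plane_normal=n, n_nodes=5)
        seg = f.points[-1] - f.points[0]
        assert abs(seg @ (n / np.linalg.norm(n))) < 1e-9

    def test_center_in_air_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="air"):
            straight_fiber((0.0, 0.0, -50.0), 0.0, grid=small_phantom,
                           n_nodes=5)

    def test_angle_range_enforced(self):
        with pytest.raises(ValueError):
            straight_fiber((0, 0, 0), 270.0, plane_normal=(0, 1, 0))


class TestSurfaceNormal:
    def test_points_outward_on_phantom(self, small_phantom):
        # point on the +x flank of the ellipse: normal ~ +x
        n = surface_normal(small_phantom, np.array([55.0, 0.0, 12.0]))
        assert n[0] > 0.8


class TestCurvedFiber:
    def test_uniform_field_gives_straight_fiber(self, small_phantom):
        from pnstim.spfd import ExposureSpec, InducedField
        e = np.zeros(small_phantom.shape + (3,))
        e[..., 2] = 1.0
        e[small_phantom.labels == 0] = 0.0
        fld = InducedField(e_vec=e, psi=np.zeros(1),
                           exposure=ExposureSpec(b_amplitude_t=1e-3,
                                                 frequency_hz=1e3),
                           grid=small_phantom, residual=0.0)
        c = np.array([52.0, 0.0, 12.0])     # inside fat
        f = curved_fiber(c, fld, n_nodes=7, diameter_um=20.0)
        seg = f.points - f.points[0]
        # collinear with z
        assert np.allclose(seg[:, :2], seg[0, :2], atol=1e-6)

    def test_azimuthal_streamline_constant_radius(self, cylinder_field):
        """Streamlines of the axial-exposure cylinder field are circles."""
        c = np.array([50.0, 0.0, 10.0])
        f = curved_fiber(c, cylinder_field, n_nodes=15, diameter_um=20.0)
        r = np.hypot(f.points[:, 0], f.points[:, 1])
        assert np.all(np.abs(r - 50.0) / 50.0 < 0.01)

    def test_zero_field_center_rejected(self, cylinder_field):
        with pytest.raises(ValueError, match="vanishes"):
            # on the cylinder axis the induced field is zero
            curved_fiber(np.array([0.0, 0.0, 10.0]), cylinder_field,
                         n_nodes=7)

    def test_short_streamline_truncates_node_count(self, small_phantom):
        """A streamline that exits the conductor truncates symmetrically."""
        from pnstim.spfd import ExposureSpec, InducedField
        e = np.zeros(small_phantom.shape + (3,))
        e[..., 2] = 1.0
        e[small_phantom.labels == 0] = 0.0
        fld = InducedField(e_vec=e, psi=np.zeros(1),
                           exposure=ExposureSpec(b_amplitude_t=1e-3,
                                                 frequency_hz=1e3),
                           grid=small_phantom, residual=0.0)
        # field along z, phantom only 24 mm tall: a 41-node (80 mm) fiber
        # cannot fit and is truncated to an odd node count with node ends
        f = curved_fiber(np.array([52.0, 0.0, 12.0]), fld, n_nodes=41,
                         diameter_um=20.0)
        assert 5 <= f.n_nodes < 41
        assert f.n_nodes % 2 == 1
        assert f.is_node[0] and f.is_node[-1]


class TestQuasipotential:
    def test_uniform_aligned_field_linear_ramp(self):
        f = uniform_field_fiber(20.0, n_nodes=11, e_vm=3.0)
        s = f.arclength_mm() * 1e-3
        assert np.allclose(f.ve, -3.0 * s)

    def test_perpendicular_fiber_zero(self, cylinder_field):
        # radial fiber is perpendicular to the azimuthal field
        from pnstim.thresholds import straight_along
        f = straight_along((50.0, 0.0, 10.0), (1.0, 0.0, 0.0),
                           n_nodes=5, diameter_um=10.0)
        ve = sample_quasipotential(f, cylinder_field)
        # scale: ~ E*length at 1 mT basis
        scale = np.pi * 1e3 * 1e-3 * 0.05 * 0.008
        assert np.abs(ve).max() < 0.02 * scale

    def test_refined_quadrature_agreement(self, cylinder_field):
        """Default subdivision matches 10x-finer quadrature within 0.1%."""
        c = np.array([50.0, 0.0, 10.0])
        f = curved_fiber(c, cylinder_field, n_nodes=11, diameter_um=20.0)
        v1 = sample_quasipotential(f, cylinder_field, max_step_mm=0.2).copy()
        v2 = sample_quasipotential(f, cylinder_field, max_step_mm=0.02)
        scale = np.abs(v2).max()
        assert np.abs(v1 - v2).max() < 1e-3 * scale

    def test_exposure_basis_normalisation(self, cylinder_field):
        """Ve is reported on a 1 mT basis regardless of the solved B."""
        from pnstim.spfd import InducedField
        f1 = curved_fiber((50.0, 0.0, 10.0), cylinder_field, n_nodes=7)
        v1 = sample_quasipotential(f1, cylinder_field).copy()
        doubled = InducedField(e_vec=2 * cylinder_field.e_vec,
                               psi=cylinder_field.psi,
                               exposure=type(cylinder_field.exposure)(
                                   b_amplitude_t=6e-4, direction=(0, 0, 1),
                                   frequency_hz=1000.0),
                               grid=cylinder_field.grid, residual=0.0)
        f2 = curved_fiber((50.0, 0.0, 10.0), doubled, n_nodes=7)
        v2 = sample_quasipotential(f2, doubled)
        assert np.allclose(v1, v2, rtol=1e-9, atol=1e-15)

    def test_compartment_outside_grid_rejected(self, cylinder_field):
        f = uniform_field_fiber(20.0, n_nodes=21)
        f.points[:, 2] += 500.0
        with pytest.raises(ValueError, match="outside"):
            sample_quasipotential(f, cylinder_field)
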