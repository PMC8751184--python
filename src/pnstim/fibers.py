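"""Fiber trajectories and quasi-potential sampling.

A myelinated fiber is represented by the ordered centers of its compartments
(alternating node / internode), following the SENN-family template: internode
length 100× the fiber diameter, nodal gap 1.5 μm, first and last compartments
are nodes.  Straight fibers are laid in the tangent plane of the body surface
at a hotspot and rotated anticlockwise from a reference axis; curved fibers
follow streamlines of the induced electric field.

The extracellular drive of the cable model is the quasi-potential: the
negative line integral of the induced field along the fiber, accumulated from
the first compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import TissueGrid
    from .spfd import InducedField

__all__ = [
    "FiberPath",
    "straight_fiber",
    "curved_fiber",
    "sample_quasipotential",
    "uniform_field_fiber",
    "surface_normal",
]

NODE_SPACING_RATIO = 100.0   # internode length / fiber diameter


@dataclass
class FiberPath:
    """Ordered compartment chain of one myelinated fiber.

    ``points`` are compartment centers in world mm; ``is_node`` marks nodes
    of Ranvier (odd count, alternating, nodes at both ends).  ``ve`` holds
    the per-compartment quasi-potential in volts on the unit-exposure basis
    recorded in ``meta['ve_basis']`` (``"1mT"`` for grid fields, ``"1V/m"``
    for uniform-field fibers).
    """

    points: np.ndarray               # (M, 3) mm
    is_node: np.ndarray              # (M,) bool
    diameter_um: float
    ve: np.ndarray | None = None     # (M,) volts at unit exposure
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.is_node = np.asarray(self.is_node, dtype=bool)
        m = len(self.is_node)
        if m % 2 == 0 or not (self.is_node[0] and self.is_node[-1]):
            raise ValueError("fiber must start and end on nodes")
        if not np.all(self.is_node[::2]) or np.any(self.is_node[1::2]):
            raise ValueError("compartments must alternate node/internode")

    @property
    def kinds(self) -> np.ndarray:
        return np.where(self.is_node, "node", "internode")

    @property
    def n_nodes(self) -> int:
        return int(self.is_node.sum())

    @property
    def internode_length_mm(self) -> float:
        return NODE_SPACING_RATIO * self.diameter_um * 1e-3

    def arclength_mm(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.points, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "kind", self.kinds)
        df.insert(0, "compartment", np.arange(len(self.is_node)))
        if self.ve is not None:
            df["ve_V"] = self.ve
        return df


def _template_arclengths(n_nodes: int, diameter_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length positions (mm) and node mask of the compartment template."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    spacing = NODE_SPACING_RATIO * diameter_um * 1e-3  # mm
    m = 2 * n_nodes - 1
    s = np.arange(m) * 0.5 * spacing
    is_node = np.zeros(m, dtype=bool)
    is_node[::2] = True
    return s, is_node


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def surface_normal(grid: "TissueGrid", point_mm: np.ndarray,
                   window: int = 3) -> np.ndarray:
    """Outward surface normal near ``point_mm``.

    Found at the air-adjacent (skin) voxel nearest the point, as the
    air-mass direction in a small neighborhood: the normalized sum of offsets
    to air voxels within ``window`` voxels.
    """
    labels = grid.labels
    air = labels == 0
    # nearest non-air voxel to the point
    idx = np.asarray(grid.world_to_index(point_mm), dtype=int)
    idx = np.clip(idx, 0, np.array(labels.shape) - 1)
    # march outward to the nearest surface voxel along the air-mass direction
    surf = _nearest_surface_voxel(grid, idx)
    lo = np.maximum(surf - window, 0)
    hi = np.minimum(surf + window + 1, labels.shape)
    acc = np.zeros(3)
    for i in range(lo[0], hi[0]):
        for j in range(lo[1], hi[1]):
            for k in range(lo[2], hi[2]):
                if air[i, j, k]:
                    acc += np.array([i, j, k]) - surf
    n = np.linalg.norm(acc)
    if n == 0:
        raise ValueError("no air voxels near point; cannot define a surface normal")
    return acc / n


def _nearest_surface_voxel(grid: "TissueGrid", idx: np.ndarray) -> np.ndarray:
    labels = grid.labels
    air = labels == 0
    surface = np.zeros_like(air)
    nz = ~air
    for ax in range(3):
        for sh in (1, -1):
            rolled = np.roll(air, sh, axis=ax)
            # roll wraps; treat domain boundary as air
            sl = [slice(None)] * 3
            sl[ax] = 0 if sh == 1 else -1
            rolled[tuple(sl)] = True
            surface |= nz & rolled
    cand = np.argwhere(surface)
    if cand.size == 0:
        raise ValueError("grid has no surface voxels")
    d = np.linalg.norm(cand - idx, axis=1)
    return cand[int(np.argmin(d))]


def _tangent_frame(normal: np.ndarray,
                   reference_axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal frame (e1, e2); e1 is the projected reference axis."""
    n = normal / np.linalg.norm(normal)
    ref = np.asarray(reference_axis, dtype=float)
    e1 = ref - np.dot(ref, n) * n
    if np.linalg.norm(e1) < 1e-9:
        # reference parallel to normal: fall back to any perpendicular
        ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# Fiber constructors
# ---------------------------------------------------------------------------


def straight_fiber(center_mm, theta_deg: float, *, diameter_um: float = 20.0,
                   n_nodes: int = 21, plane_normal=None,
                   reference_axis=(0.0, 0.0, 1.0),
                   grid: "TissueGrid | None" = None) -> FiberPath:
    """Straight fiber through ``center_mm``, rotated ``theta_deg`` in-plane.

    The fiber lies in the plane perpendicular to ``plane_normal`` (the local
    surface tangent plane when a grid is given and no normal is passed),
    rotated anticlockwise about the normal from the reference axis projected
    into the plane.  Compartments that fall outside the conductor are listed
    in ``meta['clipped']``.
    """
    center = np.asarray(center_mm, dtype=float)
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("theta_deg must lie in [0, 180]")
    if grid is not None and grid.label_at(center) == 0:
        raise ValueError("fiber center lies in air")
    if plane_normal is None:
        if grid is None:
            raise ValueError("need plane_normal or a grid to derive it")
        plane_normal = surface_normal(grid, center)
    e1, e2 = _tangent_frame(np.asarray(plane_normal, float), reference_axis)
    th = np.deg2rad(theta_deg)
    u = np.cos(th) * e1 + np.sin(th) * e2
    s, is_node = _template_arclengths(n_nodes, diameter_um)
    pts = center + (s - s[-1] / 2.0)[:, None] * u
    clipped = []
    if grid is not None:
        clipped = [int(i) for i, p in enumerate(pts) if grid.label_at(p) == 0]
    return FiberPath(points=pts, is_node=is_node, diameter_um=diameter_um,
                     meta={"geometry": "straight", "theta_deg": theta_deg,
                           "normal": np.asarray(plane_normal, float).tolist(),
                           "clipped": clipped})


def _field_interpolator(field: "InducedField"):
    g = field.grid
    ax = [g.origin[i] + (np.arange(g.labels.shape[i]) + 0.5) * g.voxel_size
          for i in range(3)]
    return RegularGridInterpolator(ax, field.e_vec, bounds_error=False,
                                   fill_value=0.0)


def curved_fiber(center_mm, field: "InducedField", *, diameter_um: float = 20.0,
                 n_nodes: int = 21, e_floor_frac: float = 0.05,
                 e_min_vm: float = 1e-9) -> FiberPath:
    """Fiber bent along the induced-field direction through ``center_mm``.

    Traces the electric-field streamline bidirectionally from the center by
    adaptive Runge–Kutta on the trilinearly interpolated field, stopping
    where the field magnitude drops below ``e_floor_frac`` of its value at
    the center (which includes leaving the conductor, where E = 0).  The
    fiber is truncated symmetrically, dropping node pairs if either branch
    is short; at least 5 nodes must fit.
    """
    center = np.asarray(center_mm, dtype=float)
    interp = _field_interpolator(field)
    e0 = np.linalg.norm(interp(center)[0])
    if e0 < e_min_vm:
        raise ValueError(
            f"induced field vanishes at fiber center (|E| = {e0:.2e} V/m)")
    floor = e_floor_frac * e0

    def rhs(sign):
        def f(_s, y):
            e = interp(y)[0]
            n = np.linalg.norm(e)
            if n < floor:
                return np.zeros(3)
            return sign * e / n
        return f

    def stop(_s, y):
        return np.linalg.norm(interp(y)[0]) - floor
    stop.terminal = True
    stop.direction = -1

    s_tmpl, is_node = _template_arclengths(n_nodes, diameter_um)
    half = s_tmpl[-1] / 2.0
    branches = {}
    for sign in (+1, -1):
        sol = solve_ivp(rhs(sign), (0.0, half), center, events=stop,
                        max_step=field.grid.voxel_size / 2.0, rtol=1e-6,
                        atol=1e-8, dense_output=True)
        reach = sol.t[-1]
        branches[sign] = (sol, reach)
    reach = min(branches[+1][1], branches[-1][1])
    if reach <= 0:
        raise ValueError("streamline exits the tissue immediately")
    spacing = NODE_SPACING_RATIO * diameter_um * 1e-3
    n_fit = int(2 * np.floor(reach / spacing)) + 1  # symmetric node count
    n_fit = min(n_fit, n_nodes)
    if n_fit < 5:
        raise ValueError(
            f"streamline too short for a fiber: reach {reach:.2f} mm fits "
            f"{n_fit} nodes (<5)")
    s_tmpl, is_node = _template_arclengths(n_fit, diameter_um)
    half = s_tmpl[-1] / 2.0
    offsets = s_tmpl - half
    pts = np.empty((offsets.size, 3))
    for i, off in enumerate(offsets):
        sol = branches[+1][0] if off >= 0 else branches[-1][0]
        pts[i] = sol.sol(abs(off))
    return FiberPath(points=pts, is_node=is_node, diameter_um=diameter_um,
                     meta={"geometry": "curved", "reach_mm": float(reach),
                           "n_nodes": n_fit})


def uniform_field_fiber(diameter_um: float = 20.0, n_nodes: int = 21,
                        e_vm: float = 1.0, direction=(0.0, 0.0, 1.0)) -> FiberPath:
    """Straight fiber in free space with a uniform field along its axis.

    The quasi-potential basis is ``e_vm`` V/m (default a 1 V/m unit basis),
    so threshold amplitudes from the search are directly in V/m.  This is
    the calibration arena for strength–duration fitting.
    """
    u = np.asarray(direction, dtype=float)
    u /= np.linalg.norm(u)
    s, is_node = _template_arclengths(n_nodes, diameter_um)
    pts = (s - s[-1] / 2.0)[:, None] * u
    ve = -e_vm * s * 1e-3  # V; s in mm
    return FiberPath(points=pts, is_node=is_node, diameter_um=diameter_um,
                     ve=ve, meta={"geometry": "straight", "theta_deg": 0.0,
                                  "ve_basis": f"{e_vm}V/m uniform"})


# ---------------------------------------------------------------------------
# Quasi-potential
# ---------------------------------------------------------------------------


def sample_quasipotential(path: FiberPath, field: "InducedField",
                          max_step_mm: float = 0.2) -> np.ndarray:
    """Quasi-potential per compartment on a 1 mT exposure basis.

    Ve(k) = −∫ E·dl accumulated from the first compartment by the trapezoid
    rule on segments subdivided to at most ``max_step_mm``; the result is
    scaled linearly from the field's exposure amplitude to 1 mT and stored
    on the path.
    """
    g = field.grid
    lo = np.asarray(g.origin)
    hi = lo + np.array(g.labels.shape) * g.voxel_size
    pts = path.points
    if np.any(pts < lo) or np.any(pts > hi):
        raise ValueError("fiber compartment outside the field grid")
    interp = _field_interpolator(field)
    ve = np.zeros(len(pts))
    acc = 0.0
    for k in range(1, len(pts)):
        a, b = pts[k - 1], pts[k]
        seg = np.linalg.norm(b - a)
        nsub = max(1, int(np.ceil(seg / max_step_mm)))
        t = np.linspace(0.0, 1.0, nsub + 1)
        sample = a + t[:, None] * (b - a)
        e = interp(sample)                      # V/m
        u = (b - a) / seg
        proj = e @ u                            # V/m along the segment
        dl = seg * 1e-3 / nsub                  # m
        acc += -np.sum(0.5 * (proj[:-1] + proj[1:]) * dl)
        ve[k] = acc
    scale = 1e-3 / field.exposure.b_amplitude_t
    ve *= scale
    path.ve = ve
    path.meta["ve_basis"] = "1mT"
    return ve
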