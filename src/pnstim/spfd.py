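"""Scalar-potential finite-difference (SPFD) magneto-quasistatic solver.

Under a uniform sinusoidal magnetic-field exposure, tissue does not perturb
the applied field and the induced electric field is

    E = −∇φ − jωA₀,

with A₀ the vector potential of the applied field and φ a scalar potential
enforcing charge conservation, ∇·σ(∇φ + jωA₀) = 0.  On a cubic voxel grid
this becomes one Kirchhoff equation per node of the voxel lattice, with
edge conductances built from the mean conductivity of the (up to four)
voxels sharing each edge.

With purely real σ the right-hand side is purely imaginary, so the
substitution φ = jωψ yields a real symmetric positive-semidefinite system
for ψ that is solved by preconditioned conjugate gradients with the
constant-potential nullspace projected out.  The per-voxel field amplitude
is E = ω|∇ψ + A₀| (peak at the exposure frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .dielectrics import ConductivityMap

__all__ = ["ExposureSpec", "InducedField", "vector_potential",
           "assemble_system", "solve_field"]


@dataclass(frozen=True)
class ExposureSpec:
    """Uniform magnetic-field exposure: peak amplitude, direction, frequency."""

    b_amplitude_t: float            # tesla, peak
    direction: tuple = (0.0, 1.0, 0.0)   # default front-to-back (y)
    frequency_hz: float = 1000.0

    def __post_init__(self):
        if self.b_amplitude_t <= 0:
            raise ValueError("B amplitude must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.frequency_hz

    @property
    def b_vector(self) -> np.ndarray:
        return self.b_amplitude_t * np.asarray(self.direction)


@dataclass
class InducedField:
    """Induced electric field of one exposure on one grid.

    ``e_vec``: (nx, ny, nz, 3) per-voxel field-vector amplitude, V/m peak,
    zero in air.  ``psi``: reduced nodal potential (φ = jωψ), zero-mean
    gauge.  ``e_mag`` is the vector magnitude.
    """

    e_vec: np.ndarray
    psi: np.ndarray
    exposure: ExposureSpec
    grid: object
    residual: float

    @property
    def e_mag(self) -> np.ndarray:
        return np.linalg.norm(self.e_vec, axis=-1)

    def e_rms(self) -> np.ndarray:
        """Root-mean-square magnitude (peak / √2), for rms-based limits."""
        return self.e_mag / np.sqrt(2.0)


def vector_potential(exposure: ExposureSpec, position_mm,
                     center_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Symmetric-gauge vector potential A₀ = ½ B × (r − r_c), SI units.

    ``position_mm`` may be a single point or an (..., 3) array of points in
    mm; the returned A₀ is in V·s/m.  The discrete curl of the sampled
    potential reproduces B exactly (A₀ is linear in position).
    """
    r = (np.asarray(position_mm, dtype=float) - np.asarray(center_mm, float)) * 1e-3
    b = exposure.b_vector
    return 0.5 * np.cross(np.broadcast_to(b, r.shape), r)


def _edge_conductance(sigma: np.ndarray, axis: int, voxel_m: float) -> np.ndarray:
    """Edge conductances s = σ̄·Δ on the edge lattice along ``axis``.

    σ̄ is the arithmetic mean over the 4 voxel slots around the edge; air
    (and out-of-domain) slots contribute zero.
    """
    pads = [(1, 1)] * 3
    pads[axis] = (0, 0)
    sp = np.pad(sigma, pads)
    oth = [a for a in range(3) if a != axis]
    s = sp
    # sum over the 2x2 perpendicular voxel neighborhood of the edge
    parts = []
    for d0 in (0, 1):
        for d1 in (0, 1):
            sl = [slice(None)] * 3
            sl[oth[0]] = slice(d0, s.shape[oth[0]] - 1 + d0)
            sl[oth[1]] = slice(d1, s.shape[oth[1]] - 1 + d1)
            parts.append(s[tuple(sl)])
    return 0.25 * sum(parts) * voxel_m


def assemble_system(cond: ConductivityMap, exposure: ExposureSpec,
                    center_mm=None):
    """Assemble the real reduced SPFD system L ψ = b over lattice nodes.

    Returns ``(L, b, meta)``: the symmetric graph-Laplacian of the edge
    conductance network (rows sum to zero), the source vector from the
    edge-projected vector potential, and assembly metadata (edge arrays,
    node-grid shape, active-node mask).  Raises if the map is all air.
    """
    sigma = cond.sigma
    if not np.any(sigma > 0):
        raise ValueError("conductivity map has no conductive voxels")
    grid = cond.grid
    vs_mm = grid.voxel_size
    vox_m = vs_mm * 1e-3
    nshape = tuple(s + 1 for s in sigma.shape)
    nn = int(np.prod(nshape))

    def nid(ix, iy, iz):
        return (ix * nshape[1] + iy) * nshape[2] + iz

    rows, cols, vals = [], [], []
    b = np.zeros(nn)
    edges = {}
    if center_mm is None:
        # conductor centroid (voxel centers weighted by presence of tissue)
        idx = np.argwhere(sigma > 0)
        center_mm = grid.origin + (idx.mean(axis=0) + 0.5) * vs_mm
    for axis in range(3):
        s_e = _edge_conductance(sigma, axis, vox_m)
        edges[axis] = s_e
        # node-index grids of the edge endpoints
        eshape = s_e.shape
        gi = np.indices(eshape)
        n1 = np.ravel_multi_index(
            [gi[0], gi[1], gi[2]], nshape)
        step = np.zeros(3, dtype=int)
        step[axis] = 1
        n2 = np.ravel_multi_index(
            [gi[0] + step[0], gi[1] + step[1], gi[2] + step[2]], nshape)
        mask = s_e > 0
        se = s_e[mask]
        a1, a2 = n1[mask], n2[mask]
        rows += [a1, a2, a1, a2]
        cols += [a2, a1, a1, a2]
        vals += [-se, -se, se, se]
        # source: A0 component at edge midpoints, alternating sign
        mid = np.stack([gi[0], gi[1], gi[2]], axis=-1).astype(float)
        mid[..., axis] += 0.5
        pos = grid.origin + mid * vs_mm          # node lattice world coords
        a0 = vector_potential(exposure, pos, center_mm)[..., axis]
        contrib = se * vox_m * a0[mask]
        np.add.at(b, a1, contrib)
        np.add.at(b, a2, -contrib)
    L = sparse.csr_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))), shape=(nn, nn))
    meta = {"node_shape": nshape, "edges": edges, "center_mm": center_mm,
            "active": np.asarray(L.diagonal() > 0)}
    return L, b, meta


def solve_field(cond: ConductivityMap, exposure: ExposureSpec,
                tol: float = 1e-6, max_iter: int = 20000) -> InducedField:
    """Solve the SPFD system and return the induced-field amplitude.

    The reduced potential ψ is solved to a relative residual ≤ ``tol`` by
    Jacobi-preconditioned conjugate gradients on the active nodes, with the
    zero-mean gauge applied afterwards.  The per-voxel field vector is
    E = ω(∇ψ + A₀) in amplitude, with ∇ψ from averaging the four parallel
    edge differences per axis and A₀ evaluated at voxel centers; air voxels
    are exactly zero.
    """
    L, b, meta = assemble_system(cond, exposure)
    active = meta["active"]
    La = L[active][:, active].tocsr()
    ba = b[active]
    d = La.diagonal()
    M = sparse.diags(1.0 / d)
    # remove the constant nullspace component from the source
    ba = ba - ba.mean()
    x, info = cg(La, ba, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    res = float(np.linalg.norm(La @ x - ba) / np.linalg.norm(ba))
    if info != 0 or res > 10 * tol:
        raise RuntimeError(
            f"SPFD solver did not converge in {max_iter} iterations "
            f"(relative residual {res:.3e})")
    psi = np.zeros(L.shape[0])
    psi[active] = x - x.mean()
    nshape = meta["node_shape"]
    psi3 = psi.reshape(nshape)

    grid = cond.grid
    sigma = cond.sigma
    vox_m = grid.voxel_size * 1e-3
    grad = np.zeros(sigma.shape + (3,))
    # average the 4 parallel edge differences of each voxel per axis
    dx = np.diff(psi3, axis=0) / vox_m   # on (nx, ny+1, nz+1)
    grad[..., 0] = 0.25 * (dx[:, :-1, :-1] + dx[:, 1:, :-1]
                           + dx[:, :-1, 1:] + dx[:, 1:, 1:])
    dy = np.diff(psi3, axis=1) / vox_m
    grad[..., 1] = 0.25 * (dy[:-1, :, :-1] + dy[1:, :, :-1]
                           + dy[:-1, :, 1:] + dy[1:, :, 1:])
    dz = np.diff(psi3, axis=2) / vox_m
    grad[..., 2] = 0.25 * (dz[:-1, :-1, :] + dz[1:, :-1, :]
                           + dz[:-1, 1:, :] + dz[1:, 1:, :])

    centers = np.stack(np.meshgrid(*grid.voxel_centers_axes(),
                                   indexing="ij"), axis=-1)
    a0 = vector_potential(exposure, centers, meta["center_mm"])
    e_vec = -exposure.omega * (grad + a0)
    e_vec[sigma == 0] = 0.0
    return InducedField(e_vec=e_vec, psi=psi3, exposure=exposure, grid=grid,
                        residual=res)
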