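"""Spatially averaged field metrics and hotspot selection.

Two standardized averaging rules reduce voxel-level artifacts before
comparing induced fields with protection limits or seeding fibers:

* 2-mm cubic averaging — each field component is vector-averaged over a
  2×2×2 mm cube lying entirely inside one tissue, then the magnitude is
  taken (ICNIRP convention, with the tissue's 99th percentile as the
  compliance value);
* 5-mm line averaging — the field component along the local field
  direction, averaged over a 5 mm segment centered on the voxel (IEEE
  convention); segments crossing out of the tissue are excluded.

Hotspots are the top-ranked averaged values within a tissue set (fat and
skin by default, the standards' surrogate for peripheral-nerve placement),
with a minimum mutual separation so they span distinct regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["Hotspot", "HotspotSet", "cube_average", "line_average",
           "percentile_filter", "top_hotspots"]


@dataclass(frozen=True)
class Hotspot:
    index: tuple[int, int, int]
    world_mm: np.ndarray
    value: float           # averaged |E|, V/m
    tissue: str


@dataclass
class HotspotSet:
    """Ranked hotspot list (descending by averaged field value)."""

    entries: list[Hotspot]
    method: str                      # 'cube2mm' | 'line5mm' | 'none'
    tissues: tuple[str, ...]

    def __len__(self):
        return len(self.entries)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(
            [{"ix": h.index[0], "iy": h.index[1], "iz": h.index[2],
              "x_mm": h.world_mm[0], "y_mm": h.world_mm[1],
              "z_mm": h.world_mm[2], "value_vm": h.value,
              "tissue": h.tissue} for h in self.entries])


def cube_average(field, grid, cube_mm: float = 2.0) -> np.ndarray:
    """Vector average of E over single-tissue cubes; NaN where undefined.

    The grid is tiled with non-overlapping cubes of ``cube_mm`` edge; each
    component is averaged over the member voxels and the vector magnitude
    assigned to all of them.  Cubes containing air or more than one tissue
    are excluded (NaN), as are air voxels.
    """
    vs = grid.voxel_size
    k = cube_mm / vs
    if vs > cube_mm:
        raise ValueError(f"voxel size {vs} mm exceeds the {cube_mm} mm cube")
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"voxel size {vs} mm does not divide {cube_mm} mm")
    k = int(round(k))
    lab = grid.labels
    e = field.e_vec
    out = np.full(lab.shape, np.nan)
    nx, ny, nz = (s // k for s in lab.shape)
    labc = lab[:nx * k, :ny * k, :nz * k].reshape(nx, k, ny, k, nz, k)
    ec = e[:nx * k, :ny * k, :nz * k].reshape(nx, k, ny, k, nz, k, 3)
    first = labc[:, 0, :, 0, :, 0]
    same = np.all(labc == first[:, None, :, None, :, None], axis=(1, 3, 5))
    valid = same & (first != 0)
    mean = ec.mean(axis=(1, 3, 5))
    mag = np.linalg.norm(mean, axis=-1)
    block = np.where(valid, mag, np.nan)
    out[:nx * k, :ny * k, :nz * k] = np.repeat(
        np.repeat(np.repeat(block, k, axis=0), k, axis=1), k, axis=2)
    out[lab == 0] = np.nan
    return out


def line_average(field, grid, length_mm: float = 5.0) -> np.ndarray:
    """Directed line average of E along the local field direction.

    For each tissue voxel, a segment of ``length_mm`` centered on the voxel
    along the local E direction is sampled at voxel-size steps by trilinear
    interpolation; the value is the mean projection of E on the segment
    direction.  Voxels whose segment leaves their tissue (within half the
    segment length of a boundary along E) are flagged NaN.
    """
    lab = grid.labels
    vs = grid.voxel_size
    e = field.e_vec
    axes = grid.voxel_centers_axes()
    interp = RegularGridInterpolator(axes, e, bounds_error=False,
                                     fill_value=0.0)
    out = np.full(lab.shape, np.nan)
    half = length_mm / 2.0
    n_steps = max(2, int(round(length_mm / vs)))
    offsets = np.linspace(-half, half, n_steps + 1)
    tissue_idx = np.argwhere(lab != 0)
    centers = grid.origin + (tissue_idx + 0.5) * vs
    evec = e[tuple(tissue_idx.T)]
    mags = np.linalg.norm(evec, axis=1)
    ok = mags > 0
    dirs = np.zeros_like(evec)
    dirs[ok] = evec[ok] / mags[ok, None]
    shape = np.array(lab.shape)

    # sample all segments at once: (N, S, 3)
    pts = centers[:, None, :] + offsets[None, :, None] * dirs[:, None, :]
    vidx = np.floor((pts - grid.origin) / vs).astype(int)
    inb = np.all((vidx >= 0) & (vidx < shape), axis=-1)       # (N, S)
    vidx_c = np.clip(vidx, 0, shape - 1)
    seg_lab = lab[vidx_c[..., 0], vidx_c[..., 1], vidx_c[..., 2]]
    own_lab = lab[tuple(tissue_idx.T)]
    same = np.all(inb & (seg_lab == own_lab[:, None]), axis=1)
    valid = ok & same
    if np.any(valid):
        ev = interp(pts[valid].reshape(-1, 3)).reshape(-1, offsets.size, 3)
        proj = np.einsum("nsk,nk->ns", ev, dirs[valid])
        out[tuple(tissue_idx[valid].T)] = proj.mean(axis=1)
    return out


def percentile_filter(values, q: float = 99.0) -> float:
    """q-th percentile (linear interpolation between closest ranks) over
    the valid (finite) values."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no valid values to take a percentile of")
    return float(np.percentile(v, q, method="linear"))


def top_hotspots(averaged: np.ndarray, grid, tissues=("fat", "skin"),
                 n: int = 100, min_separation_mm: float = 10.0,
                 method: str = "none") -> HotspotSet:
    """Top-``n`` averaged-field voxels within the tissue set.

    Candidates are ranked descending; a greedy pass enforces the minimum
    mutual separation so the set spans distinct regions rather than one
    cluster.  Returns fewer entries (with a warning) if the constraint
    exhausts the candidates.
    """
    import warnings
    lab = grid.labels
    allowed = np.zeros(lab.shape, dtype=bool)
    names = {}
    for t in tissues:
        code = grid.label_of(t)
        allowed |= lab == code
        names[code] = t
    vals = np.where(allowed & np.isfinite(averaged), averaged, -np.inf)
    order = np.argsort(vals, axis=None)[::-1]
    picked: list[Hotspot] = []
    coords: list[np.ndarray] = []
    for flat in order:
        if len(picked) >= n:
            break
        v = vals.flat[flat]
        if not np.isfinite(v):
            break
        idx = np.unravel_index(flat, lab.shape)
        world = grid.origin + (np.asarray(idx) + 0.5) * grid.voxel_size
        if min_separation_mm > 0 and coords:
            d = np.linalg.norm(np.asarray(coords) - world, axis=1)
            if np.any(d < min_separation_mm):
                continue
        picked.append(Hotspot(index=tuple(int(i) for i in idx),
                              world_mm=world, value=float(v),
                              tissue=names[int(lab[idx])]))
        coords.append(world)
    if len(picked) < n:
        warnings.warn(f"only {len(picked)} hotspots satisfy the "
                      f"separation/tissue constraints (requested {n})")
    return HotspotSet(entries=picked, method=method, tissues=tuple(tissues))
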