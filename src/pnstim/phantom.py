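"""Synthetic layered torso phantoms.

A stand-in volume conductor for licensed anatomical voxel models: an
elliptical-cylinder torso with concentric skin / subcutaneous-fat / muscle
shells and an interior cortical-bone column.  The elliptical cross section
(front–back vs lateral axes) makes the front-to-back exposure direction
meaningful, as it is for a human trunk.

Coordinate convention (used package-wide): 0-based voxel indices;
world position of a voxel center = origin + (index + 0.5) · voxel_size;
x = left–right, y = front–back, z = inferior–superior.  All lengths in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["TissueGrid", "make_layered_cylinder", "write_grid", "read_grid",
           "DEFAULT_TISSUES"]

#: default label map: air is always 0
DEFAULT_TISSUES = {0: "air", 1: "skin", 2: "fat", 3: "muscle", 4: "bone"}


@dataclass
class TissueGrid:
    """Voxel tissue-label grid.

    ``labels`` is an integer array (0 = air); ``voxel_size`` the cubic voxel
    edge in mm; ``origin`` the world coordinate (mm) of the corner of voxel
    (0,0,0).  Invariants: at least one non-air voxel, labels covered by
    ``tissue_names``, and every non-air voxel with an air face-neighbor is
    skin (the skin layer is the outermost shell).
    """

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    tissue_names: dict[int, str] = dc_field(
        default_factory=lambda: dict(DEFAULT_TISSUES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype,
                                                      np.integer):
            raise ValueError("labels must be a 3-D integer array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.tissue_names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from tissue_names")
        if not (self.labels != 0).any():
            raise ValueError("grid contains no tissue (all air)")

    # -- coordinate helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers_axes(self) -> list[np.ndarray]:
        return [self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.voxel_size
                for i in range(3)]

    def world_to_index(self, point_mm) -> np.ndarray:
        return np.floor((np.asarray(point_mm, float) - self.origin)
                        / self.voxel_size).astype(int)

    def label_at(self, point_mm) -> int:
        idx = self.world_to_index(point_mm)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return 0
        return int(self.labels[tuple(idx)])

    def label_of(self, name: str) -> int:
        for k, v in self.tissue_names.items():
            if v == name:
                return k
        raise KeyError(name)

    def tissue_volumes_mm3(self) -> dict[str, float]:
        vol = self.voxel_size ** 3
        out = {}
        for lab, name in self.tissue_names.items():
            if lab == 0:
                continue
            out[name] = float((self.labels == lab).sum()) * vol
        return out

    def surface_is_skin(self) -> bool:
        """Check the outer-shell invariant (air face-neighbors ⇒ skin)."""
        lab = self.labels
        exposed = _air_adjacent(lab)
        skin = self.label_of("skin")
        return bool(np.all(lab[exposed & (lab != 0)] == skin))


def _air_adjacent(labels: np.ndarray) -> np.ndarray:
    """Mask of voxels with at least one in-domain air face-neighbor.

    The domain boundary is treated as a cut plane (the trunk continues
    beyond the modeled section), not as air.
    """
    air = np.pad(labels == 0, 1, constant_values=False)
    c = np.zeros(labels.shape, dtype=bool)
    core = (slice(1, -1),) * 3
    for ax in range(3):
        for sh in (1, -1):
            c |= np.roll(air, sh, axis=ax)[core]
    return c


def make_layered_cylinder(radius_mm: float = 150.0, height_mm: float = 400.0,
                          layer_thicknesses: dict[str, float] | None = None,
                          voxel_size_mm: float = 2.0,
                          bone_spec: dict | None = None,
                          axis_ratio: float = 1.5,
                          origin_mm=None) -> TissueGrid:
    """Build an elliptical-cylinder torso phantom.

    Parameters
    ----------
    radius_mm
        Lateral (x) semi-axis of the outer body ellipse; the front–back (y)
        semi-axis is ``radius_mm / axis_ratio``.  A torso section is wider
        laterally than front-to-back, which is what makes front-to-back
        exposure the worst case (the induced-current loops lie in the wide
        lateral-vertical plane perpendicular to B).
    height_mm
        Extent along z.
    layer_thicknesses
        Shell thicknesses in mm for ``skin`` and ``fat`` (defaults 2 and 10);
        the remaining interior is muscle.
    voxel_size_mm
        Cubic voxel edge; every layer must be at least one voxel thick.
    bone_spec
        ``{"radius_mm": r, "center_frac": (fx, fy)}`` — circular bone column
        centered at the given fraction of the inner semi-axes (default a
        spine-like posterior column).
    axis_ratio
        Lateral to front–back semi-axis ratio of the ellipse.

    The phantom is deterministic given its arguments.
    """
    layers = {"skin": 2.0, "fat": 10.0}
    if layer_thicknesses:
        layers.update(layer_thicknesses)
    for name in ("skin", "fat"):
        if layers[name] < voxel_size_mm:
            raise ValueError(
                f"layer '{name}' ({layers[name]} mm) is thinner than one "
                f"voxel ({voxel_size_mm} mm)")
    if layers["skin"] + layers["fat"] >= radius_mm / axis_ratio:
        raise ValueError("layer thicknesses must sum to less than the radius")
    bone = {"radius_mm": min(20.0, radius_mm / 6.0), "center_frac": (0.0, -0.4)}
    if bone_spec:
        bone.update(bone_spec)

    ax_ = radius_mm
    ay = radius_mm / axis_ratio
    nx = int(np.ceil(2 * (ax_ + voxel_size_mm) / voxel_size_mm))
    ny = int(np.ceil(2 * (ay + voxel_size_mm) / voxel_size_mm))
    nz = max(1, int(np.round(height_mm / voxel_size_mm)))
    if origin_mm is None:
        origin_mm = np.array([-nx / 2.0, -ny / 2.0, 0.0]) * voxel_size_mm
    origin_mm = np.asarray(origin_mm, float)

    xs = origin_mm[0] + (np.arange(nx) + 0.5) * voxel_size_mm
    ys = origin_mm[1] + (np.arange(ny) + 0.5) * voxel_size_mm
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    def inside(ax_semi, ay_semi):
        return (X / ax_semi) ** 2 + (Y / ay_semi) ** 2 <= 1.0

    t_skin, t_fat = layers["skin"], layers["fat"]
    body = inside(ax_, ay)
    in_skin = inside(ax_ - t_skin, ay - t_skin)
    in_fat = inside(ax_ - t_skin - t_fat, ay - t_skin - t_fat)

    section = np.zeros((nx, ny), dtype=np.int16)
    section[body] = 1                      # skin
    section[in_skin] = 2                   # fat
    section[in_fat] = 3                    # muscle
    bx = bone["center_frac"][0] * (ax_ - t_skin - t_fat)
    by = bone["center_frac"][1] * (ay - t_skin - t_fat)
    rb = bone["radius_mm"]
    bone_mask = ((X - bx) ** 2 + (Y - by) ** 2 <= rb ** 2) & in_fat
    section[bone_mask] = 4                 # bone

    labels = np.repeat(section[:, :, None], nz, axis=2)
    # enforce the outer-shell invariant against voxelization stair-casing:
    # any exposed non-air voxel in-plane becomes skin (top/bottom faces of
    # the cylinder are cut surfaces, not skin)
    exposed = np.zeros((nx, ny), dtype=bool)
    air2d = np.pad(section == 0, 1, constant_values=True)
    for axx in range(2):
        for sh in (1, -1):
            exposed |= np.roll(air2d, sh, axis=axx)[1:-1, 1:-1]
    relabel = exposed & (section != 0)
    labels[relabel, :] = 1

    return TissueGrid(labels=labels, voxel_size=float(voxel_size_mm),
                      origin=origin_mm)


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 labels + JSON sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.json")
    return path.with_name(name + ".labels.json")


def write_grid(grid: TissueGrid, path) -> Path:
    """Write labels as NIfTI-1 plus a JSON sidecar with the label map."""
    path = Path(path)
    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    affine[:3, 3] = grid.origin + 0.5 * grid.voxel_size  # center of voxel 0
    img = nib.Nifti1Image(grid.labels.astype(np.int16), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    side = {
        "tissue_names": {str(k): v for k, v in grid.tissue_names.items()},
        "voxel_size_mm": grid.voxel_size,
        "origin_mm": grid.origin.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def read_grid(path) -> TissueGrid:
    """Read a grid written by :func:`write_grid`; labels must be covered
    by the sidecar map."""
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    side = json.loads(_sidecar_path(path).read_text())
    names = {int(k): v for k, v in side["tissue_names"].items()}
    present = set(np.unique(labels).tolist())
    unknown = present - set(names)
    if unknown:
        raise ValueError(f"file contains labels {sorted(unknown)} absent "
                         f"from sidecar {_sidecar_path(path).name}")
    return TissueGrid(labels=labels, voxel_size=float(side["voxel_size_mm"]),
                      origin=np.asarray(side["origin_mm"]),
                      tissue_names=names)
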