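"""Parametric knee-implant component geometry and rigid placement.

A total knee arthroplasty is modelled as three components: a cobalt-chromium
femoral component (condylar shell), a cobalt-chromium tibial component
(baseplate + stem) and a polyethylene tibial insert (slab).  Two design
variants are provided:

``accurate``
    The geometry the digital phantom itself is built from (cruciate-retaining
    style), so that inpainting with this model at the identity pose restores
    the true attenuation map inside the signal void.
``alternative``
    A perturbed, posterior-stabilised style geometry (thicker condylar shell
    with an intercondylar cam box, wider baseplate) standing in for an
    implant model from a different manufacturer.

Components are voxelised occupancy masks on a reference grid.  Placement is
a rigid-body transform (extrinsic rotations about the grid x, then y, then z
axes, in degrees, about the grid centre, followed by a translation in mm),
resampled with nearest-neighbour interpolation so the discrete label set is
preserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _geometry as geo

#: Material assigned to each component when painting a mu map.
COMPONENT_MATERIALS = {
    "femoral": "cobalt_chromium",
    "tibial": "cobalt_chromium",
    "insert": "polyethylene",
}

# Knee geometry constants (mm) shared with the phantom module; the limb axis
# runs along z with the joint line near z = 48 mm.
LIMB_CENTER = (100.0, 100.0)


def _femoral_shell(shape, voxel, inner_r, outer_r, half_width, z_lo, z_hi):
    x, y, z = geo.coordinate_grids(shape, voxel)
    cx, cy = LIMB_CENTER
    ring = np.sqrt((y - cy) ** 2 + (z - 78.0) ** 2)
    return (
        (ring >= inner_r)
        & (ring <= outer_r)
        & (z >= z_lo)
        & (z <= z_hi)
        & (np.abs(x - cx) <= half_width)
    )


def _accurate_components(shape, voxel):
    cx, cy = LIMB_CENTER
    femoral = _femoral_shell(shape, voxel, 20.0, 26.0, 26.0, 53.0, 78.0)
    plate = geo.cylinder_mask(shape, voxel, (cx, cy), 30.0, 40.0, 44.0)
    stem = geo.cylinder_mask(shape, voxel, (cx, cy), 6.0, 14.0, 40.0)
    insert = geo.cylinder_mask(shape, voxel, (cx, cy), 26.0, 44.0, 52.0)
    return {"femoral": femoral, "tibial": plate | stem, "insert": insert}


def _alternative_components(shape, voxel):
    cx, cy = LIMB_CENTER
    shell = _femoral_shell(shape, voxel, 19.0, 27.0, 28.0, 53.0, 78.0)
    cam = geo.box_mask(
        shape, voxel, (cx - 8.0, cy - 10.0, 54.0), (cx + 8.0, cy + 6.0, 72.0)
    )
    plate = geo.cylinder_mask(shape, voxel, (cx, cy), 32.0, 40.0, 45.0)
    stem = geo.cylinder_mask(shape, voxel, (cx, cy), 7.0, 12.0, 40.0)
    insert = geo.cylinder_mask(shape, voxel, (cx, cy), 24.0, 45.0, 52.0)
    return {"femoral": shell | cam, "tibial": plate | stem, "insert": insert}


_VARIANTS = {"accurate": _accurate_components, "alternative": _alternative_components}


@dataclass
class ImplantModel:
    """Per-component binary occupancy on a reference grid, with materials."""

    occupancy: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float]
    materials: dict[str, str] = field(
        default_factory=lambda: dict(COMPONENT_MATERIALS)
    )
    variant: str = "accurate"

    def __post_init__(self):
        names = list(self.occupancy)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if np.any(self.occupancy[names[a]] & self.occupancy[names[b]]):
                    raise ValueError(
                        f"components {names[a]} and {names[b]} overlap in the "
                        "reference pose"
                    )

    @property
    def components(self) -> list[str]:
        return list(self.occupancy)

    @property
    def grid_shape(self):
        return next(iter(self.occupancy.values())).shape


def build_implant_model(grid_shape, voxel_size_mm, variant: str = "accurate") -> ImplantModel:
    if variant not in _VARIANTS:
        raise ValueError(f"unknown implant variant {variant!r}; choose from {sorted(_VARIANTS)}")
    occ = _VARIANTS[variant](tuple(grid_shape), tuple(voxel_size_mm))
    return ImplantModel(occ, tuple(float(v) for v in voxel_size_mm), variant=variant)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body pose: extrinsic x -> y -> z rotations (degrees) then translation (mm).

    Rotations are about the physical centre of the reference grid.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    @property
    def is_identity(self) -> bool:
        return all(r == 0 for r in self.rotation_deg) and all(
            t == 0 for t in self.translation_mm
        )

    def apply(self, points_mm: np.ndarray, center_mm) -> np.ndarray:
        """Map physical points (N, 3) from model space to target space."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        return (self.matrix() @ (p - c).T).T + c + t

    def apply_inverse(self, points_mm: np.ndarray, center_mm) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        return (self.matrix().T @ (p - c - t).T).T + c


def apply_rigid(
    model: ImplantModel,
    pose: RigidTransform,
    target_shape=None,
    target_voxel_size_mm=None,
) -> dict[str, np.ndarray]:
    """Resample each component's occupancy into the target grid under ``pose``.

    Nearest-neighbour sampling in physical coordinates; an identity pose on
    the model's own grid reproduces the occupancy bit-for-bit, and a
    translation by an exact voxel pitch shifts indices exactly.
    """
    if target_shape is None:
        target_shape = model.grid_shape
    if target_voxel_size_mm is None:
        target_voxel_size_mm = model.voxel_size_mm
    target_shape = tuple(int(n) for n in target_shape)
    d_in = np.asarray(model.voxel_size_mm, dtype=float)
    d_out = np.asarray(target_voxel_size_mm, dtype=float)
    n_in = np.asarray(model.grid_shape, dtype=float)
    center = n_in * d_in / 2.0  # rotation centre: physical centre of model grid
    R = pose.matrix()
    t = np.asarray(pose.translation_mm, dtype=float)

    # i_in = A @ i_out + b maps output voxel indices to input indices through
    # physical space: p_out = (i_out + 0.5) * d_out; p_in = R^T (p_out - c - t) + c.
    A = np.diag(1.0 / d_in) @ R.T @ np.diag(d_out)
    b = (R.T @ (0.5 * d_out - center - t) + center) / d_in - 0.5

    out: dict[str, np.ndarray] = {}
    for name, occ in model.occupancy.items():
        resampled = ndimage.affine_transform(
            occ.astype(np.uint8),
            A,
            offset=b,
            output_shape=target_shape,
            order=0,
            mode="constant",
            cval=0,
            prefilter=False,
        )
        out[name] = resampled.astype(bool)
    return out
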