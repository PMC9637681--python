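"""Voxelisation helpers: cell-centred coordinate grids and cylinder masks."""
from __future__ import annotations

import numpy as np


def axis_centers(n: int, voxel: float) -> np.ndarray:
    """Physical centre coordinates (mm) of ``n`` voxels along one axis."""
    return (np.arange(n) + 0.5) * voxel


def coordinate_grids(shape, voxel_size_mm):
    """Broadcastable centre-coordinate arrays X (nx,1,1), Y (1,ny,1), Z (1,1,nz)."""
    nx, ny, nz = shape
    dx, dy, dz = voxel_size_mm
    x = axis_centers(nx, dx)[:, None, None]
    y = axis_centers(ny, dy)[None, :, None]
    z = axis_centers(nz, dz)[None, None, :]
    return x, y, z


def cylinder_mask(shape, voxel_size_mm, center, radius_mm, z_min, z_max) -> np.ndarray:
    """Voxels whose centre lies in a z-axis-aligned cylinder.

    ``center`` is the (x, y) axis position in mm; the cylinder spans
    ``z_min <= z < z_max``.
    """
    x, y, z = coordinate_grids(shape, voxel_size_mm)
    rho2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    return (rho2 <= radius_mm**2) & (z >= z_min) & (z < z_max)


def box_mask(shape, voxel_size_mm, lo, hi) -> np.ndarray:
    """Voxels whose centre lies in the axis-aligned box [lo, hi) (mm)."""
    x, y, z = coordinate_grids(shape, voxel_size_mm)
    return (
        (x >= lo[0]) & (x < hi[0])
        & (y >= lo[1]) & (y < hi[1])
        & (z >= lo[2]) & (z < hi[2])
    )


def volume_matched_cylinder(
    shape,
    voxel_size_mm,
    center,
    diameter_mm: float,
    volume_ml: float,
    min_voxels: int = 1,
) -> np.ndarray:
    """Voxelise a z-axis finite cylinder so its voxel count matches a target volume.

    The voxel set is chosen by ranking voxels by their signed distance outside
    the analytic cylinder surface (max of radial and axial excess) and keeping
    exactly ``round(volume / voxel_volume)`` of them, so the realised volume is
    within half a voxel volume of the target.  Ties are broken by flat index,
    which makes the mask deterministic.

    ``center`` is the 3-D cylinder centre in mm.
    """
    voxvol_ml = float(np.prod(voxel_size_mm)) / 1000.0
    target_n = int(round(volume_ml / voxvol_ml))
    if target_n < min_voxels:
        raise ValueError(
            f"volume {volume_ml} mL is unrealizable at this grid resolution "
            f"({target_n} voxels < minimum {min_voxels})"
        )
    radius = diameter_mm / 2.0
    height = 1000.0 * volume_ml / (np.pi * radius**2)

    x, y, z = coordinate_grids(shape, voxel_size_mm)
    # score <= 0 inside the analytic cylinder, grows with distance outside
    radial = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2) - radius
    axial = np.abs(z - center[2]) - height / 2.0
    score = np.maximum(radial, axial).ravel()
    if target_n > score.size:
        raise ValueError("cylinder does not fit in the grid")
    order = np.argsort(score, kind="stable")[:target_n]
    worst = float(score[order[-1]])
    if worst > float(np.linalg.norm(voxel_size_mm)):
        raise ValueError(
            "cylinder extends outside the grid or overlaps too few voxels "
            f"(boundary excess {worst:.2f} mm)"
        )
    mask = np.zeros(score.size, dtype=bool)
    mask[order] = True
    return mask.reshape(shape)
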