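"""In-memory volume containers shared across the pipeline.

All volumes are dense 3-D arrays indexed ``[x, y, z]`` with a physical voxel
size in mm.  Indices are 0-based and coordinates are cell-centred: the
physical position of voxel ``(i, j, k)`` is ``((i, j, k) + 0.5) *
voxel_size_mm``.  Slices for the projector are taken along the third (z)
axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


def _as_spacing(value) -> Spacing:
    spacing = tuple(float(v) for v in value)
    if len(spacing) != 3 or any(v <= 0 for v in spacing):
        raise ValueError(f"voxel size must be 3 positive reals, got {value!r}")
    return spacing


@dataclass
class Volume:
    """A 3-D grid of values with physical voxel spacing in mm."""

    values: np.ndarray
    voxel_size_mm: Spacing

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.values.shape}")
        self.voxel_size_mm = _as_spacing(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch between {what}: {self.shape} @ {self.voxel_size_mm} "
                f"vs {other.shape} @ {other.voxel_size_mm}"
            )


@dataclass
class LabelVolume(Volume):
    """Integer material/tissue label grid.

    ``label_names`` maps each integer label to a material name; distinct ids
    may share a material (e.g. the four vial regions are separate ids that
    all map to water-equivalent soft tissue).
    """

    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        present = set(np.unique(self.values).tolist())
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_names")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to ``name``."""
        ids = [i for i, n in self.label_names.items() if n == name]
        out = np.zeros(self.shape, dtype=bool)
        for i in ids:
            out |= self.values == i
        return out


@dataclass
class MuMap(Volume):
    """Linear-attenuation-coefficient grid in cm^-1 at 511 keV."""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("mu map contains negative attenuation coefficients")


@dataclass
class ActivityVolume(Volume):
    """Tracer concentration grid in MBq/mL."""

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("activity volume contains negative concentrations")
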