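"""Digital knee phantom: anatomy labels, tracer activity and ground truth.

The phantom emulates a cadaver-style validation setup for PET quantification
near a total knee arthroplasty: a limb (soft tissue core, adipose rim)
containing femur and tibia, a two-metal-component implant with a
polyethylene insert, and four ~1.5 mL tracer vials — a reference vial on the
skin surface away from the metal, and anterior, mid and posterior vials in
and around the joint.  An MR-style signal void is obtained by dilating the
metal components and relabelling the covered voxels as ``void``.

Vials are modelled as finite cylinders of the configured diameter (default
10 mm, matching the recovery-coefficient assumption); the voxelised vial is
volume-matched so that its voxel count times the voxel volume lands within
half a voxel volume of the dispensed tracer volume.  The in-vial activity
concentration is dispensed activity / realised volume, so the integral of
the activity image equals the configured activity exactly.

Geometry is deterministic; all coordinates are in mm on the 200 x 200 x 120
mm field of view of the default grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _geometry as geo
from .implants import LIMB_CENTER, build_implant_model
from .volumes import ActivityVolume, LabelVolume

# ---------------------------------------------------------------------------
# label ids
L_AIR = 0
L_SOFT = 1
L_ADIPOSE = 2
L_BONE = 3
L_FEMORAL = 4
L_TIBIAL = 5
L_INSERT = 6
L_VIAL_BASE = 10  # vials are L_VIAL_BASE + index
L_VOID = 99

#: material name for each structural label
STRUCTURE_NAMES = {
    L_AIR: "air",
    L_SOFT: "soft_tissue",
    L_ADIPOSE: "adipose",
    L_BONE: "bone",
    L_FEMORAL: "cobalt_chromium",
    L_TIBIAL: "cobalt_chromium",
    L_INSERT: "polyethylene",
}

VOID_NAME = "void"

# limb anatomy (mm)
SOFT_TISSUE_RADIUS = 70.0
SKIN_RADIUS = 78.0
BONE_RADIUS = 14.0
FEMUR_Z_MIN = 79.0
TIBIA_Z_MAX = 40.0


@dataclass(frozen=True)
class VialSpec:
    """One tracer vial: a z-axis cylinder with known volume and activity."""

    name: str
    volume_ml: float
    activity_mbq: float
    center: tuple[float, float, float]
    diameter_mm: float = 10.0

    def __post_init__(self):
        if self.volume_ml <= 0 or self.activity_mbq <= 0 or self.diameter_mm <= 0:
            raise ValueError(f"vial {self.name}: volume, activity and diameter must be positive")

    @property
    def concentration_mbq_per_ml(self) -> float:
        return self.activity_mbq / self.volume_ml


def default_vials() -> list[VialSpec]:
    """The four-vial layout of the validation experiment.

    Known (gold standard) volumes and activities: 1.52/1.53/1.56/1.57 mL and
    1.15/1.16/1.18/1.19 MBq for the reference, anterior, mid and posterior
    vials (totals 6.18 mL, 4.68 MBq, ~0.76 MBq/mL).
    """
    cx, cy = LIMB_CENTER
    return [
        VialSpec("reference", 1.52, 1.15, (cx, cy - 83.0, 100.0)),
        VialSpec("anterior", 1.53, 1.16, (cx, cy - 38.0, 48.0)),
        VialSpec("mid", 1.56, 1.18, (cx + 37.0, cy, 48.0)),
        VialSpec("posterior", 1.57, 1.19, (cx, cy + 38.0, 48.0)),
    ]


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (160, 160, 40)
    voxel_size_mm: tuple[float, float, float] = (1.25, 1.25, 3.0)
    vial_specs: list[VialSpec] = field(default_factory=default_vials)
    void_dilation_mm: float = 4.0
    rng_seed: int = 0
    min_vial_voxels: int = 10

    def __post_init__(self):
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if any(float(v) <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be strictly positive")
        if self.void_dilation_mm < 0:
            raise ValueError("void_dilation_mm must be >= 0")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)


def default_config() -> PhantomConfig:
    return PhantomConfig()


@dataclass(frozen=True)
class VialTruth:
    name: str
    volume_ml: float
    activity_mbq: float

    @property
    def concentration_mbq_per_ml(self) -> float:
        return self.activity_mbq / self.volume_ml


@dataclass
class GroundTruth:
    """Known per-vial volumes/activities; volumes realised by voxel counting."""

    vials: list[VialTruth]

    @property
    def total_activity_mbq(self) -> float:
        return float(sum(v.activity_mbq for v in self.vials))

    @property
    def total_volume_ml(self) -> float:
        return float(sum(v.volume_ml for v in self.vials))

    def vial(self, name: str) -> VialTruth:
        for v in self.vials:
            if v.name == name:
                return v
        raise KeyError(f"no vial named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "vial": v.name,
                "volume_ml": v.volume_ml,
                "activity_mbq": v.activity_mbq,
                "concentration_mbq_per_ml": v.concentration_mbq_per_ml,
            }
            for v in self.vials
        ]
        rows.append(
            {
                "vial": "total",
                "volume_ml": self.total_volume_ml,
                "activity_mbq": self.total_activity_mbq,
                "concentration_mbq_per_ml": self.total_activity_mbq / self.total_volume_ml
                if self.total_volume_ml
                else float("nan"),
            }
        )
        return pd.DataFrame(rows)


def vial_mask(config: PhantomConfig, spec: VialSpec) -> np.ndarray:
    """Volume-matched voxel mask for one vial on the phantom grid."""
    return geo.volume_matched_cylinder(
        config.grid_shape,
        config.voxel_size_mm,
        spec.center,
        spec.diameter_mm,
        spec.volume_ml,
        min_voxels=config.min_vial_voxels,
    )


def build_knee_phantom(config: PhantomConfig):
    """Build (LabelVolume, ActivityVolume, GroundTruth) for the knee phantom."""
    shape, voxel = config.grid_shape, config.voxel_size_mm
    cx, cy = LIMB_CENTER
    x, y, z = geo.coordinate_grids(shape, voxel)
    rho2 = (x - cx) ** 2 + (y - cy) ** 2 + 0.0 * z

    labels = np.zeros(shape, dtype=np.int16)
    labels[rho2 <= SKIN_RADIUS**2] = L_ADIPOSE
    labels[rho2 <= SOFT_TISSUE_RADIUS**2] = L_SOFT
    bone = (rho2 <= BONE_RADIUS**2) & ((z >= FEMUR_Z_MIN) | (z <= TIBIA_Z_MAX))
    labels[bone] = L_BONE

    implant = build_implant_model(shape, voxel, variant="accurate")
    labels[implant.occupancy["insert"]] = L_INSERT
    labels[implant.occupancy["tibial"]] = L_TIBIAL
    labels[implant.occupancy["femoral"]] = L_FEMORAL
    metal = (labels == L_FEMORAL) | (labels == L_TIBIAL)

    label_names = dict(STRUCTURE_NAMES)
    activity = np.zeros(shape, dtype=np.float64)
    voxvol_ml = float(np.prod(voxel)) / 1000.0
    truths: list[VialTruth] = []
    for i, spec in enumerate(config.vial_specs):
        mask = vial_mask(config, spec)
        if np.any(mask & metal):
            raise ValueError(f"vial {spec.name!r} overlaps a metal implant component")
        label_id = L_VIAL_BASE + i
        labels[mask] = label_id
        label_names[label_id] = "soft_tissue"  # water-equivalent vial contents
        realised_ml = int(mask.sum()) * voxvol_ml
        activity[mask] = spec.activity_mbq / realised_ml
        truths.append(VialTruth(spec.name, realised_ml, spec.activity_mbq))

    label_volume = LabelVolume(labels, voxel, label_names=label_names)
    activity_volume = ActivityVolume(activity, voxel)
    return label_volume, activity_volume, GroundTruth(truths)


def simulate_signal_void(labels: LabelVolume, dilation_mm: float) -> np.ndarray:
    """Binary mask of the MR signal void: metal dilated by ``dilation_mm``.

    Dilation is an exact Euclidean ball in physical units (anisotropic voxel
    sizes handled via the distance transform), so the mask is always a
    superset of the metal voxels and grows monotonically with the radius.
    """
    if dilation_mm < 0:
        raise ValueError("dilation_mm must be >= 0")
    metal = labels.mask("cobalt_chromium")
    if not metal.any():
        return np.zeros(labels.shape, dtype=bool)
    if dilation_mm == 0:
        return metal
    dist = ndimage.distance_transform_edt(~metal, sampling=labels.voxel_size_mm)
    return dist <= dilation_mm + 1e-9


def make_degraded_labels(labels: LabelVolume, void_mask: np.ndarray) -> LabelVolume:
    """Relabel voxels under the void mask as unknown/void; all else unchanged."""
    void_mask = np.asarray(void_mask)
    if void_mask.shape != labels.shape:
        raise ValueError(
            f"void mask shape {void_mask.shape} does not match labels {labels.shape}"
        )
    out = labels.values.copy()
    out[void_mask.astype(bool)] = L_VOID
    names = dict(labels.label_names)
    names[L_VOID] = VOID_NAME
    return LabelVolume(out, labels.voxel_size_mm, label_names=names)
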