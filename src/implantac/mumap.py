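"""Attenuation-map construction and signal-void inpainting strategies.

A segmentation label volume is converted to a 511 keV linear-attenuation-
coefficient map by direct per-material lookup.  When the labels contain an
MR signal void around a metal implant, three strategies fill it:

``inpaint_original``
    Leave the void as it comes out of a fat/water-based MR attenuation map:
    the void voxels carry the coefficient of air.  This reproduces the
    uncorrected behaviour that under-corrects the emission data.
``inpaint_simple_tissue``
    Fill the void uniformly with the soft-tissue coefficient.
``inpaint_with_model``
    Place rigid implant component geometry into the void: void voxels covered
    by a transformed metal component get the cobalt-chromium coefficient,
    voxels covered by the insert get polyethylene, and the remaining void is
    soft tissue.  Voxels outside the void are never modified.

All strategies are pure lookups — output values are drawn from the material
table (plus 0 for air), never interpolated.
"""
from __future__ import annotations

import logging

import numpy as np

from .implants import ImplantModel, RigidTransform, apply_rigid
from .materials import MaterialTable
from .phantom import VOID_NAME
from .volumes import LabelVolume, MuMap

logger = logging.getLogger(__name__)


def _void_ids(labels: LabelVolume) -> list[int]:
    return [i for i, n in labels.label_names.items() if n == VOID_NAME]


def _void_mask(labels: LabelVolume) -> np.ndarray:
    mask = np.zeros(labels.shape, dtype=bool)
    for i in _void_ids(labels):
        mask |= labels.values == i
    return mask


def _lookup(labels: LabelVolume, table: MaterialTable, overrides=None) -> np.ndarray:
    """Per-voxel LAC lookup via a label-id LUT; ``overrides`` maps id -> LAC."""
    overrides = overrides or {}
    present = set(np.unique(labels.values).tolist())
    unknown = sorted(
        i
        for i in present
        if i not in overrides and labels.label_names[i] not in table
    )
    if unknown:
        names = {i: labels.label_names[i] for i in unknown}
        raise ValueError(f"labels with no material-table entry: {names}")
    max_id = int(max(present))
    lut = np.zeros(max_id + 1, dtype=np.float64)
    for i in present:
        lut[i] = overrides.get(i, table.get(labels.label_names[i], 0.0))
    return lut[labels.values]


def mumap_from_labels(labels: LabelVolume, table: MaterialTable | None = None) -> MuMap:
    """Direct label -> LAC conversion; refuses label volumes with a void."""
    table = table or MaterialTable.default()
    present = set(np.unique(labels.values).tolist())
    voids = [i for i in _void_ids(labels) if i in present]
    if voids:
        raise ValueError(
            "label volume contains void voxels; use inpaint_original, "
            "inpaint_simple_tissue or inpaint_with_model instead"
        )
    return MuMap(_lookup(labels, table), labels.voxel_size_mm)


def _inpaint_constant(labels: LabelVolume, table: MaterialTable, fill_lac: float) -> MuMap:
    overrides = {i: fill_lac for i in _void_ids(labels)}
    return MuMap(_lookup(labels, table, overrides), labels.voxel_size_mm)


def inpaint_original(labels: LabelVolume, table: MaterialTable | None = None) -> MuMap:
    """Void voxels keep the coefficient of air (0) — the uncorrected map."""
    table = table or MaterialTable.default()
    return _inpaint_constant(labels, table, 0.0)


def inpaint_simple_tissue(labels: LabelVolume, table: MaterialTable | None = None) -> MuMap:
    """Void voxels are filled with the soft-tissue coefficient."""
    table = table or MaterialTable.default()
    return _inpaint_constant(labels, table, table["soft_tissue"])


def inpaint_with_model(
    labels: LabelVolume,
    table: MaterialTable | None = None,
    model: ImplantModel | None = None,
    pose: RigidTransform | None = None,
    overlap_warn_fraction: float = 0.05,
) -> MuMap:
    """Fill the void with rigidly placed implant geometry over soft tissue.

    Precedence inside the void is metal over polyethylene over soft tissue.
    A component transformed entirely outside the grid raises; a component
    whose in-grid occupancy overlaps non-void anatomy of a different
    material by more than ``overlap_warn_fraction`` logs a warning (the
    placement is likely misregistered but the map is still produced, as a
    human operator would).
    """
    table = table or MaterialTable.default()
    if model is None:
        raise ValueError("inpaint_with_model requires an implant model")
    pose = pose or RigidTransform()
    void = _void_mask(labels)
    mu = _inpaint_constant(labels, table, table["soft_tissue"])
    values = mu.values

    occ = apply_rigid(model, pose, labels.shape, labels.voxel_size_mm)
    # polyethylene first so that metal components take precedence
    order = sorted(
        model.components,
        key=lambda c: 0 if model.materials[c] == "polyethylene" else 1,
    )
    for comp in order:
        comp_occ = occ[comp]
        if model.occupancy[comp].any() and not comp_occ.any():
            raise ValueError(
                f"implant component {comp!r} transformed entirely outside the grid"
            )
        n_occ = int(comp_occ.sum())
        if n_occ:
            matching = labels.mask(model.materials[comp])
            outside = float((comp_occ & ~void & ~matching).sum()) / n_occ
            if outside > overlap_warn_fraction:
                logger.warning(
                    "component %r overlaps non-void anatomy on %.1f%% of its "
                    "voxels; check the registration pose",
                    comp,
                    100.0 * outside,
                )
        values[comp_occ & void] = table[model.materials[comp]]
    return MuMap(values, labels.voxel_size_mm)
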