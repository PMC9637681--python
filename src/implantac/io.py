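"""File formats: NIfTI volumes, sinograms, ground truth, provenance sidecars.

Volumes are written as NIfTI-1 (.nii / .nii.gz) with the voxel spacing in
the header affine (diagonal, mm).  Sinograms are .npy arrays with a JSON
sidecar carrying the projection geometry, acquisition scale and source grid.
Every writer can attach a provenance sidecar ``<path>.json`` recording the
stage, seed and configuration hash.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import GroundTruth, PhantomConfig
from .projector import ProjectionGeometry, Sinogram
from .volumes import ActivityVolume, LabelVolume, MuMap, Volume


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _write_sidecar(path: Path, metadata: dict | None, stage: str) -> None:
    if metadata is None:
        return
    sidecar = dict(metadata)
    sidecar.setdefault("stage", stage)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def write_volume(path, volume: Volume, metadata: dict | None = None) -> None:
    """Write a float volume as NIfTI-1 (float32) with spacing in the header."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(volume.values, dtype=np.float32), _affine(volume.voxel_size_mm)
    )
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))
    _write_sidecar(path, metadata, "volume")


def write_label_volume(path, labels: LabelVolume, metadata: dict | None = None) -> None:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(labels.values, dtype=np.int16), _affine(labels.voxel_size_mm)
    )
    img.header.set_zooms(labels.voxel_size_mm)
    nib.save(img, str(path))
    sidecar = dict(metadata or {})
    sidecar["label_names"] = {str(k): v for k, v in labels.label_names.items()}
    _write_sidecar(path, sidecar, "labels")


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path, kind: str = "generic") -> Volume:
    """Read a NIfTI volume; ``kind`` in {generic, activity, mu, labels}."""
    data, spacing = _load_nifti(path)
    if kind == "activity":
        return ActivityVolume(np.asarray(data, dtype=np.float64), spacing)
    if kind == "mu":
        return MuMap(np.asarray(data, dtype=np.float64), spacing)
    if kind == "labels":
        return read_label_volume(path)
    return Volume(data, spacing)


def read_label_volume(path) -> LabelVolume:
    """Read labels plus the ``label_names`` mapping from the JSON sidecar."""
    data, spacing = _load_nifti(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"label volume {path} has no sidecar {sidecar_path} with label_names"
        )
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    names = {int(k): str(v) for k, v in sidecar["label_names"].items()}
    return LabelVolume(np.asarray(data, dtype=np.int16), spacing, label_names=names)


def write_sinogram(path, sinogram: Sinogram, metadata: dict | None = None) -> None:
    path = Path(path)
    np.save(str(path), sinogram.values)
    sidecar = dict(metadata or {})
    sidecar["geometry"] = {
        "n_angles": sinogram.geometry.n_angles,
        "detector_pitch_mm": sinogram.geometry.detector_pitch_mm,
        "n_radial_bins": sinogram.geometry.n_radial_bins,
    }
    sidecar["total_acquisition_scale"] = sinogram.total_acquisition_scale
    sidecar["grid_shape"] = list(sinogram.grid_shape)
    sidecar["voxel_size_mm"] = list(sinogram.voxel_size_mm)
    _write_sidecar(path, sidecar, "sinogram")


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sinogram: {path}")
    values = np.load(str(path))
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    g = sidecar["geometry"]
    geometry = ProjectionGeometry(
        n_angles=int(g["n_angles"]),
        detector_pitch_mm=float(g["detector_pitch_mm"]),
        n_radial_bins=int(g["n_radial_bins"]),
    )
    return Sinogram(
        values,
        geometry,
        float(sidecar["total_acquisition_scale"]),
        tuple(sidecar["grid_shape"]),
        tuple(sidecar["voxel_size_mm"]),
    )


def write_ground_truth(path, truth: GroundTruth, config: PhantomConfig | None = None) -> None:
    """Ground truth as JSON (with vial geometry, for downstream ROI building)."""
    path = Path(path)
    payload = {
        "vials": [
            {
                "name": v.name,
                "volume_ml": v.volume_ml,
                "activity_mbq": v.activity_mbq,
                "concentration_mbq_per_ml": v.concentration_mbq_per_ml,
            }
            for v in truth.vials
        ],
        "total_activity_mbq": truth.total_activity_mbq,
        "total_volume_ml": truth.total_volume_ml,
    }
    if config is not None:
        payload["vial_specs"] = [asdict(v) for v in config.vial_specs]
        payload["grid_shape"] = list(config.grid_shape)
        payload["voxel_size_mm"] = list(config.voxel_size_mm)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    truth.to_frame().to_csv(path.with_suffix(".csv"), index=False)


def read_ground_truth(path):
    """Returns (GroundTruth, vial_specs or None, grid_shape, voxel_size)."""
    from .phantom import VialSpec, VialTruth

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such ground-truth file: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    truth = GroundTruth(
        [
            VialTruth(v["name"], v["volume_ml"], v["activity_mbq"])
            for v in payload["vials"]
        ]
    )
    specs = None
    if "vial_specs" in payload:
        specs = [
            VialSpec(
                s["name"], s["volume_ml"], s["activity_mbq"],
                tuple(s["center"]), s.get("diameter_mm", 10.0),
            )
            for s in payload["vial_specs"]
        ]
    grid = tuple(payload.get("grid_shape", ())) or None
    voxel = tuple(payload.get("voxel_size_mm", ())) or None
    return truth, specs, grid, voxel
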