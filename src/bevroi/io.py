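"""Readers/writers: NIfTI volumes, 16-bit PNG images with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .phantom import CTVolume
from .projection import BeamGeometry, DRRImage


def save_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI plus a JSON sidecar (isocenter, metadata)."""
    import nibabel as nib

    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), path)
    sidecar = {
        "isocenter_mm": [float(v) for v in volume.isocenter],
        "metadata": _jsonable(volume.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_volume(path) -> CTVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    iso = np.zeros(3)
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        payload = json.loads(sc.read_text())
        iso = np.asarray(payload.get("isocenter_mm", iso))
        meta = payload.get("metadata", {})
    return CTVolume(
        values=np.asarray(img.dataobj, dtype=np.float32),
        spacing=spacing,
        origin=origin,
        isocenter=iso,
        metadata=meta,
    )


def save_image(drr: DRRImage, path) -> None:
    """16-bit PNG (intensities scaled to the image range) + JSON sidecar
    carrying geometry and the scaling needed to undo the quantization."""
    import imageio.v3 as iio

    path = Path(path)
    px = np.asarray(drr.pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    iio.imwrite(path, ((px - lo) * scale).astype(np.uint16))
    sidecar = {
        "pitch_mm": drr.pitch_mm,
        "principal_point": list(drr.principal_point),
        "intensity_lo": lo,
        "intensity_hi": hi,
        "geometry": {
            "gantry_deg": drr.geometry.gantry_deg,
            "couch_deg": drr.geometry.couch_deg,
            "sad_mm": drr.geometry.sad_mm,
            "sid_mm": drr.geometry.sid_mm,
            "panel_pitch_mm": drr.geometry.panel_pitch_mm,
        },
        "metadata": _jsonable(drr.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_image(path) -> DRRImage:
    import imageio.v3 as iio

    path = Path(path)
    payload = json.loads(_sidecar_path(path).read_text())
    raw = iio.imread(path).astype(float)
    lo, hi = payload["intensity_lo"], payload["intensity_hi"]
    pixels = raw / 65535.0 * (hi - lo) + lo if hi > lo else raw * 0 + lo
    g = payload["geometry"]
    return DRRImage(
        pixels=pixels,
        pitch_mm=payload["pitch_mm"],
        principal_point=tuple(payload["principal_point"]),
        geometry=BeamGeometry(
            gantry_deg=g["gantry_deg"],
            couch_deg=g["couch_deg"],
            sad_mm=g["sad_mm"],
            sid_mm=g["sid_mm"],
            panel_pitch_mm=g["panel_pitch_mm"],
        ),
        metadata=payload.get("metadata", {}),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".png", ".tif", ".tiff"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
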