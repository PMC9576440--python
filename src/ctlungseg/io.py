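"""Reading and writing CT volumes and masks.

Supported formats: NIfTI (via nibabel), directories of per-slice 16-bit
PNGs with a JSON sidecar (via pillow), and DICOM series directories
(via pydicom, read-only). PNG stacks store ``HU + 1024`` clipped to
[0, 65535] so air (−1000 HU) is representable in an unsigned format.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .volume import CTVolume, MaskVolume

__all__ = [
    "save_nifti",
    "load_nifti_volume",
    "load_nifti_mask",
    "save_png_case",
    "load_png_case",
    "load_dicom_series",
]

_PNG_OFFSET = 1024


def _affine(spacing) -> np.ndarray:
    z, y, x = spacing if spacing is not None else (1.0, 1.0, 1.0)
    return np.diag([x, y, z, 1.0])


def save_nifti(data: CTVolume | MaskVolume, path: str | Path) -> None:
    """Write a volume or mask as NIfTI; axes stored as (x, y, z)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spacing = getattr(data, "spacing", None)
    arr = data.voxels.transpose(2, 1, 0)  # (slice,row,col) -> (x,y,z)
    img = nib.Nifti1Image(np.asarray(arr), _affine(spacing))
    nib.save(img, str(path))


def load_nifti_volume(path: str | Path, case_id: str | None = None) -> CTVolume:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).transpose(2, 1, 0).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(arr, spacing=spacing, case_id=case_id or Path(path).stem)


def load_nifti_mask(path: str | Path, case_id: str | None = None) -> MaskVolume:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    return MaskVolume((arr > 0.5).astype(np.uint8), case_id=case_id or Path(path).stem)


def save_png_case(
    volume: CTVolume,
    mask: MaskVolume | None,
    out_dir: str | Path,
    sidecar: dict | None = None,
) -> None:
    """Write a case as per-slice 16-bit PNGs plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, sl in enumerate(volume.voxels):
        stored = np.clip(sl + _PNG_OFFSET, 0, 65535).astype(np.uint16)
        Image.fromarray(stored).save(out_dir / f"slice_{k:04d}.png")
        if mask is not None:
            Image.fromarray(mask.voxels[k].astype(np.uint16) * np.uint16(65535)).save(
                out_dir / f"mask_{k:04d}.png"
            )
    meta = {
        "case_id": volume.case_id,
        "n_slices": volume.n_slices,
        "spacing": volume.spacing,
        "hu_offset": _PNG_OFFSET,
    }
    if sidecar:
        meta.update(sidecar)
    (out_dir / "case.json").write_text(json.dumps(meta, indent=2))


def load_png_case(case_dir: str | Path) -> tuple[CTVolume, MaskVolume | None, dict]:
    """Read back a :func:`save_png_case` directory."""
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "case.json").read_text())
    slices = sorted(case_dir.glob("slice_*.png"))
    if not slices:
        raise FileNotFoundError(f"no slice PNGs in {case_dir}")
    stack = np.stack(
        [np.asarray(Image.open(p), dtype=np.float32) - meta["hu_offset"] for p in slices]
    )
    spacing = tuple(meta["spacing"]) if meta.get("spacing") else None
    volume = CTVolume(stack, spacing=spacing, case_id=meta.get("case_id", case_dir.name))
    masks = sorted(case_dir.glob("mask_*.png"))
    mask = None
    if masks:
        mstack = np.stack([np.asarray(Image.open(p)) > 0 for p in masks]).astype(np.uint8)
        mask = MaskVolume(mstack, case_id=volume.case_id)
    return volume, mask, meta


def load_dicom_series(series_dir: str | Path, case_id: str | None = None) -> CTVolume:
    """Read a DICOM series directory, sorted by slice position.

    Slices are ordered by ImagePositionPatient z (falling back to
    InstanceNumber) and rescaled to HU with RescaleSlope/Intercept.
    """
    import pydicom

    series_dir = Path(series_dir)
    files = sorted(p for p in series_dir.iterdir() if p.suffix.lower() in (".dcm", ""))
    datasets = [pydicom.dcmread(str(p)) for p in files if p.is_file()]
    if not datasets:
        raise FileNotFoundError(f"no DICOM files in {series_dir}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        return float(pos[2]) if pos is not None else float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    ds0 = datasets[0]
    pixel = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(
        np.stack(slices),
        spacing=(thickness, float(pixel[0]), float(pixel[1])),
        case_id=case_id or series_dir.name,
    )
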