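"""Slice denoising and body-region crop-and-zoom.

In pediatric chest CT the thorax covers well under a fifth of the
512×512 frame, so most pixels are air and table. Each slice is first
smoothed with an isotropic 2D Gaussian (default σ = 3 px), then the body
is located by HU clipping, thresholding, morphological opening and
selection of the largest connected domain; the circumscribed rectangle
of that domain (one union box per case) is cropped out and zoomed to a
uniform 256×256. The transform is recorded so predictions can be mapped
back to original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import label, regionprops
from skimage.transform import resize

from .volume import CTVolume, MaskVolume

__all__ = [
    "PreprocessConfig",
    "CropTransform",
    "NoBodyFoundError",
    "gaussian_smooth",
    "locate_body",
    "crop_and_zoom",
    "invert_transform",
    "preprocess_case",
]


class NoBodyFoundError(RuntimeError):
    """Raised when thresholding + opening leaves no foreground."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the crop-and-zoom stage.

    sigma : Gaussian width in pixels (3 preserves lung boundaries while
    suppressing noise); body_hu_window : HU clip bounds applied before
    thresholding; body_threshold : HU separating body from air;
    opening_radius : disk radius of the morphological opening that cuts
    thin table/blanket bridges; margin : bounding-box padding in pixels;
    out_size : output side length.
    """

    sigma: float = 3.0
    body_hu_window: tuple[float, float] = (-1000.0, 400.0)
    body_threshold: float = -300.0
    opening_radius: int = 3
    margin: int = 4
    out_size: int = 256

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.out_size < 16:
            raise ValueError(f"out_size must be >= 16, got {self.out_size}")
        lo, hi = self.body_hu_window
        if lo >= hi:
            raise ValueError(f"body_hu_window must satisfy low < high, got {self.body_hu_window}")


@dataclass(frozen=True)
class CropTransform:
    """Invertible record of the body crop applied to one case.

    ``bbox`` is (row_min, row_max, col_min, col_max) in original pixel
    coordinates, 0-based and half-open; ``original_size`` is the
    (rows, cols) of the source slices; ``out_size`` the square side
    length the crop was zoomed to.
    """

    bbox: tuple[int, int, int, int]
    original_size: tuple[int, int]
    out_size: int

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.bbox
        nr, nc = self.original_size
        if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
            raise ValueError(f"bbox {self.bbox} invalid for size {self.original_size}")


def gaussian_smooth(image: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Convolve a 2D slice with an isotropic Gaussian of width ``sigma``.

    Reflect padding avoids a dark halo at the frame edges; the output
    has the same shape and (on interior-dominated images) the same mean
    as the input.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={image.ndim}")
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")


def _body_mask_2d(slice_hu: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.body_hu_window
    clipped = np.clip(slice_hu, lo, hi)
    binary = clipped > cfg.body_threshold
    if cfg.opening_radius > 0:
        binary = ndimage.binary_opening(binary, structure=morphology.disk(cfg.opening_radius))
    return binary


def _largest_component_bbox(binary: np.ndarray) -> tuple[int, int, int, int] | None:
    labels = label(binary, connectivity=2)  # 8-connectivity
    if labels.max() == 0:
        return None
    regions = regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = largest.bbox
    return r0, r1, c0, c1


def locate_body(
    data: np.ndarray | CTVolume, cfg: PreprocessConfig | None = None
) -> CropTransform:
    """Find the chest bounding box of a slice or a whole case.

    Threshold the HU-clipped image, open with a small disk to detach
    table/blanket bridges, keep the largest 8-connected component, and
    take its circumscribed rectangle plus ``cfg.margin``. For a volume
    the union box over slices is returned so a single transform serves
    the whole case.
    """
    cfg = cfg or PreprocessConfig()
    if isinstance(data, CTVolume):
        stack = data.voxels
        case_id = data.case_id
    else:
        arr = np.asarray(data)
        stack = arr[None] if arr.ndim == 2 else arr
        case_id = "slice"

    nr, nc = stack.shape[1:]
    union = None
    for sl in stack:
        box = _largest_component_bbox(_body_mask_2d(sl, cfg))
        if box is None:
            continue
        if union is None:
            union = list(box)
        else:
            union[0] = min(union[0], box[0])
            union[1] = max(union[1], box[1])
            union[2] = min(union[2], box[2])
            union[3] = max(union[3], box[3])
    if union is None:
        raise NoBodyFoundError(f"no body found in {case_id!r}: empty foreground after opening")

    m = cfg.margin
    bbox = (
        max(0, union[0] - m),
        min(nr, union[1] + m),
        max(0, union[2] - m),
        min(nc, union[3] + m),
    )
    return CropTransform(bbox=bbox, original_size=(nr, nc), out_size=cfg.out_size)


def crop_and_zoom(
    volume: CTVolume,
    mask: MaskVolume | None,
    transform: CropTransform,
    cfg: PreprocessConfig | None = None,
) -> tuple[CTVolume, MaskVolume | None]:
    """Crop every slice to the body box and resample to ``out_size``².

    The image is resampled with bilinear interpolation; the mask with
    nearest-neighbour so it stays binary.
    """
    cfg = cfg or PreprocessConfig()
    if volume.slice_shape != transform.original_size:
        raise ValueError(
            f"volume slices {volume.slice_shape} do not match transform "
            f"original_size {transform.original_size}"
        )
    if mask is not None and mask.voxels.shape != volume.voxels.shape:
        raise ValueError("mask shape does not match volume shape")

    r0, r1, c0, c1 = transform.bbox
    out = transform.out_size
    out_img = np.empty((volume.n_slices, out, out), dtype=np.float32)
    out_msk = (
        np.empty((volume.n_slices, out, out), dtype=np.uint8) if mask is not None else None
    )
    for k in range(volume.n_slices):
        crop = volume.voxels[k, r0:r1, c0:c1]
        out_img[k] = resize(
            crop.astype(np.float64), (out, out), order=1, mode="edge",
            anti_aliasing=crop.shape[0] > out, preserve_range=True,
        )
        if out_msk is not None:
            mcrop = mask.voxels[k, r0:r1, c0:c1]
            out_msk[k] = resize(
                mcrop, (out, out), order=0, mode="edge",
                anti_aliasing=False, preserve_range=True,
            ).astype(np.uint8)

    cropped = CTVolume(out_img, spacing=volume.spacing, case_id=volume.case_id)
    return cropped, (MaskVolume(out_msk, case_id=mask.case_id) if mask is not None else None)


def invert_transform(mask256: MaskVolume, transform: CropTransform) -> MaskVolume:
    """Map a mask in cropped coordinates back to the original frame.

    The prediction is nearest-neighbour resampled to the bbox size and
    placed inside the bbox; everything outside is zero.
    """
    out = transform.out_size
    if mask256.slice_shape != (out, out):
        raise ValueError(
            f"mask slices {mask256.slice_shape} do not match out_size {out}"
        )
    r0, r1, c0, c1 = transform.bbox
    nr, nc = transform.original_size
    full = np.zeros((mask256.n_slices, nr, nc), dtype=np.uint8)
    for k in range(mask256.n_slices):
        full[k, r0:r1, c0:c1] = resize(
            mask256.voxels[k], (r1 - r0, c1 - c0), order=0, mode="edge",
            anti_aliasing=False, preserve_range=True,
        ).astype(np.uint8)
    return MaskVolume(full, case_id=mask256.case_id)


def preprocess_case(
    volume: CTVolume,
    mask: MaskVolume | None = None,
    cfg: PreprocessConfig | None = None,
) -> tuple[CTVolume, MaskVolume | None, CropTransform]:
    """Smooth, locate the body, crop and zoom one case in one call."""
    cfg = cfg or PreprocessConfig()
    smoothed = np.stack([gaussian_smooth(sl, cfg.sigma) for sl in volume.voxels])
    smooth_vol = CTVolume(
        smoothed.astype(np.float32), spacing=volume.spacing, case_id=volume.case_id
    )
    transform = locate_body(smooth_vol, cfg)
    cropped, cropped_mask = crop_and_zoom(smooth_vol, mask, transform, cfg)
    return cropped, cropped_mask, transform
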