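"""Core in-memory containers for CT cases.

A case is an ordered stack of axial slices. Intensities are Hounsfield
units (HU): air ≈ −1000, aerated lung ≈ −800…−500, soft tissue ≈ 0–60,
bone a few hundred. Masks are binary lung masks aligned voxel-for-voxel
with their CT volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "MaskVolume"]


@dataclass
class CTVolume:
    """Ordered stack of axial CT slices in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, rows, cols)
        HU intensities, slice order consistent within the case
        (superior→inferior or the reverse).
    spacing : tuple of float, optional
        (z, y, x) voxel spacing in millimetres; carried through
        transformations but never required.
    case_id : str
        Identifier used in reports and error messages.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None
    case_id: str = "case"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"CTVolume expects a (slice, row, col) array, got ndim={self.voxels.ndim}"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def __iter__(self):
        return iter(self.voxels)


@dataclass
class MaskVolume:
    """Binary mask aligned to a :class:`CTVolume`; values in {0, 1}."""

    voxels: np.ndarray
    case_id: str = "case"

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(
                f"MaskVolume expects a (slice, row, col) array, got ndim={arr.ndim}"
            )
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary, found values {vals[:5]}")
        self.voxels = arr.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def copy(self) -> "MaskVolume":
        return MaskVolume(self.voxels.copy(), case_id=self.case_id)
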