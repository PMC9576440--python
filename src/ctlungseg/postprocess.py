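"""Case-level 3D connected-component filtering of predicted masks.

The network segments slices independently, so a case's stacked
prediction can contain spurious 3D blobs (table edges, streak
artifacts, pre-scan missegmentation). Stacking all slices and labeling
the mask in 3D yields a set of volumes; the two largest whose centroids
lie in the central region of the cropped frame are kept as the left and
right lungs, and everything else is discarded. The filter only ever
removes voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import MaskVolume

__all__ = ["Component3D", "FilterReport", "label_components_3d", "case_filter"]


@dataclass(frozen=True)
class Component3D:
    """One maximal 3D connected component of a binary mask."""

    label: int
    volume: int
    centroid: tuple[float, float, float]  # (z, row, col)
    bbox: tuple[int, int, int, int, int, int]  # (z0, z1, r0, r1, c0, c1), half-open

    def __post_init__(self) -> None:
        if self.volume < 1:
            raise ValueError("component volume must be >= 1")


@dataclass
class FilterReport:
    """What the case filter kept and removed, plus degenerate-case warnings."""

    kept: list[Component3D]
    removed: list[Component3D]
    warnings: list[str]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def label_components_3d(
    mask: MaskVolume | np.ndarray, connectivity: int = 26
) -> list[Component3D]:
    """All maximal 3D components, sorted by volume descending.

    Ties are broken by the (z, row, col) of each component's first
    voxel in scan order, so the ordering is fully deterministic.
    """
    voxels = mask.voxels if isinstance(mask, MaskVolume) else np.asarray(mask)
    if not np.isin(np.unique(voxels), (0, 1)).all():
        raise ValueError("mask must be binary")
    labels, n = ndimage.label(voxels, structure=_structure(connectivity))
    if n == 0:
        return []
    slices = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel())
    centroids = ndimage.center_of_mass(voxels, labels, index=range(1, n + 1))
    comps = []
    first_voxel = {}
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        inside = np.argwhere(labels[sl] == lab)[0]
        first_voxel[lab] = tuple(int(inside[d] + sl[d].start) for d in range(3))
        comps.append(
            Component3D(
                label=lab,
                volume=int(counts[lab]),
                centroid=tuple(float(c) for c in centroids[lab - 1]),
                bbox=(
                    sl[0].start, sl[0].stop, sl[1].start, sl[1].stop,
                    sl[2].start, sl[2].stop,
                ),
            )
        )
    comps.sort(key=lambda c: (-c.volume, first_voxel[c.label]))
    return comps


def case_filter(
    mask: MaskVolume,
    connectivity: int = 26,
    location_prior: float = 0.8,
    max_components: int = 2,
) -> tuple[MaskVolume, FilterReport]:
    """Keep the two largest plausibly-located 3D volumes of a case mask.

    A component qualifies when its in-plane centroid lies within the
    central ``location_prior`` fraction of the frame (the crop stage
    already centres the thorax, so peripheral blobs are table or
    artifact remnants). At most ``max_components`` qualifying
    components survive; the output is always a voxelwise subset of the
    input. Degenerate inputs (no qualifying component) yield an empty
    mask plus a warning in the report.
    """
    if not 0.0 < location_prior <= 1.0:
        raise ValueError(f"location_prior must lie in (0, 1], got {location_prior}")
    voxels = mask.voxels
    _, nr, nc = voxels.shape
    comps = label_components_3d(mask, connectivity=connectivity)

    lo_r, hi_r = nr * (1 - location_prior) / 2, nr * (1 + location_prior) / 2
    lo_c, hi_c = nc * (1 - location_prior) / 2, nc * (1 + location_prior) / 2
    kept: list[Component3D] = []
    removed: list[Component3D] = []
    for comp in comps:
        _, row, col = comp.centroid
        central = lo_r <= row <= hi_r and lo_c <= col <= hi_c
        if central and len(kept) < max_components:
            kept.append(comp)
        else:
            removed.append(comp)

    warnings = []
    if not comps:
        warnings.append(f"{mask.case_id}: empty prediction, nothing to filter")
    elif not kept:
        warnings.append(
            f"{mask.case_id}: no component passed the location prior; emitting empty mask"
        )

    if not kept:
        out = np.zeros_like(voxels)
    else:
        labels, _ = ndimage.label(voxels, structure=_structure(connectivity))
        keep_ids = np.array([c.label for c in kept])
        out = np.isin(labels, keep_ids).astype(np.uint8)
    return MaskVolume(out, case_id=mask.case_id), FilterReport(kept, removed, warnings)
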