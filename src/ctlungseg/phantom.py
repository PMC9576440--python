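"""Synthetic pediatric chest CT phantoms with ground-truth lung masks.

Pediatric chest CT differs from adult CT in three ways that break
off-the-shelf lung segmentation: the thorax occupies a small fraction of
the 512×512 frame (under 20 % of the image area), motion of the child
produces streak artifacts, and failed breath-holds collapse localized
lung regions toward soft-tissue density. The generator here emulates all
three on simple elliptical geometry so that every downstream stage —
body cropping, the segmentation network, the case-level component
filter — can be exercised end-to-end without any clinical data.

HU palette: air −1000, aerated lung −800, soft tissue +40, bone rim
+400, scanner table +300. The palette places the body/lung/background
contrasts where the preprocessing thresholds must discriminate; it makes
no claim of anatomical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume import CTVolume, MaskVolume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom_case",
    "add_streak_artifacts",
    "add_breath_hold_dropout",
    "inject_edge_blobs",
]

HU_AIR = -1000.0
HU_LUNG = -800.0
HU_SOFT = 40.0
HU_BONE = 400.0
HU_TABLE = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic chest CT case.

    ``chest_fraction`` is the target fraction of the image area covered
    by the body ellipse on the widest slice; the pediatric regime of
    interest is below 0.20. ``artifact_level`` is the streak amplitude
    in HU; ``dropout_probability`` is the per-slice probability of a
    breath-hold defect; ``noise_sigma`` is the additive Gaussian noise
    standard deviation in HU.
    """

    n_slices: int = 12
    slice_size: int = 512
    chest_fraction: float = 0.18
    artifact_level: float = 80.0
    dropout_probability: float = 0.1
    noise_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.slice_size < 32:
            raise ValueError(f"slice_size must be >= 32, got {self.slice_size}")
        if not 0.0 < self.chest_fraction < 1.0:
            raise ValueError(
                f"chest_fraction must lie in (0, 1), got {self.chest_fraction}"
            )
        if self.artifact_level < 0:
            raise ValueError(f"artifact_level must be >= 0, got {self.artifact_level}")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ValueError(
                f"dropout_probability must lie in [0, 1], got {self.dropout_probability}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass
class PhantomCase:
    """Synthetic CT + mask pair with a log of every injected defect.

    ``mask`` is the pristine ground truth (always exactly two 3D lung
    components); ``degraded_mask`` tracks what the *image* actually
    shows after breath-hold dropout removed lung voxels, so the case
    filter's behaviour on corrupted cases is testable. ``defect_log``
    records ``(slice_index, kind)`` for every streak/dropout applied.
    """

    image: CTVolume
    mask: MaskVolume
    spec: PhantomSpec
    degraded_mask: MaskVolume = None  # type: ignore[assignment]
    defect_log: list[tuple[int, str]] = field(default_factory=list)
    body_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.degraded_mask is None:
            self.degraded_mask = self.mask.copy()
        if self.image.voxels.shape != self.mask.voxels.shape:
            raise ValueError("image and mask shapes differ")


def _ellipse(rows: np.ndarray, cols: np.ndarray, center, semi) -> np.ndarray:
    cy, cx = center
    ry, rx = semi
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _lung_taper(k: int, n: int) -> float:
    # per-slice radius scale: widest mid-stack, tapering toward apex/base
    return 0.5 + 0.5 * np.sin(np.pi * (k + 0.5) / n)


def _geometry(spec: PhantomSpec):
    s = spec.slice_size
    body_center = (0.52 * s, 0.50 * s)
    # body semi-axes from the target area fraction; rows:cols ratio 0.68
    rx = np.sqrt(spec.chest_fraction * s * s / (np.pi * 0.68))
    ry = 0.68 * rx
    lungs = []
    for side in (-1.0, 1.0):
        center = (body_center[0] - 0.05 * ry, body_center[1] + side * 0.42 * rx)
        lungs.append((center, (0.55 * ry, 0.32 * rx)))
    return body_center, (ry, rx), lungs


def generate_phantom_case(spec: PhantomSpec) -> PhantomCase:
    """Build a complete phantom case from a :class:`PhantomSpec`.

    The image contains an air background near −1000 HU, a bright table
    band below the body, an elliptical soft-tissue body whose area
    fraction matches ``spec.chest_fraction``, a thin bone rim, and two
    elliptical lungs near −800 HU whose in-plane size tapers toward the
    apex and base of the stack. Streaks, dropout and noise are then
    applied according to the spec. Identical specs produce bit-identical
    cases.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.slice_size
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    body_center, body_semi, lungs = _geometry(spec)

    body = _ellipse(rows, cols, body_center, body_semi)
    rim_inner = _ellipse(rows, cols, body_center, (0.93 * body_semi[0], 0.93 * body_semi[1]))
    rim = body & ~rim_inner

    # table: thin bright band under the body, clear of the body ellipse
    table_top = int(min(body_center[0] + body_semi[0] + 12, s - 10))
    table = np.zeros((s, s), dtype=bool)
    table[table_top : table_top + 6, int(0.25 * s) : int(0.75 * s)] = True
    table &= ~body

    image = np.empty((spec.n_slices, s, s), dtype=np.float32)
    mask = np.zeros((spec.n_slices, s, s), dtype=np.uint8)
    for k in range(spec.n_slices):
        sl = np.full((s, s), HU_AIR, dtype=np.float32)
        sl[body] = HU_SOFT
        sl[rim] = HU_BONE
        sl[table] = HU_TABLE
        scale = _lung_taper(k, spec.n_slices)
        for center, semi in lungs:
            lung = _ellipse(rows, cols, center, (scale * semi[0], scale * semi[1]))
            sl[lung] = HU_LUNG
            mask[k][lung] = 1
        image[k] = sl

    body_fraction = float(body.sum()) / (s * s)
    case = PhantomCase(
        image=CTVolume(image, spacing=(5.0, 0.7, 0.7), case_id=f"phantom-{spec.seed}"),
        mask=MaskVolume(mask, case_id=f"phantom-{spec.seed}"),
        spec=spec,
        body_fraction=body_fraction,
    )

    if spec.artifact_level > 0:
        case = add_streak_artifacts(
            case, spec.artifact_level, seed=int(rng.integers(2**31))
        )
    if spec.dropout_probability > 0:
        case = add_breath_hold_dropout(
            case, spec.dropout_probability, seed=int(rng.integers(2**31))
        )
    if spec.noise_sigma > 0:
        case.image.voxels += rng.normal(
            0.0, spec.noise_sigma, size=case.image.voxels.shape
        ).astype(np.float32)
    return case


def add_streak_artifacts(case: PhantomCase, level: float, seed: int) -> PhantomCase:
    """Superimpose oriented linear streaks of amplitude ``level`` (HU).

    A random subset of slices (at least one, when ``level`` > 0) gains
    2–4 streaks at random angles and offsets, mimicking motion streaks
    from a shaking child. The ground-truth mask is untouched; the defect
    log gains one ``(slice, "streak")`` record per affected slice.
    """
    if level < 0:
        raise ValueError(f"streak amplitude must be >= 0, got {level}")
    if level == 0:
        return case
    rng = np.random.default_rng(seed)
    s = case.image.slice_shape[0]
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    xc, yc = (s - 1) / 2.0, (s - 1) / 2.0

    image = case.image.voxels.copy()
    affected = rng.random(case.image.n_slices) < 0.4
    if not affected.any():
        affected[rng.integers(case.image.n_slices)] = True
    log = list(case.defect_log)
    for k in np.flatnonzero(affected):
        for _ in range(rng.integers(2, 5)):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(-0.4 * s, 0.4 * s)
            width = rng.uniform(1.0, 2.5)
            dist = np.abs(
                (cols - xc) * np.cos(theta) + (rows - yc) * np.sin(theta) - offset
            )
            image[k] += (level * np.exp(-((dist / width) ** 2))).astype(np.float32)
        log.append((int(k), "streak"))

    return PhantomCase(
        image=CTVolume(image, spacing=case.image.spacing, case_id=case.image.case_id),
        mask=case.mask,
        spec=case.spec,
        degraded_mask=case.degraded_mask,
        defect_log=log,
        body_fraction=case.body_fraction,
    )


def add_breath_hold_dropout(case: PhantomCase, p: float, seed: int) -> PhantomCase:
    """Simulate localized lung collapse from a failed breath-hold.

    Each slice is affected independently with probability ``p``. On an
    affected slice a contiguous disk inside one lung is raised to
    soft-tissue intensity and removed from the *degraded* working mask;
    the pristine ground-truth mask is preserved, exactly as a clinician
    gold standard would still annotate the full lung.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"dropout probability must lie in [0, 1], got {p}")
    if p == 0:
        return case
    rng = np.random.default_rng(seed)
    s = case.image.slice_shape[0]
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    _, _, lungs = _geometry(case.spec)

    image = case.image.voxels.copy()
    degraded = case.degraded_mask.voxels.copy()
    log = list(case.defect_log)
    for k in range(case.image.n_slices):
        if rng.random() >= p:
            continue
        scale = _lung_taper(k, case.spec.n_slices)
        center, semi = lungs[rng.integers(2)]
        ry, rx = scale * semi[0], scale * semi[1]
        # disk centred inside the lung, radius ~ half the minor semi-axis
        jitter_r = rng.uniform(-0.3, 0.3) * ry
        jitter_c = rng.uniform(-0.3, 0.3) * rx
        radius = max(2.0, 0.5 * min(ry, rx))
        disk = (rows - (center[0] + jitter_r)) ** 2 + (
            cols - (center[1] + jitter_c)
        ) ** 2 <= radius**2
        region = disk & (case.mask.voxels[k] > 0)
        image[k][region] = HU_SOFT
        degraded[k][region] = 0
        log.append((k, "dropout"))

    return PhantomCase(
        image=CTVolume(image, spacing=case.image.spacing, case_id=case.image.case_id),
        mask=case.mask,
        spec=case.spec,
        degraded_mask=MaskVolume(degraded, case_id=case.mask.case_id),
        defect_log=log,
        body_fraction=case.body_fraction,
    )


def inject_edge_blobs(
    mask: MaskVolume, n_blobs: int, seed: int, blob_radius: int = 4
) -> tuple[MaskVolume, list[tuple[int, int, int]]]:
    """Corrupt a mask with small false-positive blobs near the frame edge.

    Emulates table/artifact missegmentations that the case-level filter
    must remove: each blob is a small sphere whose centroid lies in the
    outer 10 % band of the in-plane frame. Returns the corrupted mask
    and the list of blob centres ``(z, row, col)`` so tests can audit
    exact removal.
    """
    rng = np.random.default_rng(seed)
    voxels = mask.voxels.copy()
    nz, nr, nc = voxels.shape
    zz, rr, cc = np.mgrid[0:nz, 0:nr, 0:nc].astype(np.float64)
    centres = []
    for _ in range(n_blobs):
        z = int(rng.integers(nz))
        side = rng.integers(4)  # pick an edge band
        band = max(blob_radius + 1, int(0.05 * nr))
        if side == 0:
            r, c = int(rng.integers(band)), int(rng.integers(nc))
        elif side == 1:
            r, c = int(nr - 1 - rng.integers(band)), int(rng.integers(nc))
        elif side == 2:
            r, c = int(rng.integers(nr)), int(rng.integers(band))
        else:
            r, c = int(rng.integers(nr)), int(nc - 1 - rng.integers(band))
        blob = (zz - z) ** 2 + (rr - r) ** 2 + (cc - c) ** 2 <= blob_radius**2
        voxels[blob] = 1
        centres.append((z, r, c))
    return MaskVolume(voxels, case_id=mask.case_id), centres
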