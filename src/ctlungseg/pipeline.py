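"""End-to-end orchestration: prepare → split → train → segment → score.

Training follows the study protocol: RMSprop with an initial learning
rate of 0.001 for 10 epochs, the combined log-Dice + focal loss, a
case-level held-out test set (no slice of a test case ever enters
training) and an image-level train/validation split of the remaining
cases (≈ 0.9, the ratio of the 11 270 / 1 252 picture split of the
source protocol). Every random choice is driven by one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .losses import LossConfig, get_loss
from .metrics import CaseMetrics, score_case
from .model import ModelConfig, ResUNet, normalize_hu, predict_case
from .nn import RMSprop, Tensor
from .phantom import PhantomCase
from .postprocess import case_filter
from .preprocess import CropTransform, PreprocessConfig, preprocess_case, invert_transform
from .volume import CTVolume, MaskVolume

__all__ = [
    "TrainConfig",
    "PreparedCase",
    "SliceSample",
    "Split",
    "TrainingDivergedError",
    "prepare_cases",
    "split_dataset",
    "train",
    "run_pipeline",
]

logger = logging.getLogger("ctlungseg")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol defaults (RMSprop, lr 0.001, 10 epochs)."""

    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    val_fraction: float = 0.1
    test_cases: int = 12
    loss: str = "combined"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must lie in (0, 1), got {self.val_fraction}")
        if self.optimizer.lower() != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class PreparedCase:
    """One case after crop-and-zoom, with everything needed for scoring."""

    case_id: str
    image: CTVolume  # cropped/zoomed
    mask: MaskVolume  # cropped/zoomed gold standard
    transform: CropTransform
    original_mask: MaskVolume | None = None


@dataclass
class SliceSample:
    """One training image: a single cropped slice and its mask."""

    case_id: str
    slice_index: int
    image: np.ndarray  # (H, W) HU
    mask: np.ndarray  # (H, W) {0,1}


@dataclass
class Split:
    train: list[SliceSample]
    val: list[SliceSample]
    test: list[PreparedCase]


def prepare_cases(
    cases: list[PhantomCase] | list[tuple[CTVolume, MaskVolume]],
    cfg: PreprocessConfig | None = None,
) -> list[PreparedCase]:
    """Run the preprocessing stage over raw cases."""
    cfg = cfg or PreprocessConfig()
    prepared = []
    for case in cases:
        if isinstance(case, PhantomCase):
            volume, mask = case.image, case.mask
        else:
            volume, mask = case
        cropped, cropped_mask, transform = preprocess_case(volume, mask, cfg)
        prepared.append(
            PreparedCase(
                case_id=volume.case_id,
                image=cropped,
                mask=cropped_mask,
                transform=transform,
                original_mask=mask,
            )
        )
    return prepared


def split_dataset(cases: list[PreparedCase], cfg: TrainConfig) -> Split:
    """Case-level test split, then image-level train/val split.

    No slice of a test case can leak into training; the train/val split
    pools all remaining slices and partitions them at image level,
    seeded and reproducible.
    """
    if len(cases) < 2:
        raise ValueError(f"need at least 2 cases to split, got {len(cases)}")
    if cfg.test_cases >= len(cases):
        raise ValueError(
            f"test_cases={cfg.test_cases} leaves no training data from {len(cases)} cases"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(cases))
    test = [cases[i] for i in sorted(order[: cfg.test_cases])]
    rest = [cases[i] for i in sorted(order[cfg.test_cases :])]

    pool = [
        SliceSample(c.case_id, k, c.image.voxels[k], c.mask.voxels[k])
        for c in rest
        for k in range(c.image.n_slices)
    ]
    perm = rng.permutation(len(pool))
    n_val = max(1, int(round(cfg.val_fraction * len(pool))))
    val = [pool[i] for i in perm[:n_val]]
    train_samples = [pool[i] for i in perm[n_val:]]
    if not train_samples:
        raise ValueError("train split is empty; reduce val_fraction or add cases")
    return Split(train=train_samples, val=val, test=test)


def _stack(samples: list[SliceSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([normalize_hu(s.image) for s in samples])[:, None]
    y = np.stack([s.mask.astype(np.float32) for s in samples])[:, None]
    return x, y


@dataclass
class TrainResult:
    net: ResUNet
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def final_val_dice(self) -> float:
        return self.history[-1]["val_dice"] if self.history else float("nan")


def _val_scores(net: ResUNet, x: np.ndarray, y: np.ndarray,
                loss_fn, loss_cfg, batch_size: int) -> tuple[float, float]:
    net.eval()
    losses, dices = [], []
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        prob = net(Tensor(xb)).data
        losses.append(loss_fn(yb, prob.clip(0.0, 1.0), loss_cfg)
                      if loss_cfg is not None else loss_fn(yb, prob.clip(0.0, 1.0)))
        pred = prob >= 0.5
        truth = yb > 0.5
        inter = np.count_nonzero(pred & truth)
        denom = np.count_nonzero(pred) + np.count_nonzero(truth)
        dices.append(2.0 * inter / denom if denom else 1.0)
    net.train()
    return float(np.mean(losses)), float(np.mean(dices))


def train(
    train_samples: list[SliceSample],
    val_samples: list[SliceSample],
    model_cfg: ModelConfig | None = None,
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> TrainResult:
    """Fit the network; keep the weights of the best-validation-Dice epoch.

    Logs one line per epoch (train loss, validation loss, validation
    Dice) and aborts with a diagnostic naming the epoch and batch if
    the loss diverges.
    """
    cfg = cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig()
    loss_cfg = loss_cfg or LossConfig()
    if not train_samples:
        raise ValueError("training set is empty")
    loss_fn = get_loss(cfg.loss)
    loss_args = None if cfg.loss == "dice" else loss_cfg

    net = ResUNet(model_cfg, seed=cfg.seed)
    opt = RMSprop(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    x_train, y_train = _stack(train_samples)
    x_val, y_val = _stack(val_samples) if val_samples else (x_train[:1], y_train[:1])

    result = TrainResult(net=net)
    best_dice, best_state = -1.0, None
    net.train()
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x_train))
        epoch_losses = []
        for b, start in enumerate(range(0, len(perm), cfg.batch_size)):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = Tensor(x_train[idx]), y_train[idx]
            opt.zero_grad()
            prob = net(xb).clamp(0.0, 1.0)
            if cfg.loss == "dice":
                loss = loss_fn(yb, prob, smooth=loss_cfg.smooth)
            else:
                loss = loss_fn(yb, prob, loss_cfg)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}, batch {b + 1}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_loss, val_dice = _val_scores(
            net, x_val, y_val, loss_fn, loss_args, cfg.batch_size
        )
        entry = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_dice": val_dice,
        }
        result.history.append(entry)
        logger.info(
            "epoch %d/%d: train_loss=%.4f val_loss=%.4f val_dice=%.4f",
            epoch + 1, cfg.epochs, entry["train_loss"], val_loss, val_dice,
        )
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            result.best_epoch = epoch + 1
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return result


def run_pipeline(
    test_cases,
    net: ResUNet,
    threshold: float = 0.5,
    apply_filter: bool = True,
    connectivity: int = 26,
    location_prior: float = 0.8,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[list[CaseMetrics], list[str]]:
    """Segment each held-out case and score it in original coordinates.

    Per case: preprocess (unless already a :class:`PreparedCase`) →
    predict slicewise → (optionally) case filter → invert the crop
    transform → confusion metrics against the gold standard. A failing
    case (e.g. an all-air volume where no body is found) is logged and
    skipped; its id is returned so callers can exit nonzero.
    """
    results: list[CaseMetrics] = []
    failures: list[str] = []
    for raw in test_cases:
        case_id = None
        try:
            if isinstance(raw, PreparedCase):
                case = raw
            else:
                if isinstance(raw, PhantomCase):
                    volume, mask = raw.image, raw.mask
                else:
                    volume, mask = raw
                case_id = volume.case_id
                cropped, cropped_mask, transform = preprocess_case(
                    volume, mask, preprocess_cfg
                )
                case = PreparedCase(
                    case_id=volume.case_id,
                    image=cropped,
                    mask=cropped_mask,
                    transform=transform,
                    original_mask=mask,
                )
            case_id = case.case_id
            pred = predict_case(net, case.image, threshold=threshold)
            if apply_filter:
                pred, report = case_filter(
                    pred, connectivity=connectivity, location_prior=location_prior
                )
                for w in report.warnings:
                    logger.warning("%s", w)
            full = invert_transform(pred, case.transform)
            gold = case.original_mask if case.original_mask is not None else case.mask
            if gold.voxels.shape != full.voxels.shape:
                full = pred  # scored in cropped coordinates
                gold = case.mask
            cm = score_case(gold, full, case_id=case.case_id)
            results.append(cm)
            logger.info(
                "%s: IOU=%.4f Dice=%.4f P=%.4f R=%.4f",
                cm.case_id, cm.iou, cm.dice, cm.precision, cm.recall,
            )
        except Exception as exc:  # noqa: BLE001 — per-case isolation
            logger.error("case %s failed: %s", case_id or "<unknown>", exc)
            failures.append(case_id or "<unknown>")
    return results, failures
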