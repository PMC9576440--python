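"""Model/Results front end for the full segmentation pipeline.

:class:`LungSegmenter` plays the role of a statsmodels-style model
object: it is constructed from data (raw cases or a phantom
specification), ``fit()`` trains the network under the study protocol
and returns a :class:`SegmentationResults` carrying the fitted weights,
the training history, per-case scores on the held-out cases and a
``summary()`` table.

Example
-------
>>> from ctlungseg import LungSegmenter
>>> model = LungSegmenter.from_phantoms(n_cases=16, n_slices=6, seed=7)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import pandas as pd

from .losses import LossConfig
from .metrics import CaseMetrics, aggregate, metrics_table
from .model import ModelConfig, ResUNet, predict_case, save_checkpoint
from .phantom import PhantomSpec, generate_phantom_case
from .pipeline import (
    PreparedCase,
    Split,
    TrainConfig,
    prepare_cases,
    run_pipeline,
    split_dataset,
    train,
)
from .preprocess import PreprocessConfig, invert_transform, preprocess_case
from .volume import CTVolume, MaskVolume

__all__ = ["LungSegmenter", "SegmentationResults"]


class LungSegmenter:
    """Three-stage pediatric CT lung segmentation model.

    Parameters
    ----------
    cases : list of (CTVolume, MaskVolume) or PhantomCase
        The study cases, each an axial CT volume with its gold-standard
        lung mask.
    model_config, train_config, preprocess_config, loss_config
        Stage configurations; defaults follow the study protocol
        (σ = 3 crop-and-zoom to 256², concatenative ResUnet,
        combined loss with α = 0.3, RMSprop lr 0.001 for 10 epochs).
    """

    def __init__(
        self,
        cases,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        preprocess_config: PreprocessConfig | None = None,
        loss_config: LossConfig | None = None,
    ):
        self.cases = list(cases)
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.loss_config = loss_config or LossConfig()

    @classmethod
    def from_phantoms(
        cls,
        n_cases: int = 24,
        n_slices: int = 10,
        seed: int = 0,
        slice_size: int = 512,
        **kwargs,
    ) -> "LungSegmenter":
        """Build a model over freshly generated synthetic phantom cases."""
        cases = [
            generate_phantom_case(
                PhantomSpec(n_slices=n_slices, slice_size=slice_size, seed=seed + i)
            )
            for i in range(n_cases)
        ]
        return cls(cases, **kwargs)

    def fit(self) -> "SegmentationResults":
        """Preprocess, split, train and evaluate on the held-out cases."""
        prepared = prepare_cases(self.cases, self.preprocess_config)
        split = split_dataset(prepared, self.train_config)
        result = train(
            split.train,
            split.val,
            model_cfg=self.model_config,
            cfg=self.train_config,
            loss_cfg=self.loss_config,
        )
        case_scores, failures = run_pipeline(split.test, result.net)
        return SegmentationResults(
            model=self,
            net=result.net,
            history=result.history,
            best_epoch=result.best_epoch,
            split=split,
            case_scores=case_scores,
            failures=failures,
        )


class SegmentationResults:
    """Fitted weights, training history and held-out scores."""

    def __init__(self, model, net: ResUNet, history, best_epoch, split: Split,
                 case_scores: list[CaseMetrics], failures: list[str]):
        self.model = model
        self.net = net
        self.history = history
        self.best_epoch = best_epoch
        self.split = split
        self.case_scores = case_scores
        self.failures = failures

    # ---- estimates ---------------------------------------------------------
    @property
    def average(self) -> CaseMetrics:
        """Macro-averaged scores over the held-out cases."""
        return aggregate(self.case_scores)

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history).set_index("epoch")

    def metrics_frame(self) -> pd.DataFrame:
        """Per-case table with an Average row."""
        return metrics_table(self.case_scores)

    # ---- prediction --------------------------------------------------------
    def predict(
        self, volume: CTVolume, threshold: float = 0.5, apply_filter: bool = True
    ) -> MaskVolume:
        """Segment a new case end-to-end, in original coordinates."""
        from .postprocess import case_filter

        cropped, _, transform = preprocess_case(
            volume, None, self.model.preprocess_config
        )
        pred = predict_case(self.net, cropped, threshold=threshold)
        if apply_filter:
            pred, _ = case_filter(pred)
        return invert_transform(pred, transform)

    def save(self, path) -> None:
        save_checkpoint(self.net, path)

    # ---- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Statsmodels-style text summary of the fit."""
        avg = self.average
        mc, tc = self.model.model_config, self.model.train_config
        lines = [
            "          Pediatric CT Lung Segmentation Results",
            "=" * 64,
            f"Architecture:     ResUnet ({mc.block} blocks, depth {mc.depth}, "
            f"base {mc.base_channels})",
            f"Parameters:       {self.net.n_parameters():,}",
            f"Loss:             {tc.loss} (alpha={self.model.loss_config.alpha_combined})",
            f"Optimizer:        {tc.optimizer} (lr={tc.learning_rate}, "
            f"epochs={tc.epochs}, batch={tc.batch_size})",
            f"Training slices:  {len(self.split.train)}  "
            f"(validation {len(self.split.val)})",
            f"Held-out cases:   {len(self.split.test)}  "
            f"(failed: {len(self.failures)})",
            f"Best epoch:       {self.best_epoch}",
            "-" * 64,
            "Held-out case scores",
            self.metrics_frame().to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 64,
            f"Average: IOU={avg.iou:.4f}  Dice={avg.dice:.4f}  "
            f"Precision={avg.precision:.4f}  Recall={avg.recall:.4f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        avg = self.average if self.case_scores else None
        tail = f" mean Dice {avg.dice:.4f}" if avg else ""
        return f"<SegmentationResults: {len(self.case_scores)} cases{tail}>"
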