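"""Segmentation losses: Dice, focal, and their logarithmic combination.

The training objective couples an overlap term with a pixel-wise term:

    L_all = α · log(L_Dice) + L_f,     α = 0.3

where L_Dice(e, f) = 1 − 2|e∩f| / (|e| + |f|) measures lack of overlap
between ground truth ``e`` and prediction ``f`` (0 at complete overlap,
1 for disjoint masks), and L_f is the focal loss, a cross-entropy
modulated by (1−y′)^r to down-weight easy pixels with a class-balance
weight ɑ. The Dice term handles foreground/background imbalance, the
focal term the hard transition pixels at lung boundaries; the logarithm
and α balance the magnitudes of the two.

As printed, log(L_Dice) diverges to −∞ at perfect overlap, so L_Dice is
clamped from below at ``log_floor`` before the logarithm to keep
training finite.

All three losses accept either NumPy arrays (returning a float) or
:class:`~ctlungseg.nn.Tensor` predictions (returning a Tensor on the
gradient tape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = ["LossConfig", "dice_loss", "focal_loss", "combined_loss", "get_loss"]

_EPS = 1e-7  # probability clamp for the logarithms of the focal loss


@dataclass(frozen=True)
class LossConfig:
    """Hyper-parameters of the three losses.

    ``alpha_combined`` is the weight of the log-Dice term (0.3);
    ``focal_alpha``/``focal_gamma`` are the focal class-balance weight ɑ
    and focusing exponent r (0.25 and 2, the original focal-loss
    defaults — named in the source formulation but never assigned
    values); ``smooth`` stabilizes the Dice ratio; ``log_floor`` keeps
    log(L_Dice) finite.
    """

    alpha_combined: float = 0.3
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    smooth: float = 1.0
    log_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha_combined <= 0:
            raise ValueError(f"alpha_combined must be > 0, got {self.alpha_combined}")
        if self.focal_gamma < 0:
            raise ValueError(f"focal_gamma must be >= 0, got {self.focal_gamma}")
        if not 0.0 < self.focal_alpha < 1.0:
            raise ValueError(f"focal_alpha must lie in (0, 1), got {self.focal_alpha}")
        if self.smooth <= 0:
            raise ValueError(f"smooth must be > 0, got {self.smooth}")
        if self.log_floor <= 0:
            raise ValueError(f"log_floor must be > 0, got {self.log_floor}")


def _check_pair(e, f):
    f_arr = f.data if isinstance(f, Tensor) else np.asarray(f)
    # keep the ground truth in the prediction's dtype so float32 training
    # graphs are not silently upcast
    dtype = f_arr.dtype if np.issubdtype(f_arr.dtype, np.floating) else np.float64
    e_arr = np.asarray(e.data if isinstance(e, Tensor) else e, dtype=dtype)
    if e_arr.shape != f_arr.shape:
        raise ValueError(f"shape mismatch: ground truth {e_arr.shape} vs prediction {f_arr.shape}")
    if not np.isin(np.unique(e_arr), (0.0, 1.0)).all():
        raise ValueError("ground-truth mask must be binary")
    if f_arr.min() < 0.0 or f_arr.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return e_arr


def _maybe_float(result: Tensor, f) -> Tensor | float:
    return result if isinstance(f, Tensor) else float(result.data)


def dice_loss(e, f, smooth: float = 1.0):
    """Dice loss 1 − (2·Σef + smooth) / (Σe + Σf + smooth).

    0 at exact overlap, → 1 for disjoint nonempty masks as smooth → 0.
    ``smooth`` enters numerator and denominator alike, so the perfect-
    overlap value stays 0 for any smooth.
    """
    if smooth <= 0:
        raise ValueError(f"smooth must be > 0, got {smooth}")
    e_arr = _check_pair(e, f)
    ft = as_tensor(f)
    num = 2.0 * (Tensor(e_arr) * ft).sum() + smooth
    den = float(e_arr.sum()) + ft.sum() + smooth
    return _maybe_float(1.0 - num / den, f)


def focal_loss(e, f, cfg: LossConfig | None = None):
    """Mean focal loss over pixels.

    Positive pixels contribute −ɑ(1−y′)^r·log y′, negative pixels
    −(1−ɑ)·y′^r·log(1−y′). With r = 0 and ɑ = 0.5 this reduces to half
    the binary cross-entropy.
    """
    cfg = cfg or LossConfig()
    e_arr = _check_pair(e, f)
    ft = as_tensor(f).clamp(_EPS, 1.0 - _EPS)
    pos = Tensor(e_arr)
    neg = Tensor(1.0 - e_arr)
    a, r = cfg.focal_alpha, cfg.focal_gamma
    term_pos = -a * (1.0 - ft) ** r * ft.log() * pos
    term_neg = -(1.0 - a) * ft**r * (1.0 - ft).log() * neg
    return _maybe_float((term_pos + term_neg).mean(), f)


def combined_loss(e, f, cfg: LossConfig | None = None):
    """α·log(max(L_Dice, log_floor)) + L_f with α = ``alpha_combined``."""
    cfg = cfg or LossConfig()
    ld = dice_loss(e, as_tensor(f), smooth=cfg.smooth)
    lf = focal_loss(e, as_tensor(f), cfg)
    total = cfg.alpha_combined * ld.clamp(cfg.log_floor, np.inf).log() + lf
    return _maybe_float(total, f)


def get_loss(name: str):
    """Resolve a loss by config name: ``dice`` | ``focal`` | ``combined``."""
    try:
        return {"dice": dice_loss, "focal": focal_loss, "combined": combined_loss}[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; expected dice, focal or combined") from None
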