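"""Training-objective components for complex MR image restoration.

Self-contained formulas only: the Charbonnier penalty (a smooth L1), a
perpendicular loss designed for complex-valued targets, and an L1 gradient
loss on magnitude images, plus their weighted sum.  All are plain numpy
functions intended for reuse by any training harness; no perceptual
(pretrained-network) term is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "charbonnier", "perpendicular_loss",
           "gradient_l1_loss", "combined_loss"]


@dataclass
class LossConfig:
    charbonnier_eps: float = 1e-3
    perp_eps: float = 1e-3
    weight_charbonnier: float = 1.0
    weight_perpendicular: float = 1.0
    weight_gradient: float = 1.0

    def __post_init__(self) -> None:
        if self.charbonnier_eps <= 0 or self.perp_eps <= 0:
            raise ValueError("eps values must be positive")
        if min(self.weight_charbonnier, self.weight_perpendicular,
               self.weight_gradient) < 0:
            raise ValueError("weights must be nonnegative")


def _check_shapes(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")


def charbonnier(pred: np.ndarray, target: np.ndarray, eps: float = 1e-3) -> float:
    """Mean of ``sqrt(|pred - target|^2 + eps^2)`` — a smooth L1 penalty."""
    _check_shapes(pred, target)
    return float(np.mean(np.sqrt(np.abs(pred - target) ** 2 + eps**2)))


def perpendicular_loss(pred: np.ndarray, target: np.ndarray,
                       eps: float = 1e-3) -> float:
    """Complex-aware loss: perpendicular error component + magnitude mismatch.

    Decomposes the complex error at each pixel into the component
    perpendicular to the target phasor, ``|Im(pred * conj(target))| /
    (|target| + eps)``, plus the magnitude difference ``||pred| - |target||``.
    Unlike a plain L2 on complex values it is insensitive to how the error
    splits between noise-like phase jitter and magnitude bias, and it is
    invariant to a global phase applied to both inputs.
    """
    _check_shapes(pred, target)
    if not (np.iscomplexobj(pred) and np.iscomplexobj(target)):
        raise TypeError("perpendicular_loss needs complex inputs; "
                        "use charbonnier for real images")
    perp = np.abs(pred.real * target.imag - pred.imag * target.real)
    perp = perp / (np.abs(target) + eps)
    mag = np.abs(np.abs(pred) - np.abs(target))
    return float(np.mean(perp + mag))


def gradient_l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """L1 difference of forward finite-difference magnitude gradients.

    The mean absolute gradient mismatch is computed separately along the last
    two axes (H, W) of the magnitude images and summed; constant offsets
    between prediction and target do not contribute.
    """
    _check_shapes(pred, target)
    p, t = np.abs(pred), np.abs(target)
    dy = np.abs(np.diff(p, axis=-2) - np.diff(t, axis=-2))
    dx = np.abs(np.diff(p, axis=-1) - np.diff(t, axis=-1))
    return float(dy.mean() + dx.mean())


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  cfg: LossConfig | None = None) -> tuple[float, dict[str, float]]:
    """Weighted sum of the three terms with a per-term breakdown.

    The breakdown carries a note that no perceptual term is included.
    """
    cfg = cfg or LossConfig()
    terms = {
        "charbonnier": cfg.weight_charbonnier
        * charbonnier(pred, target, cfg.charbonnier_eps),
        "perpendicular": cfg.weight_perpendicular
        * (perpendicular_loss(pred, target, cfg.perp_eps)
           if np.iscomplexobj(pred) and np.iscomplexobj(target) else 0.0),
        "gradient": cfg.weight_gradient * gradient_l1_loss(pred, target),
    }
    terms["perceptual"] = 0.0   # not implemented: needs pretrained weights
    return float(sum(terms.values())), terms
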