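"""Hebbian and error-driven (contrastive) learning rules.

Every plastic projection mixes two rules.  The Hebbian component is the
CPCA form dw = lr * y * (x - w): weights drift toward the conditional
probability of the sender being active given the receiver is.  The
error-driven component is contrastive Hebbian learning,
dw = lr * (x+ y+  -  x- y-), contrasting an outcome (plus) phase
against an expectation (minus) phase.  Weight changes are soft-bounded
so weights stay in [0, 1]: increases are scaled by (1 - w), decreases
by w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearnParams",
    "hebbian_delta",
    "errdriven_delta",
    "mixed_delta",
    "soft_bound",
    "apply_learning",
]


@dataclass(frozen=True)
class LearnParams:
    """Learning rate and Hebbian/error-driven mixture for a projection.

    ``hebb_mix`` is the fraction of the update that is Hebbian; 1.0
    makes the projection purely Hebbian, 0.0 purely error-driven.
    """

    lr: float = 0.1
    hebb_mix: float = 0.05
    soft_bounded: bool = True

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= self.hebb_mix <= 1.0:
            raise ValueError("hebb_mix must be in [0, 1]")


def hebbian_delta(x, y, w, lr: float):
    """CPCA Hebbian update dw = lr * y * (x - w).

    ``x`` is sender activity, ``y`` receiver activity, ``w`` the current
    weight; all broadcastable.  With y = 0 nothing changes; with
    sustained x = y = 1 the weight converges monotonically to 1.
    """
    return lr * np.asarray(y) * (np.asarray(x) - np.asarray(w))


def errdriven_delta(x_plus, y_plus, x_minus, y_minus, lr: float):
    """Contrastive update dw = lr * (x+ y+ - x- y-).

    Zero when expectation matches outcome; antisymmetric under swapping
    the two phases.
    """
    return lr * (
        np.asarray(x_plus) * np.asarray(y_plus)
        - np.asarray(x_minus) * np.asarray(y_minus)
    )


def soft_bound(delta, w):
    """Scale increases by (1 - w) and decreases by w."""
    delta = np.asarray(delta)
    w = np.asarray(w)
    return np.where(delta > 0, delta * (1.0 - w), delta * w)


def mixed_delta(
    w: np.ndarray,
    x_minus: np.ndarray,
    y_minus: np.ndarray,
    x_plus: np.ndarray,
    y_plus: np.ndarray,
    params: LearnParams,
) -> np.ndarray:
    """Per-synapse mixture for a full weight matrix.

    ``w`` has shape (n_senders, n_receivers); activities are vectors.
    The Hebbian term uses plus-phase (outcome) co-activity, the standard
    CPCA convention.
    """
    lam = params.hebb_mix
    delta = np.zeros_like(w)
    if lam > 0.0:
        # outer(x+, y+) - w * y+ row-broadcast, times lr * lam
        delta += lam * params.lr * (
            np.outer(x_plus, y_plus) - w * y_plus[np.newaxis, :]
        )
    if lam < 1.0:
        delta += (1.0 - lam) * params.lr * (
            np.outer(x_plus, y_plus) - np.outer(x_minus, y_minus)
        )
    if params.soft_bounded:
        delta = soft_bound(delta, w)
    return delta


def apply_learning(
    w: np.ndarray,
    x_minus: np.ndarray,
    y_minus: np.ndarray,
    x_plus: np.ndarray,
    y_plus: np.ndarray,
    params: LearnParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Update ``w`` in place; returns ``w``.

    ``mask`` (same shape as ``w``) zeroes updates outside the
    projection's connectivity.  Weights are clipped to [0, 1] as a
    final guard; with soft bounding the clip is a no-op.
    """
    delta = mixed_delta(w, x_minus, y_minus, x_plus, y_plus, params)
    if mask is not None:
        delta *= mask
    w += delta
    np.clip(w, 0.0, 1.0, out=w)
    return w
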