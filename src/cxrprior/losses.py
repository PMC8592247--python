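"""Margin loss on class-embedding norms.

For each class k with binary target T_k and embedding vector nu_k the
per-class term is

    Gamma_k = T_k * max(0, m+ - ||nu_k||^2)
              + lambda * (1 - T_k) * max(0, ||nu_k||^2 - m-)

with m+ = 0.9, m- = 0.1 and down-weighting lambda = 0.5.  Note the
square sits on the norm *inside* the hinge; the capsule-network
original instead squares the hinge itself, which is available behind
``squared_hinge_variant`` for comparison.  The total loss is the sum
over classes, averaged over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MarginLossParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5
    squared_hinge_variant: bool = False

    def validate(self) -> None:
        if not (0 <= self.m_minus < self.m_plus <= 1):
            raise ValueError(
                f"need 0 <= m_minus < m_plus <= 1, got {self.m_minus}, {self.m_plus}"
            )
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0, got {self.lam}")


def margin_loss(
    scores: np.ndarray,
    targets: np.ndarray,
    params: MarginLossParams = MarginLossParams(),
    class_weights: np.ndarray | None = None,
) -> float:
    """Total margin loss for a batch.

    ``scores`` are the per-class norms ||nu_k|| (>= 0), ``targets``
    binary indicators, both of shape ``(..., n_classes)``.  Per-class
    terms are summed over classes and averaged over any leading batch
    axes.  ``class_weights`` (optional, mean 1) multiply each class
    term — the "dynamic weights" mechanism for class imbalance.
    """
    loss, _ = margin_loss_with_grad(scores, targets, params, class_weights)
    return loss


def margin_loss_with_grad(
    scores: np.ndarray,
    targets: np.ndarray,
    params: MarginLossParams = MarginLossParams(),
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to ``scores``.

    The gradient is the exact sub-gradient away from the hinge
    corners (zero at the corners themselves).
    """
    params.validate()
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError(f"scores shape {s.shape} != targets shape {t.shape}")
    if (s < 0).any():
        raise ValueError("scores must be non-negative norms")
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("targets must be binary")

    q = s * s                                           # ||nu||^2
    if params.squared_hinge_variant:
        pos = np.maximum(0.0, params.m_plus - s)
        neg = np.maximum(0.0, s - params.m_minus)
        terms = t * pos ** 2 + params.lam * (1 - t) * neg ** 2
        dterms_ds = -2.0 * t * pos + 2.0 * params.lam * (1 - t) * neg
    else:
        pos = np.maximum(0.0, params.m_plus - q)
        neg = np.maximum(0.0, q - params.m_minus)
        terms = t * pos + params.lam * (1 - t) * neg
        # d/ds of max(0, m+ - s^2) is -2s on the active branch.
        dterms_ds = (
            -2.0 * s * t * (pos > 0) + 2.0 * s * params.lam * (1 - t) * (neg > 0)
        )

    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64)
        terms = terms * w
        dterms_ds = dterms_ds * w

    batch = int(np.prod(s.shape[:-1])) if s.ndim > 1 else 1
    loss = float(terms.sum() / batch)
    return loss, dterms_ds / batch


def inverse_frequency_weights(targets: np.ndarray) -> np.ndarray:
    """Per-class weights = inverse class frequency, normalized to mean 1."""
    t = np.asarray(targets, dtype=np.float64)
    freq = t.reshape(-1, t.shape[-1]).mean(axis=0)
    w = 1.0 / np.maximum(freq, 1e-12)
    return w / w.mean()
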