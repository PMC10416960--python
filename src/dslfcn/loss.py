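"""Soft-weight softmax loss.

The per-pixel softmax turns class scores ``z`` into probabilities
``p[c] = exp(z[c]) / sum_t exp(z[t])``; the loss is the weighted negative
log-likelihood of each pixel's true class,

    L = -(1/N) * sum_n  omega_n * log p_n[label_n],

with ``omega`` the morphology-derived soft weights (all ones reduces it to
plain mean cross-entropy).  Normalization is by pixel count ``N``, not by
``sum(omega)``; a ``normalization="sum"`` switch divides by 1 instead (the
historic fully-convolutional convention that motivated learning rates around
1e-10 — with per-pixel normalization use learning rates around 1e-4..1e-3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax_probs", "soft_weight_softmax_loss", "loss_and_score_grad"]

PROB_FLOOR = 1e-12


def softmax_probs(scores: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel softmax over the class axis, computed stably.

    ``scores`` is a (C, H, W) (or any) array of finite class scores; the
    per-pixel maximum is subtracted before exponentiation, which leaves the
    result unchanged analytically.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    shifted = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _check_shapes(probs, labels, omega):
    if probs.shape[1:] != labels.shape:
        raise ValueError(f"probs spatial shape {probs.shape[1:]} != labels shape {labels.shape}")
    if omega is not None and omega.shape != labels.shape:
        raise ValueError(f"weight shape {omega.shape} != labels shape {labels.shape}")


def soft_weight_softmax_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    omega: np.ndarray | None = None,
    normalization: str = "pixels",
) -> float:
    """Weighted negative log-likelihood of the labeled class per pixel.

    Parameters
    ----------
    probs : (C, H, W) probabilities (per-pixel softmax output).
    labels : (H, W) integer class indices in [0, C).
    omega : (H, W) per-pixel weights; ``None`` means all ones.
    normalization : "pixels" divides by the pixel count N; "sum" leaves the
        raw weighted sum (historic convention, pairs with tiny learning rates).

    Probabilities are floored at 1e-12 so an exactly-zero labeled-class
    probability yields a large finite loss rather than infinity.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    _check_shapes(probs, labels, omega)
    if labels.min() < 0 or labels.max() >= probs.shape[0]:
        raise ValueError("labels outside [0, n_classes)")
    if normalization not in ("pixels", "sum"):
        raise ValueError("normalization must be 'pixels' or 'sum'")
    p_true = np.take_along_axis(probs, labels[None], axis=0)[0]
    terms = -np.log(np.maximum(p_true, PROB_FLOOR))
    if omega is not None:
        terms = terms * omega
    total = float(terms.sum())
    return total / labels.size if normalization == "pixels" else total


def loss_and_score_grad(
    scores: np.ndarray,
    labels: np.ndarray,
    omega: np.ndarray | None = None,
    normalization: str = "pixels",
) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to the raw scores.

    For the softmax cross-entropy the per-pixel gradient is
    ``omega_n * (p - onehot(label)) / N``; returned with the same (C, H, W)
    shape as ``scores``.
    """
    probs = softmax_probs(scores)
    loss = soft_weight_softmax_loss(probs, labels, omega, normalization)
    labels = np.asarray(labels)
    grad = probs.copy()
    c = np.arange(probs.shape[0])[:, None, None]
    grad -= (labels[None] == c).astype(np.float64)
    if omega is not None:
        grad *= omega[None]
    if normalization == "pixels":
        grad /= labels.size
    return loss, grad
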