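"""Differentiable Gram-Schmidt head and the pose-regression losses.

The network emits a 9-vector per image: a translation triple and six
unconstrained rotation parameters.  The forward pass reconstructs a proper
rotation matrix from the six parameters by Gram-Schmidt orthonormalisation;
this module provides that reconstruction together with its analytic
vector-Jacobian product so the loss can be back-propagated through the
orthonormalisation into the head.

Losses follow the printed mean-of-norms form: the translation loss is the
batch mean of Euclidean distances ``||t' - t||_2`` and the rotation loss
the batch mean of Frobenius norms ``||R' - R||_F``; the total loss is
``L_rot + lambda * L_trans``.  A squared-norm variant of both terms sits
behind a flag.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gram_schmidt_forward",
    "gram_schmidt_backward",
    "translation_loss",
    "rotation_loss",
    "total_loss",
    "translation_loss_grad",
    "rotation_loss_grad",
]

_EPS = 1e-8


def gram_schmidt_forward(r6: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Batched Gram-Schmidt ``(N, 6) -> (N, 3, 3)`` with a cache for backward.

    Column layout matches the 6D rotation representation: ``r6[:, :3]`` is
    the raw first column, ``r6[:, 3:]`` the raw second.  Near-degenerate
    rows are nudged by ``1e-8`` on the norms rather than raised, because a
    network head must stay differentiable everywhere it can reach.
    """
    r6 = np.asarray(r6)
    v1, v2 = r6[:, :3], r6[:, 3:]
    n1 = np.maximum(np.linalg.norm(v1, axis=1, keepdims=True), _EPS)
    e1 = v1 / n1
    dot = np.sum(e1 * v2, axis=1, keepdims=True)
    u2 = v2 - dot * e1
    n2 = np.maximum(np.linalg.norm(u2, axis=1, keepdims=True), _EPS)
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=2)
    cache = (v2, e1, e2, e3, n1, n2, dot)
    return R, cache


def gram_schmidt_backward(dR: np.ndarray, cache: tuple) -> np.ndarray:
    """VJP of :func:`gram_schmidt_forward`: ``dL/dR -> dL/dr6``."""
    v2, e1, e2, e3, n1, n2, dot = cache
    g1c, g2c, g3 = dR[:, :, 0], dR[:, :, 1], dR[:, :, 2]
    # e3 = e1 x e2
    ge1 = g1c + np.cross(e2, g3)
    ge2 = g2c + np.cross(g3, e1)
    # e2 = u2 / n2
    gu2 = (ge2 - np.sum(e2 * ge2, axis=1, keepdims=True) * e2) / n2
    # u2 = v2 - (e1 . v2) e1
    gv2 = gu2 - np.sum(e1 * gu2, axis=1, keepdims=True) * e1
    ge1 = ge1 - np.sum(e1 * gu2, axis=1, keepdims=True) * v2 - dot * gu2
    # e1 = v1 / n1
    gv1 = (ge1 - np.sum(e1 * ge1, axis=1, keepdims=True) * e1) / n1
    return np.concatenate([gv1, gv2], axis=1)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def translation_loss(t_pred: np.ndarray, t_gt: np.ndarray, squared: bool = False) -> float:
    """Batch mean of ``||t' - t||_2`` (or of its square when ``squared``)."""
    t_pred = np.atleast_2d(np.asarray(t_pred, dtype=float))
    t_gt = np.atleast_2d(np.asarray(t_gt, dtype=float))
    if t_pred.shape != t_gt.shape or t_pred.shape[-1] != 3:
        raise ValueError(f"shape mismatch: {t_pred.shape} vs {t_gt.shape}")
    norms = np.linalg.norm(t_pred - t_gt, axis=-1)
    return float(np.mean(norms ** 2 if squared else norms))


def rotation_loss(R_pred: np.ndarray, R_gt: np.ndarray, squared: bool = False) -> float:
    """Batch mean of Frobenius norms ``||R' - R||_F`` (or squares)."""
    R_pred = np.asarray(R_pred, dtype=float)
    R_gt = np.asarray(R_gt, dtype=float)
    if R_pred.shape != R_gt.shape or R_pred.shape[-2:] != (3, 3):
        raise ValueError(f"shape mismatch: {R_pred.shape} vs {R_gt.shape}")
    if R_pred.ndim == 2:
        R_pred, R_gt = R_pred[None], R_gt[None]
    norms = np.linalg.norm(R_pred - R_gt, axis=(-2, -1))
    return float(np.mean(norms ** 2 if squared else norms))


def total_loss(l_rot: float, l_trans: float, lambda_weight: float) -> float:
    """``L_total = L_rot + lambda * L_trans``."""
    if lambda_weight <= 0:
        raise ValueError(f"lambda_weight must be positive, got {lambda_weight}")
    return float(l_rot + lambda_weight * l_trans)


def translation_loss_grad(t_pred: np.ndarray, t_gt: np.ndarray,
                          squared: bool = False) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``t_pred``."""
    d = t_pred - t_gt
    n = d.shape[0]
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if squared:
        return float(np.mean(norms ** 2)), (2.0 / n) * d
    grad = d / (n * np.maximum(norms, _EPS))
    return float(np.mean(norms)), grad


def rotation_loss_grad(R_pred: np.ndarray, R_gt: np.ndarray,
                       squared: bool = False) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``R_pred`` (batched 3x3)."""
    d = R_pred - R_gt
    n = d.shape[0]
    norms = np.linalg.norm(d, axis=(1, 2))[:, None, None]
    if squared:
        return float(np.mean(norms ** 2)), (2.0 / n) * d
    grad = d / (n * np.maximum(norms, _EPS))
    return float(np.mean(norms)), grad
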