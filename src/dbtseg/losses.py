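"""The f_alpha overlap measure (Dice coefficient at alpha = 1) and its loss.

    f_alpha(S, T) = (1 + alpha^2) * sum_i s_i t_i / (sum_i s_i + sum_i t_i)

over the M elements of the predicted heatmap S (values in [0, 1]) and the
binary ground-truth heatmap T.  At alpha = 1 this is the Dice coefficient.
The training loss is 1 - f_alpha, so minimizing the loss maximizes
overlap; compared with a pixelwise squared error it weights the rare
positive class and the abundant background symmetrically, which is what a
segmentation task with tiny foreground objects needs.

Note the denominator is the plain sum of both heatmaps, without the
alpha^2 weighting of the classical F_alpha score; the two coincide at
alpha = 1, which is the operating point used throughout.

A smoothing epsilon added to numerator and denominator handles
all-background inputs during training; the strict form (which refuses the
undefined 0/0 case) is the default for metric use.
"""

from __future__ import annotations

import numpy as np


def f_alpha_measure(
    S: np.ndarray, T: np.ndarray, alpha: float = 1.0, eps: float = 0.0
) -> float:
    """Overlap score in [0, 1] for alpha = 1 and S in [0, 1].

    With ``eps == 0`` an all-zero S and T pair raises (0/0 undefined);
    pass a small ``eps`` to smooth instead.
    """
    S = np.asarray(S, dtype=np.float64).ravel()
    T = np.asarray(T, dtype=np.float64).ravel()
    if S.size == 0:
        raise ValueError("empty inputs")
    if S.shape != T.shape:
        raise ValueError(f"S and T must have the same element count, got {S.size} vs {T.size}")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    num = (1.0 + alpha**2) * float(S @ T) + eps
    den = float(S.sum() + T.sum()) + eps
    if den == 0.0:
        raise ValueError(
            "f_alpha is undefined when both heatmaps are entirely zero "
            "(0/0); pass a smoothing eps for training use"
        )
    return num / den


def f_alpha_loss(
    S: np.ndarray, T: np.ndarray, alpha: float = 1.0, eps: float = 0.0
) -> float:
    """Training loss 1 - f_alpha(S, T); 0 for a perfect prediction."""
    return 1.0 - f_alpha_measure(S, T, alpha, eps)


def f_alpha_loss_grad(
    S: np.ndarray, T: np.ndarray, alpha: float = 1.0, eps: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to every element of S.

    d(loss)/ds_i = -((1+a^2) t_i * den - num) / den^2 with
    num = (1+a^2)*sum(s t) + eps, den = sum(s) + sum(t) + eps.
    """
    S64 = np.asarray(S, dtype=np.float64)
    T64 = np.asarray(T, dtype=np.float64)
    if S64.shape != T64.shape:
        raise ValueError("shape mismatch between S and T")
    a2 = 1.0 + alpha**2
    num = a2 * float((S64 * T64).sum()) + eps
    den = float(S64.sum() + T64.sum()) + eps
    if den == 0.0:
        raise ValueError("undefined 0/0 f_alpha; use a positive eps")
    loss = 1.0 - num / den
    grad = -(a2 * T64 * den - num) / den**2
    return loss, grad
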