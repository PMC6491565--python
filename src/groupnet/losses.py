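"""Loss family for the grouped-convolution classifiers.

Three related losses, all functions of the probability ``p`` the softmax
assigns to the true class of a record:

* cross entropy          CE(p)  = -log p
* focal loss             FL(p)  = -(1-p)^gamma * log p, gamma >= 0
* correlated loss        CL     = main + sum_i alpha_i * aux_i

The focal modulating factor (1-p)^gamma down-weights well-classified
records; at gamma = 0 focal loss reduces exactly to cross entropy.

The correlated loss couples the three otherwise independent binary-
relevance disease classifiers: each head's loss is augmented with the
other two heads' losses weighted by the pairwise label correlation
(phi / Pearson) between the diseases. CL1 builds the terms from cross
entropy, CL2 from focal loss. Because the heads have disjoint parameters
and the correlation matrix is symmetric, training on the summed correlated
losses scales each head's gradient by (1 + sum of its incoming alphas);
see :func:`head_gradient_weights`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: probabilities are clipped below at this value before the log
EPS = 1e-7

LOSS_KINDS = ("CE", "FL", "CL1", "CL2")


@dataclass
class LossConfig:
    """Which loss to train with and its hyper-parameters.

    ``alpha`` is the 3x3 label correlation matrix whose off-diagonal
    entries weight the auxiliary terms of the correlated loss; it is
    ignored for plain CE/FL. ``use_absolute_alpha`` substitutes |alpha|,
    for cohorts where some pairwise correlations are negative.
    """

    kind: str = "CE"
    gamma: float = 2.0
    alpha: np.ndarray | None = None
    use_absolute_alpha: bool = False
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValidationError(f"loss kind must be one of {LOSS_KINDS}")
        if self.gamma < 0:
            raise ValidationError("gamma must be nonnegative")
        if self.reduction not in ("mean", "sum"):
            raise ValidationError("reduction must be 'mean' or 'sum'")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if not np.allclose(self.alpha, self.alpha.T):
                raise ValidationError("alpha matrix must be symmetric")
            if not np.allclose(np.diag(self.alpha), 1.0):
                raise ValidationError("alpha matrix must have a unit diagonal")

    @property
    def is_correlated(self) -> bool:
        return self.kind in ("CL1", "CL2")

    @property
    def base_gamma(self) -> float:
        """Focusing parameter of the per-head base loss (0 for CE/CL1)."""
        return self.gamma if self.kind in ("FL", "CL2") else 0.0

    def effective_alpha(self) -> np.ndarray:
        if self.alpha is None:
            raise ValidationError(f"loss kind {self.kind} requires an alpha matrix")
        return np.abs(self.alpha) if self.use_absolute_alpha else self.alpha


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    return np.maximum(p, EPS)


def _reduce(values: np.ndarray, reduction: str) -> float:
    if reduction == "mean":
        return float(values.mean())
    if reduction == "sum":
        return float(values.sum())
    raise ValidationError("reduction must be 'mean' or 'sum'")


def cross_entropy(p: np.ndarray, reduction: str = "mean") -> float:
    """-log p per record, reduced over the batch."""
    return _reduce(-np.log(_check_probs(p)), reduction)


def focal_loss(p: np.ndarray, gamma: float, reduction: str = "mean") -> float:
    """-(1-p)^gamma log p per record, reduced over the batch."""
    if gamma < 0:
        raise ValidationError("gamma must be nonnegative")
    p = _check_probs(p)
    return _reduce(-((1.0 - p) ** gamma) * np.log(p), reduction)


def correlated_loss(main_loss: float, aux_losses, alphas) -> float:
    """CL = main + sum_i alpha_i * aux_i, with exactly two auxiliary terms."""
    aux = np.asarray(aux_losses, dtype=float)
    al = np.asarray(alphas, dtype=float)
    if aux.shape != (2,) or al.shape != (2,):
        raise ValidationError("correlated loss takes exactly two auxiliary terms")
    return float(main_loss + al @ aux)


def br_total_loss(
    per_classifier_losses, alpha: np.ndarray
) -> tuple[float, np.ndarray]:
    """Correlated losses of the three BR heads and their training total.

    For head k, CL_k = loss_k + sum_{i != k} alpha[k, i] * loss_i; the
    total optimised during joint training is sum_k CL_k.
    """
    losses = np.asarray(per_classifier_losses, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if losses.shape != (3,) or alpha.shape != (3, 3):
        raise ValidationError("expected three head losses and a 3x3 alpha matrix")
    off = alpha - np.diag(np.diag(alpha))
    cl = losses + off @ losses
    return float(cl.sum()), cl


def head_gradient_weights(alpha: np.ndarray) -> np.ndarray:
    """Per-head gradient scaling implied by joint training on sum_k CL_k.

    Head k's parameters appear in its own CL_k and, through the auxiliary
    terms, in every other head's CL_i with weight alpha[i, k]; since the
    parameter sets are disjoint, d(total)/d(theta_k) =
    (1 + sum_{i != k} alpha[i, k]) * d(loss_k)/d(theta_k).
    """
    alpha = np.asarray(alpha, dtype=float)
    off = alpha - np.diag(np.diag(alpha))
    return 1.0 + off.sum(axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, gamma: float = 0.0
) -> tuple[float, np.ndarray]:
    """Mean focal (or, at gamma=0, cross-entropy) loss and its logit gradient.

    Returns the batch-mean loss and d(loss)/d(logits), already divided by
    the batch size. Used by the training loop as the terminal node of
    backpropagation.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    pt = np.maximum(probs[np.arange(n), targets], EPS)
    one_minus = 1.0 - pt

    loss = float(np.mean(-(one_minus**gamma) * np.log(pt)))

    # dL/dp_t; the gamma term vanishes identically at gamma = 0
    if gamma > 0:
        dldp = gamma * np.maximum(one_minus, EPS) ** (gamma - 1.0) * np.log(pt) \
            - one_minus**gamma / pt
    else:
        dldp = -1.0 / pt
    # chain through the softmax: dp_t/dz_j = p_t (1[j=t] - p_j)
    grad = probs * (dldp * pt)[:, None]
    grad[np.arange(n), targets] -= dldp * pt
    grad *= -1.0 / n
    return loss, grad
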