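"""Discrete-time hazard model primitives.

Overall survival is discretized into ``n_intervals`` right-open intervals
[t_r, t_{r+1}).  For a patient with feature bag x the network emits one
conditional hazard per interval,

    h(r | x) = P(T = r | T >= r, x),

from which the discrete survival function is the product of conditional
survival terms,

    S(r | x) = P(T > r | x) = prod_{u=0..r} (1 - h(u | x)),

with the empty-product convention S(-1) = 1.  The scalar patient risk score
is the sum of the interval hazards.

The training objective is a censoring-aware negative log-likelihood.  With
censoring indicator c (1 = right-censored, 0 = event observed) and interval
label Y:

    L_censored   = -c * log S(Y | x)
    L_uncensored = -(1 - c) * log( S(Y - 1 | x) * h(Y | x) )
    L            = L_censored + L_uncensored
    L_surv       = (1 - alpha) * L + alpha * L_uncensored

The mixing weight alpha in [0, 1] up-weights the uncensored (fully observed)
cases relative to the censored ones.  Note the algebraic identity: for an
uncensored case L = L_uncensored, hence L_surv = L for every alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HazardPrediction",
    "survival_function",
    "survival_curve",
    "risk_score",
    "loss_single",
    "loss_grad_logits",
    "EPS",
]

#: probability clamp applied inside logarithms
EPS = 1e-7


@dataclass
class HazardPrediction:
    """Per-patient output of the survival head.

    Attributes
    ----------
    hazards : (n_intervals,) conditional interval hazards, each in (0, 1).
    survival : (n_intervals,) survival function S(r) for r = 0..n_intervals-1.
    risk : scalar risk score, the sum of the hazards.
    attention : (M,) attention weights over the bag's patches (sum to 1),
        or ``None`` when the prediction did not come from a bag.
    """

    hazards: np.ndarray
    survival: np.ndarray
    risk: float
    attention: np.ndarray | None = field(default=None)


def _check_hazards(hazards: np.ndarray) -> np.ndarray:
    h = np.asarray(hazards, dtype=float)
    if h.ndim != 1 or h.size < 1:
        raise ValueError("hazards must be a non-empty 1-D vector")
    if not np.all(np.isfinite(h)) or np.any(h < 0.0) or np.any(h > 1.0):
        raise ValueError("hazards must be finite and lie in [0, 1]")
    return h


def survival_function(hazards: np.ndarray, r: int) -> float:
    """Discrete survival probability S(r) = prod_{u=0..r} (1 - h(u)).

    ``r = -1`` returns 1.0 (empty product), so the uncensored likelihood
    term S(Y-1) * h(Y) is defined at Y = 0.
    """
    h = _check_hazards(hazards)
    if not -1 <= r < h.size:
        raise ValueError(f"interval index r={r} outside [-1, {h.size - 1}]")
    if r == -1:
        return 1.0
    return float(np.prod(1.0 - h[: r + 1]))


def survival_curve(hazards: np.ndarray) -> np.ndarray:
    """Vector of S(r) for r = 0..n_intervals-1 (non-increasing)."""
    h = _check_hazards(hazards)
    return np.cumprod(1.0 - h)


def risk_score(hazards: np.ndarray) -> float:
    """Patient-level risk score: the sum of the interval hazards."""
    return float(np.sum(_check_hazards(hazards)))


def loss_single(
    hazards: np.ndarray,
    y: int,
    c: int,
    alpha: float,
    eps: float = EPS,
) -> float:
    """Censoring-weighted negative log-likelihood for one patient.

    Parameters
    ----------
    hazards : interval hazards h(0..n-1).
    y : observed interval label in {0, ..., n_intervals-1}.
    c : censoring indicator; 1 = censored, 0 = event observed.
    alpha : weight in [0, 1] mixing the full loss with the uncensored term.
    eps : probability clamp inside logarithms.
    """
    h = _check_hazards(hazards)
    n = h.size
    if not (isinstance(y, (int, np.integer)) and 0 <= y < n):
        raise ValueError(f"interval label y={y} outside {{0..{n - 1}}}")
    if c not in (0, 1):
        raise ValueError(f"censoring indicator c={c} must be 0 or 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")

    # log-space with clamped probabilities for numerical stability
    log1m = np.log(np.clip(1.0 - h, eps, 1.0))
    logh = np.log(np.clip(h, eps, 1.0))
    log_surv_y = float(np.sum(log1m[: y + 1]))        # log S(Y)
    log_surv_ym1 = float(np.sum(log1m[:y]))           # log S(Y-1), =0 at Y=0

    l_cens = -c * log_surv_y
    l_unc = -(1 - c) * (log_surv_ym1 + logh[y])
    l_full = l_cens + l_unc
    return float((1.0 - alpha) * l_full + alpha * l_unc)


def loss_grad_logits(
    hazards: np.ndarray,
    y: int,
    c: int,
    alpha: float,
) -> np.ndarray:
    """Analytic gradient of :func:`loss_single` w.r.t. the hazard logits.

    With h(u) = sigmoid(logit_u):

    * censored (c=1):  loss = (1-alpha) * -sum_{u<=Y} log(1-h_u);
      d/dlogit_u = (1-alpha) * h_u   for u <= Y, else 0.
    * uncensored (c=0): loss = -sum_{u<Y} log(1-h_u) - log h_Y;
      d/dlogit_u = h_u for u < Y, h_Y - 1 at u = Y, else 0.
    """
    h = _check_hazards(hazards)
    n = h.size
    grad = np.zeros(n)
    if c == 1:
        grad[: y + 1] = (1.0 - alpha) * h[: y + 1]
    else:
        grad[:y] = h[:y]
        grad[y] = h[y] - 1.0
    return grad
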