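"""Attention-based multiple-instance network for discrete-time survival.

One patient is one *bag*: an M x d matrix of patch feature vectors with no
patch-level labels.  The network is

1. a linear projection d -> d_h with ReLU, giving patch embeddings h_m;
2. gated attention pooling: score s_m = w^T (tanh(V h_m) * sigmoid(U h_m)),
   weights a = softmax(s), pooled bag embedding = sum_m a_m h_m.  The
   pooling is a convex combination, hence permutation invariant;
3. a two-layer prediction head d_h -> d_p -> n_intervals whose logits pass
   through a per-interval sigmoid to yield conditional hazards.

A plain ``tanh`` attention variant (s_m = w^T tanh(V h_m)) is available via
``MILConfig.attention``.  Everything is NumPy; gradients are computed by
hand in :meth:`AttentionMILNet.backward` and verified against central
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax

from .hazards import HazardPrediction, risk_score, survival_curve

__all__ = ["MILConfig", "AttentionMILNet", "attention_pool", "default_widths"]


def default_widths(input_dim: int) -> tuple[int, int, int]:
    """Default hidden widths (d_h, d_a, d_p), scaled with the feature dim.

    For d = 1024 this gives (256, 128, 128).  Small test dims keep a floor
    of 64 hidden units: below that, optimization on one-bag batches becomes
    noticeably less reliable while the parameter count stays tiny either way.
    """
    d_h = max(64, input_dim // 4)
    d_a = max(32, d_h // 2)
    d_p = max(32, d_h // 2)
    return d_h, d_a, d_p


@dataclass
class MILConfig:
    input_dim: int
    d_h: int | None = None
    d_a: int | None = None
    d_p: int | None = None
    n_intervals: int = 4
    attention: str = "gated"  # "gated" (tanh * sigmoid) or "tanh"

    def __post_init__(self) -> None:
        dh, da, dp = default_widths(self.input_dim)
        self.d_h = self.d_h or dh
        self.d_a = self.d_a or da
        self.d_p = self.d_p or dp
        if self.attention not in ("gated", "tanh"):
            raise ValueError(f"unknown attention variant {self.attention!r}")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")


class AttentionMILNet:
    """Gated-attention MIL network with hand-written backprop."""

    def __init__(self, config: MILConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d, dh, da, dp = config.input_dim, config.d_h, config.d_a, config.d_p
        n_out = config.n_intervals

        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "W_proj": he(d, (d, dh)),
            "b_proj": np.zeros(dh),
            "V": he(dh, (dh, da)),
            "b_V": np.zeros(da),
            "w_att": rng.normal(0.0, np.sqrt(1.0 / da), size=da),
            "W1": he(dh, (dh, dp)),
            "b1": np.zeros(dp),
            "W2": he(dp, (dp, n_out)),
            "b2": np.zeros(n_out),
        }
        if config.attention == "gated":
            self.params["U"] = he(dh, (dh, da))
            self.params["b_U"] = np.zeros(da)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ---------------------------------------------------------------- forward

    def forward(self, features: np.ndarray) -> dict:
        """Full forward pass; returns a cache of intermediates for backward."""
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("features must be a non-empty M x d matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature dim {X.shape[1]} != configured {self.config.input_dim}"
            )
        p = self.params
        Hpre = X @ p["W_proj"] + p["b_proj"]
        H = np.maximum(Hpre, 0.0)
        T = np.tanh(H @ p["V"] + p["b_V"])
        if self.config.attention == "gated":
            S = expit(H @ p["U"] + p["b_U"])
            G = T * S
        else:
            S = None
            G = T
        scores = G @ p["w_att"]
        a = softmax(scores)
        pooled = a @ H
        Z1pre = pooled @ p["W1"] + p["b1"]
        Z1 = np.maximum(Z1pre, 0.0)
        logits = Z1 @ p["W2"] + p["b2"]
        hazards = expit(logits)
        return {
            "X": X, "Hpre": Hpre, "H": H, "T": T, "S": S, "G": G,
            "a": a, "pooled": pooled, "Z1pre": Z1pre, "Z1": Z1,
            "logits": logits, "hazards": hazards,
        }

    def pool(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Attention pooling only: (pooled d_h vector, M attention weights)."""
        cache = self.forward(features)
        return cache["pooled"], cache["a"]

    def predict(self, features: np.ndarray) -> HazardPrediction:
        cache = self.forward(features)
        h = cache["hazards"]
        return HazardPrediction(
            hazards=h,
            survival=survival_curve(h),
            risk=risk_score(h),
            attention=cache["a"],
        )

    # --------------------------------------------------------------- backward

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given dL/dlogits."""
        p = self.params
        X, H, Hpre = cache["X"], cache["H"], cache["Hpre"]
        T, S, G, a = cache["T"], cache["S"], cache["G"], cache["a"]
        pooled, Z1, Z1pre = cache["pooled"], cache["Z1"], cache["Z1pre"]

        grads: dict[str, np.ndarray] = {}
        grads["W2"] = np.outer(Z1, dlogits)
        grads["b2"] = dlogits.copy()
        dZ1 = p["W2"] @ dlogits
        dZ1pre = dZ1 * (Z1pre > 0)
        grads["W1"] = np.outer(pooled, dZ1pre)
        grads["b1"] = dZ1pre
        dpooled = p["W1"] @ dZ1pre

        da = H @ dpooled                      # (M,)
        dH = np.outer(a, dpooled)             # (M, d_h)
        ds = a * (da - a @ da)                # softmax backward
        grads["w_att"] = G.T @ ds
        dG = np.outer(ds, p["w_att"])
        if self.config.attention == "gated":
            dT = dG * S
            dS = dG * T
            dSpre = dS * S * (1.0 - S)
            grads["U"] = H.T @ dSpre
            grads["b_U"] = dSpre.sum(axis=0)
            dH += dSpre @ p["U"].T
        else:
            dT = dG
        dTpre = dT * (1.0 - T * T)
        grads["V"] = H.T @ dTpre
        grads["b_V"] = dTpre.sum(axis=0)
        dH += dTpre @ p["V"].T

        dHpre = dH * (Hpre > 0)
        grads["W_proj"] = X.T @ dHpre
        grads["b_proj"] = dHpre.sum(axis=0)
        return grads


def attention_pool(
    features: np.ndarray, net: AttentionMILNet
) -> tuple[np.ndarray, np.ndarray]:
    """Pool a bag of patch features into one embedding.

    Returns ``(pooled, attention)`` where ``attention`` is a nonnegative
    vector of length M summing to one.
    """
    return net.pool(features)
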