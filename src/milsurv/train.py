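"""Training protocol: time discretization, Adam + cosine annealing, k-fold CV.

Overall survival time is split into four intervals at the quartiles of the
*uncensored* event times (linear-interpolation percentiles), so uncensored
training cases spread evenly across intervals.  Training minimizes the
mean censoring-weighted negative log-likelihood, one bag per optimizer
step, with Adam (beta1 = 0.9) at an initial learning rate of 2e-4 decayed
by a cosine-annealing schedule over the epochs.  Cross-validation is
stratified on the censoring indicator so every fold mirrors the cohort's
censored fraction, and the interval scheme is recomputed from each training
split only — the test fold never influences the cut points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import ClinicalRecord, PatchBag
from .evaluate import concordance_index
from .hazards import loss_grad_logits, loss_single
from .net import AttentionMILNet, MILConfig

__all__ = [
    "IntervalScheme",
    "TrainConfig",
    "discretize_times",
    "stratified_folds",
    "train_fold",
    "cross_validate",
    "predict_risks",
    "FoldResult",
    "CVResult",
]


def stratified_folds(
    censored_flags, k_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs, stratified on the censoring indicator.

    Test folds partition the cohort; each fold's censored count matches the
    cohort proportion to within one case.
    """
    cens = np.asarray(censored_flags, dtype=int)
    skf = StratifiedKFold(
        n_splits=k_folds, shuffle=True, random_state=seed % (2**32)
    )
    return [(tr, te) for tr, te in skf.split(np.zeros(cens.size), cens)]


@dataclass(frozen=True)
class IntervalScheme:
    """Right-open survival intervals [0,t1), [t1,t2), ..., [t_{n-1}, inf)."""

    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_points)
        if any(b < a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be non-decreasing")
        object.__setattr__(self, "cut_points", cuts)

    @property
    def n_intervals(self) -> int:
        return len(self.cut_points) + 1

    def label(self, t: float) -> int:
        """Interval index of time t under the right-open convention."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        return int(np.searchsorted(self.cut_points, t, side="right"))


def discretize_times(
    clinical: list[ClinicalRecord], n_intervals: int = 4
) -> IntervalScheme:
    """Quartile (in general, even-quantile) cuts of the uncensored times.

    Assigns the interval label ``y`` to every record in place.  Censored
    records beyond the last cut point fall in the final interval.
    """
    uncensored = [r.os_months for r in clinical if r.censored == 0]
    if len(uncensored) == 0:
        raise ValueError("cannot discretize: all records are censored")
    if len(uncensored) < n_intervals:
        raise ValueError(
            f"need >= {n_intervals} uncensored records, got {len(uncensored)}"
        )
    qs = [100.0 * i / n_intervals for i in range(1, n_intervals)]
    cuts = np.percentile(np.asarray(uncensored, dtype=float), qs)
    scheme = IntervalScheme(cut_points=tuple(cuts))
    for r in clinical:
        r.y = scheme.label(r.os_months)
    return scheme


@dataclass
class TrainConfig:
    """Optimization and protocol settings (defaults follow the study protocol)."""

    learning_rate: float = 2e-4
    beta1: float = 0.9          # Adam first-moment decay ("momentum")
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 1         # bags per optimizer step
    epochs: int = 40
    alpha: float = 0.31         # censored/uncensored balance in the loss
    seed: int = 0
    k_folds: int = 5
    n_intervals: int = 4
    d_h: int | None = None
    d_a: int | None = None
    d_p: int | None = None
    attention: str = "gated"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1.0 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1.0 - c.beta2) * g * g
            params[k] -= lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + c.adam_eps
            )


def _cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    return 0.5 * lr0 * (1.0 + math.cos(math.pi * epoch / total_epochs))


def predict_risks(net: AttentionMILNet, bags: list[PatchBag]) -> np.ndarray:
    return np.array([net.predict(b.features).risk for b in bags])


def train_fold(
    bags: list[PatchBag],
    clinical: list[ClinicalRecord],
    scheme: IntervalScheme,
    config: TrainConfig,
    val_bags: list[PatchBag] | None = None,
    val_clinical: list[ClinicalRecord] | None = None,
) -> tuple[AttentionMILNet, list[dict]]:
    """Train one model on (bags, clinical) labeled under ``scheme``.

    Returns the trained network and a per-epoch history of the mean training
    loss (and validation C-index when a validation split is supplied).
    Deterministic given ``config.seed``.
    """
    if len(bags) < 2:
        raise ValueError("need at least 2 training cases")
    if all(r.censored == 1 for r in clinical):
        raise ValueError("need at least one uncensored training case")
    labels = [scheme.label(r.os_months) for r in clinical]

    net = AttentionMILNet(
        MILConfig(
            input_dim=bags[0].dim, d_h=config.d_h, d_a=config.d_a,
            d_p=config.d_p, n_intervals=config.n_intervals,
            attention=config.attention,
        ),
        seed=config.seed,
    )
    opt = _Adam(net.params, config)
    rng = np.random.default_rng(config.seed + 1)
    history: list[dict] = []
    n = len(bags)
    for epoch in range(config.epochs):
        lr = _cosine_lr(config.learning_rate, epoch, config.epochs)
        order = rng.permutation(n)
        losses = np.empty(n)
        for i, j in enumerate(order):
            cache = net.forward(bags[j].features)
            loss = loss_single(
                cache["hazards"], labels[j], clinical[j].censored, config.alpha
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, lr {lr:.3g}"
                )
            dlogits = loss_grad_logits(
                cache["hazards"], labels[j], clinical[j].censored, config.alpha
            )
            grads = net.backward(cache, dlogits)
            opt.step(net.params, grads, lr)
            losses[i] = loss
        row = {"epoch": epoch, "train_loss": float(losses.mean()), "lr": lr}
        if val_bags is not None and val_clinical is not None:
            risks = predict_risks(net, val_bags)
            times = np.array([r.os_months for r in val_clinical])
            cens = np.array([r.censored for r in val_clinical])
            try:
                row["val_cindex"] = concordance_index(times, cens, risks).c
            except ValueError:
                row["val_cindex"] = float("nan")
        history.append(row)
    return net, history


@dataclass
class FoldResult:
    fold: int
    test_index: np.ndarray
    risks: np.ndarray
    cindex: float  # NaN when undefined (no comparable pairs in the fold)
    n_train: int
    n_test: int
    n_test_censored: int
    scheme: IntervalScheme
    history: list[dict] = field(repr=False, default_factory=list)


@dataclass
class CVResult:
    folds: list[FoldResult]
    oof_risks: np.ndarray       # one out-of-fold risk score per patient
    fold_of_patient: np.ndarray

    @property
    def cindexes(self) -> np.ndarray:
        return np.array([f.cindex for f in self.folds])

    @property
    def mean_cindex(self) -> float:
        return float(np.nanmean(self.cindexes))

    @property
    def cindex_range(self) -> tuple[float, float]:
        return float(np.nanmin(self.cindexes)), float(np.nanmax(self.cindexes))


def cross_validate(
    bags: list[PatchBag],
    clinical: list[ClinicalRecord],
    config: TrainConfig,
    track_history: bool = False,
) -> CVResult:
    """k-fold cross-validation stratified on the censoring indicator.

    Every patient receives exactly one out-of-fold risk score; the interval
    scheme for each fold comes from its training split only.
    """
    n = len(bags)
    if n < config.k_folds:
        raise ValueError("need at least k_folds patients")
    cens = np.array([r.censored for r in clinical])
    oof = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    folds: list[FoldResult] = []
    for k, (tr, te) in enumerate(stratified_folds(cens, config.k_folds, config.seed)):
        tr_clin = [clinical[i] for i in tr]
        scheme = discretize_times(tr_clin, config.n_intervals)
        fold_cfg = replace(config, seed=config.seed + 1000 * k)
        net, hist = train_fold(
            [bags[i] for i in tr], tr_clin, scheme, fold_cfg,
            val_bags=[bags[i] for i in te] if track_history else None,
            val_clinical=[clinical[i] for i in te] if track_history else None,
        )
        risks = predict_risks(net, [bags[i] for i in te])
        times = np.array([clinical[i].os_months for i in te])
        te_cens = cens[te]
        try:
            ci = concordance_index(times, te_cens, risks).c
        except ValueError:  # zero comparable pairs: undefined, run continues
            ci = float("nan")
        oof[te] = risks
        fold_of[te] = k
        folds.append(FoldResult(
            fold=k, test_index=te, risks=risks, cindex=ci,
            n_train=len(tr), n_test=len(te),
            n_test_censored=int(te_cens.sum()), scheme=scheme,
            history=hist,
        ))
    return CVResult(folds=folds, oof_risks=oof, fold_of_patient=fold_of)
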