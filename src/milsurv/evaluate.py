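"""Survival evaluation and risk stratification.

Implements the classical censored-survival toolkit with pinned conventions:

* Harrell's concordance index — a pair is comparable iff the shorter
  observed time belongs to an uncensored case and the times differ; risk
  ties earn half credit; orientation is explicit because a risk score that
  sums interval hazards is naturally "higher risk => earlier event";
* Kaplan-Meier product-limit estimator and the two-group log-rank test
  (observed minus expected events with the hypergeometric variance);
* median split of risk scores (strictly above the median => high group;
  scores equal to the median go low);
* cumulative/dynamic time-dependent AUC with inverse-probability-of-
  censoring weights from the Kaplan-Meier estimate of the censoring
  distribution;
* HRD (homologous recombination deficiency) scoring: TAI + LST + LOH with
  positivity strictly above 42;
* the classical two-sample comparisons (t, Wilcoxon rank-sum, chi-square,
  Spearman), delegated to scipy.

Throughout, ``censored`` is 1 for right-censored follow-up and 0 for an
observed event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CIndexResult",
    "KMCurve",
    "LogRankResult",
    "HRDRecord",
    "concordance_index",
    "km_estimate",
    "logrank_test",
    "median_split",
    "td_auc",
    "hrd_classify",
    "group_compare",
    "ttest_from_summary",
]


# ------------------------------------------------------------------- C-index

@dataclass
class CIndexResult:
    concordant: float
    tied: float
    comparable: int
    c: float
    orientation: str


def concordance_index(
    times, censored, risks, orientation: str = "higher-risk-earlier-event"
) -> CIndexResult:
    """Harrell's C over comparable pairs.

    A pair (i, j) with t_i < t_j is comparable iff case i had an observed
    event; pairs with identical times where both had events are excluded,
    and a tie (t_i = t_j) with one event makes the event case the
    "shorter" member.  Under the default orientation a comparable pair is
    concordant when the earlier-event case carries the *higher* risk;
    ``orientation="higher-risk-later-event"`` flips the direction.  Risk
    ties count 0.5.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(censored, dtype=int)
    r = np.asarray(risks, dtype=float)
    if not (t.shape == c.shape == r.shape) or t.ndim != 1 or t.size < 2:
        raise ValueError("times, censored, risks must be equal-length, n >= 2")
    if orientation not in ("higher-risk-earlier-event", "higher-risk-later-event"):
        raise ValueError(f"unknown orientation {orientation!r}")

    # pairwise, vectorized: i indexes the (uncensored) earlier-event case
    event_i = c == 0
    dt = t[:, None] - t[None, :]          # t_i - t_j
    shorter = (dt < 0) | ((dt == 0) & event_i[:, None] & (c[None, :] == 1))
    comparable = shorter & event_i[:, None]
    dr = r[:, None] - r[None, :]          # risk_i - risk_j
    if orientation == "higher-risk-earlier-event":
        conc = comparable & (dr > 0)
    else:
        conc = comparable & (dr < 0)
    ties = comparable & (dr == 0)

    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs: C-index undefined")
    n_conc = float(conc.sum())
    n_tie = float(ties.sum())
    return CIndexResult(
        concordant=n_conc, tied=n_tie, comparable=n_comp,
        c=(n_conc + 0.5 * n_tie) / n_comp, orientation=orientation,
    )


# -------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate: step function dropping only at event times."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    at_risk: np.ndarray       # n_i just before each event time
    events: np.ndarray        # d_i events at each time
    survival: np.ndarray      # S(t_i) after the drop
    censor_times: np.ndarray  # times of censored exits (tick marks)

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times, censored) -> KMCurve:
    """Kaplan-Meier estimator; censored cases leave the risk set after their
    time (at a tied time, events are counted before censored exits)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(censored, dtype=int)
    if t.ndim != 1 or t.size < 1 or np.any(t < 0):
        raise ValueError("need n >= 1 nonnegative times")
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    distinct = np.unique(t)
    n_at_risk = t.size
    ev_times, ns, ds, surv = [], [], [], []
    s = 1.0
    for ti in distinct:
        here = t == ti
        d = int(np.sum(here & (c == 0)))
        if d > 0:
            s *= 1.0 - d / n_at_risk
            ev_times.append(ti)
            ns.append(n_at_risk)
            ds.append(d)
            surv.append(s)
        n_at_risk -= int(here.sum())
    return KMCurve(
        event_times=np.array(ev_times),
        at_risk=np.array(ns, dtype=int),
        events=np.array(ds, dtype=int),
        survival=np.array(surv),
        censor_times=np.sort(np.asarray(times, dtype=float)[np.asarray(censored) == 1]),
    )


# ------------------------------------------------------------------ log-rank

@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]   # events in (A, B)
    expected: tuple[float, float]


def logrank_test(times_a, censored_a, times_b, censored_b) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time with d total events among n at risk
    (n_a from group A), the expected A events are n_a * d / n and the
    hypergeometric variance is d * (n_a/n) * (1 - n_a/n) * (n - d)/(n - 1).
    The statistic (O_A - E_A)^2 / Var is chi-square with 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ca = np.asarray(censored_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    cb = np.asarray(censored_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    c = np.concatenate([ca, cb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    if np.all(c == 1):
        raise ValueError("no events in either group: log-rank undefined")

    o_a = e_a = var = 0.0
    for ti in np.unique(t[c == 0]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & (g == 0)).sum())
        here = (t == ti) & (c == 0)
        d = int(here.sum())
        d_a = int((here & (g == 0)).sum())
        o_a += d_a
        e_a += n_a * d / n
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        stat = 0.0
    else:
        stat = (o_a - e_a) ** 2 / var
    d_total = float(np.sum(c == 0))
    return LogRankResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0,
        observed=(o_a, d_total - o_a),
        expected=(e_a, d_total - e_a),
    )


# -------------------------------------------------------------- median split

def median_split(risk_scores) -> np.ndarray:
    """Label each score 'high' (strictly above the median) or 'low'.

    The median uses the linear-interpolation convention; scores equal to
    the median fall in the low group.  Returns an array of 'high'/'low'.
    """
    r = np.asarray(risk_scores, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need at least 2 risk scores")
    med = float(np.median(r))
    labels = np.where(r > med, "high", "low")
    if np.all(labels == "low"):
        warnings.warn("all risk scores identical: every case labeled 'low'")
    return labels


# ----------------------------------------------------- time-dependent AUC

def td_auc(times, censored, risks, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW.

    Positives: event at or before the horizon.  Controls: observed time
    beyond the horizon.  Cases censored at or before the horizon carry no
    weight; positives are reweighted by 1 / G(T_i-), the Kaplan-Meier
    estimate of the censoring survival just before their event time.
    Without censoring this reduces exactly to the Mann-Whitney AUC.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(censored, dtype=int)
    r = np.asarray(risks, dtype=float)
    pos = (t <= horizon) & (c == 0)
    ctrl = t > horizon
    if pos.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("need >= 1 event before and >= 1 case past the horizon")

    # censoring distribution: flip the indicator and estimate G by KM
    g_curve = km_estimate(t, 1 - c)
    weights = np.zeros(t.size)
    for i in np.flatnonzero(pos):
        g = _km_left(g_curve, t[i])
        weights[i] = 1.0 / g if g > 0 else 0.0

    w = weights[pos]
    rp = r[pos]
    rc = r[ctrl]
    greater = (rp[:, None] > rc[None, :]).astype(float)
    ties = (rp[:, None] == rc[None, :]).astype(float)
    num = float(np.sum(w[:, None] * (greater + 0.5 * ties)))
    den = float(np.sum(w) * rc.size)
    if den == 0:
        raise ValueError("all positives carry zero censoring weight")
    return num / den


def _km_left(curve: KMCurve, t: float) -> float:
    """Left limit S(t-) of a KM curve."""
    idx = np.searchsorted(curve.event_times, t, side="left")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


# ----------------------------------------------------------------------- HRD

@dataclass
class HRDRecord:
    tai: float
    lst: float
    loh: float
    hrd_score: float
    positive: bool


def hrd_classify(tai: float, lst: float, loh: float) -> HRDRecord:
    """HRD score = TAI + LST + LOH; positive iff strictly above 42."""
    if tai < 0 or lst < 0 or loh < 0:
        raise ValueError("TAI/LST/LOH scores must be nonnegative")
    score = float(tai) + float(lst) + float(loh)
    return HRDRecord(tai=tai, lst=lst, loh=loh, hrd_score=score,
                     positive=score > 42.0)


# ------------------------------------------------------- two-sample testing

def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t test from summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)


def group_compare(a, b, test: str = "t") -> tuple[float, float]:
    """Classical two-sample comparison; returns (statistic, p-value).

    * ``t``: unpaired Student's t (pooled variance) on two value vectors;
    * ``wilcoxon``: Wilcoxon rank-sum (Mann-Whitney) on two value vectors;
    * ``chisq``: chi-square test on a contingency table (rows = categories,
      columns = groups) passed as ``a`` (``b`` ignored, may be None);
    * ``spearman``: Spearman rank correlation of the paired vectors a, b.
    """
    if test == "t":
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "wilcoxon":
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "chisq":
        table = np.asarray(a, float)
        if table.ndim != 2 or np.any(table.sum(axis=0) == 0):
            raise ValueError("chisq expects a contingency table with non-empty groups")
        res = stats.chi2_contingency(table)
        return float(res.statistic), float(res.pvalue)
    elif test == "spearman":
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size == 0 or a.size != b.size:
            raise ValueError("spearman expects paired vectors")
        res = stats.spearmanr(a, b)
        return float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
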