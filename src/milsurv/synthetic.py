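"""Synthetic cohorts with a planted, recoverable prognostic signal.

The generator emulates the statistical structure the downstream analysis
assumes about a whole-slide cohort, without any imaging:

* each patient contributes a *bag* of M patch feature vectors.  Background
  patches are iid standard normal in d dimensions; a per-patient subset of
  *informative* patches is additionally shifted by ``signal_strength`` along
  one cohort-level unit direction u, so attention pooling has a consistent
  target to find;
* the latent risk is z_j = signal_strength * (realized informative
  fraction of bag j).  The per-patient informative fraction is
  ``informative_fraction`` x Beta(0.3, 0.3) — a U-shaped spread emulating
  the wide slide-to-slide variation in tumor content, and giving the
  cohort genuine prognostic contrast (a constant fraction would plant
  none);
* discrete event intervals follow per-interval hazards
  h_j(r) = logistic( logit(baseline_hazards[r]) + beta * z_j ), sampled
  sequentially; patients surviving every interval are absorbed into the
  last one;
* right censoring is entry-independent: a censoring interval is drawn from
  a geometric law whose per-interval hazard q is calibrated numerically so
  the expected censored fraction equals ``censoring_rate``.  A patient whose
  event and censoring land in the same interval counts as uncensored;
* continuous months are synthesized uniformly inside the labeled interval
  (fixed interval width) so Kaplan-Meier / log-rank analyses can operate on
  a time axis, while the model itself consumes interval labels.

A companion generator draws tiny blob "slides" (white background, filled
ellipses in an H&E-like pink/purple band) with exact ground-truth masks to
exercise the segmentation and tiling geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data import ClinicalRecord, PatchBag, write_bag, write_clinical

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "SyntheticSlideSpec",
    "PatientTruth",
    "generate_cohort",
    "generate_slide_image",
]

#: months spanned by each discrete interval when synthesizing continuous time
INTERVAL_WIDTH_MONTHS = 12.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference cohort: 90 cases with a third censored,
    four survival intervals, and a strong planted signal (signal_strength 3,
    risk coefficient 1.5) in 32-dimensional test features.
    """

    n_patients: int = 90
    feature_dim: int = 32
    bag_size_range: tuple[int, int] = (16, 64)
    informative_fraction: float = 1.0
    signal_strength: float = 3.0
    n_intervals: int = 4
    baseline_hazards: tuple[float, ...] = (0.03, 0.06, 0.10, 0.15)
    risk_coefficient: float = 1.5
    censoring_rate: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        m_min, m_max = self.bag_size_range
        if not (1 <= m_min <= m_max):
            raise ValueError("bag_size_range must satisfy 1 <= M_min <= M_max")
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in (0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        if len(self.baseline_hazards) != self.n_intervals:
            raise ValueError("baseline_hazards length must equal n_intervals")
        if not all(0.0 < h < 1.0 for h in self.baseline_hazards):
            raise ValueError("baseline hazards must each lie in (0, 1)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class PatientTruth:
    latent_risk: float
    informative_patch_indices: np.ndarray
    true_event_interval: int


@dataclass
class SyntheticCohort:
    bags: list[PatchBag]
    clinical: list[ClinicalRecord]
    truth: list[PatientTruth]
    signal_direction: np.ndarray
    config: SyntheticConfig
    censor_hazard: float = 0.0

    def __post_init__(self) -> None:
        assert len(self.bags) == len(self.clinical) == len(self.truth)

    @property
    def n_patients(self) -> int:
        return len(self.bags)

    def to_dir(self, out_dir: str | Path) -> None:
        """Write bags (HDF5), the clinical TSV and the truth TSV."""
        out = Path(out_dir)
        bags_dir = out / "bags"
        bags_dir.mkdir(parents=True, exist_ok=True)
        for bag in self.bags:
            write_bag(bags_dir / f"{bag.patient_id}.h5", bag)
        write_clinical(out / "clinical.tsv", self.clinical)
        with open(out / "truth.tsv", "w") as f:
            f.write("patient_id\tlatent_risk\ttrue_event_interval\t"
                    "informative_patch_indices\n")
            for bag, t in zip(self.bags, self.truth):
                idx = ",".join(map(str, t.informative_patch_indices))
                f.write(f"{bag.patient_id}\t{t.latent_risk:.10g}\t"
                        f"{t.true_event_interval}\t{idx}\n")


def _event_pmf(hazards: np.ndarray) -> np.ndarray:
    """PMF over event intervals 0..n-1 with survivors absorbed into the last."""
    n = hazards.size
    pmf = np.empty(n)
    surv = 1.0
    for r in range(n - 1):
        pmf[r] = surv * hazards[r]
        surv *= 1.0 - hazards[r]
    pmf[n - 1] = surv
    return pmf


def _calibrate_censor_hazard(event_pmfs: np.ndarray, rate: float) -> float:
    """Per-interval censoring hazard q with mean P(censor < event) = rate.

    The censoring interval is geometric: P(C = r) = q (1-q)^r.  A patient is
    censored iff C < E, so P(censor | E = e) = 1 - (1-q)^e, and a patient
    with E = 0 can never be censored.  Solves for q by bisection; if the
    requested rate exceeds the attainable maximum (q -> 1), returns that
    maximum's q and the realized rate falls short.
    """
    if rate <= 0.0:
        return 0.0
    e_vals = np.arange(event_pmfs.shape[1])

    def expected(q: float) -> float:
        p_cens = 1.0 - (1.0 - q) ** e_vals
        return float(np.mean(event_pmfs @ p_cens))

    hi = 1.0 - 1e-9
    if expected(hi) <= rate:
        return hi
    return float(brentq(lambda q: expected(q) - rate, 0.0, hi, xtol=1e-12))


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one fully reproducible cohort from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, d = config.n_patients, config.feature_dim
    base = np.asarray(config.baseline_hazards, dtype=float)

    u = rng.normal(size=d)
    u /= np.linalg.norm(u)

    # bag sizes, per-patient informative fractions, latent risks, hazards
    m_min, m_max = config.bag_size_range
    bag_sizes = rng.integers(m_min, m_max + 1, size=n)
    frac_draw = config.informative_fraction * rng.beta(0.3, 0.3, size=n)
    n_inform = np.round(frac_draw * bag_sizes).astype(int)
    realized_frac = n_inform / bag_sizes
    z = config.signal_strength * realized_frac
    haz = expit(logit(base)[None, :] + config.risk_coefficient * z[:, None])
    assert np.all((haz > 0.0) & (haz < 1.0))

    pmfs = np.vstack([_event_pmf(h) for h in haz])
    q = _calibrate_censor_hazard(pmfs, config.censoring_rate)

    bags: list[PatchBag] = []
    clinical: list[ClinicalRecord] = []
    truth: list[PatientTruth] = []
    n_int = config.n_intervals
    for j in range(n):
        m = int(bag_sizes[j])
        X = rng.normal(size=(m, d))
        idx = rng.choice(m, size=int(n_inform[j]), replace=False)
        idx.sort()
        X[idx] += config.signal_strength * u
        coords = np.stack(
            [(np.arange(m) % 16) * 256, (np.arange(m) // 16) * 256], axis=1
        )
        pid = f"SYN-{j:04d}"
        bags.append(PatchBag(
            patient_id=pid, features=X, coords=coords, encoder_id="synthetic",
        ))

        # sequential event sampling; survivors absorb into the last interval
        event = n_int - 1
        for r in range(n_int - 1):
            if rng.random() < haz[j, r]:
                event = r
                break
        if q > 0.0:
            censor = int(np.floor(np.log(rng.random()) / np.log(1.0 - q)))
        else:
            censor = n_int  # beyond every interval: never censors
        is_censored = censor < event  # same-interval ties count as events
        y = censor if is_censored else event
        months = (y + rng.uniform()) * INTERVAL_WIDTH_MONTHS

        clinical.append(ClinicalRecord(
            patient_id=pid,
            os_months=float(months),
            censored=int(is_censored),
            age=float(np.clip(rng.normal(60.0, 10.8), 30.0, 90.0)),
            stage=rng.choice(
                ["I", "II", "III", "IV"], p=[0.03, 0.04, 0.68, 0.25]
            ),
            grade=rng.choice(["G2", "G3"], p=[0.05, 0.95]),
            residual=rng.choice(
                ["0", "1-10mm", "11-20mm", ">20mm", "none"],
                p=[0.05, 0.49, 0.08, 0.16, 0.22],
            ),
            tai=float(rng.poisson(15.0)),
            lst=float(rng.poisson(14.0)),
            loh=float(rng.poisson(13.0)),
        ))
        truth.append(PatientTruth(
            latent_risk=float(z[j]),
            informative_patch_indices=idx,
            true_event_interval=int(event),
        ))

    return SyntheticCohort(
        bags=bags, clinical=clinical, truth=truth,
        signal_direction=u, config=config, censor_hazard=q,
    )


# --------------------------------------------------------------- slide images

@dataclass
class SyntheticSlideSpec:
    """Blob-slide fixture: filled ellipses on a white background."""

    image_size: tuple[int, int] = (512, 512)  # (H, W)
    n_blobs: int = 2
    blob_axes_range: tuple[int, int] = (60, 140)
    tissue_color_low: tuple[int, int, int] = (160, 60, 150)
    tissue_color_high: tuple[int, int, int] = (230, 140, 220)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        a_min, a_max = self.blob_axes_range
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        if not 1 <= a_min <= a_max:
            raise ValueError("blob_axes_range must satisfy 1 <= min <= max")
        if self.n_blobs > 0 and (2 * a_max >= h or 2 * a_max >= w):
            raise ValueError("blob axes exceed image bounds")


def generate_slide_image(
    spec: SyntheticSlideSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (rgb uint8 image, bool ground-truth mask), deterministic in seed.

    Ellipse interiors use the strict inequality
    ((row-cy)/ry)^2 + ((col-cx)/rx)^2 < 1, and every blob lies fully inside
    the image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    mask = np.zeros((h, w), dtype=bool)
    lo = np.asarray(spec.tissue_color_low, dtype=float)
    hi = np.asarray(spec.tissue_color_high, dtype=float)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(spec.n_blobs):
        ry = int(rng.integers(spec.blob_axes_range[0], spec.blob_axes_range[1] + 1))
        rx = int(rng.integers(spec.blob_axes_range[0], spec.blob_axes_range[1] + 1))
        cy = int(rng.integers(ry + 1, h - ry - 1))
        cx = int(rng.integers(rx + 1, w - rx - 1))
        color = np.round(lo + rng.uniform(size=3) * (hi - lo)).astype(np.uint8)
        blob = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 < 1.0
        img[blob] = color
        mask |= blob
    return img, mask
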