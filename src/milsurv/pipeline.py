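"""End-to-end orchestration: synth -> (preprocess) -> train -> evaluate.

A run is fully determined by a :class:`RunConfig` (serializable to/from
YAML) and a single seed.  The global seed fans out to per-stage seeds by
hashing the stage name, so stages can be re-run independently with stable
randomness.  Every run writes a manifest recording the config, per-stage
timings, and a SHA-256 hash of every output file; re-running an identical
config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ClinicalRecord, read_bag, read_clinical
from .evaluate import km_estimate, logrank_test, median_split, td_auc
from .synthetic import SyntheticConfig, generate_cohort
from .train import TrainConfig, cross_validate

__all__ = ["RunConfig", "RunManifest", "filter_cohort", "run_pipeline",
           "derive_seed"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from (seed, stage name)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    run_synth: bool = True
    run_train: bool = True
    run_evaluate: bool = True
    # synth stage (None -> SyntheticConfig defaults)
    n_patients: int = 90
    feature_dim: int = 32
    censoring_rate: float = 1.0 / 3.0
    signal_strength: float = 3.0
    risk_coefficient: float = 1.5
    # train stage
    k_folds: int = 5
    epochs: int = 40
    alpha: float = 0.31
    learning_rate: float = 2e-4
    # evaluate stage
    horizons: tuple[float, ...] = (24.0, 36.0, 60.0)
    # inputs when synth is disabled
    bags_dir: str | None = None
    clinical_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "horizons" in raw:
            raw["horizons"] = tuple(raw["horizons"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # relative path -> sha256

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def filter_cohort(
    clinical_table: pd.DataFrame, available_bags: dict[str, list[str]]
) -> tuple[list[str], list[dict]]:
    """Apply the cohort inclusion criteria, row by row.

    The table may carry one row per slide (``patient_id`` plus optional
    ``slide_id`` and ``quality_ok`` columns).  Kept: patients with complete
    survival fields, a passing quality flag, and an available bag; when a
    patient has several slides, the lexicographically smallest slide id is
    retained.  Returns (included patient ids, exclusion log); the log has
    one entry per excluded row, so included + excluded == input rows.
    """
    df = clinical_table.reset_index(drop=True)
    exclusions: list[dict] = []
    kept_rows: dict[str, tuple[str, int]] = {}  # patient -> (slide_id, row)
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        slide = str(row.get("slide_id", pid))

        def exclude(reason: str) -> None:
            exclusions.append({"row": int(i), "patient_id": pid,
                               "slide_id": slide, "reason": reason})

        if pd.isna(row.get("os_months")) or pd.isna(row.get("censored")):
            exclude("missing_clinical")
            continue
        if "quality_ok" in df.columns and not bool(row["quality_ok"]):
            exclude("failed_quality")
            continue
        if pid not in available_bags or not available_bags[pid]:
            exclude("missing_bag")
            continue
        if pid in kept_rows:
            prev_slide, prev_row = kept_rows[pid]
            if slide < prev_slide:  # keep the lexicographically smallest id
                exclusions.append({
                    "row": prev_row, "patient_id": pid,
                    "slide_id": prev_slide, "reason": "duplicate_slide",
                })
                kept_rows[pid] = (slide, int(i))
            else:
                exclude("duplicate_slide")
            continue
        kept_rows[pid] = (slide, int(i))
    included = [pid for pid, _ in sorted(kept_rows.items(), key=lambda kv: kv[1][1])]
    if not included:
        raise ValueError("cohort filtering excluded every patient")
    assert len(included) + len(exclusions) == len(df)
    return included, exclusions


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config), version=__version__, seed=config.seed
    )

    def timed(stage):
        t0 = time.perf_counter()
        return lambda: manifest.stage_seconds.update(
            {stage: round(time.perf_counter() - t0, 3)}
        )

    # ---- synth ------------------------------------------------------------
    if config.run_synth:
        done = timed("synth")
        cohort = generate_cohort(SyntheticConfig(
            n_patients=config.n_patients,
            feature_dim=config.feature_dim,
            censoring_rate=config.censoring_rate,
            signal_strength=config.signal_strength,
            risk_coefficient=config.risk_coefficient,
            seed=derive_seed(config.seed, "synth"),
        ))
        cohort.to_dir(out)
        bags, clinical = cohort.bags, cohort.clinical
        done()
    else:
        if not (config.bags_dir and config.clinical_path):
            raise ValueError("synth disabled: bags_dir and clinical_path required")
        clinical = read_clinical(config.clinical_path)
        bag_paths = {p.stem: p for p in sorted(Path(config.bags_dir).glob("*.h5"))}
        clin_df = pd.DataFrame(
            [{"patient_id": r.patient_id, "os_months": r.os_months,
              "censored": r.censored} for r in clinical]
        )
        included, exclusions = filter_cohort(
            clin_df, {pid: [str(p)] for pid, p in bag_paths.items()}
        )
        with open(out / "exclusions.json", "w") as f:
            json.dump(exclusions, f, indent=2)
        clinical = [r for r in clinical if r.patient_id in set(included)]
        bags = [read_bag(bag_paths[r.patient_id]) for r in clinical]

    # ---- train ------------------------------------------------------------
    if config.run_train:
        done = timed("train")
        cv = cross_validate(bags, clinical, TrainConfig(
            k_folds=config.k_folds, epochs=config.epochs, alpha=config.alpha,
            learning_rate=config.learning_rate,
            seed=derive_seed(config.seed, "train"),
        ))
        risk_df = pd.DataFrame({
            "patient_id": [b.patient_id for b in bags],
            "risk_score": cv.oof_risks,
            "fold": cv.fold_of_patient,
        })
        risk_df.to_csv(out / "risk_scores.tsv", sep="\t", index=False)
        hist_rows = [
            {"fold": f.fold, **row} for f in cv.folds for row in f.history
        ]
        pd.DataFrame(hist_rows).to_csv(out / "history.csv", index=False)
        lo, hi = cv.cindex_range
        with open(out / "cv_metrics.json", "w") as f:
            json.dump({
                "fold_cindex": [f.cindex for f in cv.folds],
                "mean_cindex": cv.mean_cindex,
                "cindex_range": [lo, hi],
                "fold_sizes": [[f.n_train, f.n_test] for f in cv.folds],
            }, f, indent=2)
        risks = cv.oof_risks
        done()
    elif config.run_evaluate:
        risk_df = pd.read_csv(out / "risk_scores.tsv", sep="\t")
        order = {r.patient_id: i for i, r in enumerate(clinical)}
        risk_df = risk_df.sort_values(
            "patient_id", key=lambda s: s.map(order)
        )
        risks = risk_df["risk_score"].to_numpy()

    # ---- evaluate ---------------------------------------------------------
    if config.run_evaluate:
        done = timed("evaluate")
        times = np.array([r.os_months for r in clinical])
        cens = np.array([r.censored for r in clinical])
        groups = median_split(risks)
        hi_mask = groups == "high"
        lr = logrank_test(times[hi_mask], cens[hi_mask],
                          times[~hi_mask], cens[~hi_mask])
        km_rows = []
        for name, m in (("high", hi_mask), ("low", ~hi_mask)):
            curve = km_estimate(times[m], cens[m])
            for t, s, n, d in zip(curve.event_times, curve.survival,
                                  curve.at_risk, curve.events):
                km_rows.append({"group": name, "time": t, "survival": s,
                                "at_risk": n, "events": d})
        pd.DataFrame(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        aucs = {}
        for hz in config.horizons:
            try:
                aucs[f"auc_{hz:g}m"] = td_auc(times, cens, risks, hz)
            except ValueError:
                aucs[f"auc_{hz:g}m"] = None
        with open(out / "evaluation.json", "w") as f:
            json.dump({
                "logrank_statistic": lr.statistic,
                "logrank_p": lr.p_value,
                "n_high": int(hi_mask.sum()),
                "n_low": int((~hi_mask).sum()),
                **aucs,
            }, f, indent=2)
        done()

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.files[str(path.relative_to(out))] = _sha256(path)
    manifest.save(out / "manifest.json")
    return manifest
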