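"""Core data containers and on-disk formats.

Per-patient patch features travel as HDF5 containers with two datasets:
``features`` (M x d float32) and ``coords`` (M x 2 int64, 0-based top-left
corners, x = column, y = row, half-open patch extents).  The clinical table
is a TSV with columns ``patient_id, os_months, censored, age, stage, grade,
residual, tai, lst, loh``; ``censored`` follows the loss convention
(1 = right-censored, 0 = event observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PatchBag",
    "ClinicalRecord",
    "write_bag",
    "read_bag",
    "write_clinical",
    "read_clinical",
    "CLINICAL_COLUMNS",
]

CLINICAL_COLUMNS = [
    "patient_id", "os_months", "censored", "age", "stage", "grade",
    "residual", "tai", "lst", "loh",
]


@dataclass
class PatchBag:
    """All retained patches of one slide: features aligned row-wise to coords."""

    patient_id: str
    features: np.ndarray  # (M, d)
    coords: np.ndarray    # (M, 2) int, (x, y) top-left corners
    encoder_id: str = "unknown"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty M x d matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must be M x 2, aligned with features")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class ClinicalRecord:
    """Survival outcome and covariates for one patient.

    ``censored`` is 1 when follow-up ended without the event (right
    censoring) and 0 when death was observed.  ``y`` is the discrete
    interval label, filled in once an interval scheme is applied.
    """

    patient_id: str
    os_months: float
    censored: int
    age: float = float("nan")
    stage: str = ""
    grade: str = ""
    residual: str = ""
    tai: float | None = None
    lst: float | None = None
    loh: float | None = None
    y: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.censored not in (0, 1):
            raise ValueError(f"censored must be 0 or 1, got {self.censored}")
        if not self.os_months >= 0:
            raise ValueError(f"os_months must be >= 0, got {self.os_months}")


def write_bag(path: str | Path, bag: PatchBag) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int64))
        f.attrs["patient_id"] = bag.patient_id
        f.attrs["encoder_id"] = bag.encoder_id
        f.attrs["coord_convention"] = "0-based, x=column, y=row, half-open"


def read_bag(path: str | Path) -> PatchBag:
    with h5py.File(path, "r") as f:
        return PatchBag(
            patient_id=str(f.attrs.get("patient_id", Path(path).stem)),
            features=f["features"][()],
            coords=f["coords"][()],
            encoder_id=str(f.attrs.get("encoder_id", "unknown")),
        )


def write_clinical(path: str | Path, records: list[ClinicalRecord]) -> None:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "os_months": r.os_months,
            "censored": r.censored,
            "age": r.age,
            "stage": r.stage,
            "grade": r.grade,
            "residual": r.residual,
            "tai": r.tai,
            "lst": r.lst,
            "loh": r.loh,
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(ClinicalRecord(
            patient_id=str(row.patient_id),
            os_months=float(row.os_months),
            censored=int(row.censored),
            age=float(getattr(row, "age", float("nan"))),
            stage=str(getattr(row, "stage", "")),
            grade=str(getattr(row, "grade", "")),
            residual=str(getattr(row, "residual", "")),
            tai=_opt_float(getattr(row, "tai", None)),
            lst=_opt_float(getattr(row, "lst", None)),
            loh=_opt_float(getattr(row, "loh", None)),
        ))
    return records


def _opt_float(v) -> float | None:
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v
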