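"""Patient-metadata table of the 37-patient chronic stroke cohort.

The packaged fixture (``data/stroke_cohort.tsv``) holds the published
per-patient metadata of the clinical cohort the synthetic study population
is modeled on: intervention group (``Exp`` = contingent positive feedback,
``Sham`` = random feedback, ``C-`` = contingent negative feedback), gender,
age, interval since stroke, lesioned hemisphere, and the combined Fugl-Meyer
assessment (cFMA, hand + arm motor scores, 0-54 points, 54 = normal
function).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("Exp", "Sham", "C-")
CFMA_MAX = 54.0

_COLUMNS = {
    "patient": int,
    "group": str,
    "gender": str,
    "age_years": float,
    "months_since_stroke": float,
    "lesion_side": str,
    "cfma": float,
}


@dataclass(frozen=True)
class PatientRecord:
    id: int
    group: str
    gender: str
    age: float
    months_since_stroke: float
    lesion_side: str
    cfma: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if self.lesion_side not in ("L", "R"):
            raise ValueError(f"lesion_side must be 'L' or 'R', got {self.lesion_side!r}")
        if not 0.0 <= self.cfma <= CFMA_MAX:
            raise ValueError(f"cfma must be in [0, {CFMA_MAX}], got {self.cfma}")
        if self.age <= 0 or self.months_since_stroke <= 0:
            raise ValueError("age and months_since_stroke must be > 0")


def default_cohort_path() -> Path:
    """Path of the packaged cohort table."""
    return Path(importlib.resources.files("smrdecode") / "data" / "stroke_cohort.tsv")


def load_cohort_table(path: str | Path | None = None) -> list[PatientRecord]:
    """Read a tab-separated cohort table into validated records.

    Raises ``ValueError`` on an empty file, missing columns, or rows that
    fail validation (e.g. cFMA outside [0, 54]).
    """
    path = default_cohort_path() if path is None else Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"cohort table {path} is empty") from None
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"cohort table {path} has no rows")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    id=int(row["patient"]),
                    group=str(row["group"]),
                    gender=str(row["gender"]),
                    age=float(row["age_years"]),
                    months_since_stroke=float(row["months_since_stroke"]),
                    lesion_side=str(row["lesion_side"]),
                    cfma=float(row["cfma"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed cohort row {i + 1}: {exc}") from exc
    return records


def summarize_cohort(records: list[PatientRecord]) -> dict:
    """Cohort summary: mean ± sample SD of the numeric columns plus counts.

    SDs use the n-1 convention; for a single record the SD is reported as
    0.0.  Means/SDs are returned unrounded.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")

    def _stats(vals: list[float]) -> tuple[float, float]:
        a = np.asarray(vals, dtype=float)
        sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        return float(a.mean()), sd

    age = _stats([r.age for r in records])
    months = _stats([r.months_since_stroke for r in records])
    cfma = _stats([r.cfma for r in records])
    return {
        "n": len(records),
        "age_mean": age[0], "age_sd": age[1],
        "months_mean": months[0], "months_sd": months[1],
        "cfma_mean": cfma[0], "cfma_sd": cfma[1],
        "gender_counts": {g: sum(r.gender == g for r in records) for g in ("M", "F")},
        "lesion_counts": {s: sum(r.lesion_side == s for r in records) for s in ("R", "L")},
        "group_counts": {g: sum(r.group == g for r in records) for g in GROUPS},
    }
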