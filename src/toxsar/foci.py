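"""Classification of marker-positive nuclei from feature tables.

Two marker conventions:

* ``gh2ax`` — a nucleus is positive when its mean staining intensity
  reaches the threshold (DNA double-strand-break marker).
* ``ph3`` — positive when the intensity reaches the threshold *and* the
  nucleus area falls inside a window (mitosis marker; the area window
  excludes debris and aggregates).

Guideline minimum nucleus counts (2000 for gh2ax, 5000 for ph3) set a
``low_count`` flag without suppressing output.  The packaged default
thresholds are calibrated against the synthetic generator (threshold at
roughly the 99th percentile of its background intensity population);
they are stand-ins, not instrument constants, and should be overridden
for real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassifierConfig", "ClassificationResult", "classify", "condition_summary"]

MIN_NUCLEI = {"gh2ax": 2000, "ph3": 5000}

NUCLEUS_COLUMNS = ["nucleus_id", "condition", "replicate", "mean_intensity", "area"]


@dataclass(frozen=True)
class ClassifierConfig:
    marker: str  # "gh2ax" | "ph3"
    intensity_threshold: float
    area_min: float | None = None
    area_max: float | None = None
    min_nuclei: int | None = None

    def __post_init__(self):
        if self.marker not in MIN_NUCLEI:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.marker == "ph3":
            if self.area_min is None or self.area_max is None:
                raise ValueError("ph3 classification requires an area window")
            if not self.area_min < self.area_max:
                raise ValueError("area_min must be below area_max")

    @property
    def required_nuclei(self) -> int:
        return self.min_nuclei if self.min_nuclei is not None else MIN_NUCLEI[self.marker]


@dataclass(frozen=True)
class ClassificationResult:
    positive: np.ndarray  # per-nucleus boolean, input order
    proportion: float
    n_nuclei: int
    low_count: bool


def classify(nuclei: pd.DataFrame, cfg: ClassifierConfig) -> ClassificationResult:
    """Classify each nucleus and report the positive proportion."""
    if len(nuclei) == 0:
        raise ValueError("empty nucleus table")
    intensity = nuclei["mean_intensity"].to_numpy(dtype=float)
    positive = intensity >= cfg.intensity_threshold
    if cfg.marker == "ph3":
        area = nuclei["area"].to_numpy(dtype=float)
        positive &= (area >= cfg.area_min) & (area <= cfg.area_max)
    n = len(nuclei)
    return ClassificationResult(
        positive=positive,
        proportion=float(positive.mean()),
        n_nuclei=n,
        low_count=n < cfg.required_nuclei,
    )


def condition_summary(nuclei: pd.DataFrame, cfg: ClassifierConfig) -> pd.DataFrame:
    """Replicate-level positive proportions aggregated per condition.

    ``nuclei`` is a tidy feature table (columns ``nucleus_id``,
    ``condition``, ``replicate``, ``mean_intensity``, ``area``).  Each
    replicate yields one proportion; conditions report mean ± sd over
    replicates and a ``low_count`` flag if any replicate fell below the
    marker's minimum nucleus count.
    """
    missing = [c for c in NUCLEUS_COLUMNS if c not in nuclei.columns]
    if missing:
        raise ValueError(f"nucleus table lacks columns: {', '.join(missing)}")
    if len(nuclei) == 0:
        raise ValueError("empty nucleus table")

    rows = []
    for (condition, replicate), group in nuclei.groupby(
        ["condition", "replicate"], sort=False
    ):
        res = classify(group, cfg)
        rows.append(
            {
                "condition": condition,
                "replicate": replicate,
                "proportion": res.proportion,
                "n_nuclei": res.n_nuclei,
                "low_count": res.low_count,
            }
        )
    per_rep = pd.DataFrame(rows)
    out = (
        per_rep.groupby("condition", sort=False)
        .agg(
            mean=("proportion", "mean"),
            sd=("proportion", "std"),
            n_replicates=("proportion", "count"),
            n_nuclei=("n_nuclei", "sum"),
            low_count=("low_count", "any"),
        )
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
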