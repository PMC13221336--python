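"""Plate-reader normalization for LDH cytotoxicity and WST-1 viability.

Input wells carry a measurement- and a reference-wavelength absorbance;
the corrected signal is always ``a_meas - a_ref``.  Technical replicate
reads are averaged per sample first, then each biological replicate is
normalized against its own vehicle and positive controls:

* cytotoxicity % = (treatment - vehicle) / (positive - vehicle) * 100
* viability %    = 100 - (vehicle - treatment) / (vehicle - positive) * 100

Percentages are deliberately not clamped to [0, 100]; a treatment
healthier than the vehicle legitimately reports viability above 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CytotoxResult",
    "percent_cytotoxicity",
    "percent_viability",
    "aggregate",
]

VEHICLE = "vehicle"
POSITIVE = "positive"

WELL_COLUMNS = ["condition", "replicate", "read_index", "a_meas", "a_ref"]


class DegenerateControlError(ValueError):
    """Vehicle and positive control signals coincide; normalization undefined."""


@dataclass(frozen=True)
class CytotoxResult:
    condition: str
    endpoint: str  # "ldh_cytotoxicity_pct" | "wst_viability_pct"
    mean: float
    sd: float
    n: int
    single_replicate: bool = False


def percent_cytotoxicity(treatment: float, vehicle: float, positive: float) -> float:
    """Percent cytotoxicity of a background-corrected signal."""
    if positive == vehicle:
        raise DegenerateControlError("positive control equals vehicle control")
    return (treatment - vehicle) / (positive - vehicle) * 100.0


def percent_viability(treatment: float, vehicle: float, positive: float) -> float:
    """Percent viability of a background-corrected signal."""
    if vehicle == positive:
        raise DegenerateControlError("vehicle control equals positive control")
    return 100.0 - (vehicle - treatment) / (vehicle - positive) * 100.0


def _corrected_means(wells: pd.DataFrame) -> pd.DataFrame:
    """Average technical reads into one corrected signal per (condition, replicate)."""
    df = wells.copy()
    df["signal"] = df["a_meas"].astype(float) - df["a_ref"].astype(float)
    return (
        df.groupby(["condition", "replicate"], sort=False)["signal"]
        .mean()
        .reset_index()
    )


def aggregate(wells: pd.DataFrame, endpoint: str) -> list[CytotoxResult]:
    """Normalize a well table and aggregate over biological replicates.

    ``endpoint`` is ``"ldh_cytotoxicity_pct"`` or ``"wst_viability_pct"``.
    Each replicate is normalized against its replicate-matched vehicle
    and positive controls; per condition the replicate percentages are
    reduced to mean ± sd.  A single-replicate condition reports sd 0 and
    a ``single_replicate`` flag.
    """
    if endpoint not in ("ldh_cytotoxicity_pct", "wst_viability_pct"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table lacks columns: {', '.join(missing)}")

    signals = _corrected_means(wells)
    conditions = signals["condition"].unique().tolist()
    for control in (VEHICLE, POSITIVE):
        if control not in conditions:
            raise ValueError(f"missing {control!r} condition")

    normalize = (
        percent_cytotoxicity
        if endpoint == "ldh_cytotoxicity_pct"
        else percent_viability
    )
    wide = signals.pivot(index="replicate", columns="condition", values="signal")

    results = []
    for condition in conditions:
        pcts = []
        for _, row in wide.iterrows():
            t, v, p = row[condition], row[VEHICLE], row[POSITIVE]
            if np.isnan(t):
                continue  # condition absent in this replicate
            if np.isnan(v) or np.isnan(p):
                raise ValueError(
                    f"replicate {_!r} lacks a matched vehicle/positive control"
                )
            pcts.append(normalize(t, v, p))
        arr = np.asarray(pcts)
        results.append(
            CytotoxResult(
                condition=condition,
                endpoint=endpoint,
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                n=int(arr.size),
                single_replicate=arr.size == 1,
            )
        )
    return results


def results_table(results: list[CytotoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "endpoint": r.endpoint,
                "mean": r.mean,
                "sd": r.sd,
                "n": r.n,
                "single_replicate": r.single_replicate,
            }
            for r in results
        ]
    )
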