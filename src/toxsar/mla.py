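"""Mouse lymphoma assay (microwell method) calculation chain.

From raw cell counts and 96-well plate counts the chain computes, per
treatment arm:

* suspension growth ``SG = (count_day1/setup_day0) * (count_day2/setup_day1)``
  and its ratio to the vehicle control (RSG),
* cloning efficiencies from empty-well fractions via the Poisson
  zero-class estimator ``CE = -ln(empty/total) / cells_per_well``,
* relative cloning efficiency (RCE) and relative total growth
  ``RTG = RSG * RCE * 100``,
* mutation frequency ``MF = CE_tft / CE_survivor2`` with a small/large
  colony split, and
* the Global Evaluation Factor relevance call: an MF increase over the
  vehicle control beyond 126e-6 is biologically relevant.

Survivor plates are seeded at 1.6 cells per well; TFT selection plates
at nominally 2000 cells per well (1e4 cells/mL x 200 uL).  Both seeding
densities are configurable because the selection-plate density is the
one genuinely protocol-dependent number in the chain.

Plates of one role are pooled into a single wells_total/wells_empty
pair before estimating CE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GEF",
    "MlaCulture",
    "PlateCount",
    "TftPlateCount",
    "MlaResult",
    "ValidityCriterion",
    "ValidityReport",
    "suspension_growth",
    "relative_suspension_growth",
    "cloning_efficiency",
    "mutation_frequency",
    "relative_total_growth",
    "gef_call",
    "analyze",
    "validity_report",
]

#: Global Evaluation Factor (absolute mutation-frequency increase).
GEF = 126e-6

#: Default seeding densities (expected cells per well).
SURVIVOR_CELLS_PER_WELL = 1.6
TFT_CELLS_PER_WELL = 2000.0


@dataclass(frozen=True)
class MlaCulture:
    condition: str
    setup_day0: float
    count_day1: float
    setup_day1: float
    count_day2: float
    setup_day2: float


@dataclass(frozen=True)
class PlateCount:
    plate_role: str  # "survivor1" | "survivor2" | "tft"
    wells_total: int
    wells_empty: int
    cells_per_well: float

    def __post_init__(self):
        if not 0 <= self.wells_empty <= self.wells_total:
            raise ValueError("wells_empty must lie in [0, wells_total]")
        if self.cells_per_well <= 0:
            raise ValueError("cells_per_well must be positive")


@dataclass(frozen=True)
class TftPlateCount(PlateCount):
    wells_small: int = 0
    wells_large: int = 0


@dataclass(frozen=True)
class MlaResult:
    condition: str
    sg: float | None = None
    rsg: float | None = None
    ce_s1: float | None = None
    ce_s2: float | None = None
    ce_tft: float | None = None
    rce: float | None = None
    rtg: float | None = None
    mf: float | None = None
    mf_small: float | None = None
    mf_large: float | None = None
    relevant: bool | None = None
    ce_lower_bound: bool = False


def suspension_growth(culture: MlaCulture) -> float:
    """Two-day suspension growth factor."""
    if culture.setup_day0 <= 0 or culture.setup_day1 <= 0:
        raise ValueError(f"{culture.condition}: non-positive setup count")
    return (culture.count_day1 / culture.setup_day0) * (
        culture.count_day2 / culture.setup_day1
    )


def relative_suspension_growth(sg_treatment: float, sg_control: float) -> float:
    if sg_control <= 0:
        raise ValueError("control suspension growth must be positive")
    return sg_treatment / sg_control


def cloning_efficiency(plate: PlateCount) -> float:
    """Poisson zero-class cloning efficiency per seeded cell.

    With every well positive the estimator diverges; a flagged lower
    bound of ``-ln(0.5/wells_total)/cells_per_well`` is returned
    instead (accompanied by a warning).
    """
    if plate.wells_empty == 0:
        warnings.warn(
            f"{plate.plate_role}: no empty wells; reporting a lower-bound CE",
            stacklevel=2,
        )
        frac = 0.5 / plate.wells_total
    else:
        frac = plate.wells_empty / plate.wells_total
    return -math.log(frac) / plate.cells_per_well


def mutation_frequency(
    tft: TftPlateCount, survivor2: PlateCount
) -> tuple[float, float, float]:
    """Mutation frequency plus small- and large-colony components.

    The component frequencies treat wells lacking small (respectively
    large) colonies as empty when estimating the selection-plate CE.
    """
    ce_s2 = cloning_efficiency(survivor2)
    if ce_s2 <= 0:
        raise ValueError("survivor-2 cloning efficiency is zero")
    mf = cloning_efficiency(tft) / ce_s2 if tft.wells_empty < tft.wells_total else 0.0
    if tft.wells_empty == tft.wells_total:  # no mutant wells at all
        return 0.0, 0.0, 0.0

    def component(wells_positive: int) -> float:
        empty = tft.wells_total - wells_positive
        if empty == 0:
            ce = cloning_efficiency(
                TftPlateCount(
                    plate_role=tft.plate_role,
                    wells_total=tft.wells_total,
                    wells_empty=0,
                    cells_per_well=tft.cells_per_well,
                )
            )
        elif wells_positive == 0:
            return 0.0
        else:
            ce = -math.log(empty / tft.wells_total) / tft.cells_per_well
        return ce / ce_s2

    return mf, component(tft.wells_small), component(tft.wells_large)


def relative_total_growth(rsg: float, rce: float) -> float:
    """RTG percent = RSG x RCE x 100."""
    if rsg < 0 or rce < 0:
        raise ValueError("RSG and RCE must be non-negative")
    return rsg * rce * 100.0


def gef_call(mf_treatment: float, mf_vehicle: float) -> bool:
    """Biological-relevance call; strict inequality, boundary is negative."""
    if mf_treatment < 0 or mf_vehicle < 0:
        raise ValueError("mutation frequencies must be non-negative")
    return mf_treatment > mf_vehicle + GEF


# --- full-table analysis ---------------------------------------------------

INPUT_COLUMNS = [
    "condition",
    "setup_day0",
    "count_day1",
    "setup_day1",
    "count_day2",
    "setup_day2",
    "s1_total",
    "s1_empty",
    "s2_total",
    "s2_empty",
    "tft_total",
    "tft_empty",
    "tft_small",
    "tft_large",
]


def analyze(
    experiments: pd.DataFrame,
    vehicle: str = "vehicle",
    survivor_cells_per_well: float = SURVIVOR_CELLS_PER_WELL,
    tft_cells_per_well: float = TFT_CELLS_PER_WELL,
) -> dict[str, MlaResult]:
    """Run the full calculation chain on a one-row-per-condition table."""
    missing = [c for c in INPUT_COLUMNS if c not in experiments.columns]
    if missing:
        raise ValueError(f"experiment table lacks columns: {', '.join(missing)}")
    if vehicle not in set(experiments["condition"]):
        raise ValueError(f"missing vehicle condition {vehicle!r}")

    raw: dict[str, dict] = {}
    for _, row in experiments.iterrows():
        cond = str(row["condition"])
        culture = MlaCulture(
            condition=cond,
            setup_day0=float(row["setup_day0"]),
            count_day1=float(row["count_day1"]),
            setup_day1=float(row["setup_day1"]),
            count_day2=float(row["count_day2"]),
            setup_day2=float(row["setup_day2"]),
        )
        s1 = PlateCount(
            "survivor1", int(row["s1_total"]), int(row["s1_empty"]),
            survivor_cells_per_well,
        )
        s2 = PlateCount(
            "survivor2", int(row["s2_total"]), int(row["s2_empty"]),
            survivor_cells_per_well,
        )
        tft = TftPlateCount(
            "tft", int(row["tft_total"]), int(row["tft_empty"]),
            tft_cells_per_well,
            wells_small=int(row["tft_small"]), wells_large=int(row["tft_large"]),
        )
        raw[cond] = {"culture": culture, "s1": s1, "s2": s2, "tft": tft}

    sg_vehicle = suspension_growth(raw[vehicle]["culture"])
    ce_s2_vehicle = cloning_efficiency(raw[vehicle]["s2"])
    mf_vehicle = mutation_frequency(raw[vehicle]["tft"], raw[vehicle]["s2"])[0]

    results: dict[str, MlaResult] = {}
    for cond, parts in raw.items():
        sg = suspension_growth(parts["culture"])
        rsg = relative_suspension_growth(sg, sg_vehicle)
        ce_s1 = cloning_efficiency(parts["s1"])
        ce_s2 = cloning_efficiency(parts["s2"])
        lower_bound = parts["s2"].wells_empty == 0 or parts["s1"].wells_empty == 0
        rce = ce_s2 / ce_s2_vehicle
        mf, mf_small, mf_large = mutation_frequency(parts["tft"], parts["s2"])
        results[cond] = MlaResult(
            condition=cond,
            sg=sg,
            rsg=rsg,
            ce_s1=ce_s1,
            ce_s2=ce_s2,
            ce_tft=mf * ce_s2,
            rce=rce,
            rtg=relative_total_growth(rsg, rce),
            mf=mf,
            mf_small=mf_small,
            mf_large=mf_large,
            relevant=gef_call(mf, mf_vehicle),
            ce_lower_bound=lower_bound,
        )
    return results


def results_table(results: dict[str, MlaResult]) -> pd.DataFrame:
    """Report table with MF columns on the conventional x1e-6 scale."""
    rows = []
    for r in results.values():
        rows.append(
            {
                "condition": r.condition,
                "mf_e6": None if r.mf is None else r.mf * 1e6,
                "relevant": r.relevant,
                "mf_small_e6": None if r.mf_small is None else r.mf_small * 1e6,
                "mf_large_e6": None if r.mf_large is None else r.mf_large * 1e6,
                "rtg_pct": r.rtg,
                "sg": r.sg,
                "ce_s2_pct": None if r.ce_s2 is None else r.ce_s2 * 100.0,
            }
        )
    return pd.DataFrame(rows)


# --- validity criteria -----------------------------------------------------


@dataclass(frozen=True)
class ValidityCriterion:
    name: str
    observed: float | None
    acceptable_range: tuple[float | None, float | None]
    passed: bool


@dataclass(frozen=True)
class ValidityReport:
    criteria: list[ValidityCriterion] = field(default_factory=list)
    note: str = ""

    @property
    def overall(self) -> bool:
        if self.note:
            return True  # explicit override recorded in the note
        return all(c.passed for c in self.criteria)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "criterion": c.name,
                    "observed": c.observed,
                    "lo": c.acceptable_range[0],
                    "hi": c.acceptable_range[1],
                    "pass": c.passed,
                }
                for c in self.criteria
            ]
        )


def _in_range(value, lo, hi):
    if value is None:
        return False
    return (lo is None or value >= lo) and (hi is None or value <= hi)


def validity_report(
    results: dict[str, MlaResult],
    vehicle: str,
    positive: str,
    top_dose: str,
    note: str = "",
) -> ValidityReport:
    """Check the guideline acceptability criteria of the assay run.

    Requires the vehicle control, the positive control and at least one
    treatment arm (the top tested concentration) to be present.
    """
    for label in (vehicle, positive, top_dose):
        if label not in results:
            raise ValueError(f"missing condition {label!r}")
    if len(results) < 3:
        raise ValueError("need vehicle, positive control and a treatment arm")
    veh, pos, top = results[vehicle], results[positive], results[top_dose]

    criteria = [
        ValidityCriterion(
            "vehicle MF in [50, 170] x1e-6",
            None if veh.mf is None else veh.mf * 1e6,
            (50.0, 170.0),
            _in_range(None if veh.mf is None else veh.mf * 1e6, 50.0, 170.0),
        ),
    ]

    if pos.mf is None or veh.mf is None:
        mf_increase = None
        small_ok = False
    else:
        mf_increase = (pos.mf - veh.mf) * 1e6
        small_e6 = None if pos.mf_small is None else pos.mf_small * 1e6
        small_frac = (
            None
            if (pos.mf_small is None or pos.mf in (None, 0))
            else pos.mf_small / pos.mf
        )
        small_ok = (small_e6 is not None and small_e6 >= 150.0) or (
            small_frac is not None and small_frac >= 0.40
        )
    criteria.append(
        ValidityCriterion(
            "positive MF exceeds vehicle by >= 300 x1e-6",
            mf_increase,
            (300.0, None),
            _in_range(mf_increase, 300.0, None),
        )
    )
    criteria.append(
        ValidityCriterion(
            "positive small-colony MF >= 150 x1e-6 or >= 40% small",
            None if pos.mf_small is None else pos.mf_small * 1e6,
            (None, None),
            small_ok,
        )
    )
    criteria.append(
        ValidityCriterion(
            "positive RTG > 10%",
            pos.rtg,
            (10.0, None),
            pos.rtg is not None and pos.rtg > 10.0,
        )
    )
    criteria.append(
        ValidityCriterion(
            "top-dose RTG in [10, 30]%",
            top.rtg,
            (10.0, 30.0),
            _in_range(top.rtg, 10.0, 30.0),
        )
    )
    criteria.append(
        ValidityCriterion(
            "vehicle SG in [8, 32]",
            veh.sg,
            (8.0, 32.0),
            _in_range(veh.sg, 8.0, 32.0),
        )
    )
    criteria.append(
        ValidityCriterion(
            "vehicle CE in [65, 120]%",
            None if veh.ce_s2 is None else veh.ce_s2 * 100.0,
            (65.0, 120.0),
            _in_range(None if veh.ce_s2 is None else veh.ce_s2 * 100.0, 65.0, 120.0),
        )
    )
    return ValidityReport(criteria=criteria, note=note)
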