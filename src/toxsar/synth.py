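"""Seeded synthetic-data generators for every assay input format.

Each generator draws all randomness from one ``numpy`` generator seeded
per call, so identical parameters and seed reproduce identical tables.
Generators return ``(table, truth)`` where ``table`` matches the CSV
schema its paired analysis module reads and ``truth`` records the
ground-truth parameters for recovery tests.

Distributional assumptions
--------------------------
* Plate absorbance: additive Gaussian noise on the corrected signal.
* Comet tail intensity: a two-component mixture — a low-damage
  background population and a damaged responder population — each a
  normal truncated to [0, 100].  Responder fractions below one half
  make the per-slide distribution bimodal with the background mode in
  the majority.
* Microwell plates: a well is empty when no seeded cell founds a
  colony; founders per well are Poisson, so
  ``P(empty survivor well) = exp(-cells_per_well * CE)`` and
  ``P(empty selection well) = exp(-cells_per_well * MF * CE)``.
* Nucleus features: two log-normal-area populations with normal
  intensity distributions, plus an optional saturating pan-stain
  subpopulation that defeats intensity-only classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["gen_plate", "gen_comet", "gen_mla", "gen_foci"]


def gen_plate(
    seed: int,
    treatments: dict[str, float],
    noise_sd: float = 0.02,
    vehicle_signal: float = 0.20,
    positive_signal: float = 0.90,
    a_ref: float = 0.05,
    n_biological: int = 3,
    n_technical: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Absorbance wells for vehicle, positive and treatment conditions.

    ``treatments`` maps condition labels to true cytotoxicity percent;
    the true corrected treatment signal interpolates between the
    vehicle (0%) and positive (100%) signals.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if positive_signal == vehicle_signal:
        raise ValueError("degenerate controls: positive equals vehicle signal")
    rng = np.random.default_rng(seed)
    span = positive_signal - vehicle_signal
    true_signals = {"vehicle": vehicle_signal, "positive": positive_signal}
    for label, pct in treatments.items():
        true_signals[label] = vehicle_signal + span * pct / 100.0

    rows = []
    for condition, mu in true_signals.items():
        for rep in range(1, n_biological + 1):
            for read in range(1, n_technical + 1):
                corrected = mu + rng.normal(0.0, noise_sd) if noise_sd else mu
                rows.append(
                    {
                        "condition": condition,
                        "replicate": rep,
                        "read_index": read,
                        "a_meas": corrected + a_ref,
                        "a_ref": a_ref,
                    }
                )
    truth = {
        "treatments": dict(treatments),
        "noise_sd": noise_sd,
        "vehicle_signal": vehicle_signal,
        "positive_signal": positive_signal,
    }
    return pd.DataFrame(rows), truth


def _truncated_normal(rng, mean, sd, size, lo=0.0, hi=100.0):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_comet(
    seed: int,
    conditions: dict[str, float],
    background_mean: float = 1.0,
    background_sd: float = 0.5,
    damaged_mean: float = 60.0,
    damaged_sd: float = 10.0,
    n_slides: int = 3,
    n_nuclei: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Per-nucleus TI tables; ``conditions`` maps labels to responder fractions."""
    for label, p in conditions.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{label}: responder fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, p in conditions.items():
        for rep in range(1, n_slides + 1):
            damaged = rng.random(n_nuclei) < p
            ti = np.where(
                damaged,
                _truncated_normal(rng, damaged_mean, damaged_sd, n_nuclei),
                _truncated_normal(rng, background_mean, background_sd, n_nuclei),
            )
            slide = f"{condition}-s{rep}"
            for value in ti:
                rows.append(
                    {
                        "slide_id": slide,
                        "condition": condition,
                        "replicate": rep,
                        "ti": float(value),
                    }
                )
    truth = {
        "conditions": dict(conditions),
        "background_mean": background_mean,
        "background_sd": background_sd,
        "damaged_mean": damaged_mean,
        "damaged_sd": damaged_sd,
    }
    return pd.DataFrame(rows), truth


def gen_mla(
    seed: int,
    conditions: dict[str, dict],
    vehicle: str = "vehicle",
    wells_per_plate: int = 96,
    survivor_plates: int = 2,
    tft_plates: int = 4,
    survivor_cells_per_well: float = 1.6,
    tft_cells_per_well: float = 2000.0,
    setup_day0: float = 2e5,
    small_colony_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """One experiment table row per condition.

    ``conditions`` maps labels to ``{"ce": ..., "mf": ..., "sg": ...}``
    ground truth (cloning efficiency in (0, 1], mutation frequency >= 0,
    two-day suspension growth).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for condition, params in conditions.items():
        ce, mf, sg = params["ce"], params["mf"], params.get("sg", 16.0)
        if not 0.0 < ce <= 1.0:
            raise ValueError(f"{condition}: CE must lie in (0, 1]")
        if mf < 0:
            raise ValueError(f"{condition}: MF must be non-negative")

        daily = np.sqrt(sg)
        count_day1 = setup_day0 * daily
        setup_day1 = setup_day0
        count_day2 = setup_day1 * daily

        n_survivor = wells_per_plate * survivor_plates
        p_empty_survivor = np.exp(-survivor_cells_per_well * ce)
        s1_empty = int(rng.binomial(n_survivor, p_empty_survivor))
        s2_empty = int(rng.binomial(n_survivor, p_empty_survivor))

        n_tft = wells_per_plate * tft_plates
        rate = tft_cells_per_well * mf * ce
        founders = rng.poisson(rate, n_tft)
        small_founders = rng.binomial(founders, small_colony_fraction)
        large_founders = founders - small_founders
        tft_empty = int(np.sum(founders == 0))
        tft_small = int(np.sum(small_founders > 0))
        tft_large = int(np.sum(large_founders > 0))

        rows.append(
            {
                "condition": condition,
                "setup_day0": setup_day0,
                "count_day1": count_day1,
                "setup_day1": setup_day1,
                "count_day2": count_day2,
                "setup_day2": 1e4,
                "s1_total": n_survivor,
                "s1_empty": s1_empty,
                "s2_total": n_survivor,
                "s2_empty": s2_empty,
                "tft_total": n_tft,
                "tft_empty": tft_empty,
                "tft_small": tft_small,
                "tft_large": tft_large,
            }
        )
    truth = {
        "conditions": {k: dict(v) for k, v in conditions.items()},
        "vehicle": vehicle,
        "small_colony_fraction": small_colony_fraction,
        "survivor_cells_per_well": survivor_cells_per_well,
        "tft_cells_per_well": tft_cells_per_well,
    }
    return pd.DataFrame(rows), truth


def gen_foci(
    seed: int,
    conditions: dict[str, float],
    n_nuclei: int = 2000,
    n_replicates: int = 3,
    background_intensity: tuple[float, float] = (10.0, 3.0),
    positive_intensity: tuple[float, float] = (40.0, 5.0),
    area_lognorm: tuple[float, float] = (4.5, 0.3),
    pan_stain_fraction: float = 0.0,
    pan_stain_intensity: float = 255.0,
    pan_stain_area_factor: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Nucleus feature tables with ground-truth labels.

    ``conditions`` maps labels to true positive fractions.  An optional
    pan-stain subpopulation has saturating intensity and oversized area;
    it inflates intensity-only positive calls, which is exactly the
    artifact an area window guards against.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for condition, p in conditions.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{condition}: positive fraction outside [0, 1]")
        for rep in range(1, n_replicates + 1):
            u = rng.random(n_nuclei)
            pan = u < pan_stain_fraction
            positive = ~pan & (u < pan_stain_fraction + p * (1 - pan_stain_fraction))
            intensity = rng.normal(*background_intensity, n_nuclei)
            intensity[positive] = rng.normal(*positive_intensity, positive.sum())
            intensity[pan] = pan_stain_intensity
            intensity = np.clip(intensity, 0.0, None)
            area = rng.lognormal(*area_lognorm, n_nuclei)
            area[pan] *= pan_stain_area_factor
            for i in range(n_nuclei):
                rows.append(
                    {
                        "nucleus_id": f"{condition}-r{rep}-n{i}",
                        "condition": condition,
                        "replicate": rep,
                        "mean_intensity": float(intensity[i]),
                        "area": float(area[i]),
                        "true_label": (
                            "pan" if pan[i] else ("positive" if positive[i] else "background")
                        ),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "conditions": dict(conditions),
        "background_intensity": background_intensity,
        "positive_intensity": positive_intensity,
        "pan_stain_fraction": pan_stain_fraction,
    }
    return table, truth
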