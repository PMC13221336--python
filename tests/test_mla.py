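import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxsar.mla import (
    GEF,
    MlaCulture,
    MlaResult,
    PlateCount,
    TftPlateCount,
    analyze,
    cloning_efficiency,
    gef_call,
    mutation_frequency,
    relative_suspension_growth,
    relative_total_growth,
    suspension_growth,
    validity_report,
)
from toxsar.synth import gen_mla


def _culture(**kwargs):
    defaults = dict(condition="c", setup_day0=1.0, count_day1=1.0,
                    setup_day1=1.0, count_day2=1.0, setup_day2=1.0)
    defaults.update(kwargs)
    return MlaCulture(**defaults)


class TestSuspensionGrowth:
    def test_no_growth(self):
        assert suspension_growth(_culture()) == 1.0

    def test_fourfold_each_day(self):
        culture = _culture(setup_day0=1e5, count_day1=4e5,
                           setup_day1=1e5, count_day2=4e5)
        assert suspension_growth(culture) == pytest.approx(16.0)

    def test_relative_identity(self):
        assert relative_suspension_growth(12.5, 12.5) == 1.0

    def test_zero_setup_errors(self):
        with pytest.raises(ValueError):
            suspension_growth(_culture(setup_day0=0.0))


class TestCloningEfficiency:
    def test_all_empty_is_zero(self):
        plate = PlateCount("survivor1", 96, 96, 1.6)
        assert cloning_efficiency(plate) == 0.0

    def test_half_empty_survivor(self):
        plate = PlateCount("survivor1", 96, 48, 1.6)
        assert cloning_efficiency(plate) == pytest.approx(-math.log(0.5) / 1.6, abs=1e-12)
        assert cloning_efficiency(plate) == pytest.approx(0.4332, abs=1e-4)

    def test_tft_plate(self):
        # -ln(380/384)/2000 = 5.2356e-6 by hand
        plate = PlateCount("tft", 384, 380, 2000.0)
        assert cloning_efficiency(plate) == pytest.approx(5.2356e-6, abs=1e-9)

    def test_no_empty_wells_lower_bound(self):
        plate = PlateCount("survivor2", 96, 0, 1.6)
        with pytest.warns(UserWarning, match="lower-bound"):
            ce = cloning_efficiency(plate)
        assert ce == pytest.approx(-math.log(0.5 / 96) / 1.6)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            PlateCount("survivor1", 96, 97, 1.6)
        with pytest.raises(ValueError):
            PlateCount("survivor1", 96, 10, 0.0)

    @pytest.mark.parametrize("ce_true", [0.1, 0.5, 1.0])
    def test_poisson_plating_oracle(self, ce_true):
        # brute-force oracle: simulate wells with Poisson founders
        rng = np.random.default_rng(42)
        n_wells, cells = 96 * 200, 1.6
        founders = rng.poisson(cells * ce_true, n_wells)
        plate = PlateCount("survivor1", n_wells, int((founders == 0).sum()), cells)
        estimate = cloning_efficiency(plate)
        # standard error of the zero-class estimator
        p0 = math.exp(-cells * ce_true)
        se = math.sqrt((1 - p0) / (n_wells * p0)) / cells
        assert abs(estimate - ce_true) < 4 * se


class TestMutationFrequency:
    def test_zero_positive_wells(self):
        tft = TftPlateCount("tft", 384, 384, 2000.0)
        s2 = PlateCount("survivor2", 192, 96, 1.6)
        assert mutation_frequency(tft, s2) == (0.0, 0.0, 0.0)

    def test_hand_division(self):
        # choose counts giving ce_tft = 1e-4 and ce_s2 = 0.5 exactly
        tft_empty = round(384 * math.exp(-2000 * 1e-4))
        tft = TftPlateCount("tft", 384, tft_empty, 2000.0,
                            wells_small=100, wells_large=100)
        s2_empty = round(192 * math.exp(-1.6 * 0.5))
        s2 = PlateCount("survivor2", 192, s2_empty, 1.6)
        mf, _, _ = mutation_frequency(tft, s2)
        expected = (-math.log(tft_empty / 384) / 2000) / (-math.log(s2_empty / 192) / 1.6)
        assert mf == pytest.approx(expected, abs=1e-15)
        assert mf == pytest.approx(200e-6, rel=0.02)

    def test_small_large_additivity_at_low_saturation(self):
        tft = TftPlateCount("tft", 384, 374, 2000.0, wells_small=6, wells_large=4)
        s2 = PlateCount("survivor2", 192, 96, 1.6)
        mf, mf_small, mf_large = mutation_frequency(tft, s2)
        assert mf_small + mf_large == pytest.approx(mf, rel=0.01)

    def test_additivity_diverges_with_saturation(self):
        # with disjoint small/large well classes the component sum falls
        # below the total as saturation grows (-ln is nonlinear in the
        # positive-well fraction)
        tft = TftPlateCount("tft", 384, 40, 2000.0, wells_small=200, wells_large=144)
        s2 = PlateCount("survivor2", 192, 96, 1.6)
        mf, mf_small, mf_large = mutation_frequency(tft, s2)
        assert mf_small + mf_large < 0.75 * mf


class TestRelativeTotalGrowth:
    def test_identity(self):
        assert relative_total_growth(1.0, 1.0) == 100.0

    def test_quarter(self):
        assert relative_total_growth(0.5, 0.5) == 25.0

    def test_hand_value(self):
        assert relative_total_growth(0.238, 0.7) == pytest.approx(16.66, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_total_growth(-0.1, 1.0)


class TestGefCall:
    def test_relevant_high_mf(self):
        assert gef_call(1229.5e-6, 201.5e-6) is True

    def test_not_relevant_low_dose(self):
        assert gef_call(232.9e-6, 201.5e-6) is False

    def test_boundary_is_negative(self):
        mf_v = 201.5e-6
        assert gef_call(mf_v + GEF, mf_v) is False
        assert gef_call(mf_v + GEF + 1e-12, mf_v) is True

    @given(st.floats(0, 5e-3), st.floats(0, 5e-3), st.floats(1e-9, 1e-3))
    @settings(max_examples=200)
    def test_monotone_in_treatment(self, mf_t, mf_v, delta):
        if gef_call(mf_t, mf_v):
            assert gef_call(mf_t + delta, mf_v)

    def test_not_shift_invariant(self):
        # adding the same constant to both MFs preserves the call only
        # because the rule depends on the difference; scaling does not
        assert gef_call(300e-6, 100e-6) is True
        assert gef_call(300e-6 * 0.5, 100e-6 * 0.5) is False


# --- table 3-style decision inputs -----------------------------------------

PRINTED_MF = {
    "vehicle": 201.5e-6,
    "0.5uM": 232.9e-6,
    "1uM": 165.7e-6,
    "2.5uM": 281.5e-6,
    "5uM": 1229.5e-6,
    "MMS": 817e-6,
}


class TestValidityReport:
    def _results(self):
        return {
            "vehicle": MlaResult("vehicle", mf=201.5e-6, sg=12.89, ce_s2=0.98,
                                 rtg=95.53),
            "MMS": MlaResult("MMS", mf=817e-6, mf_small=430.9e-6, rtg=58.79),
            "5uM": MlaResult("5uM", mf=1229.5e-6, rtg=22.77),
        }

    def test_vehicle_mf_flagged(self):
        report = validity_report(self._results(), "vehicle", "MMS", "5uM")
        by_name = {c.name: c for c in report.criteria}
        assert not by_name["vehicle MF in [50, 170] x1e-6"].passed
        assert by_name["vehicle MF in [50, 170] x1e-6"].observed == pytest.approx(201.5)

    def test_vehicle_ce_passes(self):
        report = validity_report(self._results(), "vehicle", "MMS", "5uM")
        by_name = {c.name: c for c in report.criteria}
        assert by_name["vehicle CE in [65, 120]%"].passed
        assert by_name["vehicle CE in [65, 120]%"].observed == pytest.approx(98.0)

    def test_single_failure_is_vehicle_mf(self):
        report = validity_report(self._results(), "vehicle", "MMS", "5uM")
        failed = [c.name for c in report.criteria if not c.passed]
        assert failed == ["vehicle MF in [50, 170] x1e-6"]
        assert not report.overall

    def test_override_note(self):
        report = validity_report(self._results(), "vehicle", "MMS", "5uM",
                                 note="high vehicle MF judged negligible")
        assert report.overall

    def test_all_passing(self):
        results = self._results()
        results["vehicle"] = MlaResult("vehicle", mf=120e-6, sg=12.89,
                                       ce_s2=0.98, rtg=95.0)
        report = validity_report(results, "vehicle", "MMS", "5uM")
        assert report.overall and all(c.passed for c in report.criteria)

    def test_missing_condition(self):
        with pytest.raises(ValueError, match="missing"):
            validity_report(self._results(), "vehicle", "MMS", "10uM")


def test_gef_relevance_of_printed_mf_column():
    calls = {label: gef_call(mf, PRINTED_MF["vehicle"])
             for label, mf in PRINTED_MF.items() if label != "vehicle"}
    assert calls == {"0.5uM": False, "1uM": False, "2.5uM": False,
                     "5uM": True, "MMS": True}


class TestAnalyze:
    def test_synthetic_pipeline(self):
        table, truth = gen_mla(
            seed=1,
            conditions={
                "vehicle": {"ce": 0.9, "mf": 150e-6, "sg": 14.0},
                "treatment": {"ce": 0.7, "mf": 1500e-6, "sg": 7.0},
            },
        )
        results = analyze(table, vehicle="vehicle")
        t = results["treatment"]
        assert t.mf == pytest.approx(1500e-6, rel=0.35)
        assert t.relevant  # 1500 > 150 + 126
        assert results["vehicle"].rtg == pytest.approx(100.0, abs=15.0)
        assert results["vehicle"].sg == pytest.approx(14.0, rel=1e-6)

    def test_missing_vehicle(self):
        table, _ = gen_mla(seed=1, conditions={"t": {"ce": 0.9, "mf": 1e-4}})
        with pytest.raises(ValueError, match="vehicle"):
            analyze(table, vehicle="vehicle")

    def test_mf_recovery_unbiased(self):
        # full-pipeline bias check at vehicle-like parameters
        estimates = []
        for seed in range(100):
            table, _ = gen_mla(
                seed=seed,
                conditions={"vehicle": {"ce": 0.9, "mf": 200e-6, "sg": 14.0}},
            )
            estimates.append(analyze(table, vehicle="vehicle")["vehicle"].mf)
        bias = (np.mean(estimates) - 200e-6) / 200e-6
        assert abs(bias) < 0.10
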