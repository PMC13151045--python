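"""Fish plasma model: partitioning, TWC, refinement, conservatism."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishplasma.catalog import APIRecord, printed_tolerance
from fishplasma.fpm import (
    TWCResult,
    assess_conservatism,
    blood_water_partition,
    predict_fss_pc,
    screen,
    twc_original,
    twc_refined,
)


class TestPartition:
    def test_unit_partition_at_zero_exponent(self):
        assert blood_water_partition(0.88 / 0.73) == pytest.approx(1.0)

    def test_ibuprofen(self):
        assert blood_water_partition(1.31) == pytest.approx(1.19, abs=0.005)

    def test_ketoconazole_trout_ph(self):
        assert blood_water_partition(4.26) == pytest.approx(169.75, rel=1e-3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            blood_water_partition(float("nan"))


class TestSteadyStatePlasma:
    @pytest.mark.parametrize("w,p,expected", [
        (0.0, 7.0, 0.0), (1.0, 1.19, 1.19), (2.0, 0.5, 1.0)])
    def test_product(self, w, p, expected):
        assert predict_fss_pc(w, p) == pytest.approx(expected)


class TestTwc:
    def test_meloxicam_original(self):
        p = blood_water_partition(-1.12)
        assert twc_original(0.4, p) == pytest.approx(19.94, rel=0.01)

    def test_cilostazol_original(self):
        p = blood_water_partition(2.97)
        assert twc_original(1.2, p) == pytest.approx(0.062, rel=0.02)

    def test_unit_ratio(self):
        assert twc_original(3.3, 3.3) == pytest.approx(1.0)

    def test_missing_cmax_absent(self):
        assert twc_original(None, 1.0) is None

    def test_ibuprofen_refined(self):
        p = blood_water_partition(0.87)
        assert twc_refined(15.0, 55.0, p) == pytest.approx(0.48, rel=0.01)

    def test_tolbutamide_refined(self):
        p = blood_water_partition(1.21)
        assert twc_refined(45.0, 35.0, p) == pytest.approx(1.28, rel=0.01)

    def test_unit_rfu_equals_original(self):
        p = blood_water_partition(1.5)
        assert twc_refined(7.0, 1.0, p) == twc_original(7.0, p)

    @pytest.mark.parametrize("rfu", [None, 0.0])
    def test_missing_rfu_absent(self, rfu):
        assert twc_refined(1.0, rfu, 1.0) is None

    @given(st.floats(0.001, 100), st.floats(0.1, 100),
           st.floats(-2.0, 5.0), st.floats(-2.0, 5.0))
    def test_original_to_refined_identity(self, cmax, rfu, logd_h, logd_f):
        """twc_original / twc_refined == rfu * P_fish / P_human exactly."""
        p_h = blood_water_partition(logd_h)
        p_f = blood_water_partition(logd_f)
        ratio = twc_original(cmax, p_h) / twc_refined(cmax, rfu, p_f)
        assert ratio == pytest.approx(rfu * p_f / p_h, rel=1e-12)

    def test_monotonic_decreasing_in_logd(self):
        twcs = [twc_original(1.0, blood_water_partition(ld))
                for ld in [-1.0, 0.0, 1.0, 2.0]]
        assert all(a > b for a, b in zip(twcs, twcs[1:]))

    def test_refined_monotonic_decreasing_in_rfu(self):
        vals = [twc_refined(1.0, r, 2.0) for r in [1.0, 5.0, 25.0]]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestConservatism:
    def base(self, twc_orig=None, twc_ref=None):
        return TWCResult("x", "rainbow_trout", 1.0, 1.0, 1.0, 1.0,
                         twc_original=twc_orig, twc_refined=twc_ref)

    def test_mycophenolic_not_conservative(self):
        r = assess_conservatism(self.base(twc_orig=15.63), noec=0.1,
                                loec=0.3)
        assert r.ratio_orig_to_loec == pytest.approx(52.1, rel=0.01)
        assert r.conservative_original is False

    def test_boundary_inclusive(self):
        r = assess_conservatism(self.base(twc_orig=0.3), noec=None, loec=0.3)
        assert r.conservative_original is True

    def test_noec_fallback_sets_ratio_only(self):
        r = assess_conservatism(self.base(twc_orig=1.36), noec=0.68,
                                loec=None)
        assert r.ratio_orig_to_loec == pytest.approx(2.0)
        assert r.conservative_original is None

    def test_no_effect_data_leaves_result_untouched(self):
        r = assess_conservatism(self.base(twc_orig=1.0), None, None)
        assert r.ratio_orig_to_loec is None


def printed_mismatches(fixture, by_name, rel=0.05):
    """Compare recomputed screening columns against every printed cell.

    Tolerance per cell: ``rel`` of the printed value or half an ulp at
    its printed precision, whichever is larger; columns that depend on
    the Rf_u input additionally inherit the printed precision of that
    input (a worst-case ratio printed as the integer 1 only determines
    refined quantities to +-50%).
    """
    mismatches = []
    for idx, row in fixture.table.iterrows():
        raw = fixture.raw.loc[idx]
        r = by_name[row["name"]]
        rfu = row["rfu_trout_max"]
        rfu_slack = 0.0
        if pd.notna(rfu) and rfu > 0:
            rfu_slack = printed_tolerance(raw["rfu_trout_max"], rel=0.0) / rfu
        checks = [
            ("pbw_ph7.4", r.p_bw_original, 0.0),
            ("pbw_ph7.9", r.p_bw_refined, 0.0),
            ("twc_original_mg_per_L", r.twc_original, 0.0),
            ("twc_refined_mg_per_L", r.twc_refined, rfu_slack),
            ("twc_ratio", r.twc_ratio, rfu_slack),
            ("twc_original_over_loec", r.ratio_orig_to_loec, 0.0),
            ("twc_refined_over_loec", r.ratio_refined_to_loec, rfu_slack),
        ]
        for col, computed, extra_rel in checks:
            printed = row[col]
            if pd.isna(printed):
                continue
            tol = printed_tolerance(raw[col], rel=rel) + extra_rel * printed
            if computed is None or abs(computed - printed) > tol:
                mismatches.append((row["name"], col, printed, computed))
    return mismatches


class TestScreen:
    def test_reproduces_every_printed_cell(self, fixture44, trout_screen):
        assert printed_mismatches(fixture44, trout_screen) == []

    def test_phenylbutazone_reduction(self, trout_screen):
        assert trout_screen["Phenylbutazone"].twc_ratio == pytest.approx(
            81.7, rel=0.01)

    def test_most_cells_within_one_percent(self, fixture44, trout_screen):
        # beyond printed rounding, recomputation agrees to ~1% throughout
        assert printed_mismatches(fixture44, trout_screen, rel=0.01) == []

    def test_missing_inputs_give_absent_fields(self, trout_screen):
        assert trout_screen["Salinomycin"].twc_original is None
        assert trout_screen["Fluphenazine"].twc_refined is None
        assert trout_screen["Fluphenazine"].twc_ratio is None

    def test_empty_table(self, fixture44):
        results, errors = screen([], fixture44.species["rainbow_trout"])
        assert results == [] and errors == []

    def test_missing_logd_collected_run_continues(self, fixture44):
        apis = [
            APIRecord("NoTroutLogD", "A", {7.4: 1.0}, cmax=1.0),
            fixture44.api("Ibuprofen"),
        ]
        results, errors = screen(apis, fixture44.species["rainbow_trout"])
        assert len(results) == 1 and results[0].api_name == "Ibuprofen"
        assert len(errors) == 1 and "NoTroutLogD" in errors[0]

    def test_row_order_preserved(self, fixture44, trout_screen):
        assert list(trout_screen) == [r.name for r in fixture44.apis]
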