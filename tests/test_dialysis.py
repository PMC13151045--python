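"""Equilibrium-dialysis f_u computation, dilution correction, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from fishplasma.dialysis import (
    DialysisMeasurement,
    MeasurementError,
    aggregate_all,
    aggregate_fu,
    classify_recovery,
    compute_fu,
    compute_recovery,
    correct_dilution,
    dilute_fu,
    read_assay_table,
)


def make(api="ibu", species="rainbow_trout", lab="lab1", rep=1,
         plasma=8.0, buffer=2.0, nominal=10.0, dilution=1.0):
    return DialysisMeasurement(api, species, lab, rep, plasma, buffer,
                               nominal, dilution)


class TestComputeFu:
    @pytest.mark.parametrize("plasma,buffer,expected", [
        (10.0, 10.0, 1.0),   # fully unbound
        (10.0, 0.0, 0.0),    # fully bound
        (8.0, 2.0, 0.25),
    ])
    def test_ratio(self, plasma, buffer, expected):
        assert compute_fu(plasma, buffer) == pytest.approx(expected)

    def test_no_clamping_above_one(self):
        assert compute_fu(5.0, 6.0) == pytest.approx(1.2)

    def test_zero_plasma_is_undefined(self):
        with pytest.raises(MeasurementError):
            compute_fu(0.0, 1.0)


class TestDilutionCorrection:
    def test_unbound_is_dilution_invariant(self):
        assert correct_dilution(1.0, 10.0) == pytest.approx(1.0)

    @given(st.floats(0.0, 1.0))
    def test_identity_at_no_dilution(self, fu):
        assert correct_dilution(fu, 1.0) == fu

    def test_hand_value(self):
        # 0.1 / (10 - 0.9)
        assert correct_dilution(0.1, 10.0) == pytest.approx(0.1 / 9.1)

    def test_above_one_rejected(self):
        with pytest.raises(MeasurementError):
            correct_dilution(1.1, 10.0)

    @given(st.floats(1e-6, 1.0), st.floats(1.0, 100.0))
    @settings(max_examples=200)
    def test_round_trip(self, fu, d):
        assert correct_dilution(dilute_fu(fu, d), d) == pytest.approx(
            fu, rel=1e-12)

    def test_strictly_increasing_in_fu(self):
        fu = np.linspace(0.001, 0.999, 500)
        out = np.array([correct_dilution(f, 10.0) for f in fu])
        assert np.all(np.diff(out) > 0)

    def test_binding_equilibrium_oracle(self):
        """Dialysis of diluted plasma, simulated from mass-action binding,
        corrects back to the undiluted free fraction.

        Single binding site, trace drug: free fraction Kd / (Kd + P).
        Equal-volume chambers; at equilibrium the free concentration is
        common to both sides and the buffer chamber holds only free drug.
        """
        kd, p_tot, total_mass = 5.0, 40.0, 1e-6

        def simulate_chambers(protein):
            def residual(free):
                bound = protein * free / (kd + free)
                return 2 * free + bound - total_mass

            free = brentq(residual, 0.0, total_mass)
            plasma_total = free + protein * free / (kd + free)
            return plasma_total, free  # (plasma conc, buffer conc)

        plasma, buffer = simulate_chambers(p_tot / 10.0)  # 10% plasma
        fu10 = compute_fu(plasma, buffer)
        corrected = correct_dilution(fu10, 10.0)
        assert corrected == pytest.approx(kd / (kd + p_tot), rel=1e-4)


class TestRecovery:
    def test_full_mass_balance(self):
        # noiseless equal-volume split of a 10 uM spike
        assert compute_recovery(8.0, 2.0, 10.0) == pytest.approx(100.0)
        assert classify_recovery(100.0) == "pass"

    @pytest.mark.parametrize("pct,expected", [
        (70.0, "pass"), (60.0, "caution"), (50.0, "caution"),
        (49.9, "fail"), (40.0, "fail")])
    def test_bands(self, pct, expected):
        assert classify_recovery(pct) == expected

    def test_unequal_volumes(self):
        # double buffer volume doubles that chamber's mass contribution
        assert compute_recovery(5.0, 2.0, 10.0, plasma_volume=1.0,
                                buffer_volume=2.0) == pytest.approx(90.0)


class TestAggregation:
    def test_single_lab_collapses(self):
        ms = [make(rep=i, plasma=10.0, buffer=10.0 * fu)
              for i, fu in enumerate([0.2, 0.3, 0.4], start=1)]
        s = aggregate_fu(ms)
        assert s.fu_min == s.fu_median == s.fu_max == pytest.approx(0.3)
        assert s.n_labs == 1 and s.n_replicates == 3

    def test_two_labs_midpoint_median(self):
        ms = [make(lab="lab1", plasma=10.0, buffer=2.0),
              make(lab="lab2", plasma=10.0, buffer=6.0)]
        s = aggregate_fu(ms)
        assert (s.fu_min, s.fu_median, s.fu_max) == pytest.approx(
            (0.2, 0.4, 0.6))
        assert s.n_labs == 2

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    def test_order_statistics_property(self, fus):
        ms = [make(lab=f"lab{i}", plasma=10.0, buffer=10.0 * fu)
              for i, fu in enumerate(fus)]
        s = aggregate_fu(ms)
        assert s.fu_min <= s.fu_median <= s.fu_max

    def test_dilution_correction_applied(self):
        # diluted f_u 0.5 at D=10 corresponds to undiluted 0.5/5.5
        ms = [make(plasma=10.0, buffer=5.0, dilution=10.0)]
        s = aggregate_fu(ms)
        assert s.fu_median == pytest.approx(0.5 / 5.5)

    def test_mixed_dilutions_need_correction(self):
        ms = [make(dilution=1.0), make(rep=2, dilution=10.0)]
        with pytest.raises(ValueError, match="dilution"):
            aggregate_fu(ms, apply_dilution_correction=False)

    def test_fu_above_one_flagged_not_clamped(self):
        s = aggregate_fu([make(plasma=5.0, buffer=6.0)])
        assert "fu_above_one" in s.qc_flags
        assert s.fu_max == pytest.approx(1.2)

    def test_low_recovery_flagged(self):
        # only 60% of the nominal mass found across the chambers
        s = aggregate_fu([make(plasma=4.0, buffer=2.0)])
        assert "low_recovery" in s.qc_flags

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError, match="span"):
            aggregate_fu([make(api="a"), make(api="b")])

    def test_aggregate_all_groups_pairs(self):
        ms = [make(api="a"), make(api="b"), make(api="a", rep=2)]
        summaries = aggregate_all(ms)
        assert [s.api_name for s in summaries] == ["a", "b"]
        assert summaries[0].n_replicates == 2


class TestAssayIO:
    def test_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("api,species\nx,human\n")
        with pytest.raises(ValueError, match="missing assay columns"):
            read_assay_table(path)

    def test_bad_row_number_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "api,species,lab,replicate,plasma_conc_uM,buffer_conc_uM,"
            "nominal_uM,dilution_factor\n"
            "x,human,l,1,8.0,2.0,10,1\n"
            "y,human,l,one,8.0,2.0,10,1\n")
        with pytest.raises(ValueError, match="row 3"):
            read_assay_table(path)
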