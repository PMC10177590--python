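import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transwell import (
    Direction,
    PappConfig,
    PappStatus,
    SlopeMode,
    TranswellGeometry,
    ValidationError,
    correct_cumulative,
    efflux_ratio,
    estimate_papp,
    fit_transfer_slope,
    papp_corrected,
    papp_uncorrected,
    recovery_fraction,
    summarize_condition,
)
from transwell.model import AssayDesign, DrugSpec, PappResult
from transwell.permeability import recovery_fraction_ledger
from transwell.simulate import DiffusionSimParams, simulate_well
from conftest import make_series

DESIGN = AssayDesign(drug=DrugSpec("metoprolol", 267.36),
                     donor_concentration_mg_ml=0.4,
                     direction=Direction.AP_TO_BL)


def ledger_oracle(measured, v_s, v_r):
    """Independent aliquot-ledger: track removed mass per sampling event and
    reconstruct cumulative transported mass in the receiver chamber."""
    removed_masses = []
    corrected = []
    for c in measured:
        if c is None:
            corrected.append(None)
            continue
        transported = c * v_r + sum(removed_masses)
        corrected.append(transported / v_r)
        removed_masses.append(v_s * c)
    return corrected


class TestCumulativeCorrection:
    def test_two_point_worked_example(self, series_factory):
        cum = correct_cumulative(series_factory([1.0, 2.0]))
        np.testing.assert_allclose(cum.corrected, [1.0, 2.0 + 0.1 / 0.7 * 1.0])

    def test_all_zero_stays_zero(self, series_factory):
        cum = correct_cumulative(series_factory([0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(cum.corrected, 0.0)

    def test_single_point_unchanged(self, series_factory):
        cum = correct_cumulative(series_factory([0.7]))
        assert cum.corrected[0] == 0.7

    def test_blq_points_masked_and_excluded_from_running_sum(self, series_factory):
        cum = correct_cumulative(series_factory([1.0, None, 2.0]))
        assert np.isnan(cum.corrected[1])
        assert cum.corrected[2] == pytest.approx(2.0 + 0.1 / 0.7 * 1.0)

    def test_corrected_never_below_measured(self, series_factory):
        cum = correct_cumulative(series_factory([0.5, 0.1, 0.9, 0.2]))
        assert np.all(cum.corrected >= cum.measured)

    def test_sample_volume_must_be_below_receiver(self, series_factory):
        series = series_factory([1.0])
        bad = TranswellGeometry(sample_volume_ml=0.7)
        with pytest.raises(ValidationError):
            correct_cumulative(series, bad)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(values=st.lists(
        st.one_of(st.none(), st.floats(min_value=0, max_value=10)),
        min_size=1, max_size=6))
    def test_matches_explicit_aliquot_ledger(self, values):
        series = make_series(DESIGN, values)
        cum = correct_cumulative(series)
        oracle = ledger_oracle(values, 0.1, 0.7)
        for got, want in zip(cum.corrected, oracle):
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)


class TestTransferSlope:
    def _cum(self, design, values, times=None):
        return correct_cumulative(make_series(
            design, values, times=times,
            c0=max(100.0, 10 * max(v for v in values if v is not None))))

    def test_exact_line_has_unit_r_squared(self, design):
        cum = self._cum(design, [1.0, 2.0, 3.0], times=[15, 30, 45])
        # undo the sampling correction so the *corrected* series is the line
        cum.corrected = np.array([1.0, 2.0, 3.0])
        fit = fit_transfer_slope(cum)
        assert fit.slope == pytest.approx(1 / 15)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_point_line(self, design):
        cum = self._cum(design, [0.0, 6.0], times=[30, 90])
        cum.corrected = np.array([0.0, 6.0])
        fit = fit_transfer_slope(cum, min_points=2)
        assert fit.slope == pytest.approx(0.1)

    def test_max_window_finds_rising_segment(self, design):
        """Flat-then-rising series: brute force says the best 3+-point window
        is the rising tail with slope 0.2."""
        times = [15, 30, 45, 60, 90, 120]
        values = [0.0, 0.0, 3.0, 6.0, 12.0, 18.0]
        cum = self._cum(design, values, times=times)
        cum.corrected = np.array(values, dtype=float)
        fit = fit_transfer_slope(cum, mode=SlopeMode.MAX_WINDOW, min_points=3)

        def window_slopes():
            for i, j in itertools.combinations(range(len(times) + 1), 2):
                if j - i >= 3:
                    t = np.array(times[i:j], dtype=float)
                    y = np.array(values[i:j], dtype=float)
                    yield np.polyfit(t, y, 1)[0]

        brute_max = max(window_slopes())
        assert fit.slope == pytest.approx(brute_max)
        assert fit.slope == pytest.approx(0.2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(values=st.lists(st.floats(min_value=0, max_value=5), min_size=3,
                           max_size=6))
    def test_max_window_dominates_every_window(self, values):
        times = [15, 30, 45, 60, 90, 120][: len(values)]
        cum = self._cum(DESIGN, values, times=times)
        cum.corrected = np.array(values, dtype=float)
        best = fit_transfer_slope(cum, mode=SlopeMode.MAX_WINDOW, min_points=3)
        full = fit_transfer_slope(cum, mode=SlopeMode.FULL_RANGE, min_points=3)
        assert best.slope >= full.slope - 1e-12
        for i in range(len(values) - 2):
            for j in range(i + 3, len(values) + 1):
                t = np.array(times[i:j], dtype=float)
                y = np.array(values[i:j], dtype=float)
                assert best.slope >= np.polyfit(t, y, 1)[0] - 1e-9

    def test_too_few_quantifiable_points_signals_blq(self, design):
        cum = correct_cumulative(make_series(design, [None, None, 0.5]))
        assert fit_transfer_slope(cum, min_points=3) is None


class TestPappAlgebra:
    def test_zero_slope_zero_papp(self, geometry):
        assert papp_uncorrected(0.0, 1000.0, geometry, Direction.AP_TO_BL) == 0.0

    def test_inverts_transfer_equation(self, geometry):
        """slope = Papp * A * C0 * 60 / V_R must map back to Papp exactly."""
        papp = 1.0e-5
        c0 = 1000.0
        slope = papp * 0.33 * c0 * 60 / 0.7
        assert papp_uncorrected(slope, c0, geometry, Direction.AP_TO_BL) == \
            pytest.approx(papp, rel=1e-12)

    def test_doubling_c0_halves_papp(self, geometry):
        one = papp_uncorrected(0.01, 500.0, geometry, Direction.AP_TO_BL)
        two = papp_uncorrected(0.01, 1000.0, geometry, Direction.AP_TO_BL)
        assert two == pytest.approx(one / 2)

    def test_receiver_volume_is_direction_aware(self, geometry):
        ab = papp_uncorrected(0.01, 500.0, geometry, Direction.AP_TO_BL)
        ba = papp_uncorrected(0.01, 500.0, geometry, Direction.BL_TO_AP)
        assert ab / ba == pytest.approx(0.7 / 0.2)

    def test_nonpositive_c0_rejected(self, geometry):
        with pytest.raises(ValidationError):
            papp_uncorrected(0.01, 0.0, geometry, Direction.AP_TO_BL)


class TestRecovery:
    def test_lossless_no_transport_is_unity(self, series_factory):
        s = series_factory([0.0, 0.0], c0=0.2, donor_end=0.2)
        assert recovery_fraction(s, correct_cumulative(s)) == pytest.approx(1.0)

    def test_worked_arithmetic_example(self, design):
        # donor 0.2 -> 0.16 in 0.2 mL; corrected receiver 0.01 in 0.7 mL
        s = make_series(design, [0.01], c0=0.2, donor_end=0.16)
        rec = recovery_fraction(s, correct_cumulative(s))
        assert rec == pytest.approx((0.16 * 0.2 + 0.01 * 0.7) / (0.2 * 0.2))
        assert rec == pytest.approx(0.975)

    def test_missing_donor_end_signals_unavailable(self, series_factory):
        s = series_factory([0.01], donor_end=None)
        assert recovery_fraction(s, correct_cumulative(s)) is None

    def test_formula_equals_aliquot_ledger_route(self):
        s, _ = simulate_well(DiffusionSimParams(papp_true_cm_s=1.2e-5,
                                                noise_cv=0.07, seed=9))
        formula = recovery_fraction(s, correct_cumulative(s))
        ledger = recovery_fraction_ledger(s)
        assert formula == pytest.approx(ledger, rel=1e-12)

    def test_simulated_loss_matches_truth_ledger(self):
        params = DiffusionSimParams(papp_true_cm_s=1e-5, noise_cv=0.0,
                                    loss_rate_per_min=1e-3, seed=4)
        s, truth = simulate_well(params)
        rec = recovery_fraction(s, correct_cumulative(s))
        assert rec < 1.0
        assert rec == pytest.approx(truth.recovery_true, rel=0.01)


class TestRecoveryCorrection:
    def test_unity_recovery_leaves_papp_unchanged(self):
        value, warnings = papp_corrected(1e-5, 1.0)
        assert value == 1e-5 and warnings == []

    def test_division_example(self):
        value, _ = papp_corrected(9.2e-6, 0.92)
        assert value == pytest.approx(1.0e-5)

    def test_zero_recovery_rejected(self):
        with pytest.raises(ValidationError):
            papp_corrected(1e-5, 0.0)

    def test_recovery_above_bound_warns(self):
        _, warnings = papp_corrected(1e-5, 1.3)
        assert warnings and "1.3" in warnings[0]


class TestEstimatePapp:
    @pytest.mark.parametrize("papp_true", [1e-6, 5e-6])
    def test_sink_regime_recovery_within_five_percent(self, papp_true):
        """Noiseless wells with <5% donor depletion recover the truth."""
        s, _ = simulate_well(DiffusionSimParams(papp_true_cm_s=papp_true,
                                                noise_cv=0.0, seed=0))
        r = estimate_papp(s)
        assert r.status is PappStatus.OK
        assert r.papp_corrected == pytest.approx(papp_true, rel=0.05)

    @pytest.mark.parametrize("papp_true", [1e-5, 2e-5])
    def test_depletion_bias_is_negative_and_bounded(self, papp_true):
        """High-permeability wells deplete the donor (11% / 21% at 120 min),
        so the linear-slope estimate sits below truth by roughly half the
        depletion; the bias never exceeds the depletion itself."""
        s, truth = simulate_well(DiffusionSimParams(papp_true_cm_s=papp_true,
                                                    noise_cv=0.0, seed=0))
        r = estimate_papp(s)
        depletion = 1 - truth.donor_concentration[-1] / 0.4
        rel_err = (r.papp_corrected - papp_true) / papp_true
        assert -depletion < rel_err < 0

    def test_all_blq_returns_blq_status(self, series_factory):
        s = series_factory([None] * 6, donor_end=0.4)
        r = estimate_papp(s)
        assert r.status is PappStatus.BLQ and r.papp_corrected is None

    def test_zero_permeability_with_loq_is_blq(self):
        s, _ = simulate_well(DiffusionSimParams(papp_true_cm_s=0.0,
                                                noise_cv=0.0, loq=1e-5, seed=0))
        r = estimate_papp(s)
        assert r.status is PappStatus.BLQ

    def test_missing_donor_end_downgrades_with_warning(self, design):
        s = make_series(design, [0.001, 0.002, 0.003], donor_end=None)
        r = estimate_papp(s)
        assert r.status is PappStatus.OK
        assert r.recovery_fraction is None
        assert r.papp_corrected == r.papp_uncorrected
        assert any("recovery unavailable" in w for w in r.warnings)

    def test_scale_invariance_of_papp(self, design):
        """Multiplying every concentration by a constant leaves Papp fixed."""
        base = make_series(design, [0.001, 0.002, 0.0031, 0.004], c0=0.4,
                           donor_end=0.39)
        scaled = make_series(design, [0.01, 0.02, 0.031, 0.04], c0=4.0,
                             donor_end=3.9)
        a = estimate_papp(base)
        b = estimate_papp(scaled)
        assert a.papp_corrected == pytest.approx(b.papp_corrected, rel=1e-12)


class TestEffluxRatio:
    def _ok(self, value):
        return PappResult(well_id="w", status=PappStatus.OK, papp_corrected=value)

    def test_benchmark_mean_ratio_below_threshold(self):
        out = efflux_ratio(self._ok(17.89e-6), self._ok(13.08e-6))
        assert out.ratio == pytest.approx(0.731, abs=5e-4)
        assert not out.active_efflux_flag

    def test_ratio_above_two_flags_active_efflux(self):
        out = efflux_ratio(self._ok(1e-5), self._ok(2.5e-5))
        assert out.active_efflux_flag

    def test_equal_directions_ratio_one(self):
        out = efflux_ratio(self._ok(1e-5), self._ok(1e-5))
        assert out.ratio == 1.0 and not out.active_efflux_flag

    def test_blq_input_makes_ratio_undefined(self):
        blq = PappResult(well_id="w", status=PappStatus.BLQ)
        assert efflux_ratio(self._ok(1e-5), blq) is None


class TestConditionSummary:
    def test_two_well_mean_and_sd(self):
        results = [PappResult("a", PappStatus.OK, papp_corrected=12.12e-6),
                   PappResult("b", PappStatus.OK, papp_corrected=12.75e-6)]
        s = summarize_condition(results, {"drug": "propranolol"})
        assert s.mean * 1e6 == pytest.approx(12.435)
        assert s.sd * 1e6 == pytest.approx(abs(12.75 - 12.12) / math.sqrt(2))
        assert s.sem == pytest.approx(s.sd / math.sqrt(2))

    def test_identical_wells_zero_sd_and_cv(self):
        results = [PappResult("a", PappStatus.OK, papp_corrected=5e-6)] * 2
        s = summarize_condition(results)
        assert s.sd == 0 and s.cv_percent == 0

    def test_single_well_reports_mean_only(self):
        s = summarize_condition([PappResult("a", PappStatus.OK, papp_corrected=5e-6)])
        assert s.mean == 5e-6 and s.sd is None and s.cv_percent is None

    def test_all_blq_group_skipped(self):
        assert summarize_condition([PappResult("a", PappStatus.BLQ)]) is None
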