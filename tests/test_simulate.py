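import numpy as np
import pytest

from transwell import Direction, TranswellGeometry, ValidationError
from transwell.expression import CtTable, delta_ct
from transwell.integrity import detect_plateau, normalize_teer
from transwell.simulate import (
    CtSimParams,
    DiffusionSimParams,
    PlateCondition,
    TEERSimParams,
    simulate_ct_table,
    simulate_plate,
    simulate_teer_series,
    simulate_well,
    two_compartment_analytic,
)
from transwell.datasets import DRUGS


def _total_mass(truth):
    return truth.donor_mass + truth.receiver_mass_post + truth.sampled_mass_cumulative


class TestSimulateWell:
    def test_no_transport_leaves_everything_in_donor(self):
        s, truth = simulate_well(DiffusionSimParams(
            papp_true_cm_s=0.0, noise_cv=0.0, seed=0))
        assert np.all(truth.receiver_concentration_pre == 0)
        assert truth.donor_concentration[-1] == pytest.approx(0.4)
        assert all(p.concentration == 0 for p in s.receiver_measurements)

    def test_sink_regime_matches_linear_flux(self):
        """Early receiver mass ~ P*A*C0*t while receiver conc << donor conc."""
        p, c0 = 1e-6, 0.4
        params = DiffusionSimParams(papp_true_cm_s=p, donor_concentration_0=c0,
                                    noise_cv=0.0, seed=0)
        _, truth = simulate_well(params)
        t = truth.times_min[0]
        assert truth.receiver_concentration_pre[0] < 0.02 * truth.donor_concentration[0]
        expected = p * 60 * 0.33 * c0 * t  # mg transported in t minutes
        got = truth.receiver_mass_post[0] + truth.sampled_mass_cumulative[0]
        assert got == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("papp", [1e-6, 1e-5, 2e-5])
    @pytest.mark.parametrize("direction", [Direction.AP_TO_BL, Direction.BL_TO_AP])
    def test_mass_conserved_without_loss(self, papp, direction):
        _, truth = simulate_well(DiffusionSimParams(
            papp_true_cm_s=papp, direction=direction, noise_cv=0.03, seed=2))
        np.testing.assert_allclose(_total_mass(truth), truth.initial_mass, rtol=1e-6)
        assert truth.recovery_true == pytest.approx(1.0, abs=1e-9)

    def test_loss_rate_reduces_recovery(self):
        _, truth = simulate_well(DiffusionSimParams(
            papp_true_cm_s=1e-5, loss_rate_per_min=1e-3, noise_cv=0.0, seed=0))
        assert truth.recovery_true < 1.0

    def test_cumulative_receiver_mass_nondecreasing_noiseless(self):
        _, truth = simulate_well(DiffusionSimParams(
            papp_true_cm_s=1e-5, noise_cv=0.0, seed=0))
        cumulative = truth.receiver_mass_post + truth.sampled_mass_cumulative
        assert np.all(np.diff(cumulative) >= 0)

    def test_seed_contract_bit_identical(self):
        params = DiffusionSimParams(papp_true_cm_s=8e-6, noise_cv=0.08,
                                    loq=1e-4, seed=42)
        s1, t1 = simulate_well(params)
        s2, t2 = simulate_well(params)
        for p, q in zip(s1.receiver_measurements, s2.receiver_measurements):
            assert (p.below_loq == q.below_loq) and (
                p.below_loq or p.concentration == q.concentration)
        assert s1.donor_start_concentration == s2.donor_start_concentration
        np.testing.assert_array_equal(t1.donor_concentration, t2.donor_concentration)

    def test_loq_censoring_marks_small_values_blq(self):
        s, truth = simulate_well(DiffusionSimParams(
            papp_true_cm_s=1e-6, noise_cv=0.0, loq=5e-3, seed=0))
        assert all(p.below_loq for p in s.receiver_measurements
                   if truth.receiver_concentration_pre[0] < 5e-3)

    @pytest.mark.parametrize("papp,vd_vr", [
        (1e-6, (0.2, 0.7)), (5e-6, (0.2, 0.7)), (1e-5, (0.2, 0.7)),
        (2e-5, (0.2, 0.7)), (1e-5, (0.7, 0.2)), (2e-5, (0.7, 0.2)),
        (1e-6, (0.5, 0.5)), (5e-6, (0.5, 0.5)), (2e-5, (1.0, 0.3)),
        (1e-5, (0.3, 1.0)),
    ])
    def test_integrator_matches_analytic_two_compartment_solution(self, papp, vd_vr):
        """Matrix-exponential propagation equals the closed-form solution."""
        vd, vr = vd_vr
        geom = TranswellGeometry(apical_volume_ml=vd, basolateral_volume_ml=vr,
                                 sample_volume_ml=0.05)
        # single long interval, no intermediate events
        params = DiffusionSimParams(papp_true_cm_s=papp, geometry=geom,
                                    sampling_times_min=(120.0,), noise_cv=0.0, seed=0)
        _, truth = simulate_well(params)
        cd, cr = two_compartment_analytic(papp, geom, Direction.AP_TO_BL,
                                          0.4, 0.0, 120.0)
        assert truth.donor_concentration[0] == pytest.approx(cd, rel=1e-6)
        assert truth.receiver_concentration_pre[0] == pytest.approx(cr, rel=1e-6)


class TestSimulatePlate:
    def _conditions(self, n_drugs=1, directions=(Direction.AP_TO_BL,)):
        drugs = list(DRUGS.values())[:n_drugs]
        return [PlateCondition(drug=d, donor_concentration_mg_ml=0.4,
                               direction=dr, papp_true_cm_s=1e-5)
                for d in drugs for dr in directions]

    def test_well_count_and_distinct_ids(self):
        series, truth = simulate_plate(self._conditions(), n_wells=2, seed=0)
        assert len(series) == 2
        assert len({s.well_id for s in series}) == 2

    def test_grid_counting(self):
        conds = self._conditions(n_drugs=3,
                                 directions=(Direction.AP_TO_BL, Direction.BL_TO_AP))
        series, truth = simulate_plate(conds, n_wells=2, seed=0)
        assert len(series) == 12 and len(truth) == 12

    def test_same_seed_identical_output(self):
        a, ta = simulate_plate(self._conditions(), n_wells=2, seed=5)
        b, tb = simulate_plate(self._conditions(), n_wells=2, seed=5)
        for s, t in zip(a, b):
            assert s.well_id == t.well_id
            assert s.donor_start_concentration == t.donor_start_concentration
        assert ta.equals(tb)

    def test_duplicate_conditions_rejected(self):
        conds = self._conditions() * 2
        with pytest.raises(ValidationError):
            simulate_plate(conds, n_wells=1, seed=0)


class TestSimulateTEER:
    def test_noiseless_trajectory_approaches_plateau(self):
        params = TEERSimParams(noise_sd_ohm_cm2=0.0, n_days=30)
        df = simulate_teer_series(params)
        assert df["normalized_true_ohm_cm2"].iloc[-1] == pytest.approx(4200, rel=1e-6)

    def test_normalization_inverts_emission_exactly(self):
        params = TEERSimParams(noise_sd_ohm_cm2=0.0)
        df = simulate_teer_series(params)
        recovered = normalize_teer(df["raw_ohm"].to_numpy(),
                                   df["blank_ohm"].to_numpy(), 0.33)
        np.testing.assert_allclose(recovered, df["normalized_true_ohm_cm2"],
                                   rtol=1e-12, atol=1e-9)

    def test_colonoid_defaults_reach_plateau_band(self):
        """Final-3-day mean within 5% of the 4200 Ohm*cm2 target across seeds."""
        finals = []
        for seed in range(20):
            df = simulate_teer_series(TEERSimParams.colonoid_defaults(seed=seed))
            norm = normalize_teer(df["raw_ohm"].to_numpy(),
                                  df["blank_ohm"].to_numpy(), 0.33)
            finals.append(norm[-3:].mean())
        assert np.mean(finals) == pytest.approx(4200, rel=0.05)

    def test_caco2_defaults_plateau_near_gate(self):
        df = simulate_teer_series(TEERSimParams.caco2_defaults(seed=3))
        norm = normalize_teer(df["raw_ohm"].to_numpy(),
                              df["blank_ohm"].to_numpy(), 0.33)
        day, mean = detect_plateau(df["day"], norm)
        assert day is not None and mean == pytest.approx(500, rel=0.1)


class TestSimulateCt:
    def test_zero_noise_recovers_true_dct_exactly(self):
        params = CtSimParams(true_dct={"CDH1": 3.82, "Mdr1": 4.69},
                             replicate_sd=0.0, seed=1)
        dct = delta_ct(CtTable(simulate_ct_table(params)))
        by_gene = dct.groupby("gene")["dct"].mean()
        assert by_gene["CDH1"] == pytest.approx(3.82, abs=1e-12)
        assert by_gene["Mdr1"] == pytest.approx(4.69, abs=1e-12)

    def test_housekeeping_gene_dct_is_zero(self):
        params = CtSimParams(true_dct={"CDH1": 3.82}, replicate_sd=0.4, seed=1)
        dct = delta_ct(CtTable(simulate_ct_table(params)))
        assert np.all(dct[dct["gene"] == "GAPDH"]["dct"] == 0)

    def test_mean_recovered_dct_unbiased_over_many_seeds(self):
        """CLT check: the seed-averaged recovered dCt converges to truth."""
        true = 5.16
        estimates = []
        for seed in range(500):
            params = CtSimParams(true_dct={"GENE": true}, replicate_sd=0.3,
                                 n_replicates=3, seed=seed)
            dct = delta_ct(CtTable(simulate_ct_table(params)))
            estimates.append(dct[dct["gene"] == "GENE"]["dct"].mean())
        assert np.mean(estimates) == pytest.approx(true, abs=0.05)
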