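"""PBPK engine: steady state, mass balance, linear-limit oracle, NCA,
calibration and the clearance phenomenology of target-mediated disposition."""

import numpy as np
import pytest
from scipy.linalg import expm

import mabsim as ms
from mabsim import (CalibrationError, DoseEvent, DrugParameters,
                    InvalidArgumentError, PhysiologyParameters,
                    TMDDParameters)
from mabsim.pbpk import (I_CE_EN, I_CI_EN, I_CP_EN, I_CP_EX, I_RTOT,
                        N_STATES, SimulationResult, initialize_endogenous_steady_state,
                        rhs)

W = ms.REFERENCE_WEIGHT_KG


def linear_rate_matrix(phys):
    """Oracle: 3-compartment rate matrix when FcRn protection is absent.

    With no receptor nothing is recycled, so endosomal drug is entirely
    free and the system (plasma, endosome, interstitium) is linear.
    """
    a = phys.delta / (1 + phys.delta)
    b = 1 / (1 + phys.delta)
    kup_ve = phys.kup * phys.ve
    l_out = phys.l_lymph * (1 - phys.sigma_v)
    l_ret = phys.l_lymph * (1 - phys.sigma_i)
    return np.array([
        [-(l_out + kup_ve * a) / phys.vp, 0.0, l_ret / phys.vp],
        [kup_ve * a / phys.ve, -(phys.cl_cat + 0.0) / phys.ve,
         kup_ve * b / phys.ve],
        [l_out / phys.vi, 0.0, -(l_ret + kup_ve * b) / phys.vi],
    ])


class TestDosing:
    def test_infusion_amount_from_molecular_weight(self, drug):
        d = DoseEvent(0.0, 1.0, route="iv_infusion", infusion_duration=1.0)
        assert d.amount_umol(70.0, drug.mw) == pytest.approx(0.4703,
                                                             abs=5e-5)

    def test_unknown_route_rejected(self):
        with pytest.raises(ms.ConfigurationError):
            DoseEvent(0.0, 1.0, route="intrathecal")

    def test_dose_beyond_horizon_rejected(self, phys, drug):
        with pytest.raises(InvalidArgumentError):
            ms.simulate(phys, drug, None, None, [DoseEvent(100.0, 1.0)], 50.0)


class TestSteadyState:
    def test_rhs_vanishes_at_drug_free_steady_state(self, phys, drug,
                                                    tmdd_p):
        in_en, y0 = initialize_endogenous_steady_state(phys, drug)
        y0[I_RTOT] = tmdd_p.rmax
        dy = rhs(0.0, y0, phys, drug, tmdd_p, None, in_en)
        assert np.max(np.abs(dy)) < 1e-9

    def test_drug_free_hold_for_1000_h(self, phys, drug, tmdd_p, disease_p):
        res = ms.simulate(phys, drug, tmdd_p, disease_p, [], 1000.0,
                          output_step=10.0)
        for idx in (I_CP_EN, I_CI_EN, I_CE_EN):
            drift = np.abs(res.states[:, idx] / res.states[0, idx] - 1.0)
            assert drift.max() < 1e-3  # < 0.1%
        assert np.all(res.cp_ex_uM == 0.0)
        assert np.allclose(res.pasi, disease_p.y0, atol=1e-9)

    def test_zero_catabolism_needs_no_synthesis(self, drug):
        p = PhysiologyParameters(cl_cat=0.0)
        in_en, _ = initialize_endogenous_steady_state(p, drug)
        assert in_en == pytest.approx(0.0, abs=1e-12)

    def test_endogenous_tracer_half_life_is_igg_like(self, phys):
        """A tracer with the endogenous FcRn affinity decays with a
        2-4 week terminal half-life under the calibrated physiology."""
        tracer = DrugParameters(kd_ex=DrugParameters().kd_en)
        doses = [DoseEvent(0.0, 1.0)]
        res = ms.simulate(phys, tracer, None, None, doses, 10000.0,
                          output_step=8.0)
        amt = doses[0].amount_umol(W, tracer.mw)
        nca = ms.nca_clearance(res, amt)
        assert 14.0 <= nca["terminal_half_life_h"] / 24.0 <= 28.0


class TestRoutingLimits:
    def test_fr_one_sends_no_recycled_drug_to_interstitium(self, drug):
        phys = PhysiologyParameters(fr=1.0)
        y = np.zeros(N_STATES)
        y[I_CP_EX] = 0.1
        y[2] = 5.0  # endosomal drug, so recycling flux is active
        dy = rhs(0.0, y, phys, drug, None, None, 0.0)
        l_out = phys.l_lymph * (1 - phys.sigma_v)
        l_ret = phys.l_lymph * (1 - phys.sigma_i)
        kup_b = phys.kup * phys.ve / (1 + phys.delta)
        # interstitial balance reduces to pure convection/uptake
        expected = (l_out * y[I_CP_EX]) / phys.vi
        assert dy[1] == pytest.approx(expected, rel=1e-12)


class TestMassBalanceAndPositivity:
    @pytest.mark.parametrize("routes", ["infusion", "mixed"])
    def test_mass_balance_closed(self, phys, drug, tmdd_p, disease_p,
                                 routes):
        if routes == "infusion":
            doses = ms.make_regimen("gottlieb_escalating")
            t_end = 1400.0
        else:
            doses = [DoseEvent(0.0, 1.0, route="iv_bolus"),
                     DoseEvent(48.0, 1.0, route="sc_first_order",
                               ka=0.02, f=0.6),
                     DoseEvent(240.0, 0.5, route="iv_infusion",
                               infusion_duration=2.0)]
            t_end = 800.0
        res = ms.simulate(phys, drug, tmdd_p, disease_p, doses, t_end,
                          output_step=4.0)
        assert res.massbal_residual.max() < 1e-3
        assert np.all(res.states >= 0.0)

    def test_zero_dose_everything_stays_zero(self, phys, drug):
        res = ms.simulate(phys, drug, None, None, [], 200.0, output_step=5.0)
        assert np.all(res.states[:, :3] == 0.0)
        assert np.all(res.massbal_residual == 0.0)


class TestLinearLimit:
    def test_matrix_exponential_oracle(self, drug):
        """No FcRn, no TMDD: the engine must match the analytic linear
        3-compartment solution within 0.5% down to 0.1% of C0."""
        phys = PhysiologyParameters(fcrn_total=0.0, igg_en_baseline=1e-6,
                                    cl_cat=0.05)
        dose = DoseEvent(0.0, 1.0, route="iv_bolus")
        amt = dose.amount_umol(W, drug.mw)
        res = ms.simulate(phys, drug, None, None, [dose], 600.0,
                          output_step=2.0)
        M = linear_rate_matrix(phys)
        c0 = np.array([amt / phys.vp, 0.0, 0.0])
        ref = np.array([(expm(M * t) @ c0)[0] for t in res.time_h])
        mask = ref > 1e-3 * c0[0]
        rel = np.abs(res.cp_ex_uM[mask] - ref[mask]) / ref[mask]
        assert rel.max() < 5e-3

    def test_auc_matches_steady_state_clearance_oracle(self, drug):
        """Plasma AUC equals dose over the linear-algebra clearance."""
        phys = PhysiologyParameters(fcrn_total=0.0, igg_en_baseline=1e-6,
                                    cl_cat=0.05)
        dose = DoseEvent(0.0, 1.0, route="iv_bolus")
        amt = dose.amount_umol(W, drug.mw)
        res = ms.simulate(phys, drug, None, None, [dose], 2500.0,
                          output_step=2.0)
        M = linear_rate_matrix(phys)
        cp_ss = np.linalg.solve(M, -np.array([1.0 / phys.vp, 0.0, 0.0]))[0]
        cl_oracle = 1.0 / cp_ss
        nca = ms.nca_clearance(res, amt)
        assert nca["cl_L_per_h"] == pytest.approx(cl_oracle, rel=5e-3)


class TestNCA:
    def test_mono_exponential_closed_form(self):
        """C(t) = C0 e^{-kt} with bolus V*C0: CL must equal k*V."""
        k, v, c0 = 0.01, 3.0, 2.0
        t = np.arange(0.0, 1200.0, 1.0)
        c = c0 * np.exp(-k * t)
        n = len(t)
        states = np.zeros((n, N_STATES))
        states[:, I_CP_EX] = c
        res = SimulationResult(
            time_h=t, states=states, weight_kg=W,
            administered_umol=np.full(n, v * c0), rfree_uM=np.zeros(n),
            rbound_uM=np.zeros(n), rtot_pct_baseline=np.zeros(n),
            rfree_pct_baseline=np.zeros(n), occupancy_drive=np.zeros(n),
            cp_ex_ug_per_ml=c, massbal_residual=np.zeros(n))
        nca = ms.nca_clearance(res, v * c0)
        assert nca["cl_L_per_h"] == pytest.approx(k * v, rel=5e-3)
        assert nca["terminal_half_life_h"] == pytest.approx(np.log(2) / k,
                                                            rel=1e-6)

    def test_clearance_unit_report(self, single_1_no_tmdd, dose_1_amount):
        nca = ms.nca_clearance(single_1_no_tmdd, dose_1_amount)
        assert nca["cl_ml_per_day_per_kg"] == pytest.approx(
            nca["cl_L_per_h"] * 1000 * 24 / W, rel=1e-12)

    def test_non_decaying_tail_raises(self):
        t = np.arange(0.0, 100.0, 1.0)
        c = np.linspace(1.0, 2.0, len(t))
        states = np.zeros((len(t), N_STATES))
        states[:, I_CP_EX] = c
        res = SimulationResult(
            time_h=t, states=states, weight_kg=W,
            administered_umol=np.ones(len(t)), rfree_uM=np.zeros(len(t)),
            rbound_uM=np.zeros(len(t)), rtot_pct_baseline=np.zeros(len(t)),
            rfree_pct_baseline=np.zeros(len(t)),
            occupancy_drive=np.zeros(len(t)), cp_ex_ug_per_ml=c,
            massbal_residual=np.zeros(len(t)))
        with pytest.raises(ms.ExtrapolationError):
            ms.nca_clearance(res, 1.0)


class TestTMDDPhenomenology:
    def test_tmdd_raises_clearance(self, single_1_tmdd, single_1_no_tmdd,
                                   dose_1_amount):
        cl_with = ms.nca_clearance(single_1_tmdd, dose_1_amount)["cl_L_per_h"]
        cl_without = ms.nca_clearance(single_1_no_tmdd,
                                      dose_1_amount)["cl_L_per_h"]
        assert cl_with > cl_without

    def test_dose_dependent_clearance_ordering(self, phys, drug, tmdd_p,
                                               single_1_tmdd,
                                               single_1_no_tmdd,
                                               dose_1_amount):
        """Saturable target-mediated elimination: CL falls with dose and
        stays above the no-TMDD floor."""
        cls = {1: ms.nca_clearance(single_1_tmdd,
                                   dose_1_amount)["cl_L_per_h"]}
        for mgkg in (3, 10):
            doses = [DoseEvent(0.0, float(mgkg))]
            res = ms.simulate(phys, drug, tmdd_p, None, doses, 6000.0,
                              output_step=4.0)
            amt = doses[0].amount_umol(W, drug.mw)
            cls[mgkg] = ms.nca_clearance(res, amt)["cl_L_per_h"]
        cl_off = ms.nca_clearance(single_1_no_tmdd,
                                  dose_1_amount)["cl_L_per_h"]
        assert cls[1] > cls[3] > cls[10] > cl_off


class TestCalibration:
    def test_default_clcat_is_self_consistent(self, phys, drug,
                                              single_1_no_tmdd,
                                              dose_1_amount):
        """The shipped default cl_cat reproduces the reference clearance."""
        cl = ms.nca_clearance(single_1_no_tmdd, dose_1_amount)["cl_L_per_h"]
        assert cl == pytest.approx(drug.cl_ref, rel=0.01)

    def test_calibration_round_trip(self, phys, drug):
        cl_cat = ms.calibrate_clcat(phys, drug)
        p = phys.replace(cl_cat=cl_cat)
        doses = [DoseEvent(0.0, 1.0)]
        res = ms.simulate(p, drug, None, None, doses, 6000.0, output_step=4.0)
        amt = doses[0].amount_umol(W, drug.mw)
        cl = ms.nca_clearance(res, amt)["cl_L_per_h"]
        assert cl == pytest.approx(drug.cl_ref, rel=0.01)

    def test_per_weight_clearance_target(self, drug):
        assert ms.convert_units(drug.cl_ref, "L_per_h", "ml_per_day_per_kg",
                                weight_kg=70.0) == pytest.approx(7.78,
                                                                 abs=0.005)

    def test_more_fcrn_means_more_protection(self, phys, drug,
                                             dose_1_amount):
        p2 = phys.replace(fcrn_total=2 * phys.fcrn_total)
        doses = [DoseEvent(0.0, 1.0)]
        res = ms.simulate(p2, drug, None, None, doses, 6000.0,
                          output_step=4.0)
        cl = ms.nca_clearance(res, dose_1_amount)["cl_L_per_h"]
        assert cl < drug.cl_ref

    def test_weaker_fcrn_binding_never_lowers_clearance(self, phys, drug,
                                                        dose_1_amount):
        doses = [DoseEvent(0.0, 1.0)]
        cls = []
        for kd in (1.0, DrugParameters().kd_ex, 9.0):
            d = drug.replace(kd_ex=kd)
            res = ms.simulate(phys, d, None, None, doses, 6000.0,
                              output_step=4.0)
            cls.append(ms.nca_clearance(res, dose_1_amount)["cl_L_per_h"])
        assert cls[0] <= cls[1] <= cls[2]

    def test_unreachable_reference_reports_range(self, phys):
        greedy = DrugParameters(cl_ref=5.0)  # far above the uptake ceiling
        with pytest.raises(CalibrationError, match="achievable"):
            ms.calibrate_clcat(phys, greedy)
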