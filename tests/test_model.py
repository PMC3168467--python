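import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from gopk import (
    AVOGADRO,
    BlastDynamics,
    CellKineticParams,
    CLINICAL_BLASTS,
    CLINICAL_MEAN_PARAMS,
    CLINICAL_SYSTEMIC,
    DoseSchedule,
    InVitroConfig,
    IN_VITRO_PARAMS,
    blood_auc,
    intracellular_auc,
    one_compartment_concentration,
    saturating_total_cd33,
    simulate_in_vitro,
    simulate_patient,
)

rates = st.floats(min_value=1e-3, max_value=10.0)


class TestSaturatingClosedForm:
    def test_initial_value_is_baseline_expression(self):
        # T(0) = R_p/k_e = 2047/0.12
        assert saturating_total_cd33(0.0, IN_VITRO_PARAMS) == pytest.approx(
            17058.33, abs=0.01
        )

    def test_long_time_limit_is_production_over_internalization(self):
        # T(∞) = R_p/k_i = 2047/0.4
        assert saturating_total_cd33(1e6, IN_VITRO_PARAMS) == pytest.approx(
            2047.0 / 0.4, rel=1e-12
        )

    def test_zero_production_decays_exponentially(self):
        p = CellKineticParams(R_p=0.0, k_e=0.12, k_i=0.4, k_b=0.0, k_u=0.0)
        t = np.linspace(0, 6, 7)
        np.testing.assert_allclose(
            saturating_total_cd33(t, p), 0.0 * np.exp(-0.4 * t), atol=1e-12
        )

    def test_nonpositive_rates_rejected(self):
        p = CellKineticParams(R_p=100.0, k_e=0.0, k_i=0.4, k_b=0.0, k_u=0.0)
        with pytest.raises(ValueError, match="k_e"):
            saturating_total_cd33(1.0, p)
        p = CellKineticParams(R_p=100.0, k_e=0.1, k_i=0.0, k_b=0.0, k_u=0.0)
        with pytest.raises(ValueError, match="k_i"):
            saturating_total_cd33(1.0, p)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(r_p=st.floats(min_value=1.0, max_value=1e4), k_e=rates, k_i=rates)
    def test_matches_independent_numerical_integration(self, r_p, k_e, k_i):
        """The closed form solves dT/dt = R_p - k_i T, T(0) = R_p/k_e."""
        p = CellKineticParams(R_p=r_p, k_e=k_e, k_i=k_i, k_b=0.0, k_u=0.0)
        t = np.linspace(0.0, 6.0, 13)
        sol = solve_ivp(
            lambda _, y: r_p - k_i * y,
            (0.0, 6.0),
            [r_p / k_e],
            t_eval=t,
            rtol=1e-10,
            atol=1e-10 * r_p / k_e,
        )
        np.testing.assert_allclose(
            saturating_total_cd33(t, p), sol.y[0], rtol=1e-6
        )


class TestInVitroSystem:
    def test_no_drug_stays_at_baseline_steady_state(self):
        cfg = InVitroConfig(A_0=0.0)
        traj = simulate_in_vitro(IN_VITRO_PARAMS, cfg)
        baseline = IN_VITRO_PARAMS.baseline_cd33
        np.testing.assert_allclose(traj.R, baseline, rtol=1e-6)
        np.testing.assert_allclose(traj.B, 0.0, atol=1e-9 * baseline)

    def test_saturating_exposure_binds_over_90_percent(self, saturating_cfg):
        traj = simulate_in_vitro(IN_VITRO_PARAMS, saturating_cfg)
        window = (traj.t >= 1.0) & (traj.t <= 6.0)
        assert traj.bound_fraction[window].min() > 0.9

    def test_total_cd33_tracks_saturating_approximation(self, saturating_cfg):
        # the reduced model neglects k_e·R against k_i·B; under saturation
        # the full system should stay within ~1% of the closed form
        traj = simulate_in_vitro(IN_VITRO_PARAMS, saturating_cfg)
        closed = saturating_total_cd33(traj.t, IN_VITRO_PARAMS)
        assert np.max(np.abs(traj.T - closed) / closed) < 0.02

    def test_closed_binding_system_conserves_drug(self):
        # with production and internalization off, n_A·v·A + N·B is constant
        p = CellKineticParams(R_p=0.0, k_e=0.0, k_i=0.0, k_b=1.1e12, k_u=397.1)
        cfg = InVitroConfig.from_ug_per_ml(0.3, R_0=15000.0)
        traj = simulate_in_vitro(p, cfg)
        total = AVOGADRO * cfg.v * traj.A + cfg.N * traj.B
        assert np.max(np.abs(total / total[0] - 1.0)) < 1e-6

    def test_states_remain_nonnegative(self, saturating_cfg):
        traj = simulate_in_vitro(IN_VITRO_PARAMS, saturating_cfg)
        scale = IN_VITRO_PARAMS.baseline_cd33
        for series in (traj.A, traj.R, traj.B):
            assert series.min() > -1e-9 * max(scale, 1.0)


class TestInVivoSystem:
    def test_zero_dose_baseline(self):
        traj = simulate_patient(
            CLINICAL_MEAN_PARAMS,
            CLINICAL_SYSTEMIC,
            CLINICAL_BLASTS,
            DoseSchedule(events=()),
            horizon=48.0,
        )
        assert intracellular_auc(traj) == 0.0
        assert blood_auc(traj) == 0.0
        np.testing.assert_allclose(
            traj.R, CLINICAL_MEAN_PARAMS.baseline_cd33, rtol=1e-6
        )

    def test_horizon_must_cover_schedule(self):
        with pytest.raises(ValueError, match="horizon"):
            simulate_patient(
                CLINICAL_MEAN_PARAMS,
                CLINICAL_SYSTEMIC,
                CLINICAL_BLASTS,
                DoseSchedule.aml19_nonfractionated(),
                horizon=100.0,
            )

    def test_standard_dose_saturates_cd33_first_12h(self, mean_trajectory):
        window = (mean_trajectory.t >= 1.0) & (mean_trajectory.t <= 12.0)
        assert np.nanmin(mean_trajectory.bound_fraction[window]) > 0.9

    def test_intracellular_course_rises_plateaus_then_decays(
        self, mean_trajectory
    ):
        """S rises sharply on dosing, holds a transient plateau, then decays."""
        t, S = mean_trajectory.t, mean_trajectory.S
        peak_time = t[np.argmax(S)]
        assert peak_time < 24.0
        s_day2 = S[np.searchsorted(t, 48.0)]
        s_day6 = S[np.searchsorted(t, 144.0)]
        s_end = S[-1]
        assert s_day6 > 0.5 * s_day2  # plateau: slow loss over days 2–6
        assert s_end < 0.1 * s_day2  # decayed by day 28

    def test_matches_one_compartment_closed_form_without_blasts(self):
        traj = simulate_patient(
            CLINICAL_MEAN_PARAMS,
            CLINICAL_SYSTEMIC,
            BlastDynamics(N_0=0.0, alpha=0.104),
            DoseSchedule.single(9.0),
            horizon=120.0,
        )
        closed = one_compartment_concentration(traj.t, 9.0, CLINICAL_SYSTEMIC)
        mask = traj.t > 0.05
        rel = np.abs(traj.A_ng_ml[mask] - closed[mask]) / closed[mask]
        assert rel.max() < 1e-6

    def test_blood_auc_linear_in_dose_without_blasts(self):
        blastfree = BlastDynamics(N_0=0.0, alpha=0.104)
        aucs = []
        for dose in (4.5, 9.0):
            traj = simulate_patient(
                CLINICAL_MEAN_PARAMS, CLINICAL_SYSTEMIC, blastfree,
                DoseSchedule.single(dose), horizon=336.0,
            )
            aucs.append(blood_auc(traj))
        assert aucs[1] == pytest.approx(2.0 * aucs[0], rel=1e-6)

    def test_blast_burden_reduces_blood_exposure(self, mean_baseline):
        heavy = CLINICAL_BLASTS.replace(N_0=10 * CLINICAL_BLASTS.N_0)
        auc_mean = blood_auc(mean_baseline.simulate())
        auc_heavy = blood_auc(mean_baseline.simulate(blasts=heavy))
        assert auc_heavy < auc_mean

    def test_iauc_monotone_in_efflux_and_dose(self, mean_baseline):
        """I-AUC falls with efflux rate and rises with dose (log grids)."""
        kd_grid = CLINICAL_MEAN_PARAMS.k_d * np.logspace(-1, 1, 10)
        iaucs = [
            mean_baseline.iauc(cell=CLINICAL_MEAN_PARAMS.replace(k_d=kd))
            for kd in kd_grid
        ]
        assert np.all(np.diff(iaucs) < 0)
        dose_grid = 9.0 * np.logspace(-1, 1, 10)
        iaucs = [
            mean_baseline.iauc(schedule=DoseSchedule.single(d))
            for d in dose_grid
        ]
        assert np.all(np.diff(iaucs) > 0)

    def test_trajectory_nonnegative_and_summary_finite(self, mean_trajectory):
        for series in (
            mean_trajectory.A,
            mean_trajectory.R,
            mean_trajectory.B,
            mean_trajectory.S,
            mean_trajectory.N,
        ):
            assert series.min() >= 0.0
        summary = mean_trajectory.summary()
        assert all(np.isfinite(v) for v in summary.values())


class TestOneCompartmentClosedForm:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        k=st.floats(min_value=1e-4, max_value=1.0),
        v=st.floats(min_value=1.0, max_value=50.0),
        dose=st.floats(min_value=0.5, max_value=20.0),
    )
    def test_matches_numerical_integration(self, k, v, dose):
        sys = CLINICAL_SYSTEMIC.replace(k=k, V=v)
        rate = sys.dose_to_moles(dose) / sys.tau / v

        t = np.array([0.5, 1.0, sys.tau, 5.0, 24.0, 96.0])
        num = []
        y = [0.0]
        t0 = 0.0
        for seg_end, seg_rate in [(sys.tau, rate), (120.0, 0.0)]:
            sol = solve_ivp(
                lambda _, y, r=seg_rate: r - k * y[0],
                (t0, seg_end), y, rtol=1e-11, atol=1e-16,
                dense_output=True,
            )
            for ti in t[(t > t0) & (t <= seg_end)]:
                num.append(sol.sol(ti)[0])
            y = sol.y[:, -1]
            t0 = seg_end
        from gopk import molar_to_ng_per_ml

        expected = molar_to_ng_per_ml(np.array(num), sys.MW)
        got = one_compartment_concentration(t, dose, sys)
        # absolute floor: the oracle's own tolerance limits deep-decay tails
        np.testing.assert_allclose(
            got, expected, rtol=1e-6, atol=1e-6 * got.max()
        )
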