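import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gopk import (
    BlastDynamics,
    CLINICAL_BLASTS,
    CLINICAL_MEAN_PARAMS,
    CLINICAL_SYSTEMIC,
    CellKineticParams,
    DoseSchedule,
    EffluxAssay,
    IN_VITRO_PARAMS,
    MeasurementSet,
    NonSaturatingBindingFit,
    OneCompartmentPKFit,
    SaturatingCD33Fit,
    efflux_rate_from_dye_ratio,
    fit_blast_burden,
    fit_nonsaturating,
    fit_one_compartment,
    fit_saturating,
    one_compartment_concentration,
    saturating_total_cd33,
    simulate_patient,
)
from gopk.synthetic import (
    NoiseSpec,
    generate_blood_pk,
    generate_nonsaturating_experiment,
    generate_saturating_experiment,
)


class TestEffluxRate:
    def test_no_efflux(self):
        assert efflux_rate_from_dye_ratio(EffluxAssay(ratio=1.0)) == 0.0

    def test_inverts_mean_clinical_rate(self):
        # ratio exp(0.34 * 1.5) = e^0.51 ≈ 1.6653 maps back to k_d = 0.34
        assay = EffluxAssay(ratio=float(np.exp(0.51)))
        assert efflux_rate_from_dye_ratio(assay) == pytest.approx(0.34)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError, match="negative efflux"):
            efflux_rate_from_dye_ratio(EffluxAssay(ratio=0.8))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k_d=st.floats(min_value=0.0, max_value=3.0))
    def test_round_trips_forward_model(self, k_d):
        assay = EffluxAssay(ratio=float(np.exp(1.5 * k_d)))
        assert efflux_rate_from_dye_ratio(assay) == pytest.approx(k_d, abs=1e-12)


class TestMeasurementSet:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            MeasurementSet(kind="bogus", records=pd.DataFrame(
                {"observable": ["T"], "value": [1.0]}))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            MeasurementSet(kind="blood_pk", records=pd.DataFrame(
                {"observable": ["A_blood"], "value": [-1.0]}))

    def test_csv_round_trip(self, tmp_path):
        ms = generate_saturating_experiment(
            IN_VITRO_PARAMS, noise=NoiseSpec(cv=0.0))
        path = tmp_path / "sat.csv"
        ms.to_csv(path)
        back = MeasurementSet.from_csv(path)
        assert back.kind == ms.kind
        np.testing.assert_allclose(
            back.records["value"], ms.records["value"], rtol=1e-12)

    def test_truncated_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("kind,time_h\nsaturating_timecourse,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            MeasurementSet.from_csv(path)


class TestSaturatingFit:
    def test_noise_free_round_trip_within_one_percent(self):
        ms = generate_saturating_experiment(
            IN_VITRO_PARAMS, noise=NoiseSpec(cv=0.0))
        res = fit_saturating(ms, seed=0)
        assert res.converged
        for name in ("R_p", "k_e", "k_i"):
            assert res.estimates[name] == pytest.approx(
                getattr(IN_VITRO_PARAMS, name), rel=0.01)

    def test_two_time_points_unidentifiable(self):
        t = np.array([0.0, 3.0])
        y = saturating_total_cd33(t, IN_VITRO_PARAMS)
        with pytest.raises(ValueError, match="3 distinct time"):
            SaturatingCD33Fit().fit(t, y)

    def test_flat_observations_flagged_nonconverged(self):
        t = np.array([0.0, 1.0, 3.0, 6.0])
        est = SaturatingCD33Fit(seed=0).fit(t, np.full(4, 5000.0))
        assert not est.converged_

    def test_deterministic_given_seed(self):
        ms = generate_saturating_experiment(
            IN_VITRO_PARAMS, noise=NoiseSpec(cv=10.0, seed=3))
        r1 = fit_saturating(ms, seed=7)
        r2 = fit_saturating(ms, seed=7)
        assert r1.estimates == r2.estimates

    def test_noisy_recovery_envelope(self):
        """Median relative error over seeded 10%-noise replicates.

        With only four sampling times for three parameters, 10%
        multiplicative noise leaves the asymptote R_p/k_i weakly
        determined; the bounds below are the envelope measured once on
        this exact seeded study (medians 0.44/0.41/0.31) plus margin.
        """
        errs = {"R_p": [], "k_e": [], "k_i": []}
        for seed in range(40):
            ms = generate_saturating_experiment(
                IN_VITRO_PARAMS, noise=NoiseSpec(cv=10.0, seed=seed))
            res = fit_saturating(ms, seed=seed)
            for name in errs:
                errs[name].append(
                    abs(res.estimates[name] / getattr(IN_VITRO_PARAMS, name) - 1))
        frozen = {"R_p": 0.50, "k_e": 0.47, "k_i": 0.36}
        for name, values in errs.items():
            assert np.median(values) < frozen[name], name


class TestNonSaturatingFit:
    def test_noise_free_round_trip_within_five_percent(self):
        ms = generate_nonsaturating_experiment(
            IN_VITRO_PARAMS, noise=NoiseSpec(cv=0.0))
        res = fit_nonsaturating(ms, fixed=IN_VITRO_PARAMS, seed=0, n_starts=4)
        assert res.estimates["k_b"] == pytest.approx(1.1e12, rel=0.05)
        assert res.estimates["k_u"] == pytest.approx(397.1, rel=0.05)

    def test_equilibrium_ratio_recovered_despite_rate_rescaling(self):
        """Data from 10× faster binding kinetics at the same K_D pins the
        dissociation constant even though individual rates are ridge-like."""
        scaled = IN_VITRO_PARAMS.replace(k_b=1.1e13, k_u=3971.0)
        ms = generate_nonsaturating_experiment(scaled, noise=NoiseSpec(cv=0.0))
        res = fit_nonsaturating(ms, fixed=IN_VITRO_PARAMS, seed=0, n_starts=4)
        assert res.estimates["K_D"] == pytest.approx(
            scaled.k_u / scaled.k_b, rel=0.05)

    def test_empty_dose_list_rejected(self):
        with pytest.raises(ValueError):
            generate_nonsaturating_experiment(IN_VITRO_PARAMS, doses=[])

    def test_saturating_doses_trigger_warning(self):
        est = NonSaturatingBindingFit(fixed=IN_VITRO_PARAMS, seed=0, n_starts=1)
        doses = np.array([5.0, 10.0])
        t_total = saturating_total_cd33(0.25, IN_VITRO_PARAMS)
        with pytest.warns(UserWarning, match="saturating"):
            est.fit(doses, np.array([0.97, 0.99]) * t_total)


class TestOneCompartmentFit:
    def test_noise_free_round_trip_is_exact(self):
        times = np.linspace(0.25, 120.0, 20)
        y = one_compartment_concentration(times, 9.0, CLINICAL_SYSTEMIC)
        est = OneCompartmentPKFit(dose_mg_m2=9.0, seed=0).fit(times, y)
        assert est.k_ == pytest.approx(0.01919, rel=1e-3)
        assert est.V_ == pytest.approx(6.2, rel=1e-3)

    def test_flat_profile_estimates_negligible_elimination(self):
        times = np.linspace(0.25, 120.0, 20)
        sys0 = CLINICAL_SYSTEMIC.replace(k=0.0)
        y = one_compartment_concentration(times, 9.0, sys0)
        est = OneCompartmentPKFit(dose_mg_m2=9.0, seed=0).fit(times, y)
        assert est.k_ < 1e-4

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            OneCompartmentPKFit().fit(np.array([1.0]), np.array([100.0]))


class TestBlastBurdenFit:
    times = np.concatenate([np.linspace(0.5, 6, 8), np.linspace(8, 120, 15)])

    def test_noise_free_round_trip_within_five_percent(self):
        ms = generate_blood_pk(
            CLINICAL_MEAN_PARAMS, CLINICAL_SYSTEMIC, CLINICAL_BLASTS,
            DoseSchedule.single(9.0), times=self.times,
            noise=NoiseSpec(cv=0.0),
        )
        res = fit_blast_burden(
            ms, cell=CLINICAL_MEAN_PARAMS, sys=CLINICAL_SYSTEMIC, seed=0,
            n_starts=2,
        )
        assert res.estimates["N_0"] == pytest.approx(2.47e12, rel=0.05)
        assert res.estimates["alpha"] == pytest.approx(0.104, rel=0.05)

    def test_blast_free_data_yields_negligible_burden(self):
        ms = generate_blood_pk(
            CLINICAL_MEAN_PARAMS, CLINICAL_SYSTEMIC,
            BlastDynamics(N_0=0.0, alpha=0.104), DoseSchedule.single(9.0),
            times=self.times, noise=NoiseSpec(cv=0.0),
        )
        res = fit_blast_burden(
            ms, cell=CLINICAL_MEAN_PARAMS, sys=CLINICAL_SYSTEMIC, seed=0,
            n_starts=2,
        )
        assert res.estimates["N_0"] < 1e9
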