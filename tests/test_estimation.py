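import copy

import numpy as np
import pandas as pd
import pytest

from erysim.estimation import (
    EstimationConfig,
    IneligibleDataError,
    calibrate_stem_influx,
    cost,
    estimate,
    prepare_fit_data,
    split_adaptation_prediction,
)
from erysim.observation import hgb_from_count
from erysim.pde_solver import discrete_steady_state, total_rbc
from erysim.records_io import TreatmentRecord
from erysim.synthetic_cohort import CohortConfig, generate_patient


@pytest.fixture(scope="module")
def clean_patient():
    """A noise-free virtual patient: the global cost minimum is the truth."""
    return generate_patient(2024, CohortConfig(noise_cv=0.0))


def _theta(p):
    return np.array([p.t_rbc, p.e_endo, p.t_half, p.s_alpha, p.s_v])


def _toy_records(n, n_doses=2, start_hgb=10.0, spacing_days=2.33):
    base = pd.Timestamp("2013-01-07 08:00")
    records = []
    for i in range(n):
        s = base + pd.Timedelta(days=i * spacing_days)
        records.append(TreatmentRecord(
            patient_id="T", session_start=s, session_end=s + pd.Timedelta(hours=3.5),
            pre_hgb=start_hgb, post_hgb=start_hgb + 0.5,
            esa_dose=2000.0 if i < n_doses else 0.0,
        ))
    return records


class TestCalibration:
    def test_fixed_point(self, healthy_params, profile):
        s_ref = 1.6e7
        hgb_ref = hgb_from_count(
            total_rbc(discrete_steady_state(healthy_params, healthy_params.e_endo, s0=s_ref)),
            profile.tbv_post, healthy_params.constants.mch_pg,
        )
        s0 = calibrate_stem_influx(healthy_params, profile, hgb_ref)
        assert s0 == pytest.approx(s_ref, rel=1e-12)

    def test_linearity_in_target(self, healthy_params, profile):
        s_a = calibrate_stem_influx(healthy_params, profile, 6.0)
        s_b = calibrate_stem_influx(healthy_params, profile, 12.0)
        assert s_b == pytest.approx(2.0 * s_a, rel=1e-12)

    def test_closed_loop_hits_target(self, healthy_params, profile):
        target = 11.2
        s0 = calibrate_stem_influx(healthy_params, profile, target)
        achieved = hgb_from_count(
            total_rbc(discrete_steady_state(healthy_params, healthy_params.e_endo, s0=s0)),
            profile.tbv_post, healthy_params.constants.mch_pg,
        )
        assert abs(achieved - target) < 1e-6

    def test_target_outside_range_rejected(self, healthy_params, profile):
        with pytest.raises(ValueError):
            calibrate_stem_influx(healthy_params, profile, 25.0)


class TestCost:
    def test_zero_at_true_parameters(self, clean_patient):
        """Self-consistency: replaying the recorded doses against the true
        parameters reproduces the noise-free records."""
        data = prepare_fit_data(clean_patient.records)
        value = cost(_theta(clean_patient.true_params), data, clean_patient.profile)
        assert value < 1e-12

    def test_invariant_to_record_order(self, clean_patient):
        data = prepare_fit_data(clean_patient.records)
        shuffled = copy.copy(list(clean_patient.records))
        np.random.default_rng(3).shuffle(shuffled)
        data_shuffled = prepare_fit_data(shuffled)
        theta = _theta(clean_patient.true_params) * 1.07
        assert cost(theta, data, clean_patient.profile) == pytest.approx(
            cost(theta, data_shuffled, clean_patient.profile), rel=1e-12)

    def test_duplicated_measurements_double_the_cost(self, clean_patient):
        # duplicate every measurement row (dose-free copies, so the simulated
        # trajectory is unchanged): every residual appears twice
        theta = _theta(clean_patient.true_params) * 1.05
        duplicates = []
        for r in clean_patient.records:
            d = copy.copy(r)
            d.esa_dose = 0.0
            d.event_kind = "none"
            d.event_magnitude = 0.0
            duplicates.append(d)
        single = cost(theta, prepare_fit_data(clean_patient.records), clean_patient.profile)
        both = cost(theta, prepare_fit_data(list(clean_patient.records) + duplicates),
                    clean_patient.profile)
        assert both == pytest.approx(2.0 * single, rel=1e-12)

    def test_lifespan_perturbation_increases_cost(self, clean_patient):
        """Local identifiability probe: +20% on T_RBC must be visible."""
        data = prepare_fit_data(clean_patient.records)
        theta = _theta(clean_patient.true_params)
        base = cost(theta, data, clean_patient.profile)
        theta_off = theta.copy()
        theta_off[0] *= 1.2
        assert cost(theta_off, data, clean_patient.profile) > base + 1e-3

    def test_failure_maps_to_finite_penalty(self, clean_patient):
        data = prepare_fit_data(clean_patient.records)
        value = cost(np.array([-10.0, 8.0, 6.0, 0.01, 0.03]), data, clean_patient.profile)
        assert np.isfinite(value) and value >= 1e9


class TestSplit:
    def test_all_within_baseline(self):
        adaptation, prediction = split_adaptation_prediction(_toy_records(10))
        assert len(adaptation) == 10 and prediction == []

    def test_boundary_day_goes_to_prediction(self):
        records = _toy_records(2, spacing_days=150.0)
        adaptation, prediction = split_adaptation_prediction(records, 150.0)
        assert len(adaptation) == 1 and len(prediction) == 1

    def test_prediction_span(self):
        records = _toy_records(104, spacing_days=2.33)  # ~240 days
        adaptation, prediction = split_adaptation_prediction(records, 150.0)
        t_pred = (prediction[-1].session_end - prediction[0].session_end).days
        assert 85 <= t_pred <= 91
        assert len(adaptation) + len(prediction) == 104

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_adaptation_prediction([])


@pytest.fixture(scope="module")
def quick_config():
    return EstimationConfig(n_starts=1, n_screen=8, max_iter=60,
                            max_restarts=2, seed=5)


class TestEstimate:
    def test_too_few_doses_rejected(self, clean_patient, quick_config):
        records = [copy.copy(r) for r in clean_patient.records]
        for r in records[1:]:
            r.esa_dose = 0.0
        with pytest.raises(IneligibleDataError):
            estimate(records, clean_patient.profile, quick_config)

    def test_too_few_measurements_rejected(self, clean_patient, quick_config):
        with pytest.raises(IneligibleDataError):
            estimate(clean_patient.records[:30], clean_patient.profile, quick_config)

    def test_deterministic_given_seed(self, clean_patient, quick_config):
        r1 = estimate(clean_patient.records, clean_patient.profile, quick_config)
        r2 = estimate(clean_patient.records, clean_patient.profile, quick_config)
        assert r1.cost == r2.cost
        np.testing.assert_array_equal(_theta(r1.params_hat), _theta(r2.params_hat))

    def test_never_worse_than_any_run(self, clean_patient, quick_config):
        res = estimate(clean_patient.records, clean_patient.profile, quick_config)
        assert res.cost <= min(run.cost for run in res.runs)
        assert res.n_function_evals >= sum(run.n_evals for run in res.runs)
        assert res.mape_adaptation >= 0.0
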