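"""Covariate equations, population maximum-likelihood fit, a priori prediction."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mripbpk.covariate import (
    CovariateError,
    CovariateModel,
    FitSettings,
    apply_covariates,
    covariate_arrays,
    fit_population,
    predict_cohort,
    predict_individual,
)
from mripbpk.pbpk import EGFR_CONC, TumorPBPKParams
from mripbpk.synthetic import NoiseModel, default_groups, default_truth, generate_cohort

FAST = FitSettings(sim_rtol=1e-6, xatol=1e-4, fatol=1e-8, maxfev=300, n_starts=1)


def ktrans_model(theta_q=0.02, theta_sigma=50.0):
    return CovariateModel(structure="ktrans", theta_q=(theta_q,),
                          theta_sigma=(theta_sigma,))


class TestApplyCovariates:
    def test_zero_sigma_slope_gives_fully_reflective_wall(self, base_params):
        m = ktrans_model(theta_sigma=0.0)
        p = apply_covariates(m, 0.01, 0.0, base_params)
        assert p.sigma_v == 1.0

    def test_reciprocal_form_arithmetic(self, base_params):
        # theta_sigma * Ktrans = 100 min * 0.01 /min = 1 -> sigma = 1/2
        p = apply_covariates(ktrans_model(theta_sigma=100.0), 0.01, 0.0,
                             base_params)
        assert p.sigma_v == pytest.approx(0.5)
        assert p.q_tu == pytest.approx(0.02 * 0.01)

    @given(kt=st.floats(1e-6, 1.0), ts=st.floats(0.0, 1e4))
    def test_sigma_always_in_unit_interval(self, kt, ts):
        base = TumorPBPKParams()
        p = apply_covariates(ktrans_model(theta_sigma=ts), kt, 0.0, base)
        assert 0.0 < p.sigma_v <= 1.0

    def test_higher_ktrans_gives_more_permeable_faster_perfused_tumor(
        self, base_params
    ):
        lo = apply_covariates(ktrans_model(), 1e-5, 0.0, base_params)
        hi = apply_covariates(ktrans_model(), 1e-2, 0.0, base_params)
        assert hi.q_tu > lo.q_tu
        assert hi.sigma_v < lo.sigma_v

    def test_two_covariate_additive_predictor(self, base_params):
        m = CovariateModel(structure="ktrans+vp", theta_q=(0.02, 0.001),
                           theta_sigma=(50.0, 2.0))
        p = apply_covariates(m, 0.01, 0.05, base_params)
        assert p.q_tu == pytest.approx(0.02 * 0.01 + 0.001 * 0.05)
        assert p.sigma_v == pytest.approx(1.0 / (1.0 + 50.0 * 0.01 + 2.0 * 0.05))

    def test_base_and_population_structures_pass_through(self, base_params):
        assert apply_covariates(CovariateModel(), 0.01, 0.0, base_params) == base_params
        pop = CovariateModel(structure="population", population_q=3e-5,
                             population_sigma=0.6)
        p = apply_covariates(pop, 0.01, 0.0, base_params)
        assert p.q_tu == 3e-5 and p.sigma_v == 0.6

    def test_zero_predictor_flagged_unpredictable(self, base_params):
        with pytest.raises(CovariateError, match="unpredictable"):
            apply_covariates(ktrans_model(), 0.0, 0.0, base_params)

    def test_negative_mri_parameter_rejected(self, base_params):
        with pytest.raises(CovariateError):
            covariate_arrays(ktrans_model(), np.array([-1e-3]), np.array([0.0]),
                             base_params)

    def test_structure_slope_length_validation(self):
        with pytest.raises(ValueError):
            CovariateModel(structure="ktrans", theta_q=(), theta_sigma=())
        with pytest.raises(ValueError):
            CovariateModel(structure="ktrans+vp", theta_q=(0.1,),
                           theta_sigma=(1.0,))
        with pytest.raises(ValueError):
            CovariateModel(structure="ktrans", theta_q=(-0.1,),
                           theta_sigma=(1.0,))


class TestFitPopulation:
    def test_base_structure_echoes_tabulated_values(self, base_params, plasma,
                                                    zero_noise):
        cohort = generate_cohort(default_groups(), default_truth(), base_params,
                                 zero_noise, seed=1)
        fit = fit_population(cohort, "base", base_params, plasma, FAST)
        assert fit.model.structure == "base"
        assert fit.n_params == 1  # residual scale only
        assert fit.n_fev == 0
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert len(fit.predictions) == 26

    def test_noise_free_recovery_within_one_percent(self, base_params, plasma,
                                                    zero_noise):
        truth = default_truth()
        cohort = generate_cohort(default_groups(), truth, base_params,
                                 zero_noise, seed=1, plasma=plasma)
        fit = fit_population(cohort, "ktrans", base_params, plasma,
                             FitSettings(sim_rtol=1e-8, xatol=1e-6,
                                         fatol=1e-11, maxfev=600, n_starts=1))
        assert fit.model.theta_q[0] == pytest.approx(truth.theta_q[0], rel=0.01)
        assert fit.model.theta_sigma[0] == pytest.approx(truth.theta_sigma[0],
                                                         rel=0.01)

    def test_fit_is_deterministic(self, base_params, plasma):
        cohort = generate_cohort(default_groups(), default_truth(), base_params,
                                 NoiseModel(obs_cv=0.2), seed=5)
        f1 = fit_population(cohort, "ktrans", base_params, plasma, FAST)
        f2 = fit_population(cohort, "ktrans", base_params, plasma, FAST)
        assert f1.model.theta_q == f2.model.theta_q
        assert f1.loglik == f2.loglik

    def test_binding_arm_rejected(self, base_params, plasma, zero_noise):
        cohort = generate_cohort(default_groups("target-binding"),
                                 default_truth(), base_params, zero_noise,
                                 seed=1)
        with pytest.raises(ValueError, match="non-binding"):
            fit_population(cohort, "ktrans", base_params, plasma, FAST)

    def test_unknown_structure_rejected(self, base_params, plasma, zero_noise):
        cohort = generate_cohort(default_groups(), default_truth(), base_params,
                                 zero_noise, seed=1)
        with pytest.raises(ValueError, match="unknown structure"):
            fit_population(cohort, "kep", base_params, plasma, FAST)


class TestPredict:
    def test_reduces_to_nonbinding_model_without_target(self, base_params,
                                                        plasma, zero_noise):
        cohort = generate_cohort(default_groups(), default_truth(), base_params,
                                 zero_noise, seed=1)
        rec = cohort[0]
        t_grid = np.linspace(0.0, rec.terminal_time_h * 60.0, 50)
        sim_model = predict_individual(default_truth(), rec, base_params,
                                       plasma, t_grid)
        sim_again = predict_individual(default_truth(), rec,
                                       replace(base_params, c_egfr=0.0),
                                       plasma, t_grid)
        np.testing.assert_allclose(sim_model.tumor_total_conc,
                                   sim_again.tumor_total_conc, rtol=1e-12)

    def test_prediction_monotone_in_ktrans(self, base_params, plasma,
                                           zero_noise):
        cohort = generate_cohort(default_groups(), default_truth(), base_params,
                                 zero_noise, seed=1)
        rec_lo = replace_ktrans(cohort[0], 1e-3)
        rec_hi = replace_ktrans(cohort[0], 1e-2)
        t_grid = np.linspace(0.0, 8640.0, 100)
        lo = predict_individual(default_truth(), rec_lo, base_params, plasma,
                                t_grid)
        hi = predict_individual(default_truth(), rec_hi, base_params, plasma,
                                t_grid)
        assert hi.tumor_total_conc[-1] > lo.tumor_total_conc[-1]

    def test_end_to_end_covariate_model_beats_alternatives_a_priori(
        self, base_params, plasma
    ):
        """Fit on the non-binding arm, predict the binding arm with EGFR on:
        the covariate model's MPE must beat population and base."""
        truth = default_truth()
        noise = NoiseModel(dce_signal_cv=0.0, obs_cv=0.2, aif_variability=0.0)
        nonbind = generate_cohort(default_groups(), truth, base_params, noise,
                                  seed=21, plasma=plasma)
        binding = generate_cohort(default_groups("target-binding"), truth,
                                  base_params, noise, seed=22, plasma=plasma)
        mpes = {}
        for structure in ("base", "population", "ktrans"):
            fit = fit_population(nonbind, structure, base_params, plasma, FAST)
            table = predict_cohort(fit, binding, base_params, plasma,
                                   egfr_by_group=EGFR_CONC)
            mpes[structure] = table.mpe_percent
        assert mpes["ktrans"] < mpes["population"]
        assert mpes["ktrans"] < mpes["base"]


def replace_ktrans(rec, kt):
    from dataclasses import replace as dc_replace

    return dc_replace(rec, ktrans=kt)
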