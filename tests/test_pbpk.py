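"""Tumor PBPK model: binding quadratic, plasma forcing, ODE behaviour."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from mripbpk.pbpk import (
    ClosedSystem,
    PlasmaPKParams,
    TumorPBPKParams,
    bound_quasi_equilibrium,
    egfr_bound,
    ode_equations_text,
    plasma_forcing,
    simulate,
    simulate_terminal_batch,
    tumor_to_plasma_ratio,
)


class TestBindingQuadratic:
    def test_no_ligand_gives_zero_bound(self):
        assert bound_quasi_equilibrium(0.0, 1e-7, 1.5e-10) == 0.0

    def test_infinite_kd_limit_gives_zero_bound(self):
        assert bound_quasi_equilibrium(1e-8, 1e-8, 1e6) == pytest.approx(0.0, abs=1e-19)

    def test_bisection_oracle_on_mass_balance(self):
        # B solves B^2 - B(CT + RT + KD) + CT*RT = 0 on [0, min(CT, RT)]
        ct, rt, kd = 1e-8, 1e-8, 1.5e-10
        f = lambda b: b * b - b * (ct + rt + kd) + ct * rt  # noqa: E731
        oracle = brentq(f, 0.0, min(ct, rt), xtol=1e-25, rtol=1e-15)
        assert bound_quasi_equilibrium(ct, rt, kd) == pytest.approx(oracle, rel=1e-10)
        assert egfr_bound(ct, rt, kd) == pytest.approx(oracle, rel=1e-10)

    def test_zero_kd_is_stoichiometric_limit(self):
        assert bound_quasi_equilibrium(3e-8, 1e-8, 0.0) == pytest.approx(1e-8, rel=1e-12)
        assert bound_quasi_equilibrium(1e-8, 3e-8, 0.0) == pytest.approx(1e-8, rel=1e-12)

    @given(
        ct=st.floats(1e-12, 1e-4), rt=st.floats(1e-12, 1e-4),
        kd=st.floats(1e-14, 1e-3),
    )
    def test_bound_below_both_totals_and_mass_balance_holds(self, ct, rt, kd):
        b = bound_quasi_equilibrium(ct, rt, kd)
        assert 0.0 <= b <= min(ct, rt) * (1 + 1e-12)
        # free ligand * free receptor / bound == KD
        assert (ct - b) * (rt - b) == pytest.approx(kd * b, rel=1e-6)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            bound_quasi_equilibrium(-1e-9, 1e-8, 1e-10)

    def test_broadcasts_over_arrays(self):
        ct = np.array([0.0, 1e-8, 2e-8])
        b = bound_quasi_equilibrium(ct, 1e-8, 1.5e-10)
        assert b.shape == (3,)
        assert b[0] == 0.0 and b[1] < b[2]


class TestPlasmaForcing:
    def test_zero_coefficients_give_zero(self):
        p = PlasmaPKParams(coef_a=0.0, coef_b=0.0)
        assert plasma_forcing(p, 0.0) == 0.0

    def test_equal_rates_collapse_to_monoexponential(self):
        lam = 1e-3
        p = PlasmaPKParams(coef_a=200.0, rate_alpha=lam, coef_b=300.0, rate_beta=lam)
        t = np.array([0.0, 100.0, 1000.0])
        expected = p.dose_mol * 500.0 * np.exp(-lam * t)
        np.testing.assert_allclose(plasma_forcing(p, t), expected, rtol=1e-12)

    def test_auc_matches_quadrature(self, plasma):
        closed_form = plasma.dose_mol * (
            plasma.coef_a / plasma.rate_alpha + plasma.coef_b / plasma.rate_beta
        )
        numeric, _ = quad(lambda t: plasma_forcing(plasma, t), 0, np.inf, limit=500)
        assert numeric == pytest.approx(closed_form, rel=1e-6)

    def test_initial_concentration_implied_by_central_volume(self, plasma):
        assert plasma_forcing(plasma, 0.0) == pytest.approx(
            plasma.dose_mol / plasma.central_volume_l, rel=1e-12
        )

    def test_tabulated_curve_interpolation(self):
        p = PlasmaPKParams(curve_times_min=(0.0, 10.0, 20.0),
                           curve_conc_m=(1e-7, 5e-8, 2.5e-8))
        assert plasma_forcing(p, 5.0) == pytest.approx(7.5e-8)

    def test_negative_time_rejected(self, plasma):
        with pytest.raises(ValueError):
            plasma_forcing(plasma, -1.0)


class TestSimulate:
    def test_zero_dose_gives_identically_zero_states(self, base_params, six_day_grid):
        p = PlasmaPKParams(coef_a=0.0, coef_b=0.0)
        sim = simulate(base_params, p, six_day_grid)
        assert np.all(sim.tumor_total_conc == 0.0)
        assert np.all(sim.total_tumor_amount() == 0.0)

    def test_closed_system_conserves_mass(self, base_params, plasma, six_day_grid):
        p = replace(base_params, cl_tu=0.0, c_egfr=0.0, kgrowth=0.0)
        sim = simulate(p, plasma, six_day_grid, closed=ClosedSystem())
        total = sim.total_tumor_amount() + sim.plasma_amount
        rel_err = np.abs(total - plasma.dose_mol) / plasma.dose_mol
        assert rel_err.max() < 1e-6

    def test_linear_in_dose_without_target(self, base_params, six_day_grid):
        """Without target binding the only nonlinearity left is FcRn
        saturation; at tracer doses (FcRn far from saturation) the system is
        linear in dose to solver precision, and at therapeutic doses the
        residual saturation effect stays below ~1e-5."""
        tracer = PlasmaPKParams(dose_mg_per_kg=1e-6)
        s1 = simulate(base_params, tracer, six_day_grid, rtol=1e-10)
        s2 = simulate(base_params, replace(tracer, dose_mg_per_kg=2e-6),
                      six_day_grid, rtol=1e-10)
        np.testing.assert_allclose(
            s2.tumor_total_conc[1:], 2.0 * s1.tumor_total_conc[1:], rtol=1e-8
        )
        mg = PlasmaPKParams(dose_mg_per_kg=1.0)
        s1 = simulate(base_params, mg, six_day_grid)
        s2 = simulate(base_params, replace(mg, dose_mg_per_kg=2.0), six_day_grid)
        np.testing.assert_allclose(
            s2.tumor_total_conc[1:], 2.0 * s1.tumor_total_conc[1:], rtol=1e-5
        )

    def test_dose_ratio_invariance_without_target(self, base_params, plasma,
                                                  six_day_grid):
        double = replace(plasma, dose_mg_per_kg=2.0)
        r1 = tumor_to_plasma_ratio(simulate(base_params, plasma, six_day_grid),
                                   144.0 * 60.0)
        r2 = tumor_to_plasma_ratio(simulate(base_params, double, six_day_grid),
                                   144.0 * 60.0)
        assert r1 == pytest.approx(r2, rel=1e-5)

    def test_halving_sigma_v_increases_tumor_auc(self, base_params, plasma,
                                                 six_day_grid):
        leaky = replace(base_params, sigma_v=base_params.sigma_v / 2.0)
        auc_tight = np.trapezoid(
            simulate(base_params, plasma, six_day_grid).tumor_total_conc,
            six_day_grid)
        auc_leaky = np.trapezoid(
            simulate(leaky, plasma, six_day_grid).tumor_total_conc, six_day_grid)
        assert auc_leaky > auc_tight

    def test_sigma_v_to_one_approaches_uptake_floor(self, base_params, plasma,
                                                    six_day_grid):
        aucs = []
        for sv in (0.6, 0.8, 0.95, 0.999, 1.0):
            sim = simulate(replace(base_params, sigma_v=sv), plasma, six_day_grid)
            aucs.append(np.trapezoid(sim.tumor_total_conc, six_day_grid))
        assert all(a > b for a, b in zip(aucs, aucs[1:]))
        assert aucs[-2] == pytest.approx(aucs[-1], rel=5e-2)

    def test_target_binding_raises_late_tumor_to_plasma_ratio(
        self, base_params, plasma, six_day_grid
    ):
        t = 144.0 * 60.0
        nonbinder = simulate(base_params, plasma, six_day_grid)
        binder = simulate(base_params.with_egfr("LS174T"), plasma, six_day_grid)
        assert (tumor_to_plasma_ratio(binder, t)
                > tumor_to_plasma_ratio(nonbinder, t))

    def test_total_conc_consistent_with_subcompartments(self, base_params,
                                                        plasma, six_day_grid):
        sim = simulate(base_params.with_egfr("NCI-N87"), plasma, six_day_grid)
        rebuilt = sim.total_tumor_amount() / sim.tumor_volume
        np.testing.assert_allclose(rebuilt[1:], sim.tumor_total_conc[1:],
                                   rtol=1e-10)

    def test_states_nonnegative_over_random_parameter_sweep(self, plasma,
                                                            six_day_grid):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = TumorPBPKParams(
                q_tu=float(rng.uniform(2e-5, 5e-4)),
                sigma_v=float(rng.uniform(0.1, 0.99)),
                sigma_l=float(rng.uniform(0.0, 0.5)),
                fr=float(rng.uniform(0.3, 0.95)),
                c_egfr=float(rng.choice([0.0, 3.53e-8, 1.14e-7])),
            )
            sim = simulate(p, plasma, six_day_grid)
            for traj in (sim.vascular_amount, sim.endothelial_free_amount,
                         sim.endothelial_bound_amount,
                         sim.interstitial_free_amount, sim.egfr_bound_amount):
                assert np.all(traj >= 0.0)

    def test_batch_agrees_with_individual_simulations(self, base_params, plasma):
        q = np.array([5e-5, 1e-4, 2e-4])
        sv = np.array([0.5, 0.734, 0.9])
        ce = np.array([0.0, 3.53e-8, 0.0])
        tt = np.array([180.0, 1440.0, 8640.0])
        batch = simulate_terminal_batch(q, sv, ce, tt, base_params, plasma)
        for i in range(3):
            p = replace(base_params, q_tu=q[i], sigma_v=sv[i], c_egfr=ce[i])
            sim = simulate(p, plasma, np.array([0.0, tt[i]]))
            assert batch[i] == pytest.approx(sim.tumor_total_conc[-1], rel=1e-5)

    def test_invalid_grid_rejected(self, base_params, plasma):
        with pytest.raises(ValueError):
            simulate(base_params, plasma, np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            simulate(base_params, plasma, np.array([0.0, 5.0, 5.0]))

    def test_ratio_requires_positive_plasma(self, base_params, six_day_grid):
        zero = PlasmaPKParams(coef_a=0.0, coef_b=0.0)
        sim = simulate(base_params, zero, six_day_grid)
        with pytest.raises(ZeroDivisionError):
            tumor_to_plasma_ratio(sim, 60.0)


class TestParamValidation:
    @pytest.mark.parametrize("field,value", [
        ("sigma_v", 1.2), ("sigma_l", -0.1), ("fr", 2.0), ("q_tu", -1e-5),
    ])
    def test_out_of_range_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            TumorPBPKParams(**{field: value})

    def test_cl_tmd_is_kint_times_interstitial_volume(self, base_params):
        assert base_params.cl_tmd == pytest.approx(
            base_params.kint * base_params.vi_tu)

    def test_equations_text_names_all_transport_terms(self):
        text = ode_equations_text()
        for token in ("Q_TU", "L_TU", "sigma_V", "Clup_TU", "FR", "KD_FcRn",
                      "KD_EGFR", "Kint", "kgrowth"):
            assert token in text
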