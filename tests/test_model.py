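"""Engine-level tests: hazards, derivatives, conservation, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dmsim import model
from t2dmsim.model import (ModelState, NaturalHistoryParams, RiskProfile,
                           annual_new_cases, derivatives, incidence_hazard,
                           prevalence, simulate)


def euler_trajectory(initial, params, active, t0, t1, dt):
    """Independent fixed-step explicit-Euler oracle over the packed state."""
    C = initial.n_coverage
    y = initial.pack()
    t = t0
    n = int(round((t1 - t0) / dt))
    for _ in range(n):
        y = y + dt * derivatives(ModelState.unpack(y, C).copy(), params, active, t).pack()
        t += dt
    return ModelState.unpack(y, C)


class TestIncidenceHazard:
    @pytest.mark.parametrize("profile, rr, mult, expected", [
        (RiskProfile(obese=True), dict(rr_obese=4.0), 1.0, 0.04),
        (RiskProfile(obese=True), dict(rr_obese=4.0), 0.70, 0.028),
        (RiskProfile(), {}, 1.0, 0.01),
    ])
    def test_multiplicative_composition(self, profile, rr, mult, expected):
        p = NaturalHistoryParams(lam_a=np.log(0.01) * np.ones(2),
                                 lam_b=np.zeros(2), lam_c=np.zeros(2), **rr)
        assert incidence_hazard(profile, 0, 1, p, mult) == pytest.approx(expected)

    def test_all_factors_multiply(self):
        p = NaturalHistoryParams(lam_a=np.log(0.01) * np.ones(2),
                                 lam_b=np.zeros(2), lam_c=np.zeros(2),
                                 rr_obese=3.0, rr_inactive=1.5, rr_smoker=2.0)
        h = incidence_hazard(RiskProfile(True, True, True), 1, 5, p)
        assert h == pytest.approx(0.01 * 3.0 * 1.5 * 2.0)

    @pytest.mark.parametrize("mult", [0.0, -0.5, 1.5])
    def test_multiplier_out_of_range(self, mult):
        with pytest.raises(model.ParameterError):
            incidence_hazard(RiskProfile(), 0, 1, NaturalHistoryParams(), mult)

    @given(ob=st.booleans(), inact=st.booleans(), smk=st.booleans(),
           mult=st.floats(0.05, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_hazard_equals_lambda_times_present_rrs(self, ob, inact, smk, mult):
        p = NaturalHistoryParams()
        h = incidence_hazard(RiskProfile(ob, inact, smk), 0, 7, p, mult)
        expected = p.lambda0()[0, 6] * (p.rr_obese if ob else 1) * \
            (p.rr_inactive if inact else 1) * (p.rr_smoker if smk else 1) * mult
        assert h == pytest.approx(expected, rel=1e-12)


class TestRiskProfileLattice:
    def test_eight_distinct_profiles(self):
        assert len({p.index for p in model.ALL_PROFILES}) == 8

    def test_lattice_edges_change_one_factor(self):
        for factor, pairs in model.FACTOR_PAIRS.items():
            assert len(pairs) == 4
            for i0, i1 in pairs:
                assert bin(i0 ^ i1).count("1") == 1


class TestDerivatives:
    def test_closed_system_conserves_mass(self, toy_params, toy_state):
        d = derivatives(toy_state, toy_params, (), 2021.0)
        assert d.counts.sum() == pytest.approx(0.0, abs=1e-9)

    def test_incidence_only_flow(self, toy_state):
        p = NaturalHistoryParams(
            lam_a=np.log(0.02) * np.ones(2), lam_b=np.zeros(2), lam_c=np.zeros(2),
            rr_obese=1.0, rr_inactive=1.0, rr_smoker=1.0,
            mu=np.zeros((2, 20)), entry_rate0=np.zeros(2), kappa_t2dm=1.0,
            alpha_obese=0.0, omega_obese=0.0, alpha_inactive=0.0,
            omega_inactive=0.0, alpha_smoker=0.0, omega_smoker=0.0)
        d = derivatives(toy_state, p, (), 2021.0)
        s = toy_state.counts[..., 0, :]
        # apart from aging (which only moves mass between bands), the
        # susceptible compartments lose exactly hazard x count
        np.testing.assert_allclose(
            d.counts[..., 0, :].sum() , -(0.02 * s).sum(), rtol=1e-12)
        assert d.cum_inc.sum() == pytest.approx((0.02 * s).sum(), rel=1e-12)

    def test_rejects_nan_state(self, toy_params, toy_state):
        bad = toy_state.copy()
        bad.counts[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(model.StateError):
            derivatives(bad, toy_params, (), 2021.0)


class TestSimulate:
    def test_zero_length_horizon_returns_initial(self, toy_params, toy_state):
        traj = simulate(toy_state, toy_params, (), 2021.0, 2021.0)
        assert len(traj.states) == 1
        np.testing.assert_array_equal(traj.states[0].counts, toy_state.counts)

    def test_closed_system_conservation_over_30_years(self, toy_params, toy_state):
        traj = simulate(toy_state, toy_params, (), 2021.0, 2051.0)
        assert traj.mass_balance_error() < 1e-6
        retained = traj.states[-1].total() + traj.states[-1].cum_out.sum()
        assert abs(retained - toy_state.total()) / toy_state.total() < 1e-6

    def test_exponential_decay_closed_form(self):
        # constant hazard, no demography: total susceptibles decay as exp(-lam t)
        lam = 0.05
        p = NaturalHistoryParams(
            lam_a=np.log(lam) * np.ones(2), lam_b=np.zeros(2), lam_c=np.zeros(2),
            rr_obese=1.0, rr_inactive=1.0, rr_smoker=1.0,
            mu=np.zeros((2, 20)), entry_rate0=np.zeros(2), kappa_t2dm=1.0,
            alpha_obese=0.0, omega_obese=0.0, alpha_inactive=0.0,
            omega_inactive=0.0, alpha_smoker=0.0, omega_smoker=0.0)
        st0 = ModelState.zeros()
        st0.counts[0, 0, 0, 0, 0] = 1000.0
        traj = simulate(st0, p, (), 0.0, 10.0)
        s_tot = traj.states[-1].counts[..., 0, :].sum()
        assert s_tot == pytest.approx(1000.0 * np.exp(-lam * 10.0), rel=1e-6)

    def test_annual_new_cases_closed_form(self):
        lam = 0.03
        p = NaturalHistoryParams(
            lam_a=np.log(lam) * np.ones(2), lam_b=np.zeros(2), lam_c=np.zeros(2),
            rr_obese=1.0, rr_inactive=1.0, rr_smoker=1.0,
            mu=np.zeros((2, 20)), entry_rate0=np.zeros(2), kappa_t2dm=1.0,
            alpha_obese=0.0, omega_obese=0.0, alpha_inactive=0.0,
            omega_inactive=0.0, alpha_smoker=0.0, omega_smoker=0.0)
        st0 = ModelState.zeros()
        st0.counts[1, 3, 0, 0, 0] = 5000.0
        traj = simulate(st0, p, (), 2021.0, 2023.0)
        expected = 5000.0 * (1.0 - np.exp(-lam))
        assert annual_new_cases(traj, 2021) == pytest.approx(expected, rel=1e-6)

    def test_zero_hazard_zero_new_cases(self, toy_state):
        p = NaturalHistoryParams(
            lam_a=np.full(2, -30.0), lam_b=np.zeros(2), lam_c=np.zeros(2),
            mu=np.zeros((2, 20)), entry_rate0=np.zeros(2), kappa_t2dm=1.0)
        traj = simulate(toy_state, p, (), 2021.0, 2026.0)
        for y in range(2021, 2026):
            assert annual_new_cases(traj, y) == pytest.approx(0.0, abs=1e-6)

    def test_new_cases_outside_horizon_raises(self, toy_params, toy_state):
        traj = simulate(toy_state, toy_params, (), 2021.0, 2024.0)
        with pytest.raises(ValueError):
            annual_new_cases(traj, 2024)
        with pytest.raises(ValueError):
            annual_new_cases(traj, 2019)

    def test_euler_oracle_agreement_on_toy(self, toy_state):
        # two bands, two profiles populated; modest rates incl. an active
        # scenario so the recruitment flow is exercised too
        p = NaturalHistoryParams(
            lam_a=np.log(0.02) * np.ones(2), lam_b=np.zeros(2), lam_c=np.zeros(2),
            mu=np.full((2, 20), 0.01), entry_rate0=np.full(2, 30.0), kappa_t2dm=1.3,
            alpha_obese=0.03, omega_obese=0.02, alpha_inactive=0.05,
            omega_inactive=0.08, alpha_smoker=0.01, omega_smoker=0.02)
        st0 = ModelState.zeros(2)
        st0.counts[:, :2, :2, 0, 0] = 400.0
        sc = model.ActiveScenario(
            scenario_id="toy", bit=0,
            elig_mask=np.ones((2, 20, 8), dtype=bool),
            incidence_multiplier=0.8, effective_coverage=0.3,
            ramp_start=2021.0, ramp_end=2024.0)
        fine = euler_trajectory(st0, p, [sc], 2021.0, 2025.0, dt=5e-4)
        traj = simulate(st0, p, [sc], 2021.0, 2025.0)
        got = traj.states[-1]
        scale = fine.counts.sum()
        np.testing.assert_allclose(got.counts, fine.counts, rtol=2e-4,
                                   atol=1e-4 * scale)
        assert abs(got.counts.sum() - fine.counts.sum()) / scale < 1e-4

    def test_no_remission_diabetics_never_fall_in_closed_immortal_system(
            self, toy_params, toy_state):
        traj = simulate(toy_state, toy_params, (), 2021.0, 2041.0)
        dia = [s.diabetic_total() for s in traj.states]
        assert all(b >= a - 1e-9 for a, b in zip(dia, dia[1:]))

    def test_non_negativity(self, toy_params, toy_state):
        traj = simulate(toy_state, toy_params, (), 2021.0, 2051.0)
        for s in traj.states:
            assert s.counts.min() >= 0.0


class TestPrevalence:
    def test_all_susceptible_and_all_diabetic(self):
        st = ModelState.zeros()
        st.counts[0, 0, 0, model.SUSCEPTIBLE, 0] = 10.0
        assert prevalence(st) == 0.0
        st.counts[0, 0, 0, model.SUSCEPTIBLE, 0] = 0.0
        st.counts[0, 0, 0, model.DIABETIC, 0] = 10.0
        assert prevalence(st) == 1.0

    def test_printed_anchor_ratio(self):
        st = ModelState.zeros()
        st.counts[0, 0, 0, model.DIABETIC, 0] = 33_821.0
        st.counts[0, 0, 0, model.SUSCEPTIBLE, 0] = 197_784.0 - 33_821.0
        assert prevalence(st) == pytest.approx(0.171, abs=1e-5)

    def test_empty_selection_raises(self):
        with pytest.raises(model.SelectionError):
            prevalence(ModelState.zeros())

    def test_sex_and_age_selection(self):
        st = ModelState.zeros()
        st.counts[0, 0, 0, model.DIABETIC, 0] = 5.0
        st.counts[0, 0, 0, model.SUSCEPTIBLE, 0] = 5.0
        st.counts[1, 10, 0, model.SUSCEPTIBLE, 0] = 90.0
        assert prevalence(st, sex=0) == pytest.approx(0.5)
        assert prevalence(st, age_range=(20, 25)) == pytest.approx(0.5)
        assert prevalence(st) == pytest.approx(0.05)
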