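"""Scenario specification, coverage ramp, recruitment and forcing tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from t2dmsim import interventions as iv
from t2dmsim import model, synthetic
from t2dmsim.interventions import (InterventionSpec, ScenarioError,
                                   TargetFilter, coverage_ramp,
                                   effective_coverage, recruitment_rate)


def make_spec(**kw):
    base = dict(id="test", uptake=0.5, adherence=0.5,
                ramp_start=2021.0, ramp_end=2025.0)
    base.update(kw)
    return InterventionSpec(**base)


class TestEffectiveCoverage:
    @pytest.mark.parametrize("uptake, adherence, expected", [
        (0.5, 0.5, 0.25),   # lifestyle rows
        (0.4, 1.0, 0.40),   # public-transport row
        (0.0, 0.9, 0.0),
    ])
    def test_product(self, uptake, adherence, expected):
        s = make_spec(uptake=uptake, adherence=adherence)
        assert effective_coverage(s) == pytest.approx(expected)


class TestCoverageRamp:
    def test_linear_scale_up_then_hold(self):
        s = make_spec()  # effective 0.25, ramp 2021-2025
        assert coverage_ramp(2021.0, s) == 0.0
        assert coverage_ramp(2023.0, s) == pytest.approx(0.125)
        assert coverage_ramp(2025.0, s) == pytest.approx(0.25)
        assert coverage_ramp(2049.0, s) == pytest.approx(0.25)

    @given(t=st.floats(2000.0, 2060.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ramp_bounded_by_effective_coverage(self, t):
        s = make_spec()
        assert 0.0 <= coverage_ramp(t, s) <= effective_coverage(s) + 1e-12


class TestRecruitmentRate:
    def test_zero_before_ramp_and_at_target(self):
        s = make_spec()
        assert recruitment_rate(2019.0, s, 0.0) == 0.0
        assert recruitment_rate(2026.0, s, 0.25) == 0.0
        assert recruitment_rate(2030.0, s, 0.30) == 0.0  # above target

    def test_saturated_coverage_returns_zero(self):
        s = make_spec()
        assert recruitment_rate(2023.0, s, 1.0) == 0.0

    def test_toy_ramp_ode_tracks_target(self):
        # df/dt = rho(t, f) (1 - f) must reach uptake x adherence by ramp end
        s = make_spec()

        def rhs(t, y):
            return [recruitment_rate(t, s, y[0]) * (1.0 - y[0])]

        sol = solve_ivp(rhs, (2021.0, 2025.0), [0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        assert abs(sol.y[0, -1] - 0.25) < 1e-3


class TestSpecValidation:
    def test_uptake_out_of_range(self):
        with pytest.raises(ScenarioError, match="uptake"):
            make_spec(uptake=1.2)

    def test_ramp_ordering(self):
        with pytest.raises(ScenarioError):
            make_spec(ramp_start=2030.0, ramp_end=2025.0)

    def test_incidence_multiplier_range(self):
        with pytest.raises(ScenarioError):
            make_spec(incidence_multiplier=0.0)
        with pytest.raises(ScenarioError):
            make_spec(incidence_multiplier=1.2)


class TestScenarioLibrary:
    def test_published_uptakes_adherences_and_ramps(self, library):
        uptakes = [library.scenarios[i].uptake for i in library.ids]
        adherences = [library.scenarios[i].adherence for i in library.ids]
        assert uptakes == [0.5, 0.5, 0.5, 0.4, 0.2, 0.5, 0.5, 0.5, 0.5,
                           0.2, 0.2, 0.2]
        assert adherences == [0.5, 0.5, 0.5] + [1.0] * 9
        for sid, spec in library.scenarios.items():
            assert spec.ramp_start == 2021.0
            expected_end = 2025.0 if sid.startswith("lifestyle") else 2030.0
            assert spec.ramp_end == expected_end

    def test_twelve_scenarios_two_packages(self, library):
        assert len(library.ids) == 12
        assert set(library.packages) == {"most_optimistic", "least_optimistic"}

    def test_obesity_endpoints(self, library):
        endpoints = {sid: s.obesity_prev_target
                     for sid, s in library.scenarios.items()
                     if s.obesity_prev_target is not None}
        assert endpoints == {"public_transport": 0.509, "cycling_walking": 0.504,
                             "workplace_diet": 0.348, "subsidy_fv": 0.526,
                             "ssb_tax": 0.523, "subsidy_ssb_combined": 0.516}
        assert library.scenarios["workplace_diet"].obesity_scope == "covered"
        assert library.scenarios["public_transport"].normalize_inactivity

    def test_build_packages(self, library):
        most = library.build_package("most_optimistic")
        least = library.build_package("least_optimistic")
        assert [s.id for s in most] == ["lifestyle_obese_35", "cycling_walking",
                                        "workplace_diet", "subsidy_ssb_combined"]
        assert [s.id for s in least] == ["lifestyle_obese", "public_transport",
                                         "fv_consumption", "subsidy_fv"]
        assert not {s.id for s in most} & {s.id for s in least}
        for s in most + least:
            s.validate()

    def test_unknown_package_and_scenario(self, library):
        with pytest.raises(ScenarioError, match="available"):
            library.build_package("middling")
        with pytest.raises(ScenarioError, match="available"):
            library.get("nonexistent")

    def test_workplace_filter_covers_working_ages(self, library):
        m = library.scenarios["workplace_diet"].target_filter.mask()
        per_band = m.any(axis=(0, 2))
        assert per_band[:15].all() and not per_band[15:].any()

    def test_lifestyle_filters(self, library):
        m35 = library.scenarios["lifestyle_obese_35"].target_filter.mask()
        assert not m35[:, :5].any()          # below age 35 excluded
        assert m35[:, 5:, model.PROFILE_OBESE].all()
        assert not m35[:, :, ~model.PROFILE_OBESE].any()
        m50 = library.scenarios["lifestyle_age50"].target_filter.mask()
        assert not m50[:, :10].any() and m50[:, 10:].all()


class TestApplyEffects:
    def test_uncovered_compartment_identity(self, library):
        specs = [library.get("cycling_walking")]
        mult, adj = iv.apply_effects((0, 10, model.RiskProfile(), frozenset()),
                                     specs, 2026.0)
        assert mult == 1.0
        assert adj["extra_obesity_exit"] == 0.0

    def test_covered_cycling_multiplier(self, library):
        specs = [library.get("cycling_walking")]
        mult, _ = iv.apply_effects(
            (0, 10, model.RiskProfile(), frozenset({"cycling_walking"})),
            specs, 2026.0)
        assert mult == pytest.approx(0.76)

    def test_package_multipliers_compose(self, library):
        specs = library.build_package("most_optimistic")
        mult, _ = iv.apply_effects(
            (0, 10, model.RiskProfile(),
             frozenset({"workplace_diet", "lifestyle_obese_35"})),
            specs, 2026.0)
        # workplace RR alone at a non-obese profile (lifestyle needs obesity)
        assert mult == pytest.approx(0.93)
        mult, _ = iv.apply_effects(
            (0, 10, model.RiskProfile(obese=True),
             frozenset({"workplace_diet", "lifestyle_obese_35"})),
            specs, 2026.0)
        assert mult == pytest.approx(0.93 * 0.70)
        assert mult == pytest.approx(0.651)

    def test_duplicate_ids_rejected(self, library):
        s = library.get("fv_consumption")
        with pytest.raises(ScenarioError, match="duplicate"):
            iv.compile_scenarios([s, s])


class TestObesityForcing:
    def test_target_equal_to_baseline_gives_zero_forcing(self, fitted_params,
                                                         initial_state, baseline):
        achieved = baseline.obesity_prevalence(2030)
        spec = make_spec(id="null_forcing", uptake=0.4, adherence=1.0,
                         ramp_start=2021.0, ramp_end=2030.0,
                         obesity_prev_target=round(achieved, 6),
                         obesity_scope="total")
        sol = iv.solve_obesity_forcing([spec], initial_state, fitted_params,
                                       horizon_end=2031.0)
        assert np.max(np.abs(sol.rates["null_forcing"])) < 0.01

    def test_lower_target_needs_larger_multiplier(self, fitted_params,
                                                  initial_state):
        multipliers = []
        for tgt in (0.52, 0.50):
            spec = make_spec(id="force", uptake=0.4, adherence=1.0,
                             ramp_start=2021.0, ramp_end=2030.0,
                             obesity_prev_target=tgt, obesity_scope="total")
            sol = iv.solve_obesity_forcing([spec], initial_state, fitted_params,
                                           horizon_end=2030.0)
            multipliers.append(sol.multiplier_ramp)
        assert multipliers[1] > multipliers[0] > 0.0

    def test_unreachable_target_raises_with_closest(self, fitted_params,
                                                    initial_state):
        spec = make_spec(id="impossible", uptake=0.01, adherence=1.0,
                         ramp_start=2021.0, ramp_end=2023.0,
                         obesity_prev_target=0.05, obesity_scope="total")
        with pytest.raises(iv.InfeasibleTargetError) as err:
            iv.solve_obesity_forcing([spec], initial_state, fitted_params,
                                     horizon_end=2024.0, m_max=16.0)
        assert 0.05 < err.value.closest < 0.60
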