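"""Intervention scenarios: specifications, coverage ramps, effects, packages.

Each scenario targets a sub-population (a filter over sex, age and risk
profile), recruits an effective coverage of uptake x adherence along a linear
scale-up ramp, and acts through up to three mechanisms: a multiplicative
reduction of the T2DM onset hazard (IRR/RR) among covered people, an
obesity-prevalence endpoint to be reached by end of scale-up (implemented as a
solved, time-varying extra exit rate out of the obese state with matching
acquisition damping, applied to covered people), and normalization of physical
inactivity (covered inactive people move to the active state over the ramp).

The packaged scenario library holds the twelve individual scenarios and the
two (most/least optimistic) combination packages.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import model
from .model import (AGE_MIDPOINTS, N_AGE, N_PROFILE, N_SEX, PROFILE_OBESE,
                    ActiveScenario, ModelState, NaturalHistoryParams)

log = logging.getLogger(__name__)


class ScenarioError(ValueError):
    """An intervention specification is invalid."""


class InfeasibleTargetError(RuntimeError):
    """An obesity-prevalence target is unreachable; carries the closest value."""

    def __init__(self, message: str, closest: float):
        super().__init__(message)
        self.closest = closest


@dataclass(frozen=True)
class TargetFilter:
    """Predicate over (sex, age, risk profile) defining scenario eligibility."""

    min_age: float = 20.0
    max_age: float = 79.0
    require_obese: bool = False
    sex: str | None = None       # "female" / "male" / None for both

    def mask(self) -> np.ndarray:
        """Boolean eligibility array of shape (sex, age band, profile)."""
        m = np.ones((N_SEX, N_AGE, N_PROFILE), dtype=bool)
        age_ok = (AGE_MIDPOINTS >= self.min_age) & (AGE_MIDPOINTS <= self.max_age)
        m &= age_ok[None, :, None]
        if self.require_obese:
            m &= PROFILE_OBESE[None, None, :]
        if self.sex is not None:
            s = model.SEXES.index(self.sex)
            keep = np.zeros(N_SEX, dtype=bool)
            keep[s] = True
            m &= keep[:, None, None]
        return m


@dataclass
class InterventionSpec:
    """One scenario row: target filter, coverage, ramp window and effects."""

    id: str
    uptake: float
    adherence: float
    ramp_start: float
    ramp_end: float
    horizon_end: float = 2050.0
    incidence_multiplier: float = 1.0
    obesity_prev_target: float | None = None
    obesity_scope: str = "total"           # "total" or "covered"
    normalize_inactivity: bool = False
    bmi_shift_info: float | None = None    # kg/m^2, informational only
    target_filter: TargetFilter = field(default_factory=TargetFilter)
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("uptake", "adherence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{self.id}: {name} must be in [0, 1], got {v}")
        if not self.ramp_start < self.ramp_end <= self.horizon_end:
            raise ScenarioError(f"{self.id}: need ramp_start < ramp_end <= horizon_end")
        if not 0.0 < self.incidence_multiplier <= 1.0:
            raise ScenarioError(f"{self.id}: incidence_multiplier must be in (0, 1]")
        if self.obesity_prev_target is not None and not 0.0 < self.obesity_prev_target < 1.0:
            raise ScenarioError(f"{self.id}: obesity_prev_target must be in (0, 1)")
        if self.obesity_scope not in ("total", "covered"):
            raise ScenarioError(f"{self.id}: obesity_scope must be 'total' or 'covered'")


def effective_coverage(spec: InterventionSpec) -> float:
    """Fraction of the eligible population effectively covered: uptake x adherence."""
    return spec.uptake * spec.adherence


def coverage_ramp(t: float, spec: InterventionSpec) -> float:
    """Effective coverage at time ``t``: linear scale-up, then held constant."""
    w = np.clip((t - spec.ramp_start) / (spec.ramp_end - spec.ramp_start), 0.0, 1.0)
    return effective_coverage(spec) * float(w)


def recruitment_rate(t: float, spec: InterventionSpec,
                     current_covered_fraction: float) -> float:
    """Per-capita recruitment rate of eligible uncovered persons (per year).

    A closed-loop tracking rate: the feed-forward ramp slope plus a
    proportional correction toward the ramp target, divided by the uncovered
    fraction.  Zero whenever coverage is at or above target (in particular
    after the ramp, absent dilution by new eligibles).
    """
    if current_covered_fraction >= 1.0:
        log.warning("%s: covered fraction >= 1; recruitment suppressed", spec.id)
        return 0.0
    slope = 0.0
    if spec.ramp_start <= t < spec.ramp_end:
        slope = effective_coverage(spec) / (spec.ramp_end - spec.ramp_start)
    gain = 2.0
    rho = slope + gain * (coverage_ramp(t, spec) - current_covered_fraction)
    if rho <= 0.0:
        return 0.0
    return rho / max(1.0 - current_covered_fraction, 1e-9)


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

@dataclass
class ScenarioLibrary:
    """The packaged Table-style scenario set plus combination packages."""

    scenarios: dict[str, InterventionSpec]
    packages: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(set(self.scenarios)) != len(self.scenarios):
            raise ScenarioError("duplicate scenario ids")
        for name, ids in self.packages.items():
            unknown = [i for i in ids if i not in self.scenarios]
            if unknown:
                raise ScenarioError(f"package {name} references unknown ids {unknown}")

    def get(self, scenario_id: str) -> InterventionSpec:
        try:
            return self.scenarios[scenario_id]
        except KeyError:
            raise ScenarioError(
                f"unknown scenario '{scenario_id}'; available: "
                f"{', '.join(sorted(self.scenarios))}") from None

    def build_package(self, kind: str) -> list[InterventionSpec]:
        """The most- or least-optimistic combination of the four interventions."""
        if kind not in self.packages:
            raise ScenarioError(f"unknown package '{kind}'; available: "
                                f"{', '.join(sorted(self.packages))}")
        return [self.get(i) for i in self.packages[kind]]

    @property
    def ids(self) -> list[str]:
        return list(self.scenarios)


def _spec_from_dict(d: dict) -> InterventionSpec:
    eff = d.get("effects", {}) or {}
    filt = d.get("filter", {}) or {}
    return InterventionSpec(
        id=d["id"],
        label=d.get("label", ""),
        uptake=float(d["uptake"]),
        adherence=float(d["adherence"]),
        ramp_start=float(d["ramp"][0]),
        ramp_end=float(d["ramp"][1]),
        incidence_multiplier=float(eff.get("irr", 1.0)),
        obesity_prev_target=(float(eff["obesity_prev_target"])
                             if "obesity_prev_target" in eff else None),
        obesity_scope=eff.get("obesity_scope", "total"),
        normalize_inactivity=bool(eff.get("normalize_inactivity", False)),
        bmi_shift_info=(float(d["bmi_shift_info"]) if d.get("bmi_shift_info")
                        is not None else None),
        target_filter=TargetFilter(
            min_age=float(filt.get("min_age", 20.0)),
            max_age=float(filt.get("max_age", 79.0)),
            require_obese=bool(filt.get("require_obese", False)),
            sex=filt.get("sex"),
        ),
    )


def load_scenario_library(path=None) -> ScenarioLibrary:
    """Load the packaged scenario YAML (or a user-supplied one)."""
    if path is None:
        ref = importlib.resources.files("t2dmsim").joinpath("data/table1_scenarios.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    ids = [d["id"] for d in raw["scenarios"]]
    if len(set(ids)) != len(ids):
        raise ScenarioError("duplicate scenario ids in library file")
    scenarios = {d["id"]: _spec_from_dict(d) for d in raw["scenarios"]}
    return ScenarioLibrary(scenarios, {k: list(v) for k, v in raw.get("packages", {}).items()})


def build_package(kind: str, library: ScenarioLibrary | None = None) -> list[InterventionSpec]:
    return (library or load_scenario_library()).build_package(kind)


# ---------------------------------------------------------------------------
# Compilation to the runtime form + effect application
# ---------------------------------------------------------------------------

def compile_scenarios(specs: list[InterventionSpec]) -> list[ActiveScenario]:
    """Bind each spec to a coverage bit and precompute its eligibility mask."""
    seen = set()
    for s in specs:
        if s.id in seen:
            raise ScenarioError(f"duplicate scenario id '{s.id}' in active set")
        seen.add(s.id)
    active = []
    for bit, s in enumerate(specs):
        active.append(ActiveScenario(
            scenario_id=s.id, bit=bit, elig_mask=s.target_filter.mask(),
            incidence_multiplier=s.incidence_multiplier,
            effective_coverage=effective_coverage(s),
            ramp_start=s.ramp_start, ramp_end=s.ramp_end,
            normalize_inactivity=s.normalize_inactivity,
        ))
    return active


def apply_effects(compartment, specs: list[InterventionSpec], t: float,
                  active: list[ActiveScenario] | None = None):
    """Incidence multiplier and transition adjustments for one compartment.

    ``compartment`` is (sex index, 1-based age band, RiskProfile, covered-ids),
    where covered-ids is the set of scenario ids the person is enrolled in.
    Returns ``(multiplier, adjustments)`` where adjustments maps
    'extra_obesity_exit' (per year, additive across scenarios),
    'obesity_acq_damping' (multiplicative) and 'inactivity_normalization_rate'.
    """
    sex, age_band, profile, covered = compartment
    if active is None:
        active = compile_scenarios(specs)
    by_id = {a.scenario_id: a for a in active}
    mult = 1.0
    adj = {"extra_obesity_exit": 0.0, "obesity_acq_damping": 1.0,
           "inactivity_normalization_rate": 0.0}
    for s in specs:
        if s.id not in covered:
            continue
        a = by_id[s.id]
        if a.elig_mask[sex, age_band - 1, profile.index]:
            mult *= s.incidence_multiplier
        if a.elig_mask[sex, age_band - 1].any():
            e = a.forcing_rate(t)
            if e > 0:
                adj["extra_obesity_exit"] += e
                adj["obesity_acq_damping"] *= 1.0 / (1.0 + e)
            adj["inactivity_normalization_rate"] += a.inactivity_rate(t)
    return mult, adj


# ---------------------------------------------------------------------------
# Obesity forcing solver
# ---------------------------------------------------------------------------

def _obesity_measure(traj: model.Trajectory, year: int, spec: InterventionSpec,
                     active_sc: ActiveScenario) -> float:
    if spec.obesity_scope == "covered":
        C = traj.states[0].n_coverage
        cov_sel = ((np.arange(C) >> active_sc.bit) & 1) == 1
        agesex = active_sc.elig_mask.any(axis=2)
        return traj.obesity_prevalence(year, agesex_mask=agesex, coverage_sel=cov_sel)
    return traj.obesity_prevalence(year)


def _ramp_weights(spec: InterventionSpec) -> np.ndarray:
    """Annual piecewise-constant weights over [ramp_start, ramp_end)."""
    n = int(round(spec.ramp_end - spec.ramp_start))
    # weight of year y is the coverage ramp at its end
    return (np.arange(1, n + 1)) / n


@dataclass
class ForcingSolution:
    """Solved annual obesity-forcing rates per scenario id."""

    rates: dict[str, np.ndarray]
    year0: float
    multiplier_ramp: float


def solve_obesity_forcing(specs: list[InterventionSpec],
                          initial: ModelState,
                          params: NaturalHistoryParams,
                          horizon_end: float = 2051.0,
                          tol: float = 2e-4,
                          m_max: float = 128.0,
                          solver_rtol: float = 1e-6) -> ForcingSolution:
    """Solve the extra obesity-exit rates hitting each prevalence endpoint.

    During scale-up the annual rate of scenario k is ``m x w_k(y)`` with
    ``w_k`` the linear ramp weights; the scalar ``m`` is found by bisection so
    the simulated obesity prevalence in the stated scope hits the target at
    ramp end within ``tol``.  Covered-scope targets are solved first, then one
    shared multiplier for all total-scope targets given the covered-scope
    forcing.  After ramp end the rate for each year is re-solved by bisection
    so the prevalence is held at target through the horizon (zero whenever the
    target is already met).

    Raises :class:`InfeasibleTargetError` when even the maximal forcing cannot
    reach a target, reporting the closest achievable prevalence.
    """
    forced = [s for s in specs if s.obesity_prev_target is not None]
    if not forced:
        return ForcingSolution({}, 0.0, 0.0)
    active = compile_scenarios(specs)
    by_id = {a.scenario_id: a for a in active}
    n_cov = 2 ** len(specs)
    if initial.n_coverage != n_cov:
        init = ModelState.zeros(n_cov)
        init.counts[..., 0] = initial.counts.sum(axis=-1)
        init.cum_inc = initial.cum_inc.copy()
    else:
        init = initial.copy()

    year0 = min(s.ramp_start for s in forced)
    n_years = int(round(horizon_end - year0))
    rates = {s.id: np.zeros(n_years) for s in forced}

    def set_rates() -> None:
        for a in active:
            if a.scenario_id in rates:
                a.forcing_rates = rates[a.scenario_id]
                a.forcing_year0 = year0

    def run(t_end: float, start_state=None, t_start=None) -> model.Trajectory:
        set_rates()
        return model.simulate(start_state if start_state is not None else init,
                              params, active,
                              t_start if t_start is not None else year0,
                              t_end, rtol=solver_rtol, atol=1e-4, method="RK45")

    def solve_ramp(group: list[InterventionSpec]) -> float:
        """Shared bisection multiplier for one scope group during scale-up."""
        ramp_end = max(s.ramp_end for s in group)

        def gap(m: float) -> float:
            for s in group:
                w = _ramp_weights(s)
                idx0 = int(round(s.ramp_start - year0))
                rates[s.id][:] = 0.0
                rates[s.id][idx0:idx0 + len(w)] = m * w
                rates[s.id][idx0 + len(w):] = 0.0
            traj = run(ramp_end)
            # most stringent target in the group (smallest margin)
            worst = -np.inf
            for s in group:
                ach = _obesity_measure(traj, int(ramp_end), s, by_id[s.id])
                worst = max(worst, ach - s.obesity_prev_target)
            return worst

        g0 = gap(0.0)
        if g0 <= 0.0:
            for s in group:
                rates[s.id][:] = 0.0
            return 0.0
        lo, hi = 0.0, 4.0
        g_hi = gap(hi)
        while g_hi > 0.0:
            hi *= 2.0
            if hi > m_max:
                closest = gap(m_max) + min(s.obesity_prev_target for s in group)
                raise InfeasibleTargetError(
                    f"obesity target unreachable for {[s.id for s in group]}; "
                    f"closest achievable prevalence {closest:.4f}", closest)
            g_hi = gap(hi)
        while hi - lo > 1e-4 * max(hi, 1.0) and abs(g_hi) > 0.25 * tol:
            mid = 0.5 * (lo + hi)
            g_mid = gap(mid)
            if g_mid > 0.0:
                lo = mid
            else:
                hi, g_hi = mid, g_mid
        gap(hi)  # leave rates at the feasible endpoint
        return hi

    covered_group = [s for s in forced if s.obesity_scope == "covered"]
    total_group = [s for s in forced if s.obesity_scope == "total"]
    m_cov = solve_ramp(covered_group) if covered_group else 0.0
    m_tot = solve_ramp(total_group) if total_group else 0.0
    if covered_group and total_group:
        # re-solve the covered scope once with total-scope forcing in place
        m_cov = solve_ramp(covered_group)

    # ---- maintenance: hold each scope at target year by year ---------------
    last_ramp_end = max(s.ramp_end for s in forced)
    traj = run(last_ramp_end)
    state = traj.state_at(int(last_ramp_end))
    last_rate: dict[str, float] = {"covered": m_cov, "total": m_tot}
    for year in range(int(last_ramp_end), int(horizon_end)):
        idx = int(year - year0)

        def year_gap(values: dict[str, float]) -> dict[str, float]:
            for sid, v in values.items():
                rates[sid][idx] = v
            t1 = run(year + 1, start_state=state, t_start=float(year))
            return {s.id: _obesity_measure(t1, year + 1, s, by_id[s.id])
                    - s.obesity_prev_target for s in forced}

        # per scope group, bisect a single rate for this year; warm-start the
        # bracket from the previous year's solved rate
        values = {s.id: 0.0 for s in forced}
        for group, key in ((covered_group, "covered"), (total_group, "total")):
            if not group:
                continue
            gids = [s.id for s in group]

            def g(v: float) -> float:
                trial = dict(values)
                for sid in gids:
                    trial[sid] = v
                gaps = year_gap(trial)
                return max(gaps[sid] for sid in gids)

            if g(0.0) <= 0.0:
                for sid in gids:
                    values[sid] = 0.0
                continue
            prev = last_rate.get(key, 0.0)
            lo, hi = 0.0, max(1.5 * prev, 0.5)
            g_hi = g(hi)
            while g_hi > 0.0 and hi < m_max:
                hi *= 2.0
                g_hi = g(hi)
            for _ in range(40):
                if hi - lo < 1e-3 * max(hi, 1.0) or abs(g_hi) < 0.25 * tol:
                    break
                mid = 0.5 * (lo + hi)
                g_mid = g(mid)
                if g_mid > 0.0:
                    lo = mid
                else:
                    hi, g_hi = mid, g_mid
            for sid in gids:
                values[sid] = hi
            last_rate[key] = hi
        for sid, v in values.items():
            rates[sid][idx] = v
        traj1 = run(year + 1, start_state=state, t_start=float(year))
        state = traj1.state_at(year + 1)

    set_rates()
    return ForcingSolution({k: v.copy() for k, v in rates.items()}, year0,
                           max(m_cov, m_tot))
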