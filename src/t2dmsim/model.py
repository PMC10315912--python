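"""Deterministic compartmental model of type 2 diabetes (T2DM) in adults aged 20-79.

The population is stratified by sex, twenty 3-year age bands (20-22 ... 77-79),
the eight combinations of three modifiable risk factors (obesity, physical
inactivity, smoking), T2DM status (susceptible / diabetic, no remission), and an
intervention-coverage axis (uncovered plus one bit per active intervention
scenario).  Dynamics are a set of ordinary differential equations: continuous
aging between bands, entry at age 20, background and excess mortality,
risk-factor acquisition/exit along lattice edges (one factor at a time), T2DM
onset at a multiplicative-relative-risk hazard, and coverage recruitment flows
that track each scenario's linear scale-up ramp.  A cumulative-incidence
accumulator per (sex, age band) supports annual new-case accounting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Lattice constants
# ---------------------------------------------------------------------------

SEXES = ("female", "male")
N_SEX = 2
N_AGE = 20
BAND_WIDTH = 3.0          # years per age band; 20 bands span ages 20-79
AGE_LO = 20.0
AGE_MIDPOINTS = AGE_LO + BAND_WIDTH * (np.arange(N_AGE) + 0.5)

N_PROFILE = 8
OBESE_BIT, INACTIVE_BIT, SMOKER_BIT = 1, 2, 4
_P = np.arange(N_PROFILE)
PROFILE_OBESE = (_P & OBESE_BIT) > 0      # (8,) bool
PROFILE_INACTIVE = (_P & INACTIVE_BIT) > 0
PROFILE_SMOKER = (_P & SMOKER_BIT) > 0

N_STATUS = 2
SUSCEPTIBLE, DIABETIC = 0, 1

# lattice-edge pairs (index_without_factor, index_with_factor) for each factor
FACTOR_PAIRS = {
    "obese": [(i, i | OBESE_BIT) for i in range(8) if not i & OBESE_BIT],
    "inactive": [(i, i | INACTIVE_BIT) for i in range(8) if not i & INACTIVE_BIT],
    "smoker": [(i, i | SMOKER_BIT) for i in range(8) if not i & SMOKER_BIT],
}


class ParameterError(ValueError):
    """A natural-history or intervention parameter is out of range."""


class StateError(ValueError):
    """A model state contains NaN or negative counts."""


class SelectionError(ValueError):
    """A prevalence selection is empty or has zero population."""


def band_of_age(age: float) -> int:
    """0-based age band containing ``age`` (clipped to 20-79)."""
    return int(np.clip((age - AGE_LO) // BAND_WIDTH, 0, N_AGE - 1))


def bands_for_age_range(age_min: float, age_max: float) -> slice:
    """Slice of 0-based bands whose midpoints fall inside [age_min, age_max]."""
    sel = (AGE_MIDPOINTS >= age_min) & (AGE_MIDPOINTS <= age_max)
    idx = np.where(sel)[0]
    if idx.size == 0:
        raise SelectionError(f"no age band inside [{age_min}, {age_max}]")
    return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass(frozen=True)
class RiskProfile:
    """One corner of the risk-factor lattice."""

    obese: bool = False
    inactive: bool = False
    smoker: bool = False

    @property
    def index(self) -> int:
        return (OBESE_BIT * self.obese) | (INACTIVE_BIT * self.inactive) | (
            SMOKER_BIT * self.smoker
        )

    @classmethod
    def from_index(cls, i: int) -> "RiskProfile":
        if not 0 <= i < N_PROFILE:
            raise ValueError(f"profile index {i} outside 0..7")
        return cls(bool(i & OBESE_BIT), bool(i & INACTIVE_BIT), bool(i & SMOKER_BIT))


ALL_PROFILES = tuple(RiskProfile.from_index(i) for i in range(N_PROFILE))


# ---------------------------------------------------------------------------
# Natural-history parameters
# ---------------------------------------------------------------------------

# age coordinate used by the log-quadratic baseline hazard
_X_AGE = (AGE_MIDPOINTS - 50.0) / 10.0

# default Gompertz-like background mortality (per year), rising with age
DEFAULT_MU = 0.004 * np.exp(0.085 * (AGE_MIDPOINTS - 50.0))


def _as_sex_age(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    out = np.broadcast_to(arr, (N_SEX, N_AGE)).copy()
    if np.any(~np.isfinite(out)) or np.any(out < 0):
        raise ParameterError(f"{name} must be finite and non-negative")
    return out


@dataclass
class NaturalHistoryParams:
    """Baseline hazard, relative risks, transition, mortality and entry rates.

    The baseline T2DM hazard is log-quadratic in age,
    ``lambda0(sex, age) = exp(a_s + b_s x + c_s x^2)`` with ``x = (age-50)/10``,
    multiplied by a secular trend ``exp(gamma tau + gamma2 tau^2)`` with
    ``tau = t - trend_ref_year`` capturing drivers not modelled explicitly.
    Relative risks compose multiplicatively across co-occurring risk factors.
    """

    lam_a: np.ndarray = field(default_factory=lambda: np.full(N_SEX, -5.0))
    lam_b: np.ndarray = field(default_factory=lambda: np.full(N_SEX, 0.13))
    lam_c: np.ndarray = field(default_factory=lambda: np.full(N_SEX, -0.40))
    gamma: float = 0.0
    gamma2: float = 0.0
    trend_ref_year: float = 2021.0

    rr_obese: float = 3.6
    rr_inactive: float = 1.3
    rr_smoker: float = 1.4

    # acquisition / exit rates per year, (sex, age band)
    alpha_obese: np.ndarray = field(default_factory=lambda: np.full((N_SEX, N_AGE), 0.02))
    omega_obese: np.ndarray = field(default_factory=lambda: np.full((N_SEX, N_AGE), 0.02))
    alpha_inactive: np.ndarray = field(default_factory=lambda: np.full((N_SEX, N_AGE), 0.087))
    omega_inactive: np.ndarray = field(default_factory=lambda: np.full((N_SEX, N_AGE), 0.10))
    alpha_smoker: np.ndarray = field(default_factory=lambda: np.full((N_SEX, N_AGE), 0.0078))
    omega_smoker: np.ndarray = field(default_factory=lambda: np.full((N_SEX, N_AGE), 0.03))
    obesity_drift: float = 0.0   # alpha_obese(t) = alpha_obese * exp(drift * tau)

    mu: np.ndarray = field(default_factory=lambda: np.tile(DEFAULT_MU, (N_SEX, 1)))
    kappa_t2dm: float = 1.5      # excess-mortality multiplier for diabetics

    entry_rate0: np.ndarray = field(default_factory=lambda: np.full(N_SEX, 1500.0))
    entry_growth: float = 0.012  # per-year exponential growth of the entry flow
    entry_profile_mix: np.ndarray = field(default_factory=lambda: np.full(N_PROFILE, 1 / 8))

    def __post_init__(self) -> None:
        self.lam_a = np.broadcast_to(np.asarray(self.lam_a, float), (N_SEX,)).copy()
        self.lam_b = np.broadcast_to(np.asarray(self.lam_b, float), (N_SEX,)).copy()
        self.lam_c = np.broadcast_to(np.asarray(self.lam_c, float), (N_SEX,)).copy()
        for name in ("alpha_obese", "omega_obese", "alpha_inactive",
                     "omega_inactive", "alpha_smoker", "omega_smoker", "mu"):
            setattr(self, name, _as_sex_age(getattr(self, name), name))
        self.entry_rate0 = np.broadcast_to(np.asarray(self.entry_rate0, float), (N_SEX,)).copy()
        self.entry_profile_mix = np.asarray(self.entry_profile_mix, float).copy()
        self.validate()

    def validate(self) -> None:
        for name, v in (("rr_obese", self.rr_obese), ("rr_inactive", self.rr_inactive),
                        ("rr_smoker", self.rr_smoker)):
            if not v >= 1.0:
                raise ParameterError(f"{name} must be >= 1, got {v}")
        if not self.kappa_t2dm >= 1.0:
            raise ParameterError(f"kappa_t2dm must be >= 1, got {self.kappa_t2dm}")
        if np.any(self.entry_rate0 < 0):
            raise ParameterError("entry_rate0 must be non-negative")
        if abs(self.entry_profile_mix.sum() - 1.0) > 1e-9 or np.any(self.entry_profile_mix < 0):
            raise ParameterError("entry_profile_mix must be non-negative and sum to 1")

    # -- derived arrays -----------------------------------------------------

    def lambda0(self) -> np.ndarray:
        """Baseline (risk-factor-free) T2DM hazard, shape (sex, age band)."""
        out = np.exp(self.lam_a[:, None] + self.lam_b[:, None] * _X_AGE[None, :]
                     + self.lam_c[:, None] * _X_AGE[None, :] ** 2)
        if np.any(out <= 0) or np.any(~np.isfinite(out)):
            raise ParameterError("lambda0 must be positive and finite")
        return out

    def profile_rr(self) -> np.ndarray:
        """Multiplicative relative risk per risk profile, shape (8,)."""
        return (np.where(PROFILE_OBESE, self.rr_obese, 1.0)
                * np.where(PROFILE_INACTIVE, self.rr_inactive, 1.0)
                * np.where(PROFILE_SMOKER, self.rr_smoker, 1.0))

    def trend(self, t: float) -> float:
        tau = t - self.trend_ref_year
        return math.exp(self.gamma * tau + self.gamma2 * tau * tau)

    def copy(self) -> "NaturalHistoryParams":
        return replace(
            self,
            lam_a=self.lam_a.copy(), lam_b=self.lam_b.copy(), lam_c=self.lam_c.copy(),
            alpha_obese=self.alpha_obese.copy(), omega_obese=self.omega_obese.copy(),
            alpha_inactive=self.alpha_inactive.copy(), omega_inactive=self.omega_inactive.copy(),
            alpha_smoker=self.alpha_smoker.copy(), omega_smoker=self.omega_smoker.copy(),
            mu=self.mu.copy(), entry_rate0=self.entry_rate0.copy(),
            entry_profile_mix=self.entry_profile_mix.copy(),
        )

    def to_dict(self) -> dict:
        d = {}
        for name in ("lam_a", "lam_b", "lam_c", "alpha_obese", "omega_obese",
                     "alpha_inactive", "omega_inactive", "alpha_smoker",
                     "omega_smoker", "mu", "entry_rate0", "entry_profile_mix"):
            d[name] = getattr(self, name).tolist()
        for name in ("gamma", "gamma2", "trend_ref_year", "rr_obese", "rr_inactive",
                     "rr_smoker", "obesity_drift", "kappa_t2dm", "entry_growth"):
            d[name] = float(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        return cls(**{k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.items()})


def incidence_hazard(profile: RiskProfile, sex: int, age_band: int,
                     params: NaturalHistoryParams, effect_multiplier: float = 1.0) -> float:
    """T2DM onset hazard for one compartment (per person-year).

    ``lambda0(sex, age band)`` times the product of relative risks of the risk
    factors present, times an intervention effect multiplier in (0, 1].
    ``age_band`` is 1-based (1..20).
    """
    if not 0.0 < effect_multiplier <= 1.0:
        raise ParameterError(f"effect_multiplier must be in (0, 1], got {effect_multiplier}")
    if not 1 <= age_band <= N_AGE:
        raise ParameterError(f"age_band must be in 1..{N_AGE}, got {age_band}")
    lam0 = params.lambda0()[sex, age_band - 1]
    rr = 1.0
    if profile.obese:
        rr *= params.rr_obese
    if profile.inactive:
        rr *= params.rr_inactive
    if profile.smoker:
        rr *= params.rr_smoker
    return float(lam0 * rr * effect_multiplier)


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Population counts over the full lattice plus flow accumulators.

    ``counts`` has shape (sex, age band, profile, status, coverage class);
    ``cum_inc`` (sex, age band) accumulates every T2DM onset since t0.
    ``cum_in`` / ``cum_out`` (per sex) accumulate demographic entries at age
    20 and exits (deaths plus aging out at 80), so the exact mass balance
    ``total(t) = total(t0) + cum_in - cum_out`` is checkable on any run.
    """

    counts: np.ndarray
    cum_inc: np.ndarray
    cum_in: np.ndarray = None
    cum_out: np.ndarray = None

    def __post_init__(self) -> None:
        if self.cum_in is None:
            self.cum_in = np.zeros(N_SEX)
        if self.cum_out is None:
            self.cum_out = np.zeros(N_SEX)

    @classmethod
    def zeros(cls, n_coverage: int = 1) -> "ModelState":
        return cls(np.zeros((N_SEX, N_AGE, N_PROFILE, N_STATUS, n_coverage)),
                   np.zeros((N_SEX, N_AGE)), np.zeros(N_SEX), np.zeros(N_SEX))

    @property
    def n_coverage(self) -> int:
        return self.counts.shape[-1]

    def total(self) -> float:
        return float(self.counts.sum())

    def diabetic_total(self) -> float:
        return float(self.counts[:, :, :, DIABETIC, :].sum())

    def copy(self) -> "ModelState":
        return ModelState(self.counts.copy(), self.cum_inc.copy(),
                          self.cum_in.copy(), self.cum_out.copy())

    def validate(self, rel_tol: float = 1e-9) -> None:
        if np.any(~np.isfinite(self.counts)) or np.any(~np.isfinite(self.cum_inc)):
            raise StateError("state contains non-finite counts")
        floor = -rel_tol * max(self.total(), 1.0)
        if np.any(self.counts < floor):
            raise StateError(f"state contains negative counts below {floor:.3g}")

    def clipped(self) -> "ModelState":
        out = self.copy()
        neg = out.counts < 0
        if np.any(out.counts[neg] < -1e-9 * max(out.total(), 1.0)):
            log.warning("clipping negative counts (min %.3g) to zero", out.counts.min())
        out.counts[neg] = 0.0
        return out

    def pack(self) -> np.ndarray:
        return np.concatenate([self.counts.ravel(), self.cum_inc.ravel(),
                               self.cum_in.ravel(), self.cum_out.ravel()])

    @classmethod
    def unpack(cls, y: np.ndarray, n_coverage: int) -> "ModelState":
        n = N_SEX * N_AGE * N_PROFILE * N_STATUS * n_coverage
        m = N_SEX * N_AGE
        counts = y[:n].reshape(N_SEX, N_AGE, N_PROFILE, N_STATUS, n_coverage)
        cum = y[n:n + m].reshape(N_SEX, N_AGE)
        # views into y; copy() before mutating
        return cls(counts, cum, y[n + m:n + m + N_SEX], y[n + m + N_SEX:])


def prevalence(state: ModelState, sex: int | None = None,
               age_range: tuple[float, float] | None = None) -> float:
    """T2DM prevalence (diabetic / total) over an optional sex and age selection."""
    c = state.counts
    if sex is not None:
        c = c[sex:sex + 1]
    if age_range is not None:
        c = c[:, bands_for_age_range(*age_range)]
    tot = c.sum()
    if tot <= 0:
        raise SelectionError("prevalence undefined: selection has zero population")
    return float(c[:, :, :, DIABETIC, :].sum() / tot)


# ---------------------------------------------------------------------------
# Active intervention scenarios (compiled form consumed by the ODE engine)
# ---------------------------------------------------------------------------

@dataclass
class ActiveScenario:
    """Runtime form of one intervention scenario bound to a coverage bit.

    The higher-level scenario specification lives in :mod:`t2dmsim.interventions`;
    this container holds only what the derivative evaluation needs.
    """

    scenario_id: str
    bit: int                               # coverage bit index (0-based)
    elig_mask: np.ndarray                  # (sex, age, profile) bool: target filter
    incidence_multiplier: float = 1.0
    effective_coverage: float = 0.0        # uptake x adherence
    ramp_start: float = 2021.0
    ramp_end: float = 2030.0
    normalize_inactivity: bool = False
    inactivity_rate_cap: float = 10.0      # per year
    # annual piecewise-constant extra obesity-exit rates; index 0 = year ramp_start
    forcing_rates: np.ndarray | None = None
    forcing_year0: float = 2021.0
    tracking_gain: float = 2.0             # per year, coverage-tracking feedback

    def coverage_target(self, t: float) -> float:
        w = np.clip((t - self.ramp_start) / (self.ramp_end - self.ramp_start), 0.0, 1.0)
        return self.effective_coverage * float(w)

    def coverage_target_slope(self, t: float) -> float:
        if self.ramp_start <= t < self.ramp_end:
            return self.effective_coverage / (self.ramp_end - self.ramp_start)
        return 0.0

    def forcing_rate(self, t: float) -> float:
        if self.forcing_rates is None or len(self.forcing_rates) == 0:
            return 0.0
        i = int(np.clip(math.floor(t - self.forcing_year0), 0, len(self.forcing_rates) - 1))
        if t < self.forcing_year0:
            return 0.0
        return float(self.forcing_rates[i])

    def inactivity_rate(self, t: float) -> float:
        if not self.normalize_inactivity:
            return 0.0
        w = np.clip((t - self.ramp_start) / (self.ramp_end - self.ramp_start), 0.0, 1.0)
        return self.inactivity_rate_cap * float(w)


def _coverage_pairs(n_coverage: int, bit: int) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (without bit, with bit) for one coverage bit."""
    c = np.arange(n_coverage)
    c0 = c[(c >> bit) & 1 == 0]
    return c0, c0 | (1 << bit)


def _effect_multiplier_array(active: Sequence[ActiveScenario], n_coverage: int) -> np.ndarray:
    """Incidence multiplier per (sex, age, profile, coverage class)."""
    mult = np.ones((N_SEX, N_AGE, N_PROFILE, n_coverage))
    for sc in active:
        covered = ((np.arange(n_coverage) >> sc.bit) & 1) == 1
        m = np.where(sc.elig_mask[..., None] & covered[None, None, None, :],
                     sc.incidence_multiplier, 1.0)
        mult *= m
    return mult


def derivatives(state: ModelState, params: NaturalHistoryParams,
                active: Sequence[ActiveScenario], t: float,
                _mult: np.ndarray | None = None) -> ModelState:
    """Time derivative of the model state (same shape as the state).

    Encodes aging at rate 1/(band width), entry at age 20, background mortality
    (times ``kappa_t2dm`` for diabetics), risk-factor acquisition/exit along
    lattice edges, T2DM incidence (susceptible -> diabetic, no remission),
    intervention coverage recruitment, obesity forcing and inactivity
    normalization for covered compartments, and the cumulative-incidence flow.
    """
    state.validate(rel_tol=1e-6)
    return derivatives_unchecked(state, params, active, t, _mult)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Annual snapshots of the model state between two calendar years."""

    years: np.ndarray
    states: list
    params: NaturalHistoryParams

    def state_at(self, year: int) -> ModelState:
        idx = np.where(self.years == year)[0]
        if idx.size == 0:
            raise ValueError(f"year {year} outside trajectory {self.years[0]}-{self.years[-1]}")
        return self.states[int(idx[0])]

    def prevalence(self, year: int, sex: int | None = None,
                   age_range: tuple[float, float] | None = None) -> float:
        return prevalence(self.state_at(year), sex=sex, age_range=age_range)

    def prevalent_cases(self, year: int) -> float:
        return self.state_at(year).diabetic_total()

    def population(self, year: int) -> float:
        return self.state_at(year).total()

    def cumulative_cases(self, year: int) -> float:
        return float(self.state_at(year).cum_inc.sum())

    def mass_balance_error(self) -> float:
        """Relative violation of total(t1) = total(t0) + entries - exits."""
        first, last = self.states[0], self.states[-1]
        expected = (first.total() + (last.cum_in - first.cum_in).sum()
                    - (last.cum_out - first.cum_out).sum())
        return abs(last.total() - expected) / max(first.total(), 1.0)

    def obesity_prevalence(self, year: int,
                           agesex_mask: np.ndarray | None = None,
                           coverage_sel: np.ndarray | None = None) -> float:
        c = self.state_at(year).counts
        if coverage_sel is not None:
            c = c[..., coverage_sel]
        if agesex_mask is not None:
            c = np.where(agesex_mask[:, :, None, None, None], c, 0.0)
        tot = c.sum()
        if tot <= 0:
            raise SelectionError("obesity prevalence undefined: empty selection")
        return float(c[:, :, PROFILE_OBESE, :, :].sum() / tot)

    def aggregate_frame(self):
        """Year-indexed DataFrame of prevalence, new cases and prevalent cases."""
        import pandas as pd

        years = [int(y) for y in self.years[:-1]] if len(self.years) > 1 else [int(self.years[0])]
        rows = []
        for y in years:
            try:
                nc = annual_new_cases(self, y)
            except ValueError:
                nc = np.nan
            rows.append({"year": y, "prevalence": self.prevalence(y),
                         "annual_new_cases": nc,
                         "prevalent_cases": self.prevalent_cases(y),
                         "population": self.population(y)})
        return pd.DataFrame(rows).set_index("year")

    def to_long_frame(self):
        """Long-format export: one row per compartment per year."""
        import pandas as pd

        recs = []
        for y, st in zip(self.years, self.states):
            C = st.n_coverage
            for s in range(N_SEX):
                for b in range(N_AGE):
                    for p in range(N_PROFILE):
                        for d_ in range(N_STATUS):
                            for cc in range(C):
                                recs.append((int(y), SEXES[s], b + 1,
                                             bool(p & OBESE_BIT), bool(p & INACTIVE_BIT),
                                             bool(p & SMOKER_BIT),
                                             "diabetic" if d_ else "susceptible", cc,
                                             st.counts[s, b, p, d_, cc]))
        return pd.DataFrame(recs, columns=["year", "sex", "age_band", "obese", "inactive",
                                           "smoker", "status", "coverage", "count"])


def annual_new_cases(trajectory: Trajectory, year: int) -> float:
    """New T2DM cases during calendar year ``year`` (cumulative-incidence difference)."""
    y = np.asarray(trajectory.years)
    if year < y[0] or year + 1 > y[-1]:
        raise ValueError(f"year {year} outside horizon {y[0]}-{y[-1] - 1}")
    out = trajectory.cumulative_cases(year + 1) - trajectory.cumulative_cases(year)
    return float(max(out, 0.0))


def simulate(initial: ModelState, params: NaturalHistoryParams,
             active: Sequence[ActiveScenario] = (), t0: float = 2021.0,
             t1: float = 2051.0, rtol: float = 1e-11, atol: float = 1e-6,
             method: str = "DOP853") -> Trajectory:
    """Integrate the model from ``t0`` to ``t1`` with annual snapshots.

    Deterministic; uses an adaptive high-order Runge-Kutta solver.  With a
    closed system (no entry, no mortality) total population is conserved to
    solver tolerance over the whole horizon.
    """
    initial.validate()
    if t1 < t0:
        raise ValueError(f"t1 ({t1}) must be >= t0 ({t0})")
    if t1 == t0:
        return Trajectory(np.array([t0]), [initial.copy()], params)
    C = initial.n_coverage
    mult = _effect_multiplier_array(active, C)

    def rhs(t, y):
        # the integrator may probe slightly negative values; evaluate as-is
        st = ModelState.unpack(y, C)
        return derivatives_unchecked(st, params, active, t, mult).pack()

    t_eval = np.arange(math.ceil(t0), math.floor(t1) + 1, dtype=float)
    if t_eval.size == 0 or t_eval[0] != t0:
        t_eval = np.concatenate([[t0], t_eval[t_eval > t0]])
    sol = solve_ivp(rhs, (t0, t1), initial.pack(), method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1] if len(sol.t) else t0}: "
                           f"{sol.message}")
    states = [ModelState.unpack(sol.y[:, i], C).clipped() for i in range(sol.y.shape[1])]
    return Trajectory(sol.t.copy(), states, params)


def derivatives_unchecked(state: ModelState, params: NaturalHistoryParams,
                          active: Sequence[ActiveScenario], t: float,
                          mult: np.ndarray | None = None) -> ModelState:
    """`derivatives` without the state validation (inner solver loop)."""
    C = state.n_coverage
    c = state.counts
    d = np.zeros_like(c)
    tau = t - params.trend_ref_year

    m = mult if mult is not None else _effect_multiplier_array(active, C)
    hazard = (params.lambda0()[:, :, None, None] * params.trend(t)
              * params.profile_rr()[None, None, :, None] * m)
    inc = hazard * c[:, :, :, SUSCEPTIBLE, :]
    d[:, :, :, SUSCEPTIBLE, :] -= inc
    d[:, :, :, DIABETIC, :] += inc
    dcum = inc.sum(axis=(2, 3))

    status_kappa = np.array([1.0, params.kappa_t2dm])
    deaths = c * (params.mu[:, :, None, None, None]
                  * status_kappa[None, None, None, :, None])
    d -= deaths

    aging = c / BAND_WIDTH
    d -= aging
    d[:, 1:] += aging[:, :-1]
    # band-20 outflow leaves the modelled 20-79 population
    dout = deaths.sum(axis=(1, 2, 3, 4)) + aging[:, -1].sum(axis=(1, 2, 3))

    entry = params.entry_rate0 * math.exp(params.entry_growth * tau)
    d[:, 0, :, SUSCEPTIBLE, 0] += entry[:, None] * params.entry_profile_mix[None, :]
    din = entry.copy()

    extra_exit = np.zeros((N_SEX, N_AGE, C))
    damp = np.ones((N_SEX, N_AGE, C))
    for sc in active:
        e = sc.forcing_rate(t)
        if e > 0.0:
            covered = ((np.arange(C) >> sc.bit) & 1) == 1
            agesex = sc.elig_mask.any(axis=2)
            mm = agesex[:, :, None] & covered[None, None, :]
            extra_exit += np.where(mm, e, 0.0)
            damp *= np.where(mm, 1.0 / (1.0 + e), 1.0)

    alpha_ob = params.alpha_obese * math.exp(params.obesity_drift * tau)
    for factor, alpha, omega in (
        ("obese", alpha_ob, params.omega_obese),
        ("inactive", params.alpha_inactive, params.omega_inactive),
        ("smoker", params.alpha_smoker, params.omega_smoker),
    ):
        i0 = np.array([p[0] for p in FACTOR_PAIRS[factor]])
        i1 = np.array([p[1] for p in FACTOR_PAIRS[factor]])
        if factor == "obese":
            acq = (alpha[:, :, None, None, None] * damp[:, :, None, None, :]
                   * c[:, :, i0, :, :])
            ext = ((omega[:, :, None, None, None] + extra_exit[:, :, None, None, :])
                   * c[:, :, i1, :, :])
        else:
            acq = alpha[:, :, None, None, None] * c[:, :, i0, :, :]
            ext = omega[:, :, None, None, None] * c[:, :, i1, :, :]
        d[:, :, i0, :, :] += ext - acq
        d[:, :, i1, :, :] += acq - ext

    for sc in active:
        nu = sc.inactivity_rate(t)
        if nu > 0.0:
            covered = ((np.arange(C) >> sc.bit) & 1) == 1
            i0 = np.array([p[0] for p in FACTOR_PAIRS["inactive"]])
            i1 = np.array([p[1] for p in FACTOR_PAIRS["inactive"]])
            agesex = sc.elig_mask.any(axis=2)
            mm = (agesex[:, :, None] & covered[None, None, :]).astype(float)
            flow = nu * c[:, :, i1, :, :] * mm[:, :, None, None, :]
            d[:, :, i1, :, :] -= flow
            d[:, :, i0, :, :] += flow

    for sc in active:
        # coverage tracks the ramp target within every eligible (sex, age
        # band) stratum, so the covered fraction does not drift above target
        # at high-risk ages as covered people age
        c0, c1 = _coverage_pairs(C, sc.bit)
        elig = sc.elig_mask[:, :, :, None, None]
        elig_counts = np.where(elig, c, 0.0)
        tot_sb = elig_counts.sum(axis=(2, 3, 4))
        cov_sb = elig_counts[..., c1].sum(axis=(2, 3, 4))
        with np.errstate(invalid="ignore", divide="ignore"):
            f_sb = np.where(tot_sb > 0, cov_sb / np.maximum(tot_sb, 1e-300), 0.0)
        f_tgt = sc.coverage_target(t)
        rho = sc.coverage_target_slope(t) + sc.tracking_gain * (f_tgt - f_sb)
        rho = np.where((tot_sb > 0) & (f_sb < 1.0) & (rho > 0.0),
                       rho / np.maximum(1.0 - f_sb, 1e-9), 0.0)
        flow = rho[:, :, None, None, None] * elig_counts[..., c0]
        d[..., c0] -= flow
        d[..., c1] += flow

    return ModelState(d, dcum, din, dout)
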