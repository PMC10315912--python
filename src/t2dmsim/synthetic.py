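"""Synthetic Qatar-like baseline dataset generator.

The original national calibration data are not publicly deposited, so this
module fabricates a self-consistent stand-in world: it constructs a
ground-truth parameter set for the compartmental model and solves six scalar
knobs so that the simulated truth reproduces the published aggregate anchors —
T2DM prevalence 17.1% (2021) rising to 29.5% (2050), prevalent cases 33,821
and 84,516 (hence population totals 197,784 and 286,495), annual new cases
2,145 (2021) and 3,931 (2050), baseline obesity prevalence 53.3% in 2030, and
a cumulative 2021-2050 incidence of ~81,700 cases.  The calibration-target
surfaces (population, T2DM and risk-factor prevalence by sex, age band and
year) are then tabulated from that truth simulation, so they are dynamically
consistent with the model family by construction.

This is an explicit stand-in for the original survey data, not a
reconstruction of them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import model
from .model import (AGE_MIDPOINTS, DIABETIC, N_AGE, N_PROFILE, N_SEX, N_STATUS,
                    SEXES, SUSCEPTIBLE, ModelState, NaturalHistoryParams,
                    PROFILE_INACTIVE, PROFILE_OBESE, PROFILE_SMOKER)

TARGET_COLUMNS = ["sex", "age_band", "year", "population", "t2dm_prev",
                  "obesity_prev", "inactivity_prev", "smoking_prev"]


class ValidationError(ValueError):
    """A baseline-configuration field is out of range."""


class TargetsParseError(ValueError):
    """A calibration-targets CSV is malformed."""


@dataclass
class BaselineConfig:
    """Aggregate anchors and shape parameters of the synthetic baseline.

    Defaults equal the published values: prevalence anchors and case counts
    for 2021/2050, obesity prevalence 53.3% in 2030, and the 2023 physical
    inactivity (46.5%) and smoking (20.7%) prevalences held flat.  Population
    totals are derived as cases / prevalence.
    """

    start_year: int = 2021
    end_year: int = 2050
    t2dm_prev_start: float = 0.171
    t2dm_prev_end: float = 0.295
    cases_start: float = 33_821.0
    cases_end: float = 84_516.0
    new_cases_start: float = 2_145.0
    new_cases_end: float = 3_931.0
    cum_new_cases: float = 81_700.0      # implied cumulative 2021-2050 incidence
    obesity_prev_2030: float = 0.533
    inactivity_prev_2023: float = 0.465
    smoking_prev_2023: float = 0.207
    sex_ratio: float = 0.5               # fraction male
    # gaussian-in-age population density: (mode age, sd in years)
    age_profile_shape: tuple[float, float] = (30.0, 16.0)
    # logistic-in-age T2DM prevalence: (midpoint age, scale in years)
    t2dm_age_shape: tuple[float, float] = (50.0, 8.0)
    seed: int = 0

    @property
    def pop_20_79_start(self) -> float:
        return self.cases_start / self.t2dm_prev_start

    @property
    def pop_20_79_end(self) -> float:
        return self.cases_end / self.t2dm_prev_end

    @property
    def obesity_prev_start(self) -> float:
        # linear continuation of the 53.1% (2023) -> 53.3% (2030) gradient
        return self.obesity_prev_2030 - 0.0026

    def validate(self) -> None:
        if not self.start_year < self.end_year:
            raise ValidationError("start_year must precede end_year")
        for name in ("t2dm_prev_start", "t2dm_prev_end", "obesity_prev_2030",
                     "inactivity_prev_2023", "smoking_prev_2023", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("cases_start", "cases_end", "new_cases_start",
                     "new_cases_end", "cum_new_cases"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.t2dm_prev_start < 1.0:
            raise ValidationError("t2dm_prev_start must be in (0, 1)")


# ---------------------------------------------------------------------------
# Calibration targets container + CSV round trip
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTargets:
    """Sex x age-band x year surfaces of population and prevalences."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in TARGET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TargetsParseError(f"missing column(s): {', '.join(missing)}")
        f = self.frame
        if len(f) == 0:
            raise TargetsParseError("targets table is empty")
        for col in TARGET_COLUMNS[3:]:
            vals = pd.to_numeric(f[col], errors="coerce")
            bad = vals.isna()
            if bad.any():
                row = int(np.where(bad)[0][0])
                raise TargetsParseError(f"non-numeric value in column '{col}', row {row}")
        prev_cols = ["t2dm_prev", "obesity_prev", "inactivity_prev", "smoking_prev"]
        if (f[prev_cols].to_numpy() < 0).any() or (f[prev_cols].to_numpy() > 1).any():
            raise TargetsParseError("prevalences must lie in [0, 1]")
        if (f["population"].to_numpy() < 0).any():
            raise TargetsParseError("population counts must be non-negative")
        years = sorted(f["year"].unique())
        per_year = f.groupby("year").size()
        if per_year.nunique() != 1 or per_year.iloc[0] != N_SEX * N_AGE:
            raise TargetsParseError("every (sex, age_band) must be present for every year")
        self._years = [int(y) for y in years]

    @property
    def years(self) -> list[int]:
        return self._years

    @property
    def start_year(self) -> int:
        return self._years[0]

    @property
    def end_year(self) -> int:
        return self._years[-1]

    def surface(self, column: str) -> np.ndarray:
        """Array (sex, age band, year) of one numeric column."""
        f = self.frame.copy()
        f["sex_i"] = f["sex"].map({s: i for i, s in enumerate(SEXES)})
        f["year_i"] = f["year"].map({y: i for i, y in enumerate(self._years)})
        out = np.zeros((N_SEX, N_AGE, len(self._years)))
        out[f["sex_i"].to_numpy(), f["age_band"].to_numpy() - 1,
            f["year_i"].to_numpy()] = f[column].to_numpy(float)
        return out

    def aggregate(self, column: str, year: int) -> float:
        """Population-weighted aggregate prevalence (or total population)."""
        f = self.frame[self.frame["year"] == year]
        if len(f) == 0:
            raise ValueError(f"year {year} not in targets")
        if column == "population":
            return float(f["population"].sum())
        w = f["population"].to_numpy(float)
        return float(np.average(f[column].to_numpy(float), weights=w))

    def equals(self, other: "CalibrationTargets", tol: float = 1e-9) -> bool:
        a = self.frame.sort_values(["year", "sex", "age_band"]).reset_index(drop=True)
        b = other.frame.sort_values(["year", "sex", "age_band"]).reset_index(drop=True)
        if not (a["sex"].tolist() == b["sex"].tolist()
                and a["age_band"].tolist() == b["age_band"].tolist()
                and a["year"].tolist() == b["year"].tolist()):
            return False
        num = TARGET_COLUMNS[3:]
        return bool(np.allclose(a[num].to_numpy(float), b[num].to_numpy(float),
                                rtol=0, atol=tol))


def write_targets(targets: CalibrationTargets, path) -> None:
    """Write the targets table as UTF-8 CSV ('.' decimal, full float precision)."""
    f = targets.frame[TARGET_COLUMNS].sort_values(["year", "sex", "age_band"])
    f.to_csv(path, index=False)


def read_targets(path) -> CalibrationTargets:
    """Read a targets CSV; raises :class:`TargetsParseError` on malformed input."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TargetsParseError("targets file is empty") from exc
    if "age_band" in frame.columns:
        frame["age_band"] = pd.to_numeric(frame["age_band"], errors="coerce")
        if frame["age_band"].isna().any():
            raise TargetsParseError("non-numeric value in column 'age_band'")
        frame["age_band"] = frame["age_band"].astype(int)
    return CalibrationTargets(frame)


# ---------------------------------------------------------------------------
# Base (pre-solve) parameter construction, shared with calibration defaults
# ---------------------------------------------------------------------------

def equilibrium_rates(prev: np.ndarray, omega: float) -> np.ndarray:
    """Acquisition rate alpha = omega * p / (1 - p) holding prevalence p steady."""
    p = np.clip(np.asarray(prev, float), 0.0, 0.995)
    return omega * p / (1.0 - p)


# slow obesity remission, moderate activity churn, low smoking uptake/quit
OMEGA_OBESE = 0.02
OMEGA_INACTIVE = 0.10
OMEGA_SMOKER = 0.03


def base_params_from_marginals(pop_sb: np.ndarray, ob_sb: np.ndarray,
                               inact_sb: np.ndarray, smok_sb: np.ndarray,
                               mu_sb: np.ndarray, growth: float,
                               ref_year: float) -> NaturalHistoryParams:
    """Natural-history parameters with transitions at equilibrium for the given
    first-year marginals and an entry flow that balances aging-out, deaths and
    the target demographic growth rate."""
    # demographic balance: entry = growth + deaths + aging out of the top band
    entry0 = np.zeros(N_SEX)
    for s in range(N_SEX):
        deaths = float((mu_sb[s] * pop_sb[s]).sum())
        top_out = pop_sb[s, -1] / model.BAND_WIDTH
        entry0[s] = growth * pop_sb[s].sum() + deaths + top_out
    # entry profile: band-1 marginals, factors independent
    mix = np.ones(N_PROFILE)
    po, pi, ps = float(np.mean(ob_sb[:, 0])), float(np.mean(inact_sb[:, 0])), \
        float(np.mean(smok_sb[:, 0]))
    mix *= np.where(PROFILE_OBESE, po, 1 - po)
    mix *= np.where(PROFILE_INACTIVE, pi, 1 - pi)
    mix *= np.where(PROFILE_SMOKER, ps, 1 - ps)
    return NaturalHistoryParams(
        alpha_obese=equilibrium_rates(ob_sb, OMEGA_OBESE),
        omega_obese=np.full((N_SEX, N_AGE), OMEGA_OBESE),
        alpha_inactive=equilibrium_rates(inact_sb, OMEGA_INACTIVE),
        omega_inactive=np.full((N_SEX, N_AGE), OMEGA_INACTIVE),
        alpha_smoker=equilibrium_rates(smok_sb, OMEGA_SMOKER),
        omega_smoker=np.full((N_SEX, N_AGE), OMEGA_SMOKER),
        mu=mu_sb.copy(),
        entry_rate0=entry0,
        entry_growth=growth,
        entry_profile_mix=mix / mix.sum(),
        trend_ref_year=ref_year,
    )


def initial_state_from_marginals(pop_sb: np.ndarray, t2dm_sb: np.ndarray,
                                 ob_sb: np.ndarray, inact_sb: np.ndarray,
                                 smok_sb: np.ndarray,
                                 n_coverage: int = 1) -> ModelState:
    """Model state with independent risk factors within each (sex, band) cell
    and a status split that is uniform across risk profiles."""
    st = ModelState.zeros(n_coverage)
    prof = np.ones((N_SEX, N_AGE, N_PROFILE))
    prof *= np.where(PROFILE_OBESE[None, None, :], ob_sb[:, :, None],
                     1 - ob_sb[:, :, None])
    prof *= np.where(PROFILE_INACTIVE[None, None, :], inact_sb[:, :, None],
                     1 - inact_sb[:, :, None])
    prof *= np.where(PROFILE_SMOKER[None, None, :], smok_sb[:, :, None],
                     1 - smok_sb[:, :, None])
    base = pop_sb[:, :, None] * prof
    st.counts[:, :, :, SUSCEPTIBLE, 0] = base * (1 - t2dm_sb[:, :, None])
    st.counts[:, :, :, DIABETIC, 0] = base * t2dm_sb[:, :, None]
    return st


def initial_state_from_targets(targets: CalibrationTargets,
                               year: int | None = None,
                               n_coverage: int = 1) -> ModelState:
    """Initial model state reconstructed from a targets table at one year."""
    y = targets.start_year if year is None else year
    i = targets.years.index(y)
    return initial_state_from_marginals(
        targets.surface("population")[:, :, i],
        targets.surface("t2dm_prev")[:, :, i],
        targets.surface("obesity_prev")[:, :, i],
        targets.surface("inactivity_prev")[:, :, i],
        targets.surface("smoking_prev")[:, :, i],
        n_coverage=n_coverage,
    )


# ---------------------------------------------------------------------------
# Ground-truth construction
# ---------------------------------------------------------------------------

def _config_marginals(config: BaselineConfig):
    """First-year (sex, band) marginal surfaces implied by the config."""
    mode, sd = config.age_profile_shape
    dens = np.exp(-0.5 * ((AGE_MIDPOINTS - mode) / sd) ** 2)
    dens /= dens.sum()
    pop = np.zeros((N_SEX, N_AGE))
    pop[0] = (1 - config.sex_ratio) * config.pop_20_79_start * dens
    pop[1] = config.sex_ratio * config.pop_20_79_start * dens

    a0, s0 = config.t2dm_age_shape
    shape = 1.0 / (1.0 + np.exp(-(AGE_MIDPOINTS - a0) / s0))
    scale = config.t2dm_prev_start / float(np.average(shape, weights=dens))
    t2dm = np.tile(np.clip(scale * shape, 0.0, 0.97), (N_SEX, 1))

    ob_shape = 1.0 + 0.15 * np.tanh((AGE_MIDPOINTS - 45.0) / 15.0)
    ob_scale = config.obesity_prev_start / float(np.average(ob_shape, weights=dens))
    ob = np.tile(np.clip(ob_scale * ob_shape, 0.0, 0.95), (N_SEX, 1))

    inact = np.full((N_SEX, N_AGE), config.inactivity_prev_2023)
    smok = np.full((N_SEX, N_AGE), config.smoking_prev_2023)
    return pop, t2dm, ob, inact, smok


def _growth_rate(config: BaselineConfig) -> float:
    return float(np.log(config.pop_20_79_end / config.pop_20_79_start)
                 / (config.end_year - config.start_year))


_SOLVE_KNOBS = ("log_hazard_scale", "gamma", "gamma2", "log_mu_scale",
                "log_entry_scale", "obesity_drift")


def _apply_knobs(base: NaturalHistoryParams, x: np.ndarray) -> NaturalHistoryParams:
    p = base.copy()
    p.lam_a = p.lam_a + x[0]
    p.gamma = float(x[1])
    p.gamma2 = float(x[2])
    p.mu = p.mu * np.exp(x[3])
    p.entry_rate0 = p.entry_rate0 * np.exp(x[4])
    p.obesity_drift = float(x[5])
    return p


def _anchor_residuals(traj: model.Trajectory, config: BaselineConfig) -> np.ndarray:
    y0, y1 = config.start_year, config.end_year
    i_start = model.annual_new_cases(traj, y0)
    i_end = model.annual_new_cases(traj, y1)
    cum = traj.cumulative_cases(y1 + 1)
    prev_end = traj.prevalence(y1)
    pop_end = traj.population(y1)
    ob_2030 = traj.obesity_prevalence(min(2030, y1))
    return np.array([
        i_start / config.new_cases_start - 1.0,
        i_end / config.new_cases_end - 1.0,
        (prev_end - config.t2dm_prev_end) / max(config.t2dm_prev_end, 1e-6),
        pop_end / config.pop_20_79_end - 1.0,
        cum / config.cum_new_cases - 1.0,
        (ob_2030 - config.obesity_prev_2030) / max(config.obesity_prev_2030, 1e-6),
    ])


def generate_truth(config: BaselineConfig | None = None,
                   solver_rtol: float = 1e-8):
    """Solve the ground-truth world behind the synthetic baseline.

    Returns ``(params, initial_state, trajectory)`` where the trajectory is the
    no-intervention truth simulation whose annual surfaces become the
    calibration targets.
    """
    config = config or BaselineConfig()
    config.validate()
    pop, t2dm, ob, inact, smok = _config_marginals(config)
    growth = _growth_rate(config)
    base = base_params_from_marginals(pop, ob, inact, smok,
                                      np.tile(model.DEFAULT_MU, (N_SEX, 1)),
                                      growth, float(config.start_year))
    init = initial_state_from_marginals(pop, t2dm, ob, inact, smok)
    t0, t1 = float(config.start_year), float(config.end_year + 1)

    # analytic starting point for the hazard scale: match the instantaneous
    # incidence flow at t0 to the first-year new-case anchor
    d0 = model.derivatives(init, base, (), t0)
    inc0 = float(d0.cum_inc.sum())
    x0 = np.array([np.log(config.new_cases_start / max(inc0, 1e-9)),
                   0.015, 0.0, 0.0, 0.0, 0.0])

    def resid(x):
        p = _apply_knobs(base, x)
        traj = model.simulate(init, p, (), t0, t1, rtol=solver_rtol, atol=1e-4,
                              method="RK45")
        return _anchor_residuals(traj, config)

    sol = optimize.root(resid, x0, method="hybr", tol=1e-10)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-5:
        raise RuntimeError(f"baseline anchor solve failed: {sol.message} "
                           f"(max residual {np.max(np.abs(sol.fun)):.2e})")
    params = _apply_knobs(base, sol.x)
    traj = model.simulate(init, params, (), t0, t1)
    return params, init, traj


def _tabulate(traj: model.Trajectory, years: list[int]) -> CalibrationTargets:
    rows = []
    for y in years:
        st = traj.state_at(y)
        c = st.counts
        pop_sb = c.sum(axis=(2, 3, 4))
        with np.errstate(invalid="ignore"):
            t2dm = c[:, :, :, DIABETIC, :].sum(axis=(2, 3)) / pop_sb
            obp = c[:, :, PROFILE_OBESE, :, :].sum(axis=(2, 3, 4)) / pop_sb
            inp = c[:, :, PROFILE_INACTIVE, :, :].sum(axis=(2, 3, 4)) / pop_sb
            smp = c[:, :, PROFILE_SMOKER, :, :].sum(axis=(2, 3, 4)) / pop_sb
        for s, sex in enumerate(SEXES):
            for b in range(N_AGE):
                rows.append((sex, b + 1, int(y), pop_sb[s, b],
                             np.nan_to_num(t2dm[s, b]),
                             np.nan_to_num(obp[s, b]),
                             np.nan_to_num(inp[s, b]),
                             np.nan_to_num(smp[s, b])))
    return CalibrationTargets(pd.DataFrame(rows, columns=TARGET_COLUMNS))


def generate_baseline(config: BaselineConfig | None = None) -> CalibrationTargets:
    """Generate the synthetic calibration-target surfaces.

    Deterministic for a fixed config; the aggregate anchors are reproduced by
    construction (2021 prevalence exactly, the solved anchors to the root
    solver's tolerance).
    """
    config = config or BaselineConfig()
    _, _, traj = generate_truth(config)
    years = list(range(config.start_year, config.end_year + 1))
    return _tabulate(traj, years)
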