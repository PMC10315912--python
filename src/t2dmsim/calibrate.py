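"""Nonlinear least-squares calibration of the natural-history parameters.

The fit minimises weighted squared differences between simulated and target
surfaces (T2DM, obesity, inactivity and smoking prevalence plus population
counts) over sex x age band x calendar year.  Free parameters are a named
subset of the natural-history parameterisation; each named parameter is a
transform applied to the caller-supplied initial parameter set, so scale-type
parameters (mortality, entry flow) are expressed as log multipliers of the
initial values.  A bounded trust-region reflective solver is used, optionally
with seeded multistart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model, synthetic
from .model import DIABETIC, N_AGE, N_SEX, NaturalHistoryParams, SEXES
from .model import PROFILE_INACTIVE, PROFILE_OBESE, PROFILE_SMOKER
from .synthetic import CalibrationTargets

log = logging.getLogger(__name__)

FAMILIES = ("t2dm_prev", "obesity_prev", "inactivity_prev", "smoking_prev", "population")

# parameter name -> setter(params, value); values are absolute unless the name
# starts with log_, in which case they multiply the initial parameter set
_SETTERS = {
    "lam_a_f": lambda p, v: p.lam_a.__setitem__(0, v),
    "lam_a_m": lambda p, v: p.lam_a.__setitem__(1, v),
    "lam_b_f": lambda p, v: p.lam_b.__setitem__(0, v),
    "lam_b_m": lambda p, v: p.lam_b.__setitem__(1, v),
    "lam_c_f": lambda p, v: p.lam_c.__setitem__(0, v),
    "lam_c_m": lambda p, v: p.lam_c.__setitem__(1, v),
    "gamma": lambda p, v: setattr(p, "gamma", float(v)),
    "gamma2": lambda p, v: setattr(p, "gamma2", float(v)),
    "obesity_drift": lambda p, v: setattr(p, "obesity_drift", float(v)),
    "log_hazard_scale": lambda p, v: setattr(p, "lam_a", p.lam_a + v),
    "log_mu_scale": lambda p, v: setattr(p, "mu", p.mu * np.exp(v)),
    "log_entry_scale": lambda p, v: setattr(p, "entry_rate0", p.entry_rate0 * np.exp(v)),
    "log_alpha_obese_scale": lambda p, v: setattr(p, "alpha_obese", p.alpha_obese * np.exp(v)),
}

DEFAULT_BOUNDS = {
    "lam_a_f": (-9.0, -2.0), "lam_a_m": (-9.0, -2.0),
    "lam_b_f": (-0.5, 1.0), "lam_b_m": (-0.5, 1.0),
    "lam_c_f": (-1.0, 0.0), "lam_c_m": (-1.0, 0.0),
    "gamma": (-0.10, 0.10), "gamma2": (-0.005, 0.005),
    "obesity_drift": (-0.06, 0.06),
    "log_hazard_scale": (-2.0, 2.0),
    "log_mu_scale": (-1.5, 1.5),
    "log_entry_scale": (-1.0, 1.0),
    "log_alpha_obese_scale": (-1.5, 1.5),
}

DEFAULT_FREE = ("lam_a_f", "lam_a_m", "lam_b_f", "lam_b_m", "lam_c_f", "lam_c_m",
                "gamma", "gamma2", "log_mu_scale", "log_entry_scale", "obesity_drift")


class FitError(ValueError):
    """A fit specification is invalid."""


@dataclass
class FitSpec:
    """Free parameters, bounds, loss weights and optimizer settings.

    Weights put the prevalence families on a percentage-point scale and the
    population family on a percent scale so the families contribute comparably.
    """

    free: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {n: DEFAULT_BOUNDS[n] for n in DEFAULT_FREE})
    weights: dict[str, float] = field(
        default_factory=lambda: {f: 100.0 for f in FAMILIES})
    max_iter: int = 60
    tol: float = 1e-12
    n_starts: int = 1
    seed: int = 0
    solver_rtol: float = 1e-8

    @classmethod
    def from_yaml(cls, path) -> "FitSpec":
        """Load a fit specification from YAML (free params, weights, options)."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "free" in raw:
            kw["free"] = {k: (float(v[0]), float(v[1]))
                          for k, v in raw["free"].items()}
        if "weights" in raw:
            kw["weights"] = {k: float(v) for k, v in raw["weights"].items()}
        for key in ("max_iter", "n_starts", "seed"):
            if key in raw:
                kw[key] = int(raw[key])
        for key in ("tol", "solver_rtol"):
            if key in raw:
                kw[key] = float(raw[key])
        spec = cls(**kw)
        spec.validate()
        return spec

    def validate(self) -> None:
        if not self.free:
            raise FitError("at least one free parameter is required")
        for name, (lo, hi) in self.free.items():
            if name not in _SETTERS:
                raise FitError(f"unknown free parameter '{name}'")
            if not lo < hi:
                raise FitError(f"bounds for '{name}' must satisfy lower < upper")
        if any(w < 0 for w in self.weights.values()) or not any(
                w > 0 for w in self.weights.values()):
            raise FitError("weights must be non-negative and not all zero")


@dataclass
class FitResult:
    """Fitted parameters plus diagnostics of the least-squares solve."""

    params: NaturalHistoryParams
    rss: float
    family_rss: dict[str, float]
    converged: bool
    iterations: int
    free_values: dict[str, float]
    loss_history: list[float] = field(default_factory=list)


def apply_free(initial: NaturalHistoryParams, names: list[str],
               x: np.ndarray) -> NaturalHistoryParams:
    p = initial.copy()
    for name, v in zip(names, x):
        _SETTERS[name](p, float(v))
    return p


def default_initial_params(targets: CalibrationTargets) -> NaturalHistoryParams:
    """Analytic starting point built from the first-year target surfaces.

    Risk-factor transition rates are set at equilibrium for the first-year
    marginals, the entry flow balances the observed aggregate growth, and the
    baseline-hazard scale matches the first year's implied onset flow under
    the default age shape.
    """
    y0 = targets.start_year
    i0 = 0
    pop = targets.surface("population")[:, :, i0]
    ob = targets.surface("obesity_prev")[:, :, i0]
    inact = targets.surface("inactivity_prev")[:, :, i0]
    smok = targets.surface("smoking_prev")[:, :, i0]
    growth = float(np.log(targets.aggregate("population", targets.end_year)
                          / targets.aggregate("population", y0))
                   / (targets.end_year - y0))
    p = synthetic.base_params_from_marginals(
        pop, ob, inact, smok, np.tile(model.DEFAULT_MU, (N_SEX, 1)),
        growth, float(y0))
    # rough hazard scale: put the unscaled first-year onset flow near the
    # observed prevalence growth between the first two target years
    init = synthetic.initial_state_from_targets(targets)
    d0 = model.derivatives(init, p, (), float(y0))
    inc0 = float(d0.cum_inc.sum())
    if len(targets.years) > 1:
        i1 = 1
        d_prev = (targets.aggregate("t2dm_prev", targets.years[i1])
                  - targets.aggregate("t2dm_prev", y0))
        implied = max(d_prev, 0.005) * init.total() + 0.02 * init.diabetic_total()
        p.lam_a = p.lam_a + np.log(max(implied, 1.0) / max(inc0, 1e-9))
    return p


def _simulated_surfaces(traj: model.Trajectory, years: list[int]) -> dict[str, np.ndarray]:
    out = {f: np.zeros((N_SEX, N_AGE, len(years))) for f in FAMILIES}
    for j, y in enumerate(years):
        c = traj.state_at(y).counts
        pop_sb = c.sum(axis=(2, 3, 4))
        safe = np.maximum(pop_sb, 1e-12)
        out["population"][:, :, j] = pop_sb
        out["t2dm_prev"][:, :, j] = c[:, :, :, DIABETIC, :].sum(axis=(2, 3)) / safe
        out["obesity_prev"][:, :, j] = c[:, :, PROFILE_OBESE, :, :].sum(axis=(2, 3, 4)) / safe
        out["inactivity_prev"][:, :, j] = c[:, :, PROFILE_INACTIVE, :, :].sum(axis=(2, 3, 4)) / safe
        out["smoking_prev"][:, :, j] = c[:, :, PROFILE_SMOKER, :, :].sum(axis=(2, 3, 4)) / safe
    return out


def _residual_vector(sim: dict[str, np.ndarray], tgt: dict[str, np.ndarray],
                     weights: dict[str, float]) -> np.ndarray:
    parts = []
    for fam in FAMILIES:
        w = weights.get(fam, 0.0)
        if w == 0.0:
            continue
        if fam == "population":
            r = (sim[fam] - tgt[fam]) / np.maximum(tgt[fam], 1.0)
        else:
            r = sim[fam] - tgt[fam]
        parts.append(w * r.ravel())
    return np.concatenate(parts)


def fit_parameters(targets: CalibrationTargets, spec: FitSpec | None = None,
                   initial: NaturalHistoryParams | None = None) -> FitResult:
    """Fit the free parameters to the target surfaces by bounded least squares.

    Non-convergence within the iteration budget yields ``converged=False``
    rather than an exception; a simulation failure at a trial point is logged
    and the point is penalised.
    """
    spec = spec or FitSpec()
    spec.validate()
    if initial is None:
        initial = default_initial_params(targets)
    names = list(spec.free)
    lo = np.array([spec.free[n][0] for n in names])
    hi = np.array([spec.free[n][1] for n in names])
    x0 = np.array([_initial_value(initial, n) for n in names])
    x0 = np.clip(x0, lo, hi)

    years = targets.years
    tgt = {f: targets.surface(f) for f in FAMILIES}
    init_state = synthetic.initial_state_from_targets(targets)
    t0, t1 = float(years[0]), float(years[-1] + 1)
    loss_history: list[float] = []

    def resid(x):
        p = apply_free(initial, names, x)
        try:
            traj = model.simulate(init_state, p, (), t0, t1,
                                  rtol=spec.solver_rtol, atol=1e-4, method="RK45")
            r = _residual_vector(_simulated_surfaces(traj, years), tgt, spec.weights)
        except Exception as exc:  # penalise failed trial points
            log.warning("simulation failed at trial point (%s); penalising", exc)
            r = np.full(_n_resid(spec), 1e3)
        loss_history.append(float(r @ r))
        return r

    def _n_resid(s):
        nf = sum(1 for f in FAMILIES if s.weights.get(f, 0.0) > 0)
        return nf * N_SEX * N_AGE * len(years)

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(max(spec.n_starts - 1, 0)):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best = None
    total_nfev = 0
    for x_start in starts:
        res = least_squares(resid, x_start, bounds=(lo, hi), method="trf",
                            diff_step=1e-3, ftol=spec.tol, xtol=spec.tol,
                            gtol=spec.tol, max_nfev=spec.max_iter * (len(names) + 1))
        total_nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res

    fitted = apply_free(initial, names, best.x)
    traj = model.simulate(init_state, fitted, (), t0, t1,
                          rtol=spec.solver_rtol, atol=1e-4, method="RK45")
    sim = _simulated_surfaces(traj, years)
    fam_rss = {}
    for fam in FAMILIES:
        w = spec.weights.get(fam, 0.0)
        if fam == "population":
            r = (sim[fam] - tgt[fam]) / np.maximum(tgt[fam], 1.0)
        else:
            r = sim[fam] - tgt[fam]
        fam_rss[fam] = float((w * r.ravel()) @ (w * r.ravel()))
    converged = bool(best.status > 0)
    return FitResult(params=fitted, rss=float(2 * best.cost),
                     family_rss=fam_rss, converged=converged,
                     iterations=total_nfev,
                     free_values={n: float(v) for n, v in zip(names, best.x)},
                     loss_history=loss_history)


def _initial_value(initial: NaturalHistoryParams, name: str) -> float:
    direct = {
        "lam_a_f": initial.lam_a[0], "lam_a_m": initial.lam_a[1],
        "lam_b_f": initial.lam_b[0], "lam_b_m": initial.lam_b[1],
        "lam_c_f": initial.lam_c[0], "lam_c_m": initial.lam_c[1],
        "gamma": initial.gamma, "gamma2": initial.gamma2,
        "obesity_drift": initial.obesity_drift,
    }
    if name in direct:
        return float(direct[name])
    return 0.0  # log-scale multipliers are relative to the initial params


def residual_report(result: FitResult, targets: CalibrationTargets) -> pd.DataFrame:
    """Per (sex, age band, year, family) residual table (simulated - target)."""
    years = targets.years
    init_state = synthetic.initial_state_from_targets(targets)
    traj = model.simulate(init_state, result.params, (), float(years[0]),
                          float(years[-1] + 1), rtol=1e-9, atol=1e-5, method="RK45")
    sim = _simulated_surfaces(traj, years)
    rows = []
    for fam in FAMILIES:
        tgt = targets.surface(fam)
        for s, sex in enumerate(SEXES):
            for b in range(N_AGE):
                for j, y in enumerate(years):
                    rows.append((sex, b + 1, int(y), fam, tgt[s, b, j],
                                 sim[fam][s, b, j], sim[fam][s, b, j] - tgt[s, b, j]))
    return pd.DataFrame(rows, columns=["sex", "age_band", "year", "family",
                                       "target", "simulated", "residual"])
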