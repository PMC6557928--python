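"""Flux-objective optimization and parameter estimation.

The flux objective maximizes methane synthesis while penalizing the
amino-acid catabolic burden: score = sum(w_max * J_max) - sum(w_min * J_min),
with every flux evaluated at the steady state of the candidate
parameterization when one exists, otherwise at the end of the batch horizon
(the pre-steady-state protocol).  The search is bounded and derivative-free
(seeded differential evolution) over enzyme-activity parameters.

Parameter estimation is bounded nonlinear least squares on concentration
residuals against observed time courses, with optional multistart from
log-uniform draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from .errors import ConfigurationError, ConvergenceError, SimulationError, SrcmError
from .network import KineticModel, get_parameter, set_parameter
from .simulate import SimulationSettings, simulate_deterministic

__all__ = [
    "ObjectiveSpec",
    "OptimizationResult",
    "FitResult",
    "optimize_flux",
    "fit_parameters",
    "DEFAULT_DECISION_BOUNDS",
]

#: default relative bounds on optimized enzyme activities (x baseline)
DEFAULT_DECISION_BOUNDS = (0.2, 5.0)


@dataclass
class ObjectiveSpec:
    """Scalarized flux objective with box-bounded decision parameters.

    The shipped default maximizes methane synthesis (R13) and minimizes the
    glycine/alanine catabolic fluxes (R1-R3) with weights 1.0 and 0.1.
    ``decision`` maps parameter ids (e.g. ``"R5.vmax"``) to absolute
    (lower, upper) bounds.
    """

    maximize: tuple[str, ...] = ("R13",)
    minimize: tuple[str, ...] = ("R1", "R2", "R3")
    weight_max: float = 1.0
    weight_min: float = 0.1
    decision: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.maximize = tuple(self.maximize)
        self.minimize = tuple(self.minimize)
        if set(self.maximize) & set(self.minimize):
            raise ConfigurationError("maximize and minimize reaction sets must be disjoint")
        for pid, (lo, hi) in self.decision.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"bounds for {pid!r} must be finite with lower < upper")

    def score(self, fluxes: pd.Series) -> float:
        s = sum(self.weight_max * fluxes[r] for r in self.maximize)
        s -= sum(self.weight_min * fluxes[r] for r in self.minimize)
        return float(s)

    @classmethod
    def default_for(cls, model: KineticModel, bounds_scale=DEFAULT_DECISION_BOUNDS):
        """Decision variables: activities of R3, R5, R9, R11 around baseline."""
        decision = {}
        for rid in ("R3", "R5", "R9", "R11"):
            pid = f"{rid}.vmax"
            base = get_parameter(model, pid)
            decision[pid] = (bounds_scale[0] * base, bounds_scale[1] * base)
        return cls(decision=decision)


@dataclass
class OptimizationResult:
    parameters: pd.Series
    objective_value: float
    fluxes: pd.Series
    initial_fluxes: pd.Series
    initial_objective: float
    history: list[float]
    seed: int
    evaluations: int = 0


@dataclass
class FitResult:
    parameters: pd.Series
    rss: float
    success: bool
    n_starts: int
    message: str = ""
    stderr: pd.Series | None = None


def _candidate_fluxes(
    model: KineticModel,
    settings: SimulationSettings,
    state_eval: str,
) -> pd.Series:
    """Fluxes at the steady state when requested/available, else end-of-horizon."""
    if state_eval in ("steady", "auto"):
        from .mca import find_steady_state

        try:
            return find_steady_state(model).fluxes
        except (ConvergenceError, SrcmError):
            if state_eval == "steady":
                raise
    traj = simulate_deterministic(model, settings)
    return traj.fluxes.iloc[-1]


def optimize_flux(
    model: KineticModel,
    objective: ObjectiveSpec,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    state_eval: str = "horizon",
    maxiter: int = 12,
    popsize: int = 6,
    parsimony: bool = True,
) -> OptimizationResult:
    """Maximize the scalarized flux objective over the decision box.

    Seeded differential evolution followed (by default) by a parsimony
    pass that lowers any enzyme activity to its bound when doing so costs
    no objective value — minimal enzyme investment breaks ties in flat
    directions.  The reported optimum never falls below the starting point
    (the incumbent includes the initial parameterization).  Candidates
    whose simulation fails are penalized and skipped.
    """
    for rid in objective.maximize + objective.minimize:
        model.get_reaction(rid)  # raises StructuralError for unknown ids
    settings = settings or SimulationSettings(t_end=30.0, interval=1.0, rtol=1e-6, atol=1e-9)

    initial_fluxes = _candidate_fluxes(model, settings, state_eval)
    initial_score = objective.score(initial_fluxes)

    pids = list(objective.decision)
    if not pids:
        return OptimizationResult(
            parameters=pd.Series(dtype=float),
            objective_value=initial_score,
            fluxes=initial_fluxes,
            initial_fluxes=initial_fluxes,
            initial_objective=initial_score,
            history=[initial_score],
            seed=seed,
        )
    bounds = [objective.decision[p] for p in pids]
    x0 = np.array([np.clip(get_parameter(model, p), lo, hi) for p, (lo, hi) in
                   zip(pids, bounds)])

    history: list[float] = [initial_score]
    n_eval = 0

    def negative_score(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        m = model.copy()
        for pid, val in zip(pids, x):
            set_parameter(m, pid, float(val))
        try:
            fluxes = _candidate_fluxes(m, settings, state_eval)
        except (SimulationError, ConvergenceError):
            return 1e9
        s = objective.score(fluxes)
        if s > history[-1]:
            history.append(s)
        return -s

    result = differential_evolution(
        negative_score,
        bounds=bounds,
        x0=x0,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-8,
        polish=False,
        init="sobol",
        updating="deferred",
    )
    best_x, best_score = result.x, -result.fun
    if best_score < initial_score:
        best_x, best_score = x0, initial_score

    if parsimony:
        # Resolve objective-flat directions toward minimal enzyme investment:
        # an activity is dropped to its lower bound whenever that does not
        # reduce the scalarized objective.
        for idx in range(len(pids)):
            trial = best_x.copy()
            trial[idx] = bounds[idx][0]
            score = -negative_score(trial)
            if score >= best_score:
                best_x, best_score = trial, score

    m = model.copy()
    for pid, val in zip(pids, best_x):
        set_parameter(m, pid, float(val))
    best_fluxes = _candidate_fluxes(m, settings, state_eval)
    return OptimizationResult(
        parameters=pd.Series(best_x, index=pids),
        objective_value=float(best_score),
        fluxes=best_fluxes,
        initial_fluxes=initial_fluxes,
        initial_objective=float(initial_score),
        history=history,
        seed=seed,
        evaluations=n_eval,
    )


def fit_parameters(
    model: KineticModel,
    observed,
    free: dict[str, tuple[float, float]],
    seed: int = 0,
    n_starts: int = 1,
    log_residuals: bool = False,
    settings: SimulationSettings | None = None,
) -> FitResult:
    """Bounded least squares of free parameters against observed time courses.

    ``observed`` is a :class:`~srcmkin.synth.SyntheticDataset` or a tidy
    frame with columns (time, species, replicate, value).  Residuals are
    concentration differences (optionally log1p-scaled).  ``n_starts`` > 1
    adds multistart initial points drawn log-uniformly within bounds under
    ``seed``; integrator failures yield a large penalty residual and the
    candidate is effectively rejected.
    """
    data = observed.data if hasattr(observed, "data") else observed
    required = {"time", "species", "value"}
    if not required <= set(data.columns):
        raise ConfigurationError(f"observed data must have columns {sorted(required)}")
    pids = list(free)
    if not pids:
        raise ConfigurationError("no free parameters given")
    for pid, (lo, hi) in free.items():
        if not lo < hi:
            raise ConfigurationError(f"bounds for {pid!r} must satisfy lower < upper")
    times = np.sort(data["time"].unique())
    horizon = float(times.max())
    if settings is None:
        diffs = np.diff(times)
        step = float(diffs[diffs > 0].min()) if np.any(diffs > 0) else 1.0
        settings = SimulationSettings(t_end=max(horizon, 1e-6), interval=step,
                                      rtol=1e-8, atol=1e-12)
    if horizon > settings.t_end + 1e-9:
        raise ConfigurationError("observation times exceed the simulation horizon")
    species = list(pd.unique(data["species"]))
    for sid in species:
        model.species_index(sid)

    obs_pivot = data.pivot_table(index="time", columns="species", values="value",
                                 aggfunc="mean").reindex(times)[species]
    obs_values = obs_pivot.to_numpy().ravel()

    def residuals(x: np.ndarray) -> np.ndarray:
        m = model.copy()
        for pid, val in zip(pids, x):
            set_parameter(m, pid, float(val))
        try:
            traj = simulate_deterministic(m, settings)
        except SimulationError:
            return np.full(obs_values.shape, 1e6)
        pred = np.column_stack(
            [np.interp(times, traj.time, traj.concentrations[s].to_numpy()) for s in species]
        ).ravel()
        if log_residuals:
            return np.log1p(np.maximum(pred, 0.0)) - np.log1p(np.maximum(obs_values, 0.0))
        return pred - obs_values

    lo = np.array([free[p][0] for p in pids])
    hi = np.array([free[p][1] for p in pids])
    starts = [np.clip([get_parameter(model, p) for p in pids], lo, hi)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac")
        if best is None or sol.cost < best.cost:
            best = sol
    rss = float(2 * best.cost)
    stderr = None
    dof = obs_values.size - len(pids)
    if dof > 0 and best.jac is not None:
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
            stderr = pd.Series(np.sqrt(np.diag(cov)), index=pids)
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        parameters=pd.Series(best.x, index=pids),
        rss=rss,
        success=bool(best.success),
        n_starts=len(starts),
        message=str(best.message),
        stderr=stderr,
    )
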