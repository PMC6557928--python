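"""Steady states, linear stability, elasticities, flux control coefficients,
local parameter sensitivity.

Elasticities are scaled local derivatives e_{j,i} = (x_i/v_j) dv_j/dx_i,
computed analytically from the MM/GMA law shapes.  Flux control coefficients
C^J_e = (e/J) dJ/de are global: each enzyme activity (Vmax for MM, k for
mass action) is scaled by (1 +/- p), the steady state re-solved, and the
target flux differenced centrally.  The summation theorem (sum of C^J over
enzymes = 1) and the connectivity theorem serve as internal consistency
checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError
from .network import (
    KineticModel,
    RateLawKind,
    build_stoich_matrix,
    evaluate_fluxes,
    get_parameter,
    set_parameter,
)
from .simulate import SimulationSettings, simulate_deterministic

__all__ = [
    "SteadyState",
    "ControlAnalysis",
    "SensitivityResult",
    "find_steady_state",
    "jacobian_eigenvalues",
    "elasticity_matrix",
    "flux_control_coefficients",
    "local_sensitivity",
]


@dataclass
class SteadyState:
    state: pd.Series              # all species, mmol/ml
    fluxes: pd.Series             # all reactions, mmol/min/ml
    eigenvalues: np.ndarray       # Jacobian spectrum over internal species
    stable: bool                  # all real parts < 0
    residual_norm: float


@dataclass
class ControlAnalysis:
    elasticities: pd.DataFrame | None = None   # reactions x species
    fcc: pd.DataFrame | None = None            # fluxes x enzymes
    perturbation: float = 0.01
    undefined: set = field(default_factory=set)  # (row, col) flagged entries


@dataclass
class SensitivityResult:
    time: np.ndarray
    sensitivity: pd.DataFrame   # d x(t) / d theta, time x species
    auc: pd.Series              # integral of |dx| per species for the used step
    parameter: str
    perturbation: float


def _internal_rhs(model: KineticModel):
    sm = build_stoich_matrix(model)
    idx = [model.species_index(s) for s in sm.species_ids]
    x_full = model.initial_state()

    def f(y: np.ndarray) -> np.ndarray:
        x = x_full.copy()
        x[idx] = np.maximum(y, 0.0)
        return sm.matrix @ evaluate_fluxes(model, x)

    return f, idx, sm


def _fd_jacobian(f, y: np.ndarray) -> np.ndarray:
    m = len(y)
    jac = np.empty((m, m))
    f0 = f(y)
    for i in range(m):
        h = max(1e-8, 1e-6 * abs(y[i]))
        yp, ym = y.copy(), y.copy()
        yp[i] += h
        ym[i] = max(ym[i] - h, 0.0)
        jac[:, i] = (f(yp) - f(ym)) / (yp[i] - ym[i])
    del f0
    return jac


def find_steady_state(
    model: KineticModel,
    initial_guess: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 60,
    relax_horizon: float = 1000.0,
) -> SteadyState:
    """Root of S·v(x) = 0 over internal species.

    Damped Newton iteration from the initial state (or ``initial_guess``);
    if Newton stagnates, the system is relaxed by long-time integration and
    Newton retried.  Raises :class:`ConvergenceError` carrying the best
    residual when no root with residual norm < ``tol`` is found.
    """
    f, idx, sm = _internal_rhs(model)
    x_full = model.initial_state()
    y = (
        np.asarray(initial_guess, dtype=float)[idx]
        if initial_guess is not None and len(initial_guess) == len(model.species)
        else (np.asarray(initial_guess, dtype=float) if initial_guess is not None else x_full[idx])
    )
    y = np.maximum(y, 0.0)

    def newton(y0: np.ndarray) -> tuple[np.ndarray, float]:
        y = y0.copy()
        res = np.linalg.norm(f(y))
        for _ in range(max_iter):
            if res < tol:
                break
            jac = _fd_jacobian(f, y)
            try:
                step = np.linalg.solve(jac, -f(y))
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jac, -f(y), rcond=None)[0]
            lam, improved = 1.0, False
            for _ in range(40):
                cand = np.maximum(y + lam * step, 0.0)
                r = np.linalg.norm(f(cand))
                if r < res:
                    y, res, improved = cand, r, True
                    break
                lam *= 0.5
            if not improved:
                break
        return y, res

    y1, res1 = newton(y)
    if res1 >= tol:
        # fall back to relaxation by integration, then polish with Newton
        try:
            relax = simulate_deterministic(
                model, SimulationSettings(t_end=relax_horizon, interval=relax_horizon / 50,
                                          rtol=1e-8, atol=1e-10)
            )
            y2, res2 = newton(relax.concentrations.iloc[-1].to_numpy()[idx])
            if res2 < res1:
                y1, res1 = y2, res2
        except Exception:
            pass
    if res1 >= tol:
        raise ConvergenceError(
            f"no steady state found (best residual {res1:.3e})", best_residual=res1
        )
    x = x_full.copy()
    x[idx] = y1
    eig, stable = _eigs(model, x)
    return SteadyState(
        state=pd.Series(x, index=model.species_ids),
        fluxes=pd.Series(evaluate_fluxes(model, x), index=model.reaction_ids),
        eigenvalues=eig,
        stable=stable,
        residual_norm=float(res1),
    )


def _eigs(model: KineticModel, state: np.ndarray) -> tuple[np.ndarray, bool]:
    f, idx, _ = _internal_rhs(model)
    jac = _fd_jacobian(f, np.asarray(state, dtype=float)[idx])
    eig = np.linalg.eigvals(jac)
    return eig, bool(np.all(eig.real < 0))


def jacobian_eigenvalues(model: KineticModel, state) -> tuple[np.ndarray, bool]:
    """Eigenvalues of the internal-species Jacobian of S·v by central differences
    (step max(1e-8, 1e-6|x_i|)) and the stability verdict (all real parts < 0)."""
    state = np.asarray(state, dtype=float)
    return _eigs(model, state)


def elasticity_matrix(model: KineticModel, state) -> ControlAnalysis:
    """Scaled elasticities by analytic differentiation of the rate laws.

    MM: e w.r.t. a driving substrate s is Km/(Km+s); w.r.t. a modifier it is
    1 (Vmax is proportional to enzyme level); GMA: the kinetic order.
    Entries are NaN-flagged when the reaction flux is zero or the species
    concentration is zero (the scaling x/v is degenerate there), never
    silently zeroed.
    """
    x = np.asarray(state, dtype=float)
    v = evaluate_fluxes(model, x)
    mat = np.zeros((len(model.reactions), len(model.species)))
    undefined: set = set()
    for j, r in enumerate(model.reactions):
        law = r.rate_law
        in_law = law.referenced_species()
        for sid in in_law:
            i = model.species_index(sid)
            if v[j] == 0.0 or x[i] == 0.0:
                mat[j, i] = np.nan
                undefined.add((r.id, sid))
                continue
            if law.kind is RateLawKind.MICHAELIS_MENTEN:
                if sid in law.km:
                    mat[j, i] = law.km[sid] / (law.km[sid] + x[i])
                elif sid in law.modifiers:
                    mat[j, i] = 1.0
            else:
                fwd = law.exponents.get(sid, 0.0)
                if r.reversible and law.k_reverse is not None:
                    # net law: e = (g_f*vf - g_r*vr)/v
                    from .network import gma_rate

                    ids_f = list(law.exponents)
                    vf = gma_rate(law.k, [x[model.species_index(s)] for s in ids_f],
                                  [law.exponents[s] for s in ids_f])
                    ids_r = list(law.exponents_reverse)
                    vr = gma_rate(law.k_reverse, [x[model.species_index(s)] for s in ids_r],
                                  [law.exponents_reverse[s] for s in ids_r])
                    gr = law.exponents_reverse.get(sid, 0.0)
                    mat[j, i] = (fwd * vf - gr * vr) / v[j]
                else:
                    mat[j, i] = fwd
    df = pd.DataFrame(mat, index=model.reaction_ids, columns=model.species_ids)
    return ControlAnalysis(elasticities=df, undefined=undefined)


def _enzyme_parameters(model: KineticModel, rid: str) -> list[str]:
    law = model.get_reaction(rid).rate_law
    if law.kind is RateLawKind.MICHAELIS_MENTEN:
        return [f"{rid}.vmax"]
    pids = [f"{rid}.k"]
    if law.k_reverse is not None:
        pids.append(f"{rid}.k_reverse")
    return pids


def flux_control_coefficients(
    model: KineticModel,
    steady_state: SteadyState,
    perturbation: float = 0.01,
    enzymes: dict[str, list[str]] | None = None,
    verify_steps: bool = False,
) -> ControlAnalysis:
    """Central-difference flux control coefficients at a steady state.

    ``enzymes`` maps an enzyme label to the reactions whose activity it
    scales together (default: one enzyme per reaction).  For each enzyme the
    activity parameters are scaled by (1 +/- p), the steady state re-solved
    from the unperturbed one, and C = (J+ - J-)/(2 p J0).  Entries where a
    perturbed steady state cannot be found are NaN-flagged.

    With ``verify_steps`` the matrix is recomputed at half and double the
    perturbation; entries whose estimates disagree by more than 5% relative
    are flagged as step-size unstable (in ``ControlAnalysis.undefined``)
    while keeping the nominal value.
    """
    if verify_steps:
        nominal = flux_control_coefficients(model, steady_state, perturbation, enzymes)
        half = flux_control_coefficients(model, steady_state, perturbation / 2, enzymes)
        dbl = flux_control_coefficients(model, steady_state, perturbation * 2, enzymes)
        a, b = half.fcc.to_numpy(), dbl.fcc.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(a - b) / np.maximum(np.abs(nominal.fcc.to_numpy()), 1e-12)
        for i, rid in enumerate(nominal.fcc.index):
            for j, ename in enumerate(nominal.fcc.columns):
                if not np.isfinite(rel[i, j]) or rel[i, j] > 0.05:
                    nominal.undefined.add((rid, ename))
        return nominal
    if enzymes is None:
        enzymes = {rid: [rid] for rid in model.reaction_ids}
    J0 = steady_state.fluxes.to_numpy()
    fcc = np.full((len(model.reactions), len(enzymes)), np.nan)
    undefined: set = set()
    x0 = steady_state.state.to_numpy()
    for col, (ename, rids) in enumerate(enzymes.items()):
        pids = [p for rid in rids for p in _enzyme_parameters(model, rid)]
        flux_pm = []
        for sgn in (+1, -1):
            m = model.copy()
            for pid in pids:
                set_parameter(m, pid, get_parameter(m, pid) * (1 + sgn * perturbation))
            try:
                ss = find_steady_state(m, initial_guess=x0)
                flux_pm.append(ss.fluxes.to_numpy())
            except ConvergenceError:
                flux_pm.append(None)
        if flux_pm[0] is None or flux_pm[1] is None:
            undefined.update((rid, ename) for rid in model.reaction_ids)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            fcc[:, col] = (flux_pm[0] - flux_pm[1]) / (2 * perturbation * J0)
        for j, rid in enumerate(model.reaction_ids):
            if J0[j] == 0:
                fcc[j, col] = np.nan
                undefined.add((rid, ename))
    df = pd.DataFrame(fcc, index=model.reaction_ids, columns=list(enzymes))
    return ControlAnalysis(fcc=df, perturbation=perturbation, undefined=undefined)


def local_sensitivity(
    model: KineticModel,
    settings: SimulationSettings,
    parameter: str,
    perturbation: float = 0.01,
) -> SensitivityResult:
    """Time-resolved central-difference sensitivity dx(t)/dtheta.

    Also reports, per species, the time integral (trapezoidal) of the
    absolute concentration change |dx(t)| produced by the used step — the
    area-under-curve summary of how strongly the parameter moves each state
    variable.
    """
    theta = get_parameter(model, parameter)
    h = perturbation * abs(theta) if theta != 0 else perturbation
    trajs = []
    for sgn in (+1, -1):
        m = model.copy()
        set_parameter(m, parameter, theta + sgn * h)
        trajs.append(simulate_deterministic(m, settings))
    up, dn = trajs
    sens = (up.concentrations - dn.concentrations) / (2 * h)
    delta = (up.concentrations - dn.concentrations).abs() / 2.0
    auc = pd.Series(
        np.trapezoid(delta.to_numpy(), x=up.time, axis=0), index=delta.columns
    )
    return SensitivityResult(
        time=up.time, sensitivity=sens, auc=auc, parameter=parameter, perturbation=perturbation
    )
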