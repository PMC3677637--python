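"""Time-dependent scaled response coefficients (RCs).

The scaled RC of a quantity x with respect to a parameter q is
R_q^x(t) = (q / x(t)) * dx(t)/dq: the relative change of the time course per
relative change of the parameter, with all direct and indirect (feedback)
effects included. Raw sensitivities S(t) = dx/dq are obtained by integrating
the forward sensitivity system dS/dt = J(t) S + df/dq along the trajectory,
with the Jacobian evaluated by central finite differences of the right-hand
side. Initial sensitivities account for the parameter dependence of the
equilibrated pre-stress state (re-equilibration differencing); zero
initialization is available as an option.

An independent oracle (fd_oracle_rc) recomputes RCs from two full
simulations at q(1 +/- delta); the two routes are compared in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _core
from ._core import FIDX, OIDX
from .params import ModelParameters, N_STATES, PIDX, SIDX
from .simulate import StressProtocol, presstress_equilibrate, simulate
from .strains import StrainSpec, apply_strain, pinmask_and_state

__all__ = [
    "SensitivitySet", "ResponseCoefficientSet",
    "compute_sensitivities", "scale_rc", "response_coefficients",
    "fd_oracle_rc",
]

#: pseudo-parameter: magnitude of the NaCl step (protocol, not kinetic)
STRESS_PARAM = "NaCl_step"

X_FLOOR_DEFAULT = 1e-9


class SensitivityError(RuntimeError):
    pass


@dataclass
class SensitivitySet:
    """Raw forward sensitivities S[t, state, parameter] = dx_i/dq_j."""

    t: np.ndarray
    states: np.ndarray          # (T, 29) trajectory states
    S: np.ndarray               # (T, 29, P)
    parameters: list[str]
    params: ModelParameters


@dataclass
class ResponseCoefficientSet:
    """Scaled RCs R[t, variable, parameter]; masked entries are NaN."""

    t: np.ndarray
    variables: list[str]
    parameters: list[str]
    R: np.ndarray               # (T, V, P)
    x_floor: float

    def get(self, variable: str, parameter: str) -> np.ndarray:
        return self.R[:, self.variables.index(variable),
                      self.parameters.index(parameter)]


def _param_value(params: ModelParameters, name: str,
                 protocol: StressProtocol) -> float:
    if name == STRESS_PARAM:
        return protocol.NaCl_step
    return getattr(params, name)


def compute_sensitivities(params: ModelParameters,
                          spec: StrainSpec | str = "WT",
                          protocol: StressProtocol | None = None,
                          param_subset: list[str] | None = None,
                          init: str = "equilibrium",
                          rtol: float = 1e-8,
                          atol: float = 1e-8,
                          jac_step: float = 1e-6) -> SensitivitySet:
    """Integrate the forward sensitivity ODE for the given parameters.

    Parameters zeroed out by the strain variant are structurally absent:
    their sensitivity columns are identically zero (perturbations are
    relative). The output grid is protocol.grid() restricted to
    t >= t_stress.
    """
    protocol = protocol or StressProtocol()
    if not param_subset:
        raise ValueError("param_subset must be non-empty")
    for name in param_subset:
        if name != STRESS_PARAM and name not in PIDX:
            raise KeyError(f"unknown parameter {name!r}")
    if init not in ("equilibrium", "zero"):
        raise ValueError("init must be 'equilibrium' or 'zero'")

    sparams, pins = apply_strain(params, spec)
    p_arr = sparams.to_array()
    x0 = presstress_equilibrate(sparams, protocol.medium, pins=pins)
    mask, x0 = pinmask_and_state(pins, x0)
    grid = protocol.grid()
    grid = grid[grid >= protocol.t_stress]

    P = len(param_subset)
    active = np.zeros(P, dtype=bool)
    qvals = np.zeros(P)
    for j, name in enumerate(param_subset):
        qvals[j] = _param_value(sparams, name, protocol)
        active[j] = qvals[j] != 0.0 and name != STRESS_PARAM

    # initial sensitivities
    S0 = np.zeros((N_STATES, P))
    if init == "equilibrium":
        for j, name in enumerate(param_subset):
            if not active[j]:
                continue
            dq = 1e-4 * qvals[j]
            xp = presstress_equilibrate(
                sparams.replace(**{name: qvals[j] + dq}),
                protocol.medium, pins=pins, guess=x0)
            xm = presstress_equilibrate(
                sparams.replace(**{name: qvals[j] - dq}),
                protocol.medium, pins=pins, guess=x0)
            S0[:, j] = (xp - xm) / (2.0 * dq)

    # stress event: state jump on NaCle; its sensitivity is d(NaCle)/dq = 1
    x_start = np.array(x0)
    x_start[SIDX["NaCle"]] += protocol.NaCl_step
    for j, name in enumerate(param_subset):
        if name == STRESS_PARAM:
            S0[SIDX["NaCle"], j] = 1.0

    scale = np.maximum(np.abs(x0), 1e-3)

    def aug_rhs(t: float, y: np.ndarray) -> np.ndarray:
        x = y[:N_STATES]
        S = y[N_STATES:].reshape(N_STATES, P)
        dx = _core.rhs(t, x, p_arr, mask)
        # Jacobian by central differences, relative step on each state
        J = np.empty((N_STATES, N_STATES))
        for i in range(N_STATES):
            h = jac_step * max(abs(x[i]), scale[i])
            xp = x.copy(); xp[i] += h
            xm = x.copy(); xm[i] -= h
            J[:, i] = (_core.rhs(t, xp, p_arr, mask)
                       - _core.rhs(t, xm, p_arr, mask)) / (2.0 * h)
        dS = J @ S
        for j, name in enumerate(param_subset):
            if not active[j]:
                continue
            dq = 1e-6 * qvals[j]
            pp = p_arr.copy(); pp[PIDX[name]] += dq
            pm = p_arr.copy(); pm[PIDX[name]] -= dq
            dS[:, j] += (_core.rhs(t, x, pp, mask)
                         - _core.rhs(t, x, pm, mask)) / (2.0 * dq)
        return np.concatenate([dx, dS.ravel()])

    y0 = np.concatenate([x_start, S0.ravel()])
    res = solve_ivp(aug_rhs, (protocol.t_stress, grid[-1]), y0,
                    method="LSODA", rtol=rtol, atol=atol, t_eval=grid)
    if not res.success:
        raise SensitivityError(
            f"sensitivity integration failed ({param_subset}): {res.message}")
    Y = res.y.T
    states = Y[:, :N_STATES]
    S = Y[:, N_STATES:].reshape(len(grid), N_STATES, P)
    return SensitivitySet(grid, states, S, list(param_subset), sparams)


def scale_rc(sens: SensitivitySet,
             protocol: StressProtocol | None = None,
             x_floor: float = X_FLOOR_DEFAULT) -> ResponseCoefficientSet:
    """Scale raw state sensitivities to R = (q/x) dx/dq, masking small x."""
    protocol = protocol or StressProtocol()
    T, N, P = sens.S.shape
    R = np.empty((T, N, P))
    for j, name in enumerate(sens.parameters):
        q = _param_value(sens.params, name, protocol)
        with np.errstate(divide="ignore", invalid="ignore"):
            R[:, :, j] = q * sens.S[:, :, j] / sens.states
    R[np.abs(sens.states)[:, :, None] < x_floor] = np.nan
    from .params import STATE_NAMES
    return ResponseCoefficientSet(sens.t, list(STATE_NAMES),
                                  list(sens.parameters), R, x_floor)


# ---------------------------------------------------------------------------
# derived outputs (observables / fluxes / concentrations)

def _output_series(states: np.ndarray, p_arr: np.ndarray,
                   name: str) -> np.ndarray:
    if name in SIDX:
        return states[:, SIDX[name]]
    if name in OIDX:
        return np.array([_core.observables(x, p_arr)[OIDX[name]]
                         for x in states])
    if name in FIDX:
        return np.array([_core.fluxes(x, p_arr)[FIDX[name]] for x in states])
    raise KeyError(f"unknown output {name!r}")


def _output_grad(x: np.ndarray, p_arr: np.ndarray, name: str,
                 scale: np.ndarray) -> tuple[np.ndarray, float]:
    """(gradient wrt states, value) of a derived output at one state."""
    if name in SIDX:
        g = np.zeros(N_STATES); g[SIDX[name]] = 1.0
        return g, x[SIDX[name]]

    if name in OIDX:
        idx = OIDX[name]
        def f(xx): return _core.observables(xx, p_arr)[idx]
    else:
        idx = FIDX[name]
        def f(xx): return _core.fluxes(xx, p_arr)[idx]
    g = np.zeros(N_STATES)
    for i in range(N_STATES):
        h = 1e-6 * max(abs(x[i]), scale[i])
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g, f(x)


def response_coefficients(params: ModelParameters,
                          spec: StrainSpec | str = "WT",
                          protocol: StressProtocol | None = None,
                          param_subset: list[str] | None = None,
                          outputs: list[str] | None = None,
                          x_floor: float = X_FLOOR_DEFAULT,
                          **kwargs) -> ResponseCoefficientSet:
    """Scaled RCs of states and derived outputs (observables, fluxes).

    Derived-output sensitivities are propagated through the chain rule,
    dg/dq = grad_x g . S + dg/dq|_explicit, with the explicit parameter
    dependence evaluated by central differences.
    """
    protocol = protocol or StressProtocol()
    if not outputs:
        raise ValueError("outputs must be non-empty")
    sens = compute_sensitivities(params, spec, protocol, param_subset,
                                 **kwargs)
    p_arr = sens.params.to_array()
    scale = np.maximum(np.abs(sens.states[0]), 1e-3)
    T, P = len(sens.t), len(sens.parameters)
    R = np.full((T, len(outputs), P), np.nan)
    for k, out in enumerate(outputs):
        for it in range(T):
            x = sens.states[it]
            g, val = _output_grad(x, p_arr, out, scale)
            for j, pname in enumerate(sens.parameters):
                q = _param_value(sens.params, pname, protocol)
                if q == 0.0:
                    R[it, k, j] = 0.0
                    continue
                dgdq = g @ sens.S[it, :, j]
                if pname != STRESS_PARAM and out not in SIDX:
                    dq = 1e-6 * q
                    pp = p_arr.copy(); pp[PIDX[pname]] += dq
                    pm = p_arr.copy(); pm[PIDX[pname]] -= dq
                    dgdq += (( _output_series(x[None, :], pp, out)[0]
                              - _output_series(x[None, :], pm, out)[0])
                             / (2.0 * dq))
                R[it, k, j] = q * dgdq / val if abs(val) >= x_floor else np.nan
    return ResponseCoefficientSet(sens.t, list(outputs),
                                  list(sens.parameters), R, x_floor)


def fd_oracle_rc(params: ModelParameters,
                 spec: StrainSpec | str,
                 protocol: StressProtocol | None,
                 param: str,
                 delta_rel: float = 1e-3,
                 outputs: list[str] | None = None,
                 x_floor: float = X_FLOOR_DEFAULT,
                 rtol: float = 1e-10,
                 atol: float = 1e-12) -> ResponseCoefficientSet:
    """Independent RC oracle: central difference of two full simulations.

    Each perturbed simulation re-equilibrates its own initial condition, so
    the oracle matches compute_sensitivities with init='equilibrium'.
    """
    if not (0.0 < delta_rel <= 0.05):
        raise ValueError("delta_rel must lie in (0, 0.05]")
    protocol = protocol or StressProtocol()
    outputs = outputs or ["c_Glyi"]
    grid = protocol.grid()
    grid = grid[grid >= protocol.t_stress]
    proto = StressProtocol(t_stress=protocol.t_stress,
                           NaCl_step=protocol.NaCl_step,
                           t_end=protocol.t_end, t_grid=grid,
                           medium=protocol.medium)

    def run(factor: float):
        if param == STRESS_PARAM:
            pr = StressProtocol(t_stress=proto.t_stress,
                                NaCl_step=proto.NaCl_step * factor,
                                t_end=proto.t_end, t_grid=grid,
                                medium=proto.medium)
            return simulate(params, spec, pr, rtol=rtol, atol=atol)
        q = getattr(params, param)
        return simulate(params.replace(**{param: q * factor}), spec, proto,
                        rtol=rtol, atol=atol)

    base = simulate(params, spec, proto, rtol=rtol, atol=atol)
    hi = run(1.0 + delta_rel)
    lo = run(1.0 - delta_rel)
    p_arr = base.params.to_array()

    R = np.full((len(grid), len(outputs), 1), np.nan)
    for k, out in enumerate(outputs):
        y0 = _output_series(base.states.to_numpy(), p_arr, out)
        yp = _output_series(hi.states.to_numpy(), hi.params.to_array(), out)
        ym = _output_series(lo.states.to_numpy(), lo.params.to_array(), out)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (yp - ym) / (2.0 * delta_rel * y0)
        vals[np.abs(y0) < x_floor] = np.nan
        R[:, k, 0] = vals
    return ResponseCoefficientSet(grid, list(outputs), [param], R, x_floor)
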