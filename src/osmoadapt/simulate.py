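"""Pre-stress equilibration and trajectory integration.

The culture is equilibrated with the external pools held at their configured
pre-stress values (a growing batch culture is not at a strict steady state,
but intracellular concentrations are quasi-stationary before stress); the
NaCl step is applied as a discrete event with an integrator restart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _core
from ._core import FLUX_NAMES, OBS_NAMES
from .params import (
    INTRACELLULAR,
    Medium,
    ModelParameters,
    N_STATES,
    SIDX,
    STATE_NAMES,
)
from .strains import StrainSpec, apply_strain, pinmask_and_state

__all__ = [
    "StressProtocol", "Trajectory", "EquilibrationError", "IntegrationError",
    "presstress_equilibrate", "simulate",
]

#: default stiff-solver tolerances
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10

_N_INTRA = len(INTRACELLULAR)          # 22: indices 0..21
_IDX_HOG1U = SIDX["Hog1u"]
_IDX_HOG1PP = SIDX["Hog1PP"]


class EquilibrationError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StressProtocol:
    """A single hyperosmotic step: NaCl_step mol/L added at t_stress."""

    t_stress: float = 0.0
    NaCl_step: float = 0.4
    t_end: float = 180.0
    t_grid: np.ndarray | None = None
    medium: Medium = field(default_factory=Medium)

    def __post_init__(self) -> None:
        if self.NaCl_step < 0:
            raise ValueError("NaCl_step must be >= 0")
        if self.t_grid is not None:
            grid = np.asarray(self.t_grid, dtype=float)
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError("t_grid must be strictly increasing")
            object.__setattr__(self, "t_grid", grid)

    def grid(self) -> np.ndarray:
        if self.t_grid is not None:
            return self.t_grid
        return np.arange(self.t_stress, self.t_end + 0.5, 1.0)


@dataclass
class Trajectory:
    """Time courses of states, algebraic observables and per-cell fluxes."""

    strain: str
    t: np.ndarray
    states: pd.DataFrame        # time x 29
    observables: pd.DataFrame   # time x len(OBS_NAMES)
    fluxes: pd.DataFrame        # time x len(FLUX_NAMES)
    derivatives: pd.DataFrame   # time x 29 (dX/dt along the trajectory)
    params: ModelParameters | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        for frame in (self.states, self.observables, self.fluxes,):
            if name in frame.columns:
                return frame[name].to_numpy()
        raise KeyError(name)

    def to_long(self) -> pd.DataFrame:
        """Long-format table with columns time_min, variable, value."""
        wide = pd.concat([self.states, self.observables, self.fluxes], axis=1)
        wide.insert(0, "time_min", self.t)
        return wide.melt(id_vars="time_min", var_name="variable",
                         value_name="value")


# ---------------------------------------------------------------------------

def _equilibrium_guess(params: ModelParameters) -> np.ndarray:
    """Heuristic starting point for the intracellular fixed-point solve."""
    p = params
    g = np.zeros(_N_INTRA)
    g[SIDX["Vos"]] = p.Vos0
    g[_IDX_HOG1U] = p.Hog1tot
    g[_IDX_HOG1PP] = 0.01 * p.Hog1tot
    mu = p.mu0
    m1 = p.k_b1 / (p.d_m1 + mu) if p.d_m1 + mu > 0 else 0.0
    g[SIDX["mGPD1"]] = 2.0 * m1
    g[SIDX["Gpd1m"]] = 0.25 if m1 > 0 else 0.0
    g[SIDX["Gpd1d"]] = 0.08 if m1 > 0 else 0.0
    g[SIDX["Gpd2"]] = p.k_b2 / (p.d2 + mu) if p.d2 + mu > 0 else 0.0
    g[SIDX["mSTL1"]] = 0.6
    g[SIDX["Stl1"]] = 0.15
    g[SIDX["Pfk26a"]] = 0.05 * p.PfkT
    g[SIDX["F26DP"]] = 0.1
    g[SIDX["Fps1o"]] = 0.8
    for name, conc in (("Glci", 1.5), ("HexP", 3.0), ("FBP", 5.0),
                       ("TriP", 1.5), ("G3P", 0.01), ("Glyi", 14.0),
                       ("Pyr", 2.2), ("EtOHi", 7.2), ("AcOi", 1.4),
                       ("Trei", 10.0)):
        g[SIDX[name]] = conc * p.Vos0
    return g


def _assemble_full_state(z: np.ndarray, medium: Medium) -> np.ndarray:
    x = np.zeros(N_STATES)
    x[:_N_INTRA] = z
    x[SIDX["Glce"]] = medium.Glce
    x[SIDX["Glye"]] = medium.Glye
    x[SIDX["EtOHe"]] = medium.EtOHe
    x[SIDX["AcOe"]] = medium.AcOe
    x[SIDX["Tree"]] = medium.Tree
    x[SIDX["NaCle"]] = 0.0
    x[SIDX["CD"]] = medium.CD
    return x


def presstress_equilibrate(params: ModelParameters,
                           medium: Medium | None = None,
                           pins: dict[str, float] | None = None,
                           guess: np.ndarray | None = None,
                           tol: float = 1e-11) -> np.ndarray:
    """Solve for the pre-stress intracellular fixed point (NaCle = 0).

    External pools and cell density are held at their configured values.
    Because growth dilution acts on the conserved Hog1 moiety (which has no
    synthesis term), the Hog1u residual is replaced by the moiety condition
    Hog1u + Hog1PP = Hog1tot; all other intracellular derivatives vanish at
    the solution, and the returned state satisfies the phosphorylation
    balance given the moiety total.
    """
    medium = medium or Medium()
    pins = pins or {}
    p_arr = params.to_array()
    mask = np.ones(N_STATES)
    pin_vals: list[tuple[int, float]] = []
    for name, value in pins.items():
        mask[SIDX[name]] = 0.0
        pin_vals.append((SIDX[name], value))

    # magnitude scales: make residuals comparable across state magnitudes
    scales = np.maximum(np.abs(guess[:_N_INTRA] if guess is not None
                               else _equilibrium_guess(params)), 1e-3)

    def residual_scaled(y: np.ndarray) -> np.ndarray:
        x = _assemble_full_state(y * scales, medium)
        for k, v in pin_vals:
            x[k] = v
        dx = _core.rhs(0.0, x, p_arr, mask)
        r = dx[:_N_INTRA].copy()
        # moiety closure instead of the (structurally drifting) Hog1u balance
        r[_IDX_HOG1U] = (x[_IDX_HOG1U] + x[_IDX_HOG1PP]
                         - params.Hog1tot) / max(params.Hog1tot, 1e-6)
        return r / scales

    def residual(z: np.ndarray) -> np.ndarray:
        return residual_scaled(z / scales)

    def solve_from(z_start: np.ndarray):
        s = root(residual_scaled, z_start / scales, method="hybr",
                 options={"xtol": 1e-13, "maxfev": 20000})
        return s.x * scales, s

    z0 = np.array(guess[:_N_INTRA]) if guess is not None \
        else _equilibrium_guess(params)
    for k, v in pin_vals:
        if k < _N_INTRA:
            z0[k] = v

    z, sol = solve_from(z0)
    res = residual(z)
    if np.max(np.abs(res)) <= 1e-7 and np.any(z < -1e-9):
        # spurious mirror branch (the quadratic dimerization term admits a
        # negative-monomer fixed point); restart from the reflected iterate
        z, sol = solve_from(np.abs(z))
        res = residual(z)
    if np.max(np.abs(res)) > 1e-7 or np.any(z < -1e-9):
        # fall back: relax toward the fixed point by integration (with a
        # synthesis term compensating growth dilution of the Hog1 moiety,
        # which otherwise has no fixed point), then polish by root-solving.
        iu, ip = _IDX_HOG1U, _IDX_HOG1PP

        def relax_rhs(t: float, y: np.ndarray) -> np.ndarray:
            dy = _core.rhs(t, y, p_arr, mask)
            obs = _core.observables(y, p_arr)
            dy[iu] += obs[5] * (y[iu] + y[ip])
            return dy

        x = _assemble_full_state(np.abs(z0), medium)
        x[iu] = max(params.Hog1tot - x[ip], 0.0)
        for k, v in pin_vals:
            x[k] = v
        try:
            relax = solve_ivp(relax_rhs, (0.0, 3000.0), x, method="LSODA",
                              rtol=1e-9, atol=1e-11)
        except (FloatingPointError, ZeroDivisionError, ValueError) as exc:
            raise EquilibrationError(
                f"pre-stress equilibration failed during relaxation: {exc}"
            ) from exc
        if not relax.success:
            raise EquilibrationError(
                f"pre-stress equilibration failed: {sol.message}; "
                f"max residual {np.max(np.abs(res)):.3e}")
        z, sol = solve_from(relax.y[:_N_INTRA, -1])
        res = residual(z)
        if np.max(np.abs(res)) <= 1e-7 and np.any(z < -1e-9):
            z, sol = solve_from(np.abs(z))
            res = residual(z)
        if np.max(np.abs(res)) > 1e-7 or np.any(z < -1e-9):
            negs = [(INTRACELLULAR[i], float(z[i]))
                    for i in np.flatnonzero(z < -1e-9)]
            raise EquilibrationError(
                "pre-stress equilibration did not converge; residuals "
                f"(scaled): max {np.max(np.abs(res)):.3e}; "
                f"negative entries: {negs}")
    x = _assemble_full_state(z, medium)
    for k, v in pin_vals:
        x[k] = v
    # numerical guard: clip solver round-off negatives
    x[np.abs(x) < 1e-14] = 0.0
    if np.any(x < -1e-9):
        raise EquilibrationError("equilibrium has negative entries")
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------

def simulate(params: ModelParameters,
             spec: StrainSpec | str = "WT",
             protocol: StressProtocol | None = None,
             rtol: float = RTOL_DEFAULT,
             atol: float = ATOL_DEFAULT,
             x0: np.ndarray | None = None,
             min_step: float = 0.0) -> Trajectory:
    """Integrate one strain through the stress protocol.

    The initial condition is the strain's pre-stress fixed point unless x0
    is given. The NaCl step is applied exactly at t_stress by stopping and
    restarting the integrator. Output arrives on protocol.grid().
    """
    protocol = protocol or StressProtocol()
    sparams, pins = apply_strain(params, spec)
    strain_name = spec if isinstance(spec, str) else spec.name
    p_arr = sparams.to_array()
    grid = protocol.grid()
    t0, t_end = float(grid[0]), float(grid[-1])
    ts = protocol.t_stress
    if t0 > ts and protocol.NaCl_step > 0:
        raise ValueError("output grid must start at or before t_stress")

    if x0 is None:
        x0 = presstress_equilibrate(sparams, protocol.medium, pins=pins)
    mask, x0 = pinmask_and_state(pins, x0)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return _core.rhs(t, y, p_arr, mask)

    pieces_t: list[np.ndarray] = []
    pieces_y: list[np.ndarray] = []

    def integrate(ta: float, tb: float, xa: np.ndarray,
                  t_eval: np.ndarray) -> np.ndarray:
        if tb <= ta:
            return xa
        res = solve_ivp(f, (ta, tb), xa, method="LSODA",
                        rtol=rtol, atol=atol, min_step=min_step,
                        t_eval=t_eval if len(t_eval) else None)
        if not res.success:
            last = res.t[-1] if len(res.t) else ta
            raise IntegrationError(
                f"integration failed for {strain_name} at t = {last:.3f} min: "
                f"{res.message}")
        if len(t_eval):
            pieces_t.append(res.t)
            pieces_y.append(res.y)
            if res.t[-1] == tb:
                return res.y[:, -1]
        # endpoint not on the grid: integrate to it exactly
        res2 = solve_ivp(f, (ta, tb), xa, method="LSODA",
                         rtol=rtol, atol=atol, min_step=min_step,
                         t_eval=[tb])
        if not res2.success:
            raise IntegrationError(
                f"integration failed for {strain_name}: {res2.message}")
        return res2.y[:, -1]

    x = np.array(x0, dtype=float)
    if t0 < ts:
        x = integrate(t0, ts, x, grid[grid < ts])
    # stress event: instantaneous NaCl addition, integrator restart
    x_evt = x.copy()
    x_evt[SIDX["NaCle"]] += protocol.NaCl_step
    if t_end >= ts:
        eval_post = grid[grid >= ts]
        x = integrate(ts, t_end, x_evt, eval_post)

    t_all = np.concatenate(pieces_t) if pieces_t else np.array([t0])
    y_all = (np.concatenate(pieces_y, axis=1) if pieces_y
             else x0.reshape(-1, 1))
    # align to requested grid (event time appears once, post-step values)
    states = np.empty((len(grid), N_STATES))
    for i, tg in enumerate(grid):
        j = np.flatnonzero(np.isclose(t_all, tg))[-1]
        states[i] = y_all[:, j]

    obs = np.empty((len(grid), len(OBS_NAMES)))
    flx = np.empty((len(grid), len(FLUX_NAMES)))
    der = np.empty((len(grid), N_STATES))
    for i in range(len(grid)):
        obs[i] = _core.observables(states[i], p_arr)
        flx[i] = _core.fluxes(states[i], p_arr)
        der[i] = _core.rhs(grid[i], states[i], p_arr, mask)

    return Trajectory(
        strain=strain_name,
        t=grid,
        states=pd.DataFrame(states, columns=list(STATE_NAMES)),
        observables=pd.DataFrame(obs, columns=list(OBS_NAMES)),
        fluxes=pd.DataFrame(flx, columns=list(FLUX_NAMES)),
        derivatives=pd.DataFrame(der, columns=[f"d_{n}" for n in STATE_NAMES]),
        params=sparams,
    )
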