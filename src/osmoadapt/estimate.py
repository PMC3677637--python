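"""Multi-strain weighted least-squares parameter estimation.

The objective simulates every strain in the problem once per parameter
vector, maps model observables onto the measured variables, applies the
chi-square-optimal analytic scaling factor to every relative (arbitrary-unit)
dataset, and sums weighted squared residuals. Optimization runs in log10
parameter space (positivity, scale-spanning kinetics) with seeded
Latin-hypercube multistarts refined by trust-region least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .params import MEASURED_VARIABLES, ModelParameters
from .simulate import (
    EquilibrationError,
    IntegrationError,
    StressProtocol,
    Trajectory,
    simulate,
)

__all__ = [
    "FitProblem", "FitResult", "optimal_scaling", "objective", "fit",
    "measurement_series", "RELATIVE_VARIABLES", "DEFAULT_FIT_PARAMETERS",
]

#: measured variables reported in arbitrary units (western/northern blots)
RELATIVE_VARIABLES = ("Hog1PP", "Gpd1tot", "mGPD1", "mSTL1")

#: default identifiable subset used in the synthetic recovery experiment
DEFAULT_FIT_PARAMETERS = (
    "mu0", "theta_H", "Lp_A", "k_dp", "k_h1",
    "d_m1", "kcatGpd1", "k_fps", "k_cH", "kTPSh",
)

#: objective value returned on simulation failure (plus residual count),
#: so optimizers can continue past infeasible parameter vectors
PENALTY_BASE = 1e10

#: data beyond this time (min) are excluded from the objective
FIT_WINDOW_END = 180.0

_SIGMA_REL_DEFAULT = 0.15


def measurement_series(traj: Trajectory, variable: str) -> np.ndarray:
    """Model counterpart of one measured variable along a trajectory.

    Intracellular metabolites are reported as concentrations (mM); external
    pools and cell density directly; blot-type variables in model units
    (their scale is absorbed by the per-dataset scaling factor).
    """
    mapping = {
        "Hog1PP": "Hog1PP", "Gpd1tot": "Gpd1tot",
        "mGPD1": "mGPD1", "mSTL1": "mSTL1",
        "Glci": "c_Glci", "Glyi": "c_Glyi", "EtOHi": "c_EtOHi",
        "Trei": "c_Trei",
        "Glce": "Glce", "Glye": "Glye", "EtOHe": "EtOHe",
        "AcOe": "AcOe", "Tree": "Tree", "CD": "CD",
    }
    if variable not in mapping:
        raise KeyError(f"no measurement mapping for variable {variable!r}")
    return traj[mapping[variable]]


@dataclass
class FitProblem:
    """Measurement table plus fitting configuration.

    data must follow the MeasurementTable schema (columns strain, variable,
    time_min, replicate, value, ...). Weights sigma are per point:
    sigma = sigma_rel * |value| + sigma_abs(variable).
    """

    data: pd.DataFrame
    fit_parameters: tuple[str, ...] = DEFAULT_FIT_PARAMETERS
    base: ModelParameters = field(default_factory=ModelParameters)
    protocol: StressProtocol = field(default_factory=StressProtocol)
    sigma_rel: float = _SIGMA_REL_DEFAULT
    sigma_abs: dict[str, float] = field(default_factory=dict)
    relative_flags: tuple[str, ...] = RELATIVE_VARIABLES
    bounds_decades: float = 2.0
    rtol: float = 1e-6
    atol: float = 1e-8
    min_step: float = 1e-7

    # prepared by __post_init__
    _datasets: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"strain", "variable", "time_min", "replicate", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"data table lacks columns {sorted(missing)}")
        unknown = set(df["variable"]) - set(MEASURED_VARIABLES)
        if unknown:
            raise ValueError(
                f"variables without measurement mapping: {sorted(unknown)}")
        df = df[df["time_min"] <= FIT_WINDOW_END]
        self._datasets = []
        for (strain, variable), grp in df.groupby(["strain", "variable"]):
            sig = (self.sigma_rel * np.abs(grp["value"].to_numpy())
                   + self.sigma_abs.get(variable,
                                        self._default_floor(variable)))
            self._datasets.append({
                "strain": strain,
                "variable": variable,
                "t": grp["time_min"].to_numpy(dtype=float),
                "y": grp["value"].to_numpy(dtype=float),
                "sigma": sig,
                "relative": variable in self.relative_flags,
            })
        self.strains = sorted({d["strain"] for d in self._datasets})
        self.times = np.unique(df["time_min"].to_numpy(dtype=float))
        # log10 box centred on the base parameter values
        theta0 = np.array([getattr(self.base, n) for n in self.fit_parameters])
        if np.any(theta0 <= 0):
            raise ValueError("fit parameters must be positive at the centre")
        self.log_center = np.log10(theta0)
        self.log_lo = self.log_center - self.bounds_decades
        self.log_hi = self.log_center + self.bounds_decades
        # honour hard parameter caps (fractions cannot exceed 1)
        caps = {"theta_H": 1.0}
        for j, name in enumerate(self.fit_parameters):
            if name in caps:
                self.log_hi[j] = min(self.log_hi[j], np.log10(caps[name]))

    @staticmethod
    def _default_floor(variable: str) -> float:
        # small absolute noise floors in each variable's unit
        if variable == "CD":
            return 1e5
        if variable in RELATIVE_VARIABLES:
            return 1e-4
        return 0.05

    def params_from_log(self, log_theta: np.ndarray) -> ModelParameters:
        vals = 10.0 ** np.asarray(log_theta, dtype=float)
        return self.base.replace(**dict(zip(self.fit_parameters, vals)))

    def n_residuals(self) -> int:
        return int(sum(len(d["y"]) for d in self._datasets))


@dataclass
class FitResult:
    theta: ModelParameters
    log_theta: np.ndarray
    objective: float
    scalings: dict[tuple[str, str], float]
    start_index: int
    converged: bool
    seed: int | None = None
    n_evals: int = 0


def optimal_scaling(y_model: np.ndarray, y_data: np.ndarray,
                    sigma: np.ndarray) -> float:
    """Chi-square-minimizing scale s for relative data, clamped to >= 0.

    s = sum(y_m y_d / sigma^2) / sum(y_m^2 / sigma^2).
    """
    y_model = np.asarray(y_model, float)
    y_data = np.asarray(y_data, float)
    sigma = np.asarray(sigma, float)
    if not (len(y_model) == len(y_data) == len(sigma)):
        raise ValueError("length mismatch")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    denom = np.sum(y_model ** 2 / sigma ** 2)
    if denom == 0.0:
        raise ZeroDivisionError("all-zero model prediction: scaling undefined")
    s = np.sum(y_model * y_data / sigma ** 2) / denom
    return float(max(s, 0.0))


def _residuals(theta: ModelParameters, problem: FitProblem
               ) -> tuple[np.ndarray, dict[tuple[str, str], float]]:
    grid = problem.times
    if grid[0] > problem.protocol.t_stress:
        grid = np.insert(grid, 0, problem.protocol.t_stress)
    proto = StressProtocol(t_stress=problem.protocol.t_stress,
                           NaCl_step=problem.protocol.NaCl_step,
                           t_end=float(grid[-1]), t_grid=grid,
                           medium=problem.protocol.medium)
    trajs = {s: simulate(theta, s, proto, rtol=problem.rtol,
                         atol=problem.atol, min_step=problem.min_step)
             for s in problem.strains}
    res: list[np.ndarray] = []
    scalings: dict[tuple[str, str], float] = {}
    for d in problem._datasets:
        traj = trajs[d["strain"]]
        ym_full = measurement_series(traj, d["variable"])
        idx = np.searchsorted(traj.t, d["t"])
        ym = ym_full[idx]
        s = 1.0
        if d["relative"]:
            # an identically-zero prediction (e.g. Hog1PP in the hog1
            # deletion) has no defined scale; score the data unscaled
            s = 0.0 if not np.any(ym) else optimal_scaling(ym, d["y"],
                                                           d["sigma"])
            scalings[(d["strain"], d["variable"])] = s
        res.append((s * ym - d["y"]) / d["sigma"])
    return np.concatenate(res), scalings


def objective(theta: ModelParameters, problem: FitProblem) -> float:
    """Weighted sum of squares; penalized (not raised) on solver failure."""
    try:
        r, _ = _residuals(theta, problem)
    except (EquilibrationError, IntegrationError, FloatingPointError,
            ZeroDivisionError, ValueError):
        return PENALTY_BASE + problem.n_residuals()
    return float(np.sum(r ** 2))


def fit(problem: FitProblem, n_starts: int = 20, seed: int = 0,
        x0: np.ndarray | None = None,
        triage_top: int = 10, triage_nfev: int = 60,
        refine_top: int = 4, max_nfev: int = 400,
        polish_nfev: int = 400) -> list[FitResult]:
    """Cascaded multistart weighted least squares in log10 parameter space.

    Starts are Latin-hypercube samples of the log10 box (seeded, hence
    bitwise reproducible). All starts are scored at their initial point;
    the best `triage_top` receive a short trust-region-reflective
    refinement; the best `refine_top` of those are refined in full; and
    the incumbent gets a final polish. Results are sorted by objective.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    P = len(problem.fit_parameters)
    if x0 is not None:
        starts = np.atleast_2d(np.asarray(x0, dtype=float))
    else:
        sampler = qmc.LatinHypercube(d=P, seed=seed)
        unit = sampler.random(n_starts)
        starts = problem.log_lo + unit * (problem.log_hi - problem.log_lo)

    def res_fn(log_theta: np.ndarray) -> np.ndarray:
        try:
            r, _ = _residuals(problem.params_from_log(log_theta), problem)
            if not np.all(np.isfinite(r)):
                raise FloatingPointError("non-finite residuals")
            return r
        except (EquilibrationError, IntegrationError, FloatingPointError,
                ZeroDivisionError, ValueError):
            # flat penalties strand the optimizer on infeasible plateaus;
            # a mild pull toward the (feasible) box centre restores a
            # descent direction
            n = problem.n_residuals()
            dist = float(np.linalg.norm(log_theta - problem.log_center))
            return np.full(n, np.sqrt((PENALTY_BASE + n) / n)
                           * (1.0 + 0.05 * dist))

    def local(start: np.ndarray, budget: int):
        # the finite-difference step must sit well above the integration
        # noise floor (rtol ~1e-6) or the Jacobian is noise and the
        # optimizer stalls immediately
        sol = least_squares(res_fn, start, method="trf",
                            bounds=(problem.log_lo, problem.log_hi),
                            max_nfev=budget, x_scale="jac",
                            diff_step=3e-3, ftol=1e-10, xtol=1e-10,
                            gtol=1e-10)
        return sol.x, float(2.0 * sol.cost), bool(sol.success), int(sol.nfev)

    # stage 0: score every start
    state = [{"x": s, "obj": float(np.sum(res_fn(s) ** 2)),
              "start": i, "converged": False, "nev": 1}
             for i, s in enumerate(starts)]

    if x0 is not None:
        stages = [(len(state), max_nfev)]
    else:
        stages = [(min(triage_top, len(state)), triage_nfev),
                  (min(refine_top, len(state)), max_nfev)]
    for top, budget in stages:
        state.sort(key=lambda d: d["obj"])
        for d in state[:top]:
            x, obj, conv, nev = local(d["x"], budget)
            if obj <= d["obj"]:
                d.update(x=x, obj=obj, converged=conv)
            d["nev"] += nev

    # final polish of the incumbent
    state.sort(key=lambda d: d["obj"])
    x, obj, conv, nev = local(state[0]["x"], polish_nfev)
    if obj <= state[0]["obj"]:
        state[0].update(x=x, obj=obj, converged=conv)
    state[0]["nev"] += nev
    state.sort(key=lambda d: d["obj"])

    results: list[FitResult] = []
    for d in state:
        theta = problem.params_from_log(d["x"])
        try:
            _, scalings = _residuals(theta, problem)
        except Exception:
            scalings = {}
        results.append(FitResult(theta, d["x"], d["obj"], scalings,
                                 d["start"], d["converged"], seed, d["nev"]))
    return results
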