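"""Public model surface: state/observable/flux evaluation and carbon closure.

The dynamic state is a 29-entry float vector in the order of
``params.STATE_NAMES``; helper constructors/validators convert between dicts
and arrays. All quantities follow the unit conventions documented in
params.py.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from ._core import FIDX, FLUX_NAMES, OBS_NAMES, OIDX
from .params import (
    ModelParameters,
    N_STATES,
    SIDX,
    STATE_NAMES,
)

__all__ = [
    "STATE_NAMES", "OBS_NAMES", "FLUX_NAMES", "SIDX", "OIDX", "FIDX",
    "state_from_dict", "state_to_dict", "validate_state",
    "evaluate_rhs", "compute_observables", "reaction_fluxes",
    "Observables", "STOICHIOMETRY", "CARBON_COUNTS", "check_carbon_closure",
]


def state_from_dict(values: dict[str, float]) -> np.ndarray:
    """Build a state vector from a complete {state name: value} mapping."""
    unknown = set(values) - set(STATE_NAMES)
    if unknown:
        raise KeyError(f"unknown state name(s): {sorted(unknown)}")
    missing = set(STATE_NAMES) - set(values)
    if missing:
        raise KeyError(f"missing state name(s): {sorted(missing)}")
    return np.array([values[n] for n in STATE_NAMES], dtype=float)


def state_to_dict(x: np.ndarray) -> dict[str, float]:
    return dict(zip(STATE_NAMES, map(float, x)))


def validate_state(x: np.ndarray, tol: float = 1e-9) -> None:
    """Enforce ModelState invariants; raises naming the offending index."""
    x = np.asarray(x, dtype=float)
    if x.shape != (N_STATES,):
        raise ValueError(f"state vector must have length {N_STATES}, "
                         f"got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        k = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite state entry {STATE_NAMES[k]} (index {k})")
    if np.any(x < -tol):
        k = int(np.flatnonzero(x < -tol)[0])
        raise ValueError(
            f"negative state entry {STATE_NAMES[k]} (index {k}): {x[k]!r}")
    if x[SIDX["Vos"]] <= 0:
        raise ValueError("degenerate volume: Vos must be > 0")
    if x[SIDX["CD"]] <= 0:
        raise ValueError("cell density CD must be > 0")
    if not (-tol <= x[SIDX["Fps1o"]] <= 1 + tol):
        raise ValueError("Fps1o must lie in [0, 1]")


@dataclass(frozen=True)
class Observables:
    """Algebraic observables of one state (see OBS_NAMES for the raw array)."""

    Vtot: float
    Pi_i: float
    Pi_e: float
    Pi_t: float
    u: float
    mu: float
    Gpd1tot: float
    concentrations: dict[str, float]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Observables":
        conc = {n: float(arr[OIDX[n]]) for n in OBS_NAMES if n.startswith("c_")}
        return cls(*(float(arr[i]) for i in range(7)), concentrations=conc)


def evaluate_rhs(state: np.ndarray, t: float,
                 params: ModelParameters,
                 pinmask: np.ndarray | None = None) -> np.ndarray:
    """Time derivative dX/dt of the 29-entry state vector (validated)."""
    validate_state(state)
    return _core.rhs(t, np.asarray(state, dtype=float),
                     params.to_array(), pinmask)


def compute_observables(state: np.ndarray,
                        params: ModelParameters) -> Observables:
    state = np.asarray(state, dtype=float)
    if state[SIDX["Vos"]] <= 0:
        raise ValueError("degenerate volume: Vos must be > 0")
    return Observables.from_array(_core.observables(state, params.to_array()))


def reaction_fluxes(state: np.ndarray,
                    params: ModelParameters) -> dict[str, float]:
    """All per-cell reaction/process rates (amol/min), keyed by name."""
    validate_state(state)
    arr = _core.fluxes(np.asarray(state, dtype=float), params.to_array())
    return dict(zip(FLUX_NAMES, map(float, arr)))


# ---------------------------------------------------------------------------
# carbon bookkeeping
#
# Stoichiometry of every mass-carrying reaction, including the virtual sinks
# CO2 (decarboxylation) and BIOMASS (six carbons per glucose-equivalent
# drained). F26DP is catalytic and excluded. Transport reactions move a
# species between compartments and are trivially balanced.
STOICHIOMETRY: dict[str, dict[str, float]] = {
    "vHXT": {"Glce": -1, "Glci": +1},
    "vHK": {"Glci": -1, "HexP": +1},
    "vPFK": {"HexP": -1, "FBP": +1},
    "vALD": {"FBP": -1, "TriP": +2},
    "vLG": {"TriP": -1, "Pyr": +1},
    "vPDC": {"Pyr": -1, "EtOHi": +1, "CO2": +1},
    "vALD6": {"Pyr": -1, "AcOi": +1, "CO2": +1},
    "vGPD1": {"TriP": -1, "G3P": +1},
    "vGPD2": {"TriP": -1, "G3P": +1},
    "vGPP": {"G3P": -1, "Glyi": +1},
    "vTPS": {"HexP": -2, "Trei": +1},
    "vNTH": {"Trei": -1, "Glci": +2},
    "vFPS": {"Glyi": -1, "Glye": +1},
    "vSTL": {"Glye": -1, "Glyi": +1},
    "vEtOHt": {"EtOHi": -1, "EtOHe": +1},
    "vAcOt": {"AcOi": -1, "AcOe": +1},
    "vTret": {"Trei": -1, "Tree": +1},
    "vBM": {"HexP": -1, "BIOMASS": +1},
}

#: carbon atoms per molecule of each mass-carrying species
CARBON_COUNTS: dict[str, int] = {
    "Glci": 6, "HexP": 6, "FBP": 6, "TriP": 3, "G3P": 3, "Glyi": 3,
    "Pyr": 3, "EtOHi": 2, "AcOi": 2, "Trei": 12,
    "Glce": 6, "Glye": 3, "EtOHe": 2, "AcOe": 2, "Tree": 12,
    "CO2": 1, "BIOMASS": 6,
}


def check_carbon_closure(params: ModelParameters | None = None
                         ) -> dict[str, float]:
    """Carbon-weighted stoichiometric sum of every reaction (all must be 0).

    ``params`` is accepted for interface symmetry; closure is a structural
    property of the stoichiometry and carbon assignment, not of rate values.
    """
    residuals: dict[str, float] = {}
    for rxn, stoich in STOICHIOMETRY.items():
        total = 0.0
        for species, coeff in stoich.items():
            if species not in CARBON_COUNTS:
                raise KeyError(
                    f"missing carbon assignment for species {species!r} "
                    f"in reaction {rxn}")
            total += coeff * CARBON_COUNTS[species]
        residuals[rxn] = total
    return residuals
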