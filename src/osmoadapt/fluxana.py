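"""Glycerol flux decomposition, ternary coordinates, growth trade-off metrics.

The net rate of change of the intracellular glycerol *concentration* is split
into three mechanistic contributions:

* ``J_Gpd1``  - glycerol production attributed to the Gpd1 dimer (the
  Gpd1-share of the G3P-phosphatase flux),
* ``J_Fps1``  - net transport through Fps1 (influx positive),
* ``J_Others`` - everything else: Gpd2-attributed production, Stl1 uptake,
  and the concentration effects of volume change and growth dilution.

The three terms sum to d(cGlyi)/dt exactly, pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SIDX
from .simulate import Trajectory

__all__ = [
    "FluxDecomposition", "decompose_glycerol_flux", "ternary_coordinates",
    "first_gpd1_dominance", "half_rise_time",
    "doubling_time", "flux_shares", "total_carbon_series",
]


@dataclass
class FluxDecomposition:
    """Absolute (mM/min) and relative contributions to net glycerol flux."""

    t: np.ndarray
    J_Gpd1: np.ndarray
    J_Fps1: np.ndarray
    J_Others: np.ndarray
    r_Gpd1: np.ndarray
    r_Fps1: np.ndarray
    r_Others: np.ndarray
    all_zero: np.ndarray        # bool mask of degenerate instants

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "J_Gpd1": self.J_Gpd1, "J_Fps1": self.J_Fps1,
            "J_Others": self.J_Others,
            "r_Gpd1": self.r_Gpd1, "r_Fps1": self.r_Fps1,
            "r_Others": self.r_Others,
        })


def decompose_glycerol_flux(traj: Trajectory) -> FluxDecomposition:
    """Split d(cGlyi)/dt into Gpd1-, Fps1- and other contributions.

    Production through the G3P-phosphatase step is attributed to Gpd1 vs
    Gpd2 in proportion to their instantaneous upstream G3P-producing fluxes.
    Relative contributions are absolute-value shares, so efflux and influx
    phases both render on the ternary simplex.
    """
    for col in ("vGPP", "vGPD1", "vGPD2", "vFPS", "vSTL"):
        if col not in traj.fluxes.columns:
            raise KeyError(f"trajectory lacks flux column {col!r}")
    Vos = traj["Vos"]
    cGlyi = traj["c_Glyi"]
    mu = traj["mu"]
    dVos = traj.derivatives["d_Vos"].to_numpy()
    vGPP = traj["vGPP"]
    vGPD1 = traj["vGPD1"]
    vGPD2 = traj["vGPD2"]
    upstream = vGPD1 + vGPD2
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(upstream > 0, vGPD1 / np.where(upstream > 0, upstream, 1.0), 0.0)
    J_Gpd1 = vGPP * w1 / Vos
    J_Fps1 = -traj["vFPS"] / Vos
    J_Others = (vGPP * (1.0 - w1) + traj["vSTL"]) / Vos \
        - cGlyi * dVos / Vos - mu * cGlyi

    denom = np.abs(J_Gpd1) + np.abs(J_Fps1) + np.abs(J_Others)
    all_zero = denom == 0.0
    safe = np.where(all_zero, 1.0, denom)
    r_Gpd1 = np.where(all_zero, 1.0 / 3.0, np.abs(J_Gpd1) / safe)
    r_Fps1 = np.where(all_zero, 1.0 / 3.0, np.abs(J_Fps1) / safe)
    r_Others = np.where(all_zero, 1.0 / 3.0, np.abs(J_Others) / safe)
    return FluxDecomposition(traj.t, J_Gpd1, J_Fps1, J_Others,
                             r_Gpd1, r_Fps1, r_Others, all_zero)


def ternary_coordinates(decomp: FluxDecomposition) -> np.ndarray:
    """(r_Fps1, r_Gpd1, r_Others) triples, each non-negative, summing to 1."""
    return np.column_stack([decomp.r_Fps1, decomp.r_Gpd1, decomp.r_Others])


def first_gpd1_dominance(decomp: FluxDecomposition) -> float:
    """First time (min) the Gpd1 contribution is the largest of the three."""
    dominant = (decomp.r_Gpd1 > decomp.r_Fps1) & (decomp.r_Gpd1 > decomp.r_Others)
    idx = np.flatnonzero(dominant & (decomp.t >= 0))
    if len(idx) == 0:
        return float("nan")
    return float(decomp.t[idx[0]])


def half_rise_time(t: np.ndarray, y: np.ndarray,
                   t_ref: float = 180.0) -> float:
    """First time y exceeds half of its value at t_ref (min)."""
    i_ref = int(np.argmin(np.abs(t - t_ref)))
    half = 0.5 * y[i_ref]
    idx = np.flatnonzero(y >= half)
    if len(idx) == 0:
        return float("nan")
    return float(t[idx[0]])


def total_carbon_series(params, spec="WT", protocol=None,
                        rtol: float = 1e-8, atol: float = 1e-10):
    """Total carbon per mL of culture (mM carbon) along a stress simulation.

    Integrates the model together with two bookkeeping pools (released CO2
    and biomass drain, per mL of culture) so that, by construction, the
    total is conserved exactly; the numerical drift of the returned series
    measures integrator error. Returns (t, carbon_mM).
    """
    import numpy as _np
    from scipy.integrate import solve_ivp as _solve_ivp

    from . import _core
    from .model import CARBON_COUNTS
    from .params import N_STATES, SIDX
    from .simulate import StressProtocol, presstress_equilibrate
    from .strains import apply_strain, pinmask_and_state

    protocol = protocol or StressProtocol()
    sparams, pins = apply_strain(params, spec)
    p_arr = sparams.to_array()
    x0 = presstress_equilibrate(sparams, protocol.medium, pins=pins)
    mask, x0 = pinmask_and_state(pins, x0)
    iPDC, iALD6, iBM = 5, 6, 17  # FLUX_NAMES indices vPDC, vALD6, vBM
    iCD = SIDX["CD"]

    def aug(t, y):
        x = y[:N_STATES]
        dx = _core.rhs(t, x, p_arr, mask)
        v = _core.fluxes(x, p_arr)
        fac = x[iCD] * 1e-12
        return _np.concatenate([dx, [fac * (v[iPDC] + v[iALD6]),
                                     fac * v[iBM]]])

    grid = protocol.grid()
    y0 = _np.concatenate([x0, [0.0, 0.0]])
    y0[SIDX["NaCle"]] += protocol.NaCl_step
    res = _solve_ivp(aug, (protocol.t_stress, grid[-1]), y0,
                     method="LSODA", rtol=rtol, atol=atol, t_eval=grid)
    if not res.success:
        raise RuntimeError(f"carbon bookkeeping integration failed: "
                           f"{res.message}")
    Y = res.y
    cell_idx = [SIDX[n] for n in ("Glci", "HexP", "FBP", "TriP", "G3P",
                                  "Glyi", "Pyr", "EtOHi", "AcOi", "Trei")]
    cell_nc = _np.array([CARBON_COUNTS[n] for n in
                         ("Glci", "HexP", "FBP", "TriP", "G3P", "Glyi",
                          "Pyr", "EtOHi", "AcOi", "Trei")], dtype=float)
    ext_idx = [SIDX[n] for n in ("Glce", "Glye", "EtOHe", "AcOe", "Tree")]
    ext_nc = _np.array([CARBON_COUNTS[n] for n in
                        ("Glce", "Glye", "EtOHe", "AcOe", "Tree")],
                       dtype=float)
    fac = Y[iCD] * 1e-12
    carbon = (ext_nc @ Y[ext_idx]
              + fac * (cell_nc @ Y[cell_idx])
              + CARBON_COUNTS["CO2"] * Y[N_STATES]
              + CARBON_COUNTS["BIOMASS"] * Y[N_STATES + 1])
    return res.t, carbon


def doubling_time(traj: Trajectory, window: tuple[float, float]) -> float:
    """ln(2) / (least-squares slope of ln CD) over the window, in minutes."""
    t0, t1 = window
    sel = (traj.t >= t0) & (traj.t <= t1)
    if sel.sum() < 3:
        raise ValueError("doubling-time window must span >= 3 grid points")
    t = traj.t[sel]
    lncd = np.log(traj["CD"][sel])
    slope = np.polyfit(t, lncd, 1)[0]
    if slope <= 0:
        return float("inf")
    return float(np.log(2.0) / slope)


def flux_shares(traj: Trajectory, t: float) -> dict[str, float]:
    """Carbon shares of glucose uptake routed to the three major fates.

    Shares are carbon-weighted instantaneous rates relative to the glucose
    uptake carbon flux: biomass drain, the glycerol branch (carbon entering
    via Gpd1/Gpd2), and lower glycolysis (carbon committed to the
    ethanol/acetate branch). The remainder (pool_change_share) is net
    accumulation in intracellular pools, dilution losses and trehalose
    export; the four terms sum to 1 exactly.
    """
    i = int(np.argmin(np.abs(traj.t - t)))
    if not np.isclose(traj.t[i], t, atol=0.51):
        raise ValueError(f"time {t} not on trajectory grid")
    vHXT = traj["vHXT"][i]
    if vHXT <= 1e-12:
        raise ValueError("glucose uptake is ~0; shares undefined")
    uptake_C = 6.0 * vHXT
    biomass_C = 6.0 * traj["vBM"][i]
    glycerol_C = 3.0 * (traj["vGPD1"][i] + traj["vGPD2"][i])
    lower_C = 3.0 * traj["vLG"][i]
    shares = {
        "biomass_share": biomass_C / uptake_C,
        "glycerol_share": glycerol_C / uptake_C,
        "ethanol_acetate_share": lower_C / uptake_C,
    }
    shares["pool_change_share"] = 1.0 - sum(shares.values())
    return shares
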