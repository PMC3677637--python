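"""Symbolic (sympy) mirror of the model equations.

One symbolic definition of observables, reaction rates and the full
right-hand side, kept deliberately independent of the numeric core in
_core.py: the test suite lambdifies these expressions and checks them
against the numeric implementation at random states, and the SBML exporter
prints them as content MathML. The C1-smoothed clip is expressed with
Piecewise so the symbolic and numeric forms agree exactly.
"""

from __future__ import annotations

from functools import lru_cache

import sympy as sp

from ._core import CLIP_EPS, FLUX_NAMES
from .params import PARAM_NAMES, STATE_NAMES

__all__ = ["state_symbols", "param_symbols", "symbolic_observables",
           "symbolic_fluxes", "symbolic_rhs", "TIME"]

TIME = sp.Symbol("time", real=True)


@lru_cache(maxsize=1)
def state_symbols() -> dict[str, sp.Symbol]:
    return {n: sp.Symbol(n, real=True) for n in STATE_NAMES}


@lru_cache(maxsize=1)
def param_symbols() -> dict[str, sp.Symbol]:
    return {n: sp.Symbol(n, positive=True) for n in PARAM_NAMES}


def _sclip01(z):
    e = CLIP_EPS
    return sp.Piecewise(
        (0, z <= -e),
        ((z + e) ** 2 / (4 * e), z < e),
        (z, z <= 1 - e),
        (1 - (1 + e - z) ** 2 / (4 * e), z < 1 + e),
        (1, True),
    )


@lru_cache(maxsize=1)
def symbolic_observables() -> dict[str, sp.Expr]:
    x = state_symbols()
    p = param_symbols()
    Vos = x["Vos"]
    n_osm = p["n0"] + sum(x[n] for n in (
        "Glci", "HexP", "FBP", "TriP", "G3P", "Glyi", "Pyr",
        "EtOHi", "AcOi", "Trei", "F26DP"))
    Pi_i = n_osm / Vos / 1000
    Pi_e = (p["Pi_e0"] + p["i_vh"] * x["NaCle"]
            + (x["Glce"] + x["Glye"] + x["EtOHe"] + x["AcOe"] + x["Tree"])
            / 1000)
    ft = _sclip01((Vos - p["V_lp"]) / (p["Vos0"] - p["V_lp"]))
    Pi_t = p["Pi_t0"] * ft
    u = 1 - ft
    fg = _sclip01((Vos - p["V_gmin"]) / (p["Vos0"] - p["V_gmin"]))
    mu = (p["mu0"] * fg
          * (1 - p["theta_H"] * x["Hog1PP"] / (p["K_gH"] + x["Hog1PP"])))
    obs = {
        "Vtot": p["Vb"] + Vos,
        "Pi_i": Pi_i, "Pi_e": Pi_e, "Pi_t": Pi_t, "u": u, "mu": mu,
        "Gpd1tot": x["Gpd1m"] + 2 * x["Gpd1d"],
    }
    for n in ("Glci", "HexP", "FBP", "TriP", "G3P", "Glyi", "Pyr",
              "EtOHi", "AcOi", "Trei"):
        obs[f"c_{n}"] = x[n] / Vos
    return obs


@lru_cache(maxsize=1)
def symbolic_fluxes() -> dict[str, sp.Expr]:
    x = state_symbols()
    p = param_symbols()
    obs = symbolic_observables()
    Vos = x["Vos"]
    u, mu = obs["u"], obs["mu"]
    c = {n: x[n] / Vos for n in ("Glci", "HexP", "FBP", "TriP", "G3P",
                                 "Glyi", "Pyr", "EtOHi", "AcOi", "Trei",
                                 "F26DP")}
    v = {
        "vHXT": (p["kHXT"] * (x["Glce"] - c["Glci"])
                 / (p["KHXT"] + x["Glce"] + c["Glci"])),
        "vHK": (p["VmHK"] * c["Glci"] / (p["KHK"] + c["Glci"])
                * p["K_iHK"] / (p["K_iHK"] + c["HexP"])),
        "vPFK": (p["VmPFK"]
                 * (1 + p["aF"] * c["F26DP"] / (p["KF26"] + c["F26DP"]))
                 * c["HexP"] / (p["KPFK"] + c["HexP"])),
        "vALD": p["kALD"] * x["FBP"],
        "vLG": p["VmLG"] * c["TriP"] / (p["KLG"] + c["TriP"]),
        "vPDC": p["VmPDC"] * c["Pyr"] / (p["KPDC"] + c["Pyr"]),
        "vALD6": p["VmALD6"] * c["Pyr"] / (p["KALD6"] + c["Pyr"]),
        "vGPD1": (p["kcatGpd1"] * x["Gpd1d"]
                  * c["TriP"] / (p["KGPD"] + c["TriP"])),
        "vGPD2": (p["kcatGpd2"] * x["Gpd2"]
                  * c["TriP"] / (p["KGPD"] + c["TriP"])),
        "vGPP": p["VmGPP"] * c["G3P"] / (p["KGPP"] + c["G3P"]),
        "vTPS": ((p["kTPS0"] + p["kTPSh"] * x["Hog1PP"])
                 * c["HexP"] / (p["KTPS"] + c["HexP"])),
        "vNTH": p["kNTH"] * x["Trei"],
        "vFPS": p["k_fps"] * x["Fps1o"] * (c["Glyi"] - x["Glye"]),
        "vSTL": (p["VmSTL"] * x["Stl1"] * x["Glye"]
                 / (p["KSTL"] + x["Glye"])),
        "vEtOHt": p["k_tE"] * (c["EtOHi"] - x["EtOHe"]),
        "vAcOt": p["k_tA"] * (c["AcOi"] - x["AcOe"]),
        "vTret": p["k_tT"] * (c["Trei"] - x["Tree"]),
        "vBM": (p["gamma_bm"] * mu * c["HexP"] / (p["K_bm"] + c["HexP"])),
        "v_ph": p["k_ph"] * u * x["Hog1u"],
        "v_dp": p["k_dp"] * x["Hog1PP"],
        "v_txGPD1": p["k_b1"] + p["k_h1"] * x["Hog1PP"] + p["k_o1"] * u,
        "v_txGPD2": p["k_b2"] + p["k_o2"] * u,
        "v_txSTL1": (p["k_s0"] * p["K_rep"] / (p["K_rep"] + x["Glce"])
                     + p["k_s1"] * x["Hog1PP"]),
        "v_dim": p["k_dim"] * x["Gpd1m"] ** 2,
        "v_undim": p["k_undim"] * x["Gpd1d"],
        "v_a26": p["k_a26"] * x["Hog1PP"] * (p["PfkT"] - x["Pfk26a"]),
        "v_f26": (p["k_f26"] * x["Pfk26a"]
                  * c["HexP"] / (p["K_f26s"] + c["HexP"])),
    }
    assert set(v) == set(FLUX_NAMES)
    return v


@lru_cache(maxsize=1)
def symbolic_rhs() -> dict[str, sp.Expr]:
    """dX/dt for every state, keyed by state name."""
    x = state_symbols()
    p = param_symbols()
    obs = symbolic_observables()
    v = symbolic_fluxes()
    mu, u = obs["mu"], obs["u"]
    hfrac = sp.Piecewise((x["Hog1PP"] / p["Hog1tot"], p["Hog1tot"] > 0),
                         (0, True))
    fac = x["CD"] * sp.Rational(1, 10 ** 12)
    d = {
        "Vos": p["Lp_A"] * (obs["Pi_i"] - obs["Pi_e"] - obs["Pi_t"]),
        "Hog1u": -v["v_ph"] + v["v_dp"] - mu * x["Hog1u"],
        "Hog1PP": v["v_ph"] - v["v_dp"] - mu * x["Hog1PP"],
        "mGPD1": v["v_txGPD1"] - p["d_m1"] * x["mGPD1"] - mu * x["mGPD1"],
        "Gpd1m": (p["ks1"] * x["mGPD1"] - p["kd1"] * x["Gpd1m"]
                  - 2 * v["v_dim"] + 2 * v["v_undim"] - mu * x["Gpd1m"]),
        "Gpd1d": (v["v_dim"] - v["v_undim"] - p["kd1d"] * x["Gpd1d"]
                  - mu * x["Gpd1d"]),
        "Gpd2": v["v_txGPD2"] - p["d2"] * x["Gpd2"] - mu * x["Gpd2"],
        "mSTL1": v["v_txSTL1"] - p["d_ms"] * x["mSTL1"] - mu * x["mSTL1"],
        "Stl1": (p["ks_s"] * x["mSTL1"] - p["kd_s"] * x["Stl1"]
                 - mu * x["Stl1"]),
        "Pfk26a": v["v_a26"] - p["k_i26"] * x["Pfk26a"] - mu * x["Pfk26a"],
        "F26DP": v["v_f26"] - p["d_f26"] * x["F26DP"] - mu * x["F26DP"],
        "Fps1o": (p["k_open"] * (1 - x["Fps1o"])
                  - (p["k_cT"] * u + p["k_cH"] * hfrac) * x["Fps1o"]),
        "Glci": v["vHXT"] + 2 * v["vNTH"] - v["vHK"] - mu * x["Glci"],
        "HexP": (v["vHK"] - v["vPFK"] - 2 * v["vTPS"] - v["vBM"]
                 - mu * x["HexP"]),
        "FBP": v["vPFK"] - v["vALD"] - mu * x["FBP"],
        "TriP": (2 * v["vALD"] - v["vLG"] - v["vGPD1"] - v["vGPD2"]
                 - mu * x["TriP"]),
        "G3P": v["vGPD1"] + v["vGPD2"] - v["vGPP"] - mu * x["G3P"],
        "Glyi": v["vGPP"] - v["vFPS"] + v["vSTL"] - mu * x["Glyi"],
        "Pyr": v["vLG"] - v["vPDC"] - v["vALD6"] - mu * x["Pyr"],
        "EtOHi": v["vPDC"] - v["vEtOHt"] - mu * x["EtOHi"],
        "AcOi": v["vALD6"] - v["vAcOt"] - mu * x["AcOi"],
        "Trei": v["vTPS"] - v["vNTH"] - v["vTret"] - mu * x["Trei"],
        "Glce": -fac * v["vHXT"],
        "Glye": fac * (v["vFPS"] - v["vSTL"]),
        "EtOHe": fac * v["vEtOHt"],
        "AcOe": fac * v["vAcOt"],
        "Tree": fac * v["vTret"],
        "NaCle": sp.Integer(0),
        "CD": mu * x["CD"],
    }
    assert set(d) == set(STATE_NAMES)
    return d
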