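"""Scalar numerical core of the model: observables, fluxes, right-hand side.

These functions operate on plain float64 arrays (state vector x, parameter
vector p in the canonical orders of params.STATE_NAMES / PARAM_NAMES) so that
numba can compile them; a pure-Python fallback is used when numba is absent.
All public, validated entry points live in model.py.
"""

from __future__ import annotations

import numpy as np

from .params import PIDX, SIDX

# blending half-width of the C1 clip used in turgor / signal / growth factors
CLIP_EPS = 0.01

# ---------------------------------------------------------------------------
# index constants (module-level ints are compile-time constants for numba)
iVos = SIDX["Vos"]; iHog1u = SIDX["Hog1u"]; iHog1PP = SIDX["Hog1PP"]
imGPD1 = SIDX["mGPD1"]; iGpd1m = SIDX["Gpd1m"]; iGpd1d = SIDX["Gpd1d"]
iGpd2 = SIDX["Gpd2"]; imSTL1 = SIDX["mSTL1"]; iStl1 = SIDX["Stl1"]
iPfk26a = SIDX["Pfk26a"]; iF26DP = SIDX["F26DP"]; iFps1o = SIDX["Fps1o"]
iGlci = SIDX["Glci"]; iHexP = SIDX["HexP"]; iFBP = SIDX["FBP"]
iTriP = SIDX["TriP"]; iG3P = SIDX["G3P"]; iGlyi = SIDX["Glyi"]
iPyr = SIDX["Pyr"]; iEtOHi = SIDX["EtOHi"]; iAcOi = SIDX["AcOi"]
iTrei = SIDX["Trei"]; iGlce = SIDX["Glce"]; iGlye = SIDX["Glye"]
iEtOHe = SIDX["EtOHe"]; iAcOe = SIDX["AcOe"]; iTree = SIDX["Tree"]
iNaCle = SIDX["NaCle"]; iCD = SIDX["CD"]

jVb = PIDX["Vb"]; jVos0 = PIDX["Vos0"]; jLp_A = PIDX["Lp_A"]
jPi_t0 = PIDX["Pi_t0"]; jV_lp = PIDX["V_lp"]; jn0 = PIDX["n0"]
ji_vh = PIDX["i_vh"]; jPi_e0 = PIDX["Pi_e0"]
jHog1tot = PIDX["Hog1tot"]; jk_ph = PIDX["k_ph"]; jk_dp = PIDX["k_dp"]
jk_b1 = PIDX["k_b1"]; jk_h1 = PIDX["k_h1"]; jk_o1 = PIDX["k_o1"]
jd_m1 = PIDX["d_m1"]; jks1 = PIDX["ks1"]; jkd1 = PIDX["kd1"]
jk_dim = PIDX["k_dim"]; jk_undim = PIDX["k_undim"]; jkd1d = PIDX["kd1d"]
jk_b2 = PIDX["k_b2"]; jk_o2 = PIDX["k_o2"]; jd2 = PIDX["d2"]
jk_s0 = PIDX["k_s0"]; jK_rep = PIDX["K_rep"]; jk_s1 = PIDX["k_s1"]
jd_ms = PIDX["d_ms"]; jks_s = PIDX["ks_s"]; jkd_s = PIDX["kd_s"]
jPfkT = PIDX["PfkT"]; jk_a26 = PIDX["k_a26"]; jk_i26 = PIDX["k_i26"]
jk_f26 = PIDX["k_f26"]; jK_f26s = PIDX["K_f26s"]; jd_f26 = PIDX["d_f26"]
jk_open = PIDX["k_open"]; jk_cT = PIDX["k_cT"]; jk_cH = PIDX["k_cH"]
jk_fps = PIDX["k_fps"]
jkHXT = PIDX["kHXT"]; jKHXT = PIDX["KHXT"]; jVmHK = PIDX["VmHK"]
jKHK = PIDX["KHK"]; jK_iHK = PIDX["K_iHK"]
jVmPFK = PIDX["VmPFK"]; jKPFK = PIDX["KPFK"]
jaF = PIDX["aF"]; jKF26 = PIDX["KF26"]; jkALD = PIDX["kALD"]
jVmLG = PIDX["VmLG"]; jKLG = PIDX["KLG"]; jVmPDC = PIDX["VmPDC"]
jKPDC = PIDX["KPDC"]; jVmALD6 = PIDX["VmALD6"]; jKALD6 = PIDX["KALD6"]
jkcatGpd1 = PIDX["kcatGpd1"]; jkcatGpd2 = PIDX["kcatGpd2"]
jKGPD = PIDX["KGPD"]; jVmGPP = PIDX["VmGPP"]; jKGPP = PIDX["KGPP"]
jkTPS0 = PIDX["kTPS0"]; jkTPSh = PIDX["kTPSh"]; jKTPS = PIDX["KTPS"]
jkNTH = PIDX["kNTH"]; jk_tE = PIDX["k_tE"]; jk_tA = PIDX["k_tA"]
jk_tT = PIDX["k_tT"]; jVmSTL = PIDX["VmSTL"]; jKSTL = PIDX["KSTL"]
jmu0 = PIDX["mu0"]; jtheta_H = PIDX["theta_H"]; jK_gH = PIDX["K_gH"]
jV_gmin = PIDX["V_gmin"]; jgamma_bm = PIDX["gamma_bm"]
jK_bm = PIDX["K_bm"]

OBS_NAMES: tuple[str, ...] = (
    "Vtot", "Pi_i", "Pi_e", "Pi_t", "u", "mu", "Gpd1tot",
    "c_Glci", "c_HexP", "c_FBP", "c_TriP", "c_G3P", "c_Glyi",
    "c_Pyr", "c_EtOHi", "c_AcOi", "c_Trei",
)
OIDX = {n: i for i, n in enumerate(OBS_NAMES)}

FLUX_NAMES: tuple[str, ...] = (
    "vHXT", "vHK", "vPFK", "vALD", "vLG", "vPDC", "vALD6",
    "vGPD1", "vGPD2", "vGPP", "vTPS", "vNTH", "vFPS", "vSTL",
    "vEtOHt", "vAcOt", "vTret", "vBM",
    "v_ph", "v_dp", "v_txGPD1", "v_txGPD2", "v_txSTL1",
    "v_dim", "v_undim", "v_a26", "v_f26",
)
FIDX = {n: i for i, n in enumerate(FLUX_NAMES)}
N_FLUXES = len(FLUX_NAMES)


def _identity_decorator(func):
    return func


try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=False, fastmath=False)(func)
except Exception:  # pragma: no cover
    _jit = _identity_decorator


def _sclip01_py(z: float) -> float:
    """C1 clip of z to [0, 1] with quadratic corners of half-width CLIP_EPS."""
    e = CLIP_EPS
    if z <= -e:
        return 0.0
    if z < e:
        d = z + e
        return d * d / (4.0 * e)
    if z <= 1.0 - e:
        return z
    if z < 1.0 + e:
        d = 1.0 + e - z
        return 1.0 - d * d / (4.0 * e)
    return 1.0


def _observables_py(x, p):
    """Algebraic observables as a float64 array in OBS_NAMES order."""
    out = np.empty(len(OBS_NAMES))
    Vos = x[iVos]
    out[0] = p[jVb] + Vos                                      # Vtot
    n_osm = p[jn0]
    for k in (iGlci, iHexP, iFBP, iTriP, iG3P, iGlyi, iPyr,
              iEtOHi, iAcOi, iTrei, iF26DP):
        n_osm += x[k]
    out[1] = n_osm / Vos / 1000.0                              # Pi_i (Osm)
    out[2] = (p[jPi_e0] + p[ji_vh] * x[iNaCle]
              + (x[iGlce] + x[iGlye] + x[iEtOHe] + x[iAcOe] + x[iTree])
              / 1000.0)                                        # Pi_e
    zt = (Vos - p[jV_lp]) / (p[jVos0] - p[jV_lp])
    ft = _sclip01(zt)
    out[3] = p[jPi_t0] * ft                                    # Pi_t
    out[4] = 1.0 - ft                                          # u
    zg = (Vos - p[jV_gmin]) / (p[jVos0] - p[jV_gmin])
    hog_inhib = 1.0 - p[jtheta_H] * x[iHog1PP] / (p[jK_gH] + x[iHog1PP])
    out[5] = p[jmu0] * _sclip01(zg) * hog_inhib                # mu
    out[6] = x[iGpd1m] + 2.0 * x[iGpd1d]                       # Gpd1tot
    out[7] = x[iGlci] / Vos
    out[8] = x[iHexP] / Vos
    out[9] = x[iFBP] / Vos
    out[10] = x[iTriP] / Vos
    out[11] = x[iG3P] / Vos
    out[12] = x[iGlyi] / Vos
    out[13] = x[iPyr] / Vos
    out[14] = x[iEtOHi] / Vos
    out[15] = x[iAcOi] / Vos
    out[16] = x[iTrei] / Vos
    return out


def _fluxes_py(x, p, obs):
    """Per-cell reaction/process rates (amol/min) in FLUX_NAMES order."""
    v = np.empty(N_FLUXES)
    Vos = x[iVos]
    u = obs[4]
    mu = obs[5]
    cGlci = x[iGlci] / Vos
    cHexP = x[iHexP] / Vos
    cTriP = x[iTriP] / Vos
    cG3P = x[iG3P] / Vos
    cGlyi = x[iGlyi] / Vos
    cPyr = x[iPyr] / Vos
    cEtOHi = x[iEtOHi] / Vos
    cAcOi = x[iAcOi] / Vos
    cTrei = x[iTrei] / Vos
    cF26 = x[iF26DP] / Vos
    cGlce = x[iGlce]

    v[0] = (p[jkHXT] * (cGlce - cGlci)
            / (p[jKHXT] + cGlce + cGlci))                             # vHXT
    v[1] = (p[jVmHK] * cGlci / (p[jKHK] + cGlci)
            * p[jK_iHK] / (p[jK_iHK] + cHexP))                        # vHK
    v[2] = (p[jVmPFK] * (1.0 + p[jaF] * cF26 / (p[jKF26] + cF26))
            * cHexP / (p[jKPFK] + cHexP))                             # vPFK
    v[3] = p[jkALD] * x[iFBP]                                         # vALD
    v[4] = p[jVmLG] * cTriP / (p[jKLG] + cTriP)                       # vLG
    v[5] = p[jVmPDC] * cPyr / (p[jKPDC] + cPyr)                       # vPDC
    v[6] = p[jVmALD6] * cPyr / (p[jKALD6] + cPyr)                     # vALD6
    v[7] = p[jkcatGpd1] * x[iGpd1d] * cTriP / (p[jKGPD] + cTriP)      # vGPD1
    v[8] = p[jkcatGpd2] * x[iGpd2] * cTriP / (p[jKGPD] + cTriP)       # vGPD2
    v[9] = p[jVmGPP] * cG3P / (p[jKGPP] + cG3P)                       # vGPP
    v[10] = ((p[jkTPS0] + p[jkTPSh] * x[iHog1PP])
             * cHexP / (p[jKTPS] + cHexP))                            # vTPS
    v[11] = p[jkNTH] * x[iTrei]                                       # vNTH
    v[12] = p[jk_fps] * x[iFps1o] * (cGlyi - x[iGlye])                # vFPS
    v[13] = p[jVmSTL] * x[iStl1] * x[iGlye] / (p[jKSTL] + x[iGlye])   # vSTL
    v[14] = p[jk_tE] * (cEtOHi - x[iEtOHe])                           # vEtOHt
    v[15] = p[jk_tA] * (cAcOi - x[iAcOe])                             # vAcOt
    v[16] = p[jk_tT] * (cTrei - x[iTree])                             # vTret
    v[17] = (p[jgamma_bm] * mu
             * cHexP / (p[jK_bm] + cHexP))                        # vBM
    v[18] = p[jk_ph] * u * x[iHog1u]                                  # v_ph
    v[19] = p[jk_dp] * x[iHog1PP]                                     # v_dp
    v[20] = p[jk_b1] + p[jk_h1] * x[iHog1PP] + p[jk_o1] * u           # v_txGPD1
    v[21] = p[jk_b2] + p[jk_o2] * u                                   # v_txGPD2
    v[22] = (p[jk_s0] * p[jK_rep] / (p[jK_rep] + cGlce)
             + p[jk_s1] * x[iHog1PP])                                 # v_txSTL1
    v[23] = p[jk_dim] * x[iGpd1m] * x[iGpd1m]                         # v_dim
    v[24] = p[jk_undim] * x[iGpd1d]                                   # v_undim
    v[25] = p[jk_a26] * x[iHog1PP] * (p[jPfkT] - x[iPfk26a])          # v_a26
    v[26] = (p[jk_f26] * x[iPfk26a]
             * cHexP / (p[jK_f26s] + cHexP))                          # v_f26
    return v


def _rhs_py(t, x, p, pinmask):
    """Time derivative of the 29-entry state vector.

    pinmask: float64[29]; entries set to 0.0 freeze the corresponding state
    (used for strain pins such as constitutively open Fps1, and to hold the
    externals fixed during pre-stress equilibration).
    """
    obs = _observables(x, p)
    v = _fluxes(x, p, obs)
    mu = obs[5]
    u = obs[4]
    dx = np.zeros(x.shape[0])

    # water flux
    dx[iVos] = p[jLp_A] * (obs[1] - obs[2] - obs[3])

    # Hog1 two-reaction signaling, with growth dilution
    dx[iHog1u] = -v[18] + v[19] - mu * x[iHog1u]
    dx[iHog1PP] = v[18] - v[19] - mu * x[iHog1PP]

    # gene expression / proteins
    dx[imGPD1] = v[20] - p[jd_m1] * x[imGPD1] - mu * x[imGPD1]
    dx[iGpd1m] = (p[jks1] * x[imGPD1] - p[jkd1] * x[iGpd1m]
                  - 2.0 * v[23] + 2.0 * v[24] - mu * x[iGpd1m])
    dx[iGpd1d] = v[23] - v[24] - p[jkd1d] * x[iGpd1d] - mu * x[iGpd1d]
    dx[iGpd2] = v[21] - p[jd2] * x[iGpd2] - mu * x[iGpd2]
    dx[imSTL1] = v[22] - p[jd_ms] * x[imSTL1] - mu * x[imSTL1]
    dx[iStl1] = p[jks_s] * x[imSTL1] - p[jkd_s] * x[iStl1] - mu * x[iStl1]

    # Pfk26/27 activation and F26DP
    dx[iPfk26a] = v[25] - p[jk_i26] * x[iPfk26a] - mu * x[iPfk26a]
    dx[iF26DP] = v[26] - p[jd_f26] * x[iF26DP] - mu * x[iF26DP]

    # Fps1 gating
    hfrac = x[iHog1PP] / p[jHog1tot] if p[jHog1tot] > 0.0 else 0.0
    dx[iFps1o] = (p[jk_open] * (1.0 - x[iFps1o])
                  - (p[jk_cT] * u + p[jk_cH] * hfrac) * x[iFps1o])

    # metabolites (per-cell amounts, growth dilution on each)
    dx[iGlci] = v[0] + 2.0 * v[11] - v[1] - mu * x[iGlci]
    dx[iHexP] = v[1] - v[2] - 2.0 * v[10] - v[17] - mu * x[iHexP]
    dx[iFBP] = v[2] - v[3] - mu * x[iFBP]
    dx[iTriP] = 2.0 * v[3] - v[4] - v[7] - v[8] - mu * x[iTriP]
    dx[iG3P] = v[7] + v[8] - v[9] - mu * x[iG3P]
    dx[iGlyi] = v[9] - v[12] + v[13] - mu * x[iGlyi]
    dx[iPyr] = v[4] - v[5] - v[6] - mu * x[iPyr]
    dx[iEtOHi] = v[5] - v[14] - mu * x[iEtOHi]
    dx[iAcOi] = v[6] - v[15] - mu * x[iAcOi]
    dx[iTrei] = v[10] - v[11] - v[16] - mu * x[iTrei]

    # external pools, corrected for cell density (amol/min/cell * cells/mL
    # * 1e-12 -> mM/min)
    fac = x[iCD] * 1.0e-12
    dx[iGlce] = -fac * v[0]
    dx[iGlye] = fac * (v[12] - v[13])
    dx[iEtOHe] = fac * v[14]
    dx[iAcOe] = fac * v[15]
    dx[iTree] = fac * v[16]
    dx[iNaCle] = 0.0
    dx[iCD] = mu * x[iCD]

    for k in range(x.shape[0]):
        dx[k] *= pinmask[k]
    return dx


_sclip01 = _jit(_sclip01_py)
_observables = _jit(_observables_py)
_fluxes = _jit(_fluxes_py)
_rhs = _jit(_rhs_py)

NO_PINS = np.ones(29)


def rhs(t: float, x: np.ndarray, p: np.ndarray,
        pinmask: np.ndarray | None = None) -> np.ndarray:
    if pinmask is None:
        pinmask = NO_PINS
    return _rhs(t, x, p, pinmask)


def observables(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return _observables(x, p)


def fluxes(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    return _fluxes(x, p, _observables(x, p))
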