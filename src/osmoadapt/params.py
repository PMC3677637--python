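"""Parameter and state-vector catalogues for the osmoadaptation model.

Units
-----
* intracellular amounts: amol/cell (1 amol / 1 fL = 1 mM)
* volumes: fL/cell
* external concentrations: mM, except added NaCl which is in M
* osmotic pressures / osmolarities: Osm
* time: min; cell density: cells/mL

The dataclass defaults constitute the calibrated reference parameter set
(theta-star) used throughout: it was hand-tuned in stages (pre-stress
quasi-steady state, then signaling kinetics, then glycerol/flux dynamics)
to reproduce the qualitative timing of wild-type and mutant osmoadaptation
after a 0.4 M NaCl step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Names of the 29 dynamic state variables, in canonical order.
STATE_NAMES: tuple[str, ...] = (
    "Vos",      # osmotically active volume (fL)
    "Hog1u",    # unphosphorylated Hog1 (amol)
    "Hog1PP",   # dually phosphorylated Hog1 (amol)
    "mGPD1",    # GPD1 mRNA (au)
    "Gpd1m",    # Gpd1 monomer (amol)
    "Gpd1d",    # Gpd1 dimer (amol)
    "Gpd2",     # Gpd2 protein (amol)
    "mSTL1",    # STL1 mRNA (au)
    "Stl1",     # Stl1 transporter (amol)
    "Pfk26a",   # active Pfk26/27 (amol)
    "F26DP",    # fructose-2,6-bisphosphate (amol)
    "Fps1o",    # open fraction of Fps1 (dimensionless)
    "Glci",     # intracellular glucose (amol)
    "HexP",     # hexose phosphates (amol)
    "FBP",      # fructose-1,6-bisphosphate (amol)
    "TriP",     # triose phosphates (amol)
    "G3P",      # glycerol-3-phosphate (amol)
    "Glyi",     # intracellular glycerol (amol)
    "Pyr",      # pyruvate (amol)
    "EtOHi",    # intracellular ethanol (amol)
    "AcOi",     # intracellular acetate (amol)
    "Trei",     # intracellular trehalose (amol)
    "Glce",     # external glucose (mM)
    "Glye",     # external glycerol (mM)
    "EtOHe",    # external ethanol (mM)
    "AcOe",     # external acetate (mM)
    "Tree",     # external trehalose (mM)
    "NaCle",    # added external NaCl (M)
    "CD",       # cell density (cells/mL)
)

N_STATES = len(STATE_NAMES)
assert N_STATES == 29

#: index lookup
SIDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: intracellular per-cell states (everything that is an amount or fraction
#: carried by one cell); these are the unknowns of pre-stress equilibration.
INTRACELLULAR = STATE_NAMES[:22]

#: per-cell amounts subject to growth dilution (-mu*X): all per-cell pools
#: except the osmotic volume itself and the open-channel fraction.
DILUTED = tuple(n for n in INTRACELLULAR if n not in ("Vos", "Fps1o"))

#: intracellular metabolites counted in the internal osmolarity
OSMOTIC_METABOLITES = (
    "Glci", "HexP", "FBP", "TriP", "G3P", "Glyi", "Pyr", "EtOHi",
    "AcOi", "Trei", "F26DP",
)

#: the 14 model variables with measurement mappings (see estimate.py)
MEASURED_VARIABLES = (
    "Hog1PP", "Gpd1tot", "mGPD1", "mSTL1",
    "Glci", "Glce", "Glyi", "Glye",
    "EtOHi", "EtOHe", "AcOe", "Trei", "Tree", "CD",
)


@dataclass(frozen=True)
class ModelParameters:
    """Shared kinetic/biophysical parameter set (all strains use one set).

    Rate constants are per minute; Vmax-type constants are amol/min/cell;
    Michaelis constants are mM; permeability-type constants (k_fps, k_tE,
    k_tA, k_tT) are fL/min so that k*(c_in - c_out) is an amol/min flux.
    """

    # --- biophysics ---
    Vb: float = 25.0        # basal (osmotically inactive) volume, fL
    Vos0: float = 35.0      # pre-stress osmotically active volume, fL
    Lp_A: float = 20.0      # water permeability x area, fL/min/Osm
    Pi_t0: float = 0.2      # pre-stress turgor pressure, Osm
    V_lp: float = 28.0      # Vos at which turgor vanishes, fL
    n0: float = 17510.1     # background osmotically active amount, amol
    i_vh: float = 2.0       # van't Hoff factor of NaCl
    Pi_e0: float = 0.24     # medium background osmolarity, Osm

    # --- Hog1 signaling (two reactions) ---
    Hog1tot: float = 0.01   # total Hog1, amol
    k_ph: float = 4.0       # phosphorylation, 1/min (per unit signal u)
    k_dp: float = 1.0       # dephosphorylation, 1/min

    # --- GPD1 expression / Gpd1 protein ---
    k_b1: float = 0.006     # basal GPD1 transcription, au/min
    k_h1: float = 80.0      # Hog1-dependent transcription, au/min/amol
    k_o1: float = 0.04      # Hog1-independent osmotic transcription, au/min
    d_m1: float = 0.03       # GPD1 mRNA decay, 1/min
    ks1: float = 0.025      # translation, amol/min/au
    kd1: float = 0.01       # Gpd1 monomer degradation, 1/min
    k_dim: float = 0.05    # dimerization, 1/min/amol
    k_undim: float = 0.01   # dimer dissociation, 1/min
    kd1d: float = 0.03      # dimer degradation, 1/min

    # --- GPD2 (lumped protein pool) ---
    k_b2: float = 0.0157    # basal production, amol/min
    k_o2: float = 0.008      # osmotic production, amol/min (per unit u)
    d2: float = 0.008        # degradation, 1/min

    # --- STL1 expression / Stl1 protein ---
    k_s0: float = 1.0       # glucose-repressible transcription, au/min
    K_rep: float = 5.0      # glucose repression constant, mM
    k_s1: float = 200.0    # Hog1-dependent transcription, au/min/amol
    d_ms: float = 0.1       # STL1 mRNA decay, 1/min
    ks_s: float = 0.0127      # translation, amol/min/au
    kd_s: float = 0.05      # Stl1 degradation, 1/min

    # --- Pfk26/27 and F26DP ---
    PfkT: float = 0.02      # total Pfk26/27, amol
    k_a26: float = 60.0     # Hog1-dependent activation, 1/min/amol
    k_i26: float = 0.1      # inactivation, 1/min
    k_f26: float = 100.0    # F26DP synthesis, 1/min (per amol active enzyme)
    K_f26s: float = 3.0     # HexP saturation of F26DP synthesis, mM
    d_f26: float = 0.5      # F26DP turnover, 1/min

    # --- Fps1 gating and permeability ---
    k_open: float = 0.06    # reopening, 1/min
    k_cT: float = 0.08       # turgor-loss-driven closure, 1/min
    k_cH: float = 1.2       # Hog1PP-driven closure, 1/min
    k_fps: float = 6.0     # glycerol permeability of open Fps1, fL/min

    # --- glycolysis / branches ---
    kHXT: float = 6130.0    # glucose carrier Vmax, amol/min
    KHXT: float = 25.0      # mM
    VmHK: float = 13530.0   # hexokinase Vmax
    KHK: float = 0.8
    K_iHK: float = 4.0      # HexP product inhibition of hexokinase, mM
    VmPFK: float = 4510.0   # Pfk1 Vmax (F26DP modulates Vmax)
    KPFK: float = 0.4
    aF: float = 0.35         # maximal fractional Vmax boost by F26DP
    KF26: float = 0.05      # F26DP activation constant, mM
    kALD: float = 23.5      # aldolase mass action, 1/min (amount-based)
    VmLG: float = 10700.0   # lumped lower glycolysis Vmax
    KLG: float = 0.5
    VmPDC: float = 14900.0  # pyruvate -> ethanol Vmax
    KPDC: float = 2.0
    VmALD6: float = 600.0   # pyruvate -> acetate Vmax
    KALD6: float = 2.0
    kcatGpd1: float = 980.0  # Gpd1 dimer kcat, 1/min
    kcatGpd2: float = 54.0  # Gpd2 kcat, 1/min
    KGPD: float = 0.1
    VmGPP: float = 5000.0    # G3P phosphatase Vmax
    KGPP: float = 0.5
    kTPS0: float = 60.0     # basal trehalose synthesis Vmax
    kTPSh: float = 25000.0  # Hog1PP-dependent boost, amol/min/amol
    KTPS: float = 3.0
    kNTH: float = 0.08      # trehalose mobilization, 1/min (amount-based)
    k_tE: float = 3500.0    # ethanol membrane exchange, fL/min
    k_tA: float = 350.0     # acetate membrane exchange, fL/min
    k_tT: float = 0.2       # trehalose membrane exchange, fL/min
    VmSTL: float = 600.0    # Stl1 kcat, 1/min
    KSTL: float = 1.0       # mM

    # --- growth ---
    mu0: float = 0.0077     # unstressed specific growth rate, 1/min
    theta_H: float = 0.5    # maximal Hog1-dependent growth inhibition
    K_gH: float = 0.002     # Hog1PP half-inhibition, amol
    V_gmin: float = 24.0    # Vos below which growth stops, fL
    gamma_bm: float = 1.35e5  # carbon drain per growth, amol glucose-equiv
    K_bm: float = 1.0       # HexP availability saturation of the drain, mM

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is not finite")
            if name == "theta_H":
                if not (0.0 <= value <= 1.0):
                    raise ValueError("theta_H must be in [0, 1]")
            elif value < 0:
                raise ValueError(f"parameter {name} must be non-negative")

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def replace(self, **edits: float) -> "ModelParameters":
        unknown = set(edits) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **edits)

    # JSON round-trip -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls(**json.loads(Path(path).read_text()))


PARAM_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ModelParameters)
)
PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass(frozen=True)
class Medium:
    """Configured t = -infinity culture state (YPD, mid-exponential phase)."""

    Glce: float = 111.0     # 2% glucose, mM
    Glye: float = 0.2       # mM
    EtOHe: float = 5.0      # mM
    AcOe: float = 0.5       # mM
    Tree: float = 0.02      # mM
    CD: float = 1.0e7       # cells/mL (OD600 ~ 0.7-1)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


def reference_parameters() -> ModelParameters:
    """The calibrated reference parameter set (theta-star)."""
    return ModelParameters()
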