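"""Synthetic time-course measurement tables.

Two generators emulate the structure of the study's dataset (per-strain
tidy tables of metabolite, blot and cell-density measurements over 0-240
min after a 0.4 M NaCl step):

* model-based: simulate the model at a parameter set and add seeded
  lognormal multiplicative noise (positivity-preserving);
* phenomenological: closed-form wild-type template curves reproducing the
  qualitative features reported for the real data - monotone external
  glucose decrease, monotone ethanol/acetate/glycerol/cell-density
  increase, a fast transient Hog1-phosphorylation pulse, a transient
  intracellular glycerol bump, and an intracellular trehalose course with
  two peaks, at 45 and 180 min.

Both modes share one table schema and pass the same reader (io module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MEASURED_VARIABLES, Medium, ModelParameters
from .estimate import measurement_series
from .simulate import StressProtocol, simulate

__all__ = [
    "NoiseSpec", "TABLE_COLUMNS", "VARIABLE_INFO",
    "METABOLITE_SCHEDULE", "PROTEIN_SCHEDULE",
    "generate_model_based", "generate_phenomenological",
    "trehalose_template", "validate_table",
]

TABLE_COLUMNS = ("strain", "variable", "compartment", "time_min",
                 "replicate", "value", "unit", "method")

#: compartment and unit per measured variable
VARIABLE_INFO: dict[str, tuple[str, str]] = {
    "Hog1PP": ("intracellular", "au"),
    "Gpd1tot": ("intracellular", "au"),
    "mGPD1": ("intracellular", "au"),
    "mSTL1": ("intracellular", "au"),
    "Glci": ("intracellular", "mM"),
    "Glyi": ("intracellular", "mM"),
    "EtOHi": ("intracellular", "mM"),
    "Trei": ("intracellular", "mM"),
    "Glce": ("extracellular", "mM"),
    "Glye": ("extracellular", "mM"),
    "EtOHe": ("extracellular", "mM"),
    "AcOe": ("extracellular", "mM"),
    "Tree": ("extracellular", "mM"),
    "CD": ("total", "cells/mL"),
}

#: default sampling schedules (min): metabolites by HPLC-like cadence,
#: phospho/protein blots denser early to bracket the Hog1 pulse
METABOLITE_SCHEDULE = (0.0, 10.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0)
PROTEIN_SCHEDULE = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0)

_PROTEIN_VARIABLES = ("Hog1PP", "Gpd1tot", "mGPD1", "mSTL1")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: lognormal multiplicative, mean-unbiased."""

    sigma_rel: float = 0.15
    sigma_abs: dict[str, float] = field(default_factory=dict)
    n_rep: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")


def _apply_noise(values: np.ndarray, variable: str, noise: NoiseSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if noise.sigma_rel == 0.0 and not noise.sigma_abs:
        return values.copy()
    out = values.copy()
    if noise.sigma_rel > 0:
        # lognormal with CV exactly sigma_rel and mean exactly y
        s2 = np.log1p(noise.sigma_rel ** 2)
        draw = rng.normal(0.0, np.sqrt(s2), size=values.shape)
        out = out * np.exp(draw - 0.5 * s2)
    floor = noise.sigma_abs.get(variable, 0.0)
    if floor > 0:
        out = out + rng.normal(0.0, floor, size=values.shape)
    return np.maximum(out, 0.0)


def _rows(strain: str, variable: str, t: np.ndarray, rep: int,
          values: np.ndarray, method: str) -> pd.DataFrame:
    comp, unit = VARIABLE_INFO[variable]
    return pd.DataFrame({
        "strain": strain, "variable": variable, "compartment": comp,
        "time_min": t, "replicate": rep, "value": values,
        "unit": unit, "method": method,
    })


def validate_table(df: pd.DataFrame) -> None:
    """Enforce MeasurementTable invariants (schema, sign, uniqueness)."""
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0].tolist()
        raise ValueError(f"negative measurement values at rows {bad[:5]}")
    unknown = set(df["variable"]) - set(MEASURED_VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")
    key = ["strain", "variable", "time_min", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate (strain, variable, time, replicate) records at rows "
            f"{df.index[dup].tolist()[:5]}")


def generate_model_based(params: ModelParameters | None = None,
                         strains: list[str] = ("WT",),
                         schedule: dict | list | None = None,
                         noise: NoiseSpec | None = None,
                         medium: Medium | None = None,
                         nacl_step: float = 0.4,
                         t_end: float = 240.0) -> pd.DataFrame:
    """Simulate strains at a parameter set and sample noisy measurements.

    schedule may be a list of times applied to all 14 variables, or a dict
    {variable: times}; the default uses the metabolite/protein cadences.
    With sigma_rel = 0 and no absolute floors, values equal the simulated
    observables exactly.
    """
    params = params or ModelParameters()
    noise = noise or NoiseSpec()
    medium = medium or Medium()
    rng = np.random.default_rng(noise.seed)

    if schedule is None:
        sched = {v: (PROTEIN_SCHEDULE if v in _PROTEIN_VARIABLES
                     else METABOLITE_SCHEDULE) for v in MEASURED_VARIABLES}
    elif isinstance(schedule, dict):
        sched = {v: schedule[v] for v in schedule}
    else:
        sched = {v: tuple(schedule) for v in MEASURED_VARIABLES}
    for v, times in sched.items():
        tarr = np.asarray(times, dtype=float)
        if tarr.min() < 0 or tarr.max() > t_end:
            raise ValueError(f"schedule for {v} outside [0, {t_end}]")

    all_times = np.unique(np.concatenate(
        [np.asarray(ts, dtype=float) for ts in sched.values()]))
    if all_times[0] > 0.0:
        all_times = np.insert(all_times, 0, 0.0)
    proto = StressProtocol(NaCl_step=nacl_step, t_end=float(all_times[-1]),
                           t_grid=all_times, medium=medium)

    frames = []
    for strain in strains:
        traj = simulate(params, strain, proto)
        for variable, times in sched.items():
            tarr = np.asarray(times, dtype=float)
            clean = measurement_series(traj, variable)[
                np.searchsorted(traj.t, tarr)]
            # integrator round-off can leave ~atol-scale negatives on
            # species that have decayed to zero
            clean = np.maximum(clean, 0.0)
            for rep in range(1, noise.n_rep + 1):
                noisy = _apply_noise(clean, variable, noise, rng)
                frames.append(_rows(strain, variable, tarr, rep, noisy,
                                    "simulated"))
    df = pd.concat(frames, ignore_index=True)
    validate_table(df)
    return df


# ---------------------------------------------------------------------------
# phenomenological templates

def trehalose_template(t, baseline: float = 8.0,
                       amp1: float = 14.0, width1: float = 16.0,
                       amp2: float = 10.0, width2: float = 24.0):
    """Two-bump intracellular trehalose course (mM), peaks at 45 and 180 min.

    Sum of two well-separated Gaussian bumps on a constant baseline; the
    noise-free curve has local maxima exactly at t = 45 and t = 180 min.
    """
    t = np.asarray(t, dtype=float)
    return (baseline
            + amp1 * np.exp(-0.5 * ((t - 45.0) / width1) ** 2)
            + amp2 * np.exp(-0.5 * ((t - 180.0) / width2) ** 2))


def _wt_templates() -> dict[str, callable]:
    """Closed-form wild-type curves for all 14 measured variables."""
    def hog1pp(t):
        # fast single pulse, peak before 15 min, small basal
        tau = 8.0
        return 0.02 + np.where(t > 0, (t / tau) * np.exp(1.0 - t / tau), 0.0)

    def glyi(t):
        # transient accumulation peaking between 30 and 60 min
        tp = 45.0
        bump = (t / tp) ** 2 * np.exp(2.0 * (1.0 - t / tp))
        return 15.0 + 700.0 * bump + 280.0 * (1 - np.exp(-t / 60.0))

    def gpd1(t):
        return 0.5 + 4.0 * (t / 60.0) ** 2 / (1.0 + (t / 60.0) ** 2)

    def mgpd1(t):
        tau = 18.0
        return 0.4 + 7.0 * np.where(t > 0, (t / tau) * np.exp(1 - t / tau), 0)

    def mstl1(t):
        tau = 14.0
        return 0.6 + 9.0 * np.where(t > 0, (t / tau) * np.exp(1 - t / tau), 0)

    def cd(t):
        # growth with a transient stress-induced slowdown
        mu0 = 0.0077
        arrest = 0.9 * 45.0 * (1.0 - np.exp(-t / 45.0))
        return 1.0e7 * np.exp(mu0 * (t - arrest))

    return {
        "Hog1PP": hog1pp,
        "Gpd1tot": gpd1,
        "mGPD1": mgpd1,
        "mSTL1": mstl1,
        "Glci": lambda t: 1.5 + 0.4 * np.exp(-((t - 10) / 25.0) ** 2),
        "Glyi": glyi,
        "EtOHi": lambda t: 7.0 + 0.04 * t,
        "Trei": trehalose_template,
        "Glce": lambda t: 111.0 * np.exp(-t / 900.0),
        "Glye": lambda t: 0.2 + 0.008 * t,
        "EtOHe": lambda t: 5.0 + 0.10 * t,
        "AcOe": lambda t: 0.5 + 0.006 * t,
        "Tree": lambda t: 0.02 + 0.0004 * t,
        "CD": cd,
    }


def generate_phenomenological(noise: NoiseSpec | None = None,
                              schedule: dict | list | None = None
                              ) -> pd.DataFrame:
    """Wild-type template measurement table (no model simulation involved)."""
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    templates = _wt_templates()
    if schedule is None:
        sched = {v: (PROTEIN_SCHEDULE if v in _PROTEIN_VARIABLES
                     else METABOLITE_SCHEDULE) for v in MEASURED_VARIABLES}
    elif isinstance(schedule, dict):
        sched = dict(schedule)
    else:
        sched = {v: tuple(schedule) for v in MEASURED_VARIABLES}

    frames = []
    for variable, times in sched.items():
        tarr = np.asarray(times, dtype=float)
        clean = np.asarray(templates[variable](tarr), dtype=float)
        for rep in range(1, noise.n_rep + 1):
            noisy = _apply_noise(clean, variable, noise, rng)
            frames.append(_rows("WT", variable, tarr, rep, noisy, "template"))
    df = pd.concat(frames, ignore_index=True)
    validate_table(df)
    return df
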