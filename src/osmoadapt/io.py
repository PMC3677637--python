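"""Tabular/config IO and run manifests.

CSV (UTF-8, '.' decimal, comma separator) is the single tabular dialect.
Measurement tables follow the schema defined in synth.TABLE_COLUMNS; the
reader validates types, signs and key uniqueness and reports offending
line numbers (1-based, header included, as an editor shows them).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import MEASURED_VARIABLES, Medium, ModelParameters
from .synth import TABLE_COLUMNS, NoiseSpec

__all__ = [
    "MeasurementTableError", "read_timecourse_csv", "write_timecourse_csv",
    "RunConfig", "write_manifest",
]


class MeasurementTableError(ValueError):
    pass


def _lineno(row_index: int) -> int:
    # pandas row 0 sits on file line 2 (line 1 is the header)
    return int(row_index) + 2


def read_timecourse_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy measurement table.

    Raises MeasurementTableError naming file line numbers for malformed
    rows, negative values, unknown variables and duplicate keys.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise MeasurementTableError(
            f"{path.name}: missing columns {sorted(missing)}")

    problems: list[str] = []
    for col in ("time_min", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            problems.append(f"line {_lineno(i)}: non-numeric {col} "
                            f"({df.loc[i, col]!r})")
        df[col] = coerced
    nan_rows = df.index[df[["strain", "variable", "time_min", "value"]]
                        .isna().any(axis=1)]
    for i in nan_rows:
        problems.append(f"line {_lineno(i)}: incomplete record")
    if problems:
        raise MeasurementTableError(
            f"{path.name}: malformed rows:\n  " + "\n  ".join(problems))

    neg = df.index[df["value"] < 0]
    if len(neg):
        raise MeasurementTableError(
            f"{path.name}: negative values at lines "
            f"{[_lineno(i) for i in neg]}")
    unknown = sorted(set(df["variable"]) - set(MEASURED_VARIABLES))
    if unknown:
        lines = [_lineno(i) for i in
                 df.index[df["variable"].isin(unknown)][:5]]
        raise MeasurementTableError(
            f"{path.name}: unknown variable(s) {unknown} "
            f"(first lines {lines})")
    key = ["strain", "variable", "time_min", "replicate"]
    dup_mask = df.duplicated(subset=key, keep=False)
    if dup_mask.any():
        groups = df[dup_mask].groupby(key).groups
        pairs = [f"{k}: lines {[_lineno(i) for i in v]}"
                 for k, v in list(groups.items())[:5]]
        raise MeasurementTableError(
            f"{path.name}: duplicate (strain, variable, time, replicate) "
            f"records:\n  " + "\n  ".join(pairs))
    return df


def write_timecourse_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=list(TABLE_COLUMNS))


# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON serializable)."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    medium: Medium = field(default_factory=Medium)
    strains: tuple[str, ...] = ("WT",)
    nacl_step: float = 0.4
    t_stress: float = 0.0
    t_end: float = 180.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    outdir: Path = Path(".")
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "medium": self.medium.to_dict(),
            "strains": list(self.strains),
            "nacl_step": self.nacl_step,
            "t_stress": self.t_stress,
            "t_end": self.t_end,
            "noise": {"sigma_rel": self.noise.sigma_rel,
                      "sigma_abs": dict(self.noise.sigma_abs),
                      "n_rep": self.noise.n_rep,
                      "seed": self.noise.seed},
            "seed": self.seed,
            "outdir": str(self.outdir),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "parameters" in kwargs:
            kwargs["parameters"] = ModelParameters(**kwargs["parameters"])
        if "medium" in kwargs:
            kwargs["medium"] = Medium(**kwargs["medium"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseSpec(
                sigma_rel=kwargs["noise"].get("sigma_rel", 0.15),
                sigma_abs=kwargs["noise"].get("sigma_abs", {}),
                n_rep=kwargs["noise"].get("n_rep", 3),
                seed=kwargs["noise"].get("seed", 0))
        if "strains" in kwargs:
            kwargs["strains"] = tuple(kwargs["strains"])
        if "outdir" in kwargs:
            kwargs["outdir"] = Path(kwargs["outdir"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)


def write_manifest(outdir: str | Path, config: RunConfig,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "osmoadapt": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest["extra"] = extra
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
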