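"""Strain variants: derive mutant models from the shared wild-type parameters.

Every mutant is expressed as parameter edits (and, for the constitutively
open Fps1 allele, a pinned state) applied to the one shared parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParameters, PARAM_NAMES, SIDX, N_STATES

__all__ = ["StrainSpec", "STRAINS", "strain_spec", "apply_strain"]

#: default gain on Hog1->Fps1 closure for the membrane-tethered Hog1 allele
ATT_GAIN_DEFAULT = 2.0


@dataclass(frozen=True)
class StrainSpec:
    """A named genetic background.

    edits map parameter names to override values (absolute, not fold);
    scale maps parameter names to multiplicative factors applied to the
    wild-type value; pinned_states holds states frozen at a fixed value.
    """

    name: str
    edits: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    pinned_states: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in list(self.edits) + list(self.scale):
            if key not in PARAM_NAMES:
                raise KeyError(
                    f"strain {self.name!r} edits unknown parameter {key!r}")
        for key in self.pinned_states:
            if key not in SIDX:
                raise KeyError(
                    f"strain {self.name!r} pins unknown state {key!r}")

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name, "edits": self.edits, "scale": self.scale,
            "pinned_states": self.pinned_states,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str | Path) -> "StrainSpec":
        if isinstance(text, Path):
            text = text.read_text()
        d = json.loads(text)
        return cls(name=d["name"], edits=d.get("edits", {}),
                   scale=d.get("scale", {}),
                   pinned_states=d.get("pinned_states", {}))


def _builtin_strains(att_gain: float = ATT_GAIN_DEFAULT
                     ) -> dict[str, StrainSpec]:
    ref = ModelParameters()
    return {
        "WT": StrainSpec("WT"),
        # no Hog1 at all: phosphorylation pool empty
        "hog1D": StrainSpec("hog1D", edits={"Hog1tot": 0.0}),
        # no GPD1 transcription -> no Gpd1 mRNA/protein
        "gpd1D": StrainSpec("gpd1D",
                            edits={"k_b1": 0.0, "k_h1": 0.0, "k_o1": 0.0}),
        # single deletions keep half the Pfk26/27 pool (absolute edits so
        # that apply_strain stays idempotent)
        "pfk26D": StrainSpec("pfk26D", edits={"PfkT": 0.5 * ref.PfkT}),
        "pfk27D": StrainSpec("pfk27D", edits={"PfkT": 0.5 * ref.PfkT}),
        "pfk26/27D": StrainSpec("pfk26/27D", edits={"PfkT": 0.0}),
        # membrane-tethered Hog1: no transcriptional output, enhanced
        # membrane-proximal closure of Fps1, Pfk26/27 activation retained
        "HOG1-att": StrainSpec("HOG1-att",
                               edits={"k_h1": 0.0, "k_s1": 0.0,
                                      "k_cH": att_gain * ref.k_cH}),
        # constitutively open Fps1
        "FPS1-D1": StrainSpec("FPS1-D1",
                              edits={"k_cT": 0.0, "k_cH": 0.0},
                              pinned_states={"Fps1o": 1.0}),
        "stl1D": StrainSpec("stl1D", edits={"VmSTL": 0.0}),
        # in-silico double mutant used for the Stl1 context analysis
        "gpd1D stl1D": StrainSpec(
            "gpd1D stl1D",
            edits={"k_b1": 0.0, "k_h1": 0.0, "k_o1": 0.0, "VmSTL": 0.0}),
    }


STRAINS: dict[str, StrainSpec] = _builtin_strains()

#: unicode aliases accepted by strain_spec
_ALIASES = {
    "hog1Δ": "hog1D", "gpd1Δ": "gpd1D",
    "pfk26Δ": "pfk26D", "pfk27Δ": "pfk27D",
    "pfk26/27Δ": "pfk26/27D", "stl1Δ": "stl1D",
    "FPS1-Δ1": "FPS1-D1",
    "gpd1Δ stl1Δ": "gpd1D stl1D",
}


def strain_spec(name: str) -> StrainSpec:
    """Look up a built-in strain by name (ASCII or unicode-delta spelling)."""
    key = _ALIASES.get(name, name)
    if key not in STRAINS:
        raise KeyError(
            f"unknown strain {name!r}; known: {sorted(STRAINS)}")
    return STRAINS[key]


def apply_strain(params: ModelParameters,
                 spec: StrainSpec | str
                 ) -> tuple[ModelParameters, dict[str, float]]:
    """Return the edited parameter copy and the pinned-state map.

    The input parameter set is never mutated (ModelParameters is frozen) and
    the operation is idempotent for the built-in strains: edits assign
    absolute values, and scale factors only touch parameters no other edit
    produces.
    """
    if isinstance(spec, str):
        spec = strain_spec(spec)
    edits = dict(spec.edits)
    for key, factor in spec.scale.items():
        edits[key] = getattr(params, key) * factor
    return params.replace(**edits) if edits else params, dict(spec.pinned_states)


def pinmask_and_state(pins: dict[str, float],
                      x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply pinned states to an initial condition; return (pinmask, x0')."""
    mask = np.ones(N_STATES)
    x = np.array(x0, dtype=float)
    for name, value in pins.items():
        mask[SIDX[name]] = 0.0
        x[SIDX[name]] = value
    return mask, x
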