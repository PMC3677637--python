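"""SBML Level 3 Version 1 export of the strain models.

The exporter writes one document per strain variant. Chemical pools are
species (intracellular amounts in the ``cell`` compartment, external
concentrations in ``medium``); the osmotic volume, the open-Fps1 fraction
and the cell density are non-constant parameters. All dynamics are encoded
as rate rules whose MathML is printed from the symbolic model layer, so the
exported equations are exactly the ones the simulator integrates (species
additionally carry boundaryCondition="true" and the mass-carrying reaction
topology is listed with kinetic laws for annotation). The NaCl step is an
event triggered at the stress time.

Import of third-party SBML is out of scope. Structural self-validation
(well-formedness, id uniqueness, required attributes) replaces schema
validation, which would require an external validator.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

import sympy as sp
from sympy.printing.mathml import MathMLContentPrinter

from .model import STOICHIOMETRY
from .params import Medium, ModelParameters, SIDX, STATE_NAMES
from .simulate import StressProtocol, presstress_equilibrate
from .strains import StrainSpec, apply_strain, strain_spec
from .symbolic import symbolic_fluxes, symbolic_rhs

__all__ = ["export_sbml", "validate_sbml_structure", "SbmlExportError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"

#: states exported as parameters with rate rules rather than species
_PARAMETER_STATES = ("Vos", "Fps1o", "CD")
_EXTERNAL_STATES = ("Glce", "Glye", "EtOHe", "AcOe", "Tree", "NaCle")


class SbmlExportError(RuntimeError):
    pass


class _PlainContentPrinter(MathMLContentPrinter):
    """Content printer emitting symbol names verbatim in <ci> elements."""

    def _print_Symbol(self, sym):  # noqa: N802 (sympy API)
        ci = self.dom.createElement("ci")
        ci.appendChild(self.dom.createTextNode(sym.name))
        return ci


def _mathml(expr: sp.Expr) -> ET.Element:
    """Content-MathML <math> element for a sympy expression."""
    body = _PlainContentPrinter().doprint(expr)
    xml = f'<math xmlns="{MATHML_NS}">{body}</math>'
    try:
        return ET.fromstring(xml)
    except ET.ParseError as exc:  # pragma: no cover
        raise SbmlExportError(f"MathML serialization failed: {exc}") from exc


def _sanitize(name: str) -> str:
    return (name.replace("/", "_").replace("-", "_")
            .replace("Δ", "D").replace(" ", "_"))


def export_sbml(params: ModelParameters,
                spec: StrainSpec | str = "WT",
                protocol: StressProtocol | None = None,
                medium: Medium | None = None) -> str:
    """Serialize one strain model as an SBML L3V1 document (XML string).

    Initial values come from the strain's pre-stress fixed point; the
    stress event adds protocol.NaCl_step to NaCle at protocol.t_stress.
    Output is byte-stable for identical inputs.
    """
    protocol = protocol or StressProtocol()
    medium = medium or protocol.medium
    if isinstance(spec, str):
        spec = strain_spec(spec)
    sparams, pins = apply_strain(params, spec)
    x0 = presstress_equilibrate(sparams, medium, pins=pins)
    for name, value in pins.items():
        x0[SIDX[name]] = value

    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", level="3", version="1")
    model = ET.SubElement(sbml, "model",
                          id=f"osmoadaptation_{_sanitize(spec.name)}",
                          name=f"Osmoadaptation model ({spec.name})",
                          timeUnits="minute", substanceUnits="item")

    notes = ET.SubElement(model, "notes")
    body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
    p = ET.SubElement(body, "{http://www.w3.org/1999/xhtml}p")
    p.text = (f"Yeast hyperosmotic-stress adaptation model, strain "
              f"{spec.name}. Amounts in amol/cell, volumes in fL, external "
              f"concentrations in mM, NaCl in M, time in min. Dynamics are "
              f"given by rate rules; the reaction list documents the "
              f"mass-carrying topology.")

    comps = ET.SubElement(model, "listOfCompartments")
    ET.SubElement(comps, "compartment", id="cell", constant="false",
                  spatialDimensions="3", size=repr(sparams.Vb + sparams.Vos0))
    ET.SubElement(comps, "compartment", id="medium", constant="true",
                  spatialDimensions="3", size="1.0")

    species = ET.SubElement(model, "listOfSpecies")
    for name in STATE_NAMES:
        if name in _PARAMETER_STATES:
            continue
        comp = "medium" if name in _EXTERNAL_STATES else "cell"
        ET.SubElement(
            species, "species", id=name, compartment=comp,
            initialAmount=repr(float(x0[SIDX[name]])),
            hasOnlySubstanceUnits="true", boundaryCondition="true",
            constant="false")

    plist = ET.SubElement(model, "listOfParameters")
    for name, value in sparams.to_dict().items():
        ET.SubElement(plist, "parameter", id=name, value=repr(value),
                      constant="true")
    for name in _PARAMETER_STATES:
        ET.SubElement(plist, "parameter", id=name,
                      value=repr(float(x0[SIDX[name]])), constant="false")
    ET.SubElement(plist, "parameter", id="NaCl_step",
                  value=repr(protocol.NaCl_step), constant="true")

    rules = ET.SubElement(model, "listOfRules")
    rhs = symbolic_rhs()
    # strain-pinned states are frozen (rate 0)
    for name in STATE_NAMES:
        expr = sp.Integer(0) if name in pins else rhs[name]
        rule = ET.SubElement(rules, "rateRule", variable=name)
        rule.append(_mathml(expr))

    reactions = ET.SubElement(model, "listOfReactions")
    fluxes = symbolic_fluxes()
    for rxn, stoich in STOICHIOMETRY.items():
        r = ET.SubElement(reactions, "reaction", id=rxn, reversible="true")
        reac = ET.SubElement(r, "listOfReactants")
        prod = ET.SubElement(r, "listOfProducts")
        for sp_name, coeff in sorted(stoich.items()):
            if sp_name in ("CO2", "BIOMASS"):
                continue  # virtual sinks, not model species
            target = reac if coeff < 0 else prod
            ET.SubElement(target, "speciesReference", species=sp_name,
                          stoichiometry=repr(float(abs(coeff))),
                          constant="true")
        kl = ET.SubElement(r, "kineticLaw")
        kl.append(_mathml(fluxes[rxn]))

    events = ET.SubElement(model, "listOfEvents")
    ev = ET.SubElement(events, "event", id="nacl_step",
                       useValuesFromTriggerTime="true")
    trig = ET.SubElement(ev, "trigger", initialValue="false",
                         persistent="true")
    trig.append(ET.fromstring(
        f'<math xmlns="{MATHML_NS}"><apply><geq/>'
        f'<csymbol encoding="text" definitionURL="{TIME_CSYMBOL}">'
        f'time</csymbol><cn>{protocol.t_stress}</cn></apply></math>'))
    eas = ET.SubElement(ev, "listOfEventAssignments")
    ea = ET.SubElement(eas, "eventAssignment", variable="NaCle")
    ea.append(ET.fromstring(
        f'<math xmlns="{MATHML_NS}"><apply><plus/><ci>NaCle</ci>'
        f'<ci>NaCl_step</ci></apply></math>'))

    raw = ET.tostring(sbml, encoding="unicode")
    pretty = minidom.parseString(raw).toprettyxml(indent="  ")
    doc = "\n".join(line for line in pretty.splitlines() if line.strip())
    validate_sbml_structure(doc)
    return doc


def validate_sbml_structure(document: str) -> None:
    """Structural self-validation of an exported document.

    Checks well-formedness, the SBML L3V1 namespace, id uniqueness across
    compartments/species/parameters, presence of required attributes, and
    that every rate-rule variable and event-assignment target exists.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise SbmlExportError(f"document is not well-formed XML: {exc}")
    if root.tag != f"{{{SBML_NS}}}sbml":
        raise SbmlExportError(f"unexpected root element {root.tag}")
    if root.get("level") != "3" or root.get("version") != "1":
        raise SbmlExportError("document is not SBML Level 3 Version 1")
    ns = {"s": SBML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise SbmlExportError("missing <model>")
    ids: list[str] = []
    for tag in ("s:listOfCompartments/s:compartment",
                "s:listOfSpecies/s:species",
                "s:listOfParameters/s:parameter"):
        for el in model.findall(tag, ns):
            if el.get("id") is None:
                raise SbmlExportError(f"element {el.tag} lacks an id")
            if el.get("constant") is None:
                raise SbmlExportError(f"{el.get('id')}: missing 'constant'")
            ids.append(el.get("id"))
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SbmlExportError(f"duplicate ids: {dup}")
    defined = set(ids)
    for rule in model.findall("s:listOfRules/s:rateRule", ns):
        var = rule.get("variable")
        if var not in defined:
            raise SbmlExportError(f"rate rule targets unknown id {var!r}")
        if rule.find(f"{{{MATHML_NS}}}math") is None:
            raise SbmlExportError(f"rate rule for {var} lacks MathML")
    for ea in model.findall(
            "s:listOfEvents/s:event/s:listOfEventAssignments/"
            "s:eventAssignment", ns):
        if ea.get("variable") not in defined:
            raise SbmlExportError(
                f"event assignment targets unknown id {ea.get('variable')!r}")
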