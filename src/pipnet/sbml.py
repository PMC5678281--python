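"""SBML import/export of the model (subset of SBML Level 3 core).

The writer emits species, global activity parameters, reactions with
local kinetic parameters and explicit MathML kinetic laws matching the
package's rate semantics (enzyme-activity multipliers are exported as
global parameters referenced from each kinetic law, never baked into the
rate constants).  The reader accepts Level 2 and Level 3 documents,
matching species through a documented, editable alias table; entities it
cannot map are reported, never silently dropped.

Rate-law structure is recovered from the local parameter names
(``k`` mass action, ``vmax``/``km`` Michaelis-Menten, ``v`` zeroth order)
with a package annotation carrying the enzyme label and inhibitor
sensitivity; documents written by other tools fall back to a reaction-id
lookup and a mass-action default.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

from lxml import etree

from .model import (
    CONSTANT_SPECIES,
    Enzyme,
    ModelSpec,
    RateLaw,
    ReactionSpec,
    Species,
)

__all__ = ["read_sbml", "write_sbml", "evaluate_mathml", "SPECIES_ALIASES",
           "SbmlError"]

_SBML_L3 = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML = "http://www.w3.org/1998/Math/MathML"
_ANN = "urn:pipnet:sbml-annotation"

#: Data-driven identifier mapping: lowercase alias -> internal species.
#: Extend this table to import models whose species use other names.
SPECIES_ALIASES: dict[str, Species] = {
    **{sp.value.lower(): sp for sp in Species},
    "pi(3,4,5)p3": Species.PIP3,
    "pi345p3": Species.PIP3,
    "pip3": Species.PIP3,
    "pi(4,5)p2": Species.PI45P2,
    "pi45p2": Species.PI45P2,
    "pip2": Species.PI45P2,
    "pi(3,4)p2": Species.PI34P2,
    "pi34p2": Species.PI34P2,
    "pi(3,4)p2_bg": Species.PI34P2_BG,
    "pi34p2bg": Species.PI34P2_BG,
    "pi3p": Species.PI3P,
    "pi4p": Species.PI4P,
    "egf": Species.EGF,
    "egfr": Species.EGFR_INACTIVE,
    "egfr_a": Species.EGFR_ACTIVE,
    "pi3k": Species.PI3K_INACTIVE,
    "pi3k_a": Species.PI3K_ACTIVE,
}

#: Fallback enzyme assignment for documents without package annotations.
_REACTION_ENZYME_FALLBACK: dict[str, Enzyme] = {
    "pi3k_pip3_synthesis": Enzyme.PI3K,
    "pten_pip3": Enzyme.PTEN,
    "ship2_pip3": Enzyme.SHIP2,
    "x_pip3": Enzyme.X,
    "inpp4b_pi34p2": Enzyme.INPP4B,
    "pten_pi34p2": Enzyme.PTEN,
    "y_pi34p2": Enzyme.Y,
}


class SbmlError(ValueError):
    """Unparsable or unmappable SBML content."""


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


# -- writing ----------------------------------------------------------------

def _math_ci(parent: etree._Element, name: str) -> None:
    ci = etree.SubElement(parent, _q(_MATHML, "ci"))
    ci.text = f" {name} "


def _kinetic_math(rx: ReactionSpec) -> etree._Element:
    """MathML for one reaction's rate, referencing the activity parameter."""
    math = etree.Element(_q(_MATHML, "math"))
    law = rx.rate_law
    factors: list[str] = [f"activity_{rx.enzyme.value}"]
    if law.kind == "mass_action":
        factors = ["k"] + factors
    elif law.kind == "zeroth_order":
        factors = ["v"] + factors
    if rx.substrate is not None and law.kind != "zeroth_order":
        factors.append(rx.substrate.value)
    if rx.activator is not None:
        factors.append(rx.activator.value)

    if law.kind == "michaelis_menten":
        div = etree.SubElement(math, _q(_MATHML, "apply"))
        etree.SubElement(div, _q(_MATHML, "divide"))
        num = etree.SubElement(div, _q(_MATHML, "apply"))
        etree.SubElement(num, _q(_MATHML, "times"))
        for f in ["vmax"] + factors:
            _math_ci(num, f)
        den = etree.SubElement(div, _q(_MATHML, "apply"))
        etree.SubElement(den, _q(_MATHML, "plus"))
        _math_ci(den, "km")
        _math_ci(den, rx.substrate.value)
    else:
        mul = etree.SubElement(math, _q(_MATHML, "apply"))
        etree.SubElement(mul, _q(_MATHML, "times"))
        for f in factors:
            _math_ci(mul, f)
    return math


def write_sbml(model: ModelSpec, path: str) -> None:
    """Serialize the model to an SBML Level 3 file."""
    nsmap = {None: _SBML_L3, "math": _MATHML, "pipnet": _ANN}
    sbml = etree.Element(_q(_SBML_L3, "sbml"), nsmap=nsmap,
                         attrib={"level": "3", "version": "2"})
    mdl = etree.SubElement(sbml, _q(_SBML_L3, "model"),
                           attrib={"id": "pipnet_model",
                                   "name": model.provenance})
    ann = etree.SubElement(mdl, _q(_SBML_L3, "annotation"))
    meta = etree.SubElement(ann, _q(_ANN, "meta"))
    meta.set("egf_dose", repr(float(model.egf_dose)))
    meta.set("pi34p2_background", repr(float(model.pi34p2_background)))
    meta.set("provenance", model.provenance)

    comps = etree.SubElement(mdl, _q(_SBML_L3, "listOfCompartments"))
    etree.SubElement(comps, _q(_SBML_L3, "compartment"),
                     attrib={"id": "cell", "size": "1", "constant": "true",
                             "spatialDimensions": "3"})

    sps = etree.SubElement(mdl, _q(_SBML_L3, "listOfSpecies"))
    for sp in Species:
        etree.SubElement(sps, _q(_SBML_L3, "species"), attrib={
            "id": sp.value,
            "compartment": "cell",
            "initialConcentration": repr(float(model.initial_state.get(sp, 0.0))),
            "constant": "true" if sp in CONSTANT_SPECIES else "false",
            "boundaryCondition": "true" if sp in CONSTANT_SPECIES else "false",
            "hasOnlySubstanceUnits": "false",
        })

    pars = etree.SubElement(mdl, _q(_SBML_L3, "listOfParameters"))
    for enzyme in Enzyme:
        etree.SubElement(pars, _q(_SBML_L3, "parameter"), attrib={
            "id": f"activity_{enzyme.value}",
            "value": repr(float(model.activity(enzyme))),
            "constant": "true",
        })

    rxs = etree.SubElement(mdl, _q(_SBML_L3, "listOfReactions"))
    for rx in model.reactions:
        el = etree.SubElement(rxs, _q(_SBML_L3, "reaction"),
                              attrib={"id": rx.id, "reversible": "false"})
        rann = etree.SubElement(el, _q(_SBML_L3, "annotation"))
        rmeta = etree.SubElement(rann, _q(_ANN, "reaction"))
        rmeta.set("enzyme", rx.enzyme.value)
        rmeta.set("pi3k_effective", "true" if rx.pi3k_effective else "false")
        rmeta.set("kind", rx.rate_law.kind)
        if rx.substrate is not None:
            lst = etree.SubElement(el, _q(_SBML_L3, "listOfReactants"))
            etree.SubElement(lst, _q(_SBML_L3, "speciesReference"), attrib={
                "species": rx.substrate.value, "stoichiometry": "1",
                "constant": "true"})
        if rx.product is not None:
            lst = etree.SubElement(el, _q(_SBML_L3, "listOfProducts"))
            etree.SubElement(lst, _q(_SBML_L3, "speciesReference"), attrib={
                "species": rx.product.value, "stoichiometry": "1",
                "constant": "true"})
        if rx.activator is not None:
            lst = etree.SubElement(el, _q(_SBML_L3, "listOfModifiers"))
            etree.SubElement(lst, _q(_SBML_L3, "modifierSpeciesReference"),
                             attrib={"species": rx.activator.value})
        kl = etree.SubElement(el, _q(_SBML_L3, "kineticLaw"))
        kl.append(_kinetic_math(rx))
        lps = etree.SubElement(kl, _q(_SBML_L3, "listOfLocalParameters"))
        law = rx.rate_law
        if law.kind == "mass_action":
            locals_ = {"k": law.k}
        elif law.kind == "michaelis_menten":
            locals_ = {"vmax": law.vmax, "km": law.km}
        else:
            locals_ = {"v": law.v}
        for name, value in locals_.items():
            etree.SubElement(lps, _q(_SBML_L3, "localParameter"),
                             attrib={"id": name, "value": repr(float(value))})

    etree.ElementTree(sbml).write(path, pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


# -- reading ----------------------------------------------------------------

def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _find_all(parent: etree._Element, name: str) -> list[etree._Element]:
    """Matching elements by local name, excluding package annotations."""
    return [
        el for el in parent.iter()
        if _local(el.tag) == name
        and not (isinstance(el.tag, str) and el.tag.startswith(f"{{{_ANN}}}"))
    ]


def _map_species(sbml_id: str) -> Optional[Species]:
    return SPECIES_ALIASES.get(sbml_id.strip().lower())


def read_sbml(path: str) -> ModelSpec:
    """Parse an SBML L2/L3 file into a ModelSpec.

    Species are matched by the alias table; an unmapped species that
    participates in a reaction raises ``SbmlError`` listing the internal
    candidates, and unmapped bystanders produce a warning.
    """
    try:
        tree = etree.parse(path)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SbmlError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlError(f"{path} is not an SBML document (root {root.tag!r})")

    species_map: dict[str, Species] = {}
    unmapped: list[str] = []
    initial: dict[Species, float] = {sp: 0.0 for sp in Species}
    for el in _find_all(root, "species"):
        sid = el.get("id", "")
        sp = _map_species(sid)
        if sp is None:
            unmapped.append(sid)
            continue
        species_map[sid] = sp
        conc = el.get("initialConcentration", el.get("initialAmount", "0"))
        initial[sp] = float(conc)

    activities: dict[Enzyme, float] = {}
    egf_dose, background = 1.0, initial.get(Species.PI34P2_BG, 0.0)
    for el in _find_all(root, "parameter"):
        pid = el.get("id", "")
        if pid.startswith("activity_"):
            label = pid[len("activity_"):]
            try:
                activities[Enzyme(label)] = float(el.get("value", "1"))
            except ValueError:
                warnings.warn(f"unknown activity parameter {pid!r} ignored")
        elif pid == "egf_dose":
            egf_dose = float(el.get("value", "1"))

    for meta in _find_all(root, "meta"):
        if meta.get("egf_dose") is not None:
            egf_dose = float(meta.get("egf_dose"))
        if meta.get("pi34p2_background") is not None:
            background = float(meta.get("pi34p2_background"))
    provenance = "sbml-import"
    for el in _find_all(root, "model"):
        provenance = el.get("name") or provenance
        break

    def species_ref(rx_el: etree._Element, list_name: str) -> Optional[Species]:
        for lst in rx_el:
            if _local(lst.tag) != list_name:
                continue
            for ref in lst:
                sid = ref.get("species")
                if sid is None:
                    continue
                if sid in species_map:
                    return species_map[sid]
                raise SbmlError(
                    f"reaction {rx_el.get('id')!r} references unmapped species "
                    f"{sid!r}; add it to SPECIES_ALIASES (candidates: "
                    f"{sorted(s.value for s in Species)})"
                )
        return None

    reactions: list[ReactionSpec] = []
    for el in _find_all(root, "reaction"):
        rid = el.get("id", f"reaction_{len(reactions)}")
        substrate = species_ref(el, "listOfReactants")
        product = species_ref(el, "listOfProducts")
        activator = species_ref(el, "listOfModifiers")

        local_params: dict[str, float] = {}
        for lp in _find_all(el, "localParameter") + _find_all(el, "parameter"):
            local_params[lp.get("id", "")] = float(lp.get("value", "0"))

        kind = None
        enzyme = _REACTION_ENZYME_FALLBACK.get(rid)
        pi3k_eff = False
        for rmeta in el.iter(_q(_ANN, "reaction")):
            kind = rmeta.get("kind")
            pi3k_eff = rmeta.get("pi3k_effective") == "true"
            try:
                enzyme = Enzyme(rmeta.get("enzyme", ""))
            except ValueError:
                pass
        if kind is None:  # infer from local parameter names
            if {"vmax", "km"} <= set(local_params):
                kind = "michaelis_menten"
            elif "v" in local_params and "k" not in local_params:
                kind = "zeroth_order"
            else:
                kind = "mass_action"
        if enzyme is None:
            warnings.warn(f"reaction {rid!r}: no enzyme label, assuming basal")
            enzyme = Enzyme.BASAL

        if kind == "mass_action":
            law = RateLaw("mass_action", k=local_params.get("k", 0.0))
        elif kind == "michaelis_menten":
            law = RateLaw("michaelis_menten", vmax=local_params.get("vmax", 0.0),
                          km=local_params.get("km", 1.0))
        else:
            law = RateLaw("zeroth_order", v=local_params.get("v", 0.0))
        reactions.append(ReactionSpec(rid, substrate, product, enzyme, law,
                                      activator=activator,
                                      pi3k_effective=pi3k_eff))

    required_missing = [sp for sp in (Species.PI45P2, Species.PIP3, Species.PI34P2)
                        if sp not in species_map.values()]
    if required_missing:
        raise SbmlError(
            "SBML model lacks species mappable to "
            + ", ".join(sp.value for sp in required_missing)
            + f"; unmapped ids were {unmapped!r}"
        )
    if unmapped:
        warnings.warn(f"unmapped SBML species ignored: {unmapped}")

    return ModelSpec(
        reactions=tuple(reactions),
        initial_state=initial,
        enzyme_activities={e: activities.get(e, 1.0) for e in Enzyme},
        egf_dose=egf_dose,
        pi34p2_background=background,
        provenance=provenance,
    )


# -- MathML evaluation (for cross-checking kinetic laws) --------------------

def evaluate_mathml(elem: etree._Element, env: Mapping[str, float]) -> float:
    """Evaluate a MathML expression tree against a symbol environment."""
    tag = _local(elem.tag)
    if tag == "math":
        children = list(elem)
        if len(children) != 1:
            raise ValueError("math element must have one child")
        return evaluate_mathml(children[0], env)
    if tag == "ci":
        name = (elem.text or "").strip()
        if name not in env:
            raise KeyError(f"unbound symbol {name!r} in kinetic law")
        return float(env[name])
    if tag == "cn":
        return float((elem.text or "0").strip())
    if tag == "apply":
        children = list(elem)
        op = _local(children[0].tag)
        args = [evaluate_mathml(c, env) for c in children[1:]]
        if op == "times":
            out = 1.0
            for a in args:
                out *= a
            return out
        if op == "plus":
            return sum(args)
        if op == "divide":
            return args[0] / args[1]
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")
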