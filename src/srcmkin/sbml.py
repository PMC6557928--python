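"""SBML Level 3 Version 1 interchange for the MM/GMA kinetic-law subset.

The writer emits compartments, species (with ``boundaryCondition`` flags),
reactions with MathML kinetic laws and local parameters, and unit
definitions in the package's mmol/ml/min system; metabolite charges and
transporter classes travel in a package annotation namespace.  The reader
accepts documents whose kinetic laws match the canonical Michaelis–Menten or
generalized-mass-action shapes and rejects anything else with a precise
message.
"""

from __future__ import annotations

from lxml import etree

from .errors import SbmlError, UnsupportedConstructError
from .network import (
    Compartment,
    KineticModel,
    RateLaw,
    RateLawKind,
    Reaction,
    Species,
    validate_model,
)

__all__ = ["export_sbml", "import_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://srcmkin.invalid/annotations"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS
_A = "{%s}" % ANNOT_NS


def _math(tag: str, *children, text: str | None = None) -> etree._Element:
    el = etree.Element(_M + tag)
    if text is not None:
        el.text = text
    for c in children:
        el.append(c)
    return el


def _ci(name: str) -> etree._Element:
    return _math("ci", text=" %s " % name)


def _cn(value: float) -> etree._Element:
    return _math("cn", text=" %r " % float(value))


def _apply(op: str, *args) -> etree._Element:
    return _math("apply", _math(op), *args)


def _mm_math(rxn: Reaction) -> etree._Element:
    law = rxn.rate_law
    factors = [_ci(f"vmax_{rxn.id}")]
    for sid in law.km:
        factors.append(
            _apply("divide", _ci(sid), _apply("plus", _ci(f"km_{rxn.id}_{sid}"), _ci(sid)))
        )
    for sid in law.modifiers:
        factors.append(_apply("divide", _ci(sid), _ci(f"mod0_{rxn.id}_{sid}")))
    return factors[0] if len(factors) == 1 else _apply("times", *factors)


def _gma_term(rxn_id: str, k_name: str, exponents: dict[str, float],
              exp_prefix: str = "g") -> etree._Element:
    factors = [_ci(k_name)]
    for sid in exponents:
        factors.append(_apply("power", _ci(sid), _ci(f"{exp_prefix}_{rxn_id}_{sid}")))
    return factors[0] if len(factors) == 1 else _apply("times", *factors)


def export_sbml(model: KineticModel) -> str:
    """Serialize a validated model to an SBML L3V1 document string."""
    report = validate_model(model)
    if not report.ok:
        raise SbmlError("refusing to export invalid model: " + "; ".join(report))

    nsmap = {None: SBML_NS}
    sbml = etree.Element(_S + "sbml", nsmap=nsmap, level="3", version="1")
    mdl = etree.SubElement(sbml, _S + "model", id=model.metadata.get("name", "model"))

    units = etree.SubElement(mdl, _S + "listOfUnitDefinitions")
    for uid, kinds in {
        "mmol": [("mole", "-3", "1")],
        "ml": [("litre", "-3", "1")],
        "min_u": [("second", "0", "60")],
        "mmol_per_ml": [("mole", "-3", "1"), ("litre", "-3", "-1")],
        "mmol_per_min_per_ml": [("mole", "-3", "1"), ("litre", "-3", "-1"), ("second", "0", "-1")],
    }.items():
        ud = etree.SubElement(units, _S + "unitDefinition", id=uid)
        lo = etree.SubElement(ud, _S + "listOfUnits")
        for kind, scale, exp in kinds:
            mult = "60" if (kind == "second" and uid == "min_u") else "1"
            etree.SubElement(
                lo, _S + "unit", kind=kind, scale=scale,
                exponent=exp if exp != "1" else "1", multiplier=mult,
            )

    comps = etree.SubElement(mdl, _S + "listOfCompartments")
    for c in model.compartments:
        etree.SubElement(
            comps, _S + "compartment", id=c.id, name=c.label or c.id,
            size="1", constant="true", spatialDimensions="3",
        )

    sps = etree.SubElement(mdl, _S + "listOfSpecies")
    for s in model.species:
        el = etree.SubElement(
            sps, _S + "species", id=s.id, name=s.name or s.id, compartment=s.compartment,
            initialConcentration=repr(float(s.initial_concentration)),
            boundaryCondition="true" if s.boundary else "false",
            hasOnlySubstanceUnits="false", constant="false",
            substanceUnits="mmol",
        )
        if s.charge:
            ann = etree.SubElement(el, _S + "annotation")
            etree.SubElement(ann, _A + "charge", nsmap={"srcm": ANNOT_NS}).text = str(s.charge)

    rxns = etree.SubElement(mdl, _S + "listOfReactions")
    for r in model.reactions:
        el = etree.SubElement(
            rxns, _S + "reaction", id=r.id, name=r.name or r.id,
            reversible="true" if r.reversible else "false", fast="false",
        )
        if r.transporter_class or r.ec_number:
            ann = etree.SubElement(el, _S + "annotation")
            info = etree.SubElement(ann, _A + "info", nsmap={"srcm": ANNOT_NS})
            if r.transporter_class:
                info.set("transporterClass", r.transporter_class.value)
            if r.ec_number:
                info.set("ec", r.ec_number)
        reactants = [(s, -c) for s, c in r.stoichiometry.items() if c < 0]
        products = [(s, c) for s, c in r.stoichiometry.items() if c > 0]
        if reactants:
            lo = etree.SubElement(el, _S + "listOfReactants")
            for sid, coef in reactants:
                etree.SubElement(lo, _S + "speciesReference", species=sid,
                                 stoichiometry=repr(float(coef)), constant="true")
        if products:
            lo = etree.SubElement(el, _S + "listOfProducts")
            for sid, coef in products:
                etree.SubElement(lo, _S + "speciesReference", species=sid,
                                 stoichiometry=repr(float(coef)), constant="true")
        if r.rate_law.modifiers:
            lo = etree.SubElement(el, _S + "listOfModifiers")
            for sid in r.rate_law.modifiers:
                etree.SubElement(lo, _S + "modifierSpeciesReference", species=sid)

        kl = etree.SubElement(el, _S + "kineticLaw")
        math_el = etree.SubElement(kl, _M + "math", nsmap={None: MATHML_NS})
        params = etree.SubElement(kl, _S + "listOfLocalParameters")
        law = r.rate_law
        if law.kind is RateLawKind.MICHAELIS_MENTEN:
            math_el.append(_mm_math(r))
            etree.SubElement(params, _S + "localParameter", id=f"vmax_{r.id}",
                             value=repr(float(law.vmax)), units="mmol_per_min_per_ml")
            for sid, km in law.km.items():
                etree.SubElement(params, _S + "localParameter", id=f"km_{r.id}_{sid}",
                                 value=repr(float(km)), units="mmol_per_ml")
            for sid in law.modifiers:
                e0 = model.get_species(sid).initial_concentration
                etree.SubElement(params, _S + "localParameter", id=f"mod0_{r.id}_{sid}",
                                 value=repr(float(e0)), units="mmol_per_ml")
        else:
            fwd = _gma_term(r.id, f"k_{r.id}", law.exponents)
            if r.reversible and law.k_reverse is not None:
                rev = _gma_term(r.id, f"krev_{r.id}", law.exponents_reverse,
                                exp_prefix="grev")
                math_el.append(_apply("minus", fwd, rev))
                etree.SubElement(params, _S + "localParameter", id=f"krev_{r.id}",
                                 value=repr(float(law.k_reverse)), units="mmol_per_min_per_ml")
                for sid, g in law.exponents_reverse.items():
                    etree.SubElement(params, _S + "localParameter",
                                     id=f"grev_{r.id}_{sid}", value=repr(float(g)),
                                     units="dimensionless")
            else:
                math_el.append(fwd)
            etree.SubElement(params, _S + "localParameter", id=f"k_{r.id}",
                             value=repr(float(law.k)), units="mmol_per_min_per_ml")
            for sid, g in law.exponents.items():
                etree.SubElement(params, _S + "localParameter", id=f"g_{r.id}_{sid}",
                                 value=repr(float(g)), units="dimensionless")

    return etree.tostring(sbml, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _strip(el: etree._Element) -> str:
    return etree.QName(el).localname


def _flatten_times(el: etree._Element) -> list[etree._Element]:
    """Children of an <apply><times/>...</apply>, or the element itself."""
    if _strip(el) == "apply":
        children = list(el)
        if children and _strip(children[0]) == "times":
            return children[1:]
    return [el]


def _match_mm_factor(el, species: set[str], params: dict, rid: str):
    """Recognize s/(km+s) saturation factors and modifier ratios m/m0."""
    if _strip(el) != "apply":
        return None
    children = list(el)
    if not children or _strip(children[0]) != "divide" or len(children) != 3:
        return None
    num, den = children[1], children[2]
    if _strip(num) != "ci":
        return None
    sid = num.text.strip()
    if sid not in species:
        return None
    if _strip(den) == "ci":  # modifier ratio m / m0
        p = den.text.strip()
        if p in params:
            return ("modifier", sid)
        return None
    if _strip(den) == "apply":
        dch = list(den)
        if len(dch) == 3 and _strip(dch[0]) == "plus":
            names = [c.text.strip() for c in dch[1:] if _strip(c) == "ci"]
            if len(names) == 2 and sid in names:
                km_name = names[0] if names[1] == sid else names[1]
                if km_name in params:
                    return ("km", sid, params[km_name])
    return None


def _parse_mm(el, species: set[str], params: dict, rid: str) -> RateLaw | None:
    factors = _flatten_times(el)
    vmax = None
    km: dict[str, float] = {}
    modifiers: list[str] = []
    for f in factors:
        if _strip(f) == "ci" and f.text.strip() in params and f.text.strip().startswith("vmax"):
            vmax = params[f.text.strip()]
            continue
        matched = _match_mm_factor(f, species, params, rid)
        if matched is None:
            return None
        if matched[0] == "km":
            km[matched[1]] = matched[2]
        else:
            modifiers.append(matched[1])
    if vmax is None or not km:
        return None
    return RateLaw(kind=RateLawKind.MICHAELIS_MENTEN, vmax=vmax, km=km,
                   modifiers=tuple(modifiers))


def _parse_gma_term(el, species: set[str], params: dict):
    factors = _flatten_times(el)
    k = None
    exponents: dict[str, float] = {}
    for f in factors:
        if _strip(f) == "ci" and f.text.strip() in params:
            if k is not None:
                return None
            k = params[f.text.strip()]
            continue
        if _strip(f) == "apply":
            ch = list(f)
            if len(ch) == 3 and _strip(ch[0]) == "power" and _strip(ch[1]) == "ci":
                sid = ch[1].text.strip()
                expo = ch[2]
                if sid in species:
                    if _strip(expo) == "ci" and expo.text.strip() in params:
                        exponents[sid] = params[expo.text.strip()]
                        continue
                    if _strip(expo) == "cn":
                        exponents[sid] = float(expo.text.strip())
                        continue
            return None
        else:
            return None
    if k is None or not exponents:
        return None
    return k, exponents


def _parse_law(math_el, species: set[str], params: dict, rid: str) -> RateLaw:
    roots = [c for c in math_el]
    if len(roots) != 1:
        raise UnsupportedConstructError(f"reaction {rid!r}: kinetic law must have one root")
    root = roots[0]
    law = _parse_mm(root, species, params, rid)
    if law is not None:
        return law
    # net reversible mass action: minus(fwd, rev)
    if _strip(root) == "apply":
        ch = list(root)
        if ch and _strip(ch[0]) == "minus" and len(ch) == 3:
            fwd = _parse_gma_term(ch[1], species, params)
            rev = _parse_gma_term(ch[2], species, params)
            if fwd and rev:
                return RateLaw(kind=RateLawKind.GENERALIZED_MASS_ACTION, k=fwd[0],
                               exponents=fwd[1], k_reverse=rev[0], exponents_reverse=rev[1])
    term = _parse_gma_term(root, species, params)
    if term:
        return RateLaw(kind=RateLawKind.GENERALIZED_MASS_ACTION, k=term[0], exponents=term[1])
    raise UnsupportedConstructError(
        f"reaction {rid!r}: kinetic law is neither canonical Michaelis–Menten "
        f"nor generalized mass action"
    )


def import_sbml(document: str | bytes) -> KineticModel:
    """Parse an SBML L3V1 document into a validated :class:`KineticModel`."""
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"malformed XML: {exc}") from exc
    mdl = root.find(_S + "model")
    if mdl is None:
        raise SbmlError("document has no <model> element")

    compartments = [
        Compartment(c.get("id"), c.get("name", ""))
        for c in mdl.findall(f"{_S}listOfCompartments/{_S}compartment")
    ]
    species = []
    for el in mdl.findall(f"{_S}listOfSpecies/{_S}species"):
        charge = 0
        ch = el.find(f"{_S}annotation/{_A}charge")
        if ch is not None and ch.text:
            charge = int(ch.text)
        species.append(
            Species(
                id=el.get("id"),
                compartment=el.get("compartment"),
                name=el.get("name", ""),
                initial_concentration=float(el.get("initialConcentration", "0")),
                charge=charge,
                boundary=el.get("boundaryCondition", "false") == "true",
            )
        )
    sid_set = {s.id for s in species}

    reactions = []
    for el in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        rid = el.get("id")
        stoich: dict[str, float] = {}
        for ref in el.findall(f"{_S}listOfReactants/{_S}speciesReference"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) - float(
                ref.get("stoichiometry", "1")
            )
        for ref in el.findall(f"{_S}listOfProducts/{_S}speciesReference"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) + float(
                ref.get("stoichiometry", "1")
            )
        kl = el.find(_S + "kineticLaw")
        if kl is None:
            raise UnsupportedConstructError(f"reaction {rid!r} has no kineticLaw")
        params = {
            p.get("id"): float(p.get("value"))
            for p in kl.findall(f"{_S}listOfLocalParameters/{_S}localParameter")
        }
        math_el = kl.find(_M + "math")
        if math_el is None:
            raise UnsupportedConstructError(f"reaction {rid!r}: kineticLaw has no <math>")
        law = _parse_law(math_el, sid_set, params, rid)
        tclass = ec = None
        info = el.find(f"{_S}annotation/{_A}info")
        if info is not None:
            tclass = info.get("transporterClass")
            ec = info.get("ec")
        reactions.append(
            Reaction(
                id=rid,
                name=el.get("name", ""),
                stoichiometry=stoich,
                rate_law=law,
                reversible=el.get("reversible", "false") == "true"
                and law.k_reverse is not None,
                ec_number=ec,
                transporter_class=tclass,
            )
        )

    model = KineticModel(compartments, species, reactions,
                         metadata={"name": mdl.get("id", "model")})
    report = validate_model(model)
    if not report.ok:
        raise SbmlError("imported model is invalid: " + "; ".join(report))
    return model
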