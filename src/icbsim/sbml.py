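"""SBML Level 3 export of the assembled model structure.

Writes the reduced model - compartments, species (one per state variable)
and the scalar parameters - as an SBML L3v2 document for interoperability
with SBML-aware tooling.  The document is generated directly as XML and
checked by an in-package structural validator (required attributes, id
uniqueness and referential integrity of compartment links); exports are
deterministic, so identical models produce byte-identical documents.
"""

from __future__ import annotations

from dataclasses import fields

from lxml import etree

from .engine import AssembledModel

__all__ = ["export_sbml", "validate_sbml", "SbmlValidationError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"

_COMPARTMENT_OF = {
    "NT": "tdln", "NT1": "tdln", "NT2": "tdln", "PRO1": "tdln", "PRO2": "tdln",
    "PRO3": "tdln", "mAPC_ln": "tdln", "TAA_ln": "tdln",
    "E_blood": "blood",
    "C": "tumor", "APC_t": "tumor", "mAPC_t": "tumor", "TAA_t": "tumor",
}


def _compartment_of(name: str) -> str:
    if name in _COMPARTMENT_OF:
        return _COMPARTMENT_OF[name]
    if name.startswith("E_"):
        return name.split("_")[1]
    if name.startswith("pk_"):
        return "pk_" + name.split("_")[-1]
    raise ValueError(f"no compartment mapping for state {name!r}")


class SbmlValidationError(ValueError):
    pass


def export_sbml(model: AssembledModel) -> bytes:
    """Serialise the model structure as an SBML L3v2 document (bytes)."""
    root = etree.Element("{%s}sbml" % SBML_NS, nsmap={None: SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    mdl = etree.SubElement(root, "{%s}model" % SBML_NS)
    mdl.set("id", "icbsim_reduced")
    mdl.set("name", "reduced checkpoint-blockade tumor-immune model")

    comp_ids = sorted({_compartment_of(n) for n in model.state_names})
    lc = etree.SubElement(mdl, "{%s}listOfCompartments" % SBML_NS)
    for cid in comp_ids:
        c = etree.SubElement(lc, "{%s}compartment" % SBML_NS)
        c.set("id", cid)
        c.set("constant", "false" if cid in ("tumor", "pk_tumor") else "true")

    ls = etree.SubElement(mdl, "{%s}listOfSpecies" % SBML_NS)
    for name in model.state_names:
        s = etree.SubElement(ls, "{%s}species" % SBML_NS)
        s.set("id", name.replace("-", "_"))
        s.set("compartment", _compartment_of(name))
        s.set("hasOnlySubstanceUnits", "true")
        s.set("boundaryCondition", "false")
        s.set("constant", "false")

    lp = etree.SubElement(mdl, "{%s}listOfParameters" % SBML_NS)

    def add_param(pid: str, value: float) -> None:
        p = etree.SubElement(lp, "{%s}parameter" % SBML_NS)
        p.set("id", pid)
        p.set("value", repr(float(value)))
        p.set("constant", "true")

    mp = model.p
    for block, prefix in ((mp.priming, "priming"), (mp.killing, "killing"),
                          (mp.trafficking, "traffic"), (mp.antigen, "antigen"),
                          (mp.growth, "growth")):
        for f in fields(block):
            v = getattr(block, f.name)
            if isinstance(v, (int, float)):
                add_param(f"{prefix}_{f.name}", v)
    add_param("hill_m", mp.panel.m)
    for ax in mp.panel.killing_axes + mp.panel.priming_axes:
        stem = ax.name.replace("-", "_")
        add_param(f"kd_{stem}", ax.kd)
        add_param(f"receptor_{stem}", ax.receptor_density)
        add_param(f"ligand_{stem}", ax.ligand_density)

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def validate_sbml(document: bytes) -> None:
    """Structural validation; raises ``SbmlValidationError`` at the first
    invalid element."""
    root = etree.fromstring(document)
    if root.tag != "{%s}sbml" % SBML_NS:
        raise SbmlValidationError(f"root element is {root.tag}, not sbml")
    if root.get("level") != "3":
        raise SbmlValidationError("level attribute must be '3'")
    mdl = root.find("{%s}model" % SBML_NS)
    if mdl is None or not mdl.get("id"):
        raise SbmlValidationError("missing model element or model id")

    comp_ids = set()
    for c in mdl.iterfind(".//{%s}compartment" % SBML_NS):
        cid = c.get("id")
        if not cid:
            raise SbmlValidationError("compartment without id")
        if cid in comp_ids:
            raise SbmlValidationError(f"duplicate compartment id {cid!r}")
        if c.get("constant") is None:
            raise SbmlValidationError(f"compartment {cid!r} missing 'constant'")
        comp_ids.add(cid)

    seen = set()
    for s in mdl.iterfind(".//{%s}species" % SBML_NS):
        sid = s.get("id")
        if not sid:
            raise SbmlValidationError("species without id")
        if sid in seen:
            raise SbmlValidationError(f"duplicate species id {sid!r}")
        seen.add(sid)
        comp = s.get("compartment")
        if comp not in comp_ids:
            raise SbmlValidationError(
                f"species {sid!r} references unknown compartment {comp!r}")
        for attr in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if s.get(attr) is None:
                raise SbmlValidationError(f"species {sid!r} missing {attr!r}")

    pids = set()
    for p in mdl.iterfind(".//{%s}parameter" % SBML_NS):
        pid = p.get("id")
        if not pid or p.get("value") is None:
            raise SbmlValidationError("parameter missing id or value")
        if pid in pids:
            raise SbmlValidationError(f"duplicate parameter id {pid!r}")
        pids.add(pid)
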