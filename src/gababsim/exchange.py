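"""Model exchange: SBtab and SBML serialization, run manifests.

The biochemical network (reactions, rates, initial concentrations) is
exported to the spreadsheet-oriented SBtab TSV format and to SBML Level 3
with explicit mass-action kinetic laws.  Both exports round-trip through
the matching importers: the rebuilt network evaluates the same
right-hand side as the original.  Electrical/protocol configuration lives
in native YAML config, not in the exchange formats.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .network import (
    RELEASE_SPECIES,
    SPECIES,
    ReactionSpec,
    SignalingNetwork,
)

__all__ = [
    "export_sbtab",
    "import_sbtab",
    "export_sbml",
    "import_sbml",
    "validate_sbml",
    "RunManifest",
]

_FMT = "%.12g"


def _format_side(side) -> str:
    if not side:
        return "Ø"
    parts = []
    for sp, nu in side:
        parts.append(sp if nu == 1 else _FMT % nu + " " + sp)
    return " + ".join(parts)


def _parse_side(text: str):
    text = text.strip()
    if text in ("", "Ø"):
        return ()
    out = []
    for term in text.split(" + "):
        bits = term.split()
        if len(bits) == 1:
            out.append((bits[0], 1.0))
        else:
            out.append((bits[1], float(bits[0])))
    return tuple(out)


def export_sbtab(network: SignalingNetwork) -> str:
    """Serialize the network as an SBtab TSV document.

    Two tables: Reaction (formula + rate coefficients) and Compound
    (initial concentrations, nM).  The export is deterministic, so
    export -> import -> export is byte-identical.
    """
    lines = []
    lines.append("!!SBtab SBtabVersion='1.0' Document='gababsim'\t"
                 "TableType='Reaction'\tTableName='Reaction'")
    lines.append("!ID\t!ReactionFormula\t!IsReversible\t!kf\t!kb")
    for r in network.reactions:
        arrow = "<=>" if r.reversible else "->"
        formula = f"{_format_side(r.reactants)} {arrow} " \
                  f"{_format_side(r.products)}"
        lines.append(f"{r.name}\t{formula}\t"
                     f"{'True' if r.reversible else 'False'}\t"
                     f"{_FMT % r.kf}\t{_FMT % r.kb}")
    lines.append("")
    lines.append("!!SBtab SBtabVersion='1.0' Document='gababsim'\t"
                 "TableType='Compound'\tTableName='Compound'")
    lines.append("!ID\t!InitialValue\t!Unit")
    for sp, v in zip(network.species, network.y0):
        lines.append(f"{sp}\t{_FMT % v}\tnM")
    lines.append("")
    return "\n".join(lines)


def import_sbtab(text: str) -> SignalingNetwork:
    """Rebuild a network from its SBtab export."""
    reactions: list[ReactionSpec] = []
    inits: dict[str, float] = {}
    mode = None
    header: list[str] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("!!SBtab"):
            mode = "reaction" if "TableType='Reaction'" in line \
                else "compound" if "TableType='Compound'" in line else None
            header = []
            continue
        if line.startswith("!"):
            header = line.split("\t")
            continue
        if mode is None:
            continue
        row = dict(zip(header, line.split("\t")))
        if mode == "reaction":
            formula = row["!ReactionFormula"]
            arrow = "<=>" if "<=>" in formula else "->"
            lhs, rhs = formula.split(f" {arrow} ")
            reactions.append(ReactionSpec(
                name=row["!ID"],
                reactants=_parse_side(lhs), products=_parse_side(rhs),
                kf=float(row["!kf"]), kb=float(row["!kb"])))
        else:
            inits[row["!ID"]] = float(row["!InitialValue"])
    species = [s for s in (*SPECIES, *RELEASE_SPECIES) if s in inits]
    y0 = np.array([inits[s] for s in species])
    return SignalingNetwork(reactions, species, y0)


# --------------------------------------------------------------------
# SBML Level 3

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml_product(parent, rate_id: str, side) -> None:
    """<apply><times/> rate * species^stoich ... </apply> (or bare ci)."""
    factors = [("ci", rate_id)]
    for sp, nu in side:
        factors.append(("pow", sp, nu) if nu != 1 else ("ci", sp))
    if len(factors) == 1:
        etree.SubElement(parent, f"{{{MATHML_NS}}}ci").text = rate_id
        return
    apply = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(apply, f"{{{MATHML_NS}}}times")
    for f in factors:
        if f[0] == "ci":
            etree.SubElement(apply, f"{{{MATHML_NS}}}ci").text = f[1]
        else:
            p = etree.SubElement(apply, f"{{{MATHML_NS}}}apply")
            etree.SubElement(p, f"{{{MATHML_NS}}}power")
            etree.SubElement(p, f"{{{MATHML_NS}}}ci").text = f[1]
            cn = etree.SubElement(p, f"{{{MATHML_NS}}}cn")
            cn.set("type", "integer")
            cn.text = str(int(f[2]))


def export_sbml(network: SignalingNetwork,
                model_id: str = "gabab_signaling") -> str:
    """Serialize the network as an SBML Level 3 Version 2 document.

    Every reaction carries an explicit mass-action kinetic law
    kf*prod(reactants) - kb*prod(products) over global rate parameters,
    matching the simulator's right-hand side.  Units are nM and ms.
    """
    nsmap = {None: SBML_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap,
                         attrib={"level": "3", "version": "2"})
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model",
                             attrib={"id": model_id,
                                     "timeUnits": "millisecond"})
    lc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(lc, f"{{{SBML_NS}}}compartment",
                     attrib={"id": "synapse", "size": "1",
                             "constant": "true", "spatialDimensions": "3"})
    ls = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp, v in zip(network.species, network.y0):
        etree.SubElement(ls, f"{{{SBML_NS}}}species", attrib={
            "id": sp, "compartment": "synapse",
            "initialConcentration": _FMT % v,
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false", "constant": "false"})
    lp = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for r in network.reactions:
        for tag, val in (("kf", r.kf), ("kb", r.kb)):
            etree.SubElement(lp, f"{{{SBML_NS}}}parameter", attrib={
                "id": f"{tag}_{r.name}", "value": _FMT % val,
                "constant": "true"})
    lr = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rx = etree.SubElement(lr, f"{{{SBML_NS}}}reaction", attrib={
            "id": r.name, "reversible": "true" if r.reversible else "false"})
        if r.reactants:
            lref = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp, nu in r.reactants:
                etree.SubElement(lref, f"{{{SBML_NS}}}speciesReference",
                                 attrib={"species": sp,
                                         "stoichiometry": _FMT % nu,
                                         "constant": "true"})
        if r.products:
            lpr = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, nu in r.products:
                etree.SubElement(lpr, f"{{{SBML_NS}}}speciesReference",
                                 attrib={"species": sp,
                                         "stoichiometry": _FMT % nu,
                                         "constant": "true"})
        kl = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        if r.reversible:
            minus = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
            etree.SubElement(minus, f"{{{MATHML_NS}}}minus")
            _mathml_product(minus, f"kf_{r.name}", r.reactants)
            _mathml_product(minus, f"kb_{r.name}", r.products)
        else:
            _mathml_product(math, f"kf_{r.name}", r.reactants)
    return etree.tostring(sbml, pretty_print=True,
                          xml_declaration=True,
                          encoding="UTF-8").decode()


def validate_sbml(text: str) -> list[str]:
    """Structural validation of an SBML export; returns error messages.

    Checks well-formedness, required containers, id uniqueness, and that
    every species reference resolves.  (Full schema validation requires
    the SBML toolchain; these checks cover the constructs this package
    emits.)
    """
    errors = []
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed: {exc}"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        errors.append("root element is not sbml (level 3 namespace)")
        return errors
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return ["missing model element"]
    species = [s.get("id") for s in
               model.iter(f"{{{SBML_NS}}}species")]
    if len(set(species)) != len(species):
        errors.append("duplicate species ids")
    if not species:
        errors.append("no species declared")
    rids = [r.get("id") for r in model.iter(f"{{{SBML_NS}}}reaction")]
    if len(set(rids)) != len(rids):
        errors.append("duplicate reaction ids")
    known = set(species)
    for ref in model.iter(f"{{{SBML_NS}}}speciesReference"):
        if ref.get("species") not in known:
            errors.append(f"unresolved species {ref.get('species')!r}")
        if ref.get("stoichiometry") is None:
            errors.append("speciesReference without stoichiometry")
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        if rx.find(f"{{{SBML_NS}}}kineticLaw") is None:
            errors.append(f"reaction {rx.get('id')} lacks a kinetic law")
    return errors


def import_sbml(text: str) -> SignalingNetwork:
    """Rebuild a network from this package's SBML export."""
    root = etree.fromstring(text.encode())
    model = root.find(f"{{{SBML_NS}}}model")
    inits: dict[str, float] = {}
    for s in model.iter(f"{{{SBML_NS}}}species"):
        inits[s.get("id")] = float(s.get("initialConcentration", "0"))
    params = {p.get("id"): float(p.get("value", "0"))
              for p in model.iter(f"{{{SBML_NS}}}parameter")}
    reactions = []
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        rid = rx.get("id")

        def side(tag):
            lst = rx.find(f"{{{SBML_NS}}}{tag}")
            if lst is None:
                return ()
            return tuple((ref.get("species"),
                          float(ref.get("stoichiometry")))
                         for ref in lst)
        reactions.append(ReactionSpec(
            name=rid, reactants=side("listOfReactants"),
            products=side("listOfProducts"),
            kf=params[f"kf_{rid}"], kb=params[f"kb_{rid}"]))
    species = [s for s in (*SPECIES, *RELEASE_SPECIES) if s in inits]
    y0 = np.array([inits[s] for s in species])
    return SignalingNetwork(reactions, species, y0)


# --------------------------------------------------------------------
# Run manifests

def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one tool run."""

    command: str
    config: dict
    seed: int | None = None
    tool_version: str = ""
    solver: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def register(self, path) -> None:
        p = Path(path)
        self.outputs[p.name] = _digest(p)

    def write(self, path) -> None:
        if not self.tool_version:
            from . import __version__
            self.tool_version = __version__
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         default=str) + "\n")
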