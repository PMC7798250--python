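"""Volume→area rescaling of trans-compartment kinetic laws in SBML models.

Published multi-compartment models conventionally scale transport rates
with a compartment volume (e.g. ``V_nuc * (k_f*[S] - k_r*[P])``), so any
later change of the compartment sizes silently re-scales the transport
flux with the *volume* even though membrane flux physically scales with
the *membrane area*.  This module

1. reads an SBML document into a small editable view (libsbml underneath),
2. finds reactions whose participants span more than one compartment,
3. rewrites each such kinetic law from ``V × expression`` to
   ``A × expression`` — introducing an explicit area parameter (µm²) and
   multiplying the embedded rate constants by V_ref/A_ref so that the
   amount rate is bit-for-bit unchanged at the reference geometry — and
4. re-exports the document, so volume/area scenarios can be compared.

Only laws that *structurally* factor as (compartment size) × expression
are touched; anything else raises :class:`NotRescalableError` rather than
silently guessing.
"""

from __future__ import annotations

import copy
import json
import math
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import libsbml
import numpy as np
import pandas as pd
import sympy
from sympy.parsing.sympy_parser import (convert_xor, parse_expr,
                                        standard_transformations)
from sympy.printing.str import StrPrinter

from .errors import (NotRescalableError, SBMLReadError, UnsupportedFeatureError)
from .geometry import CompartmentGeometry
from .model import Compartment, Model, Reaction, Species
from .simulate import integrate

__all__ = [
    "SBMLModelView",
    "read_sbml",
    "write_sbml",
    "view_to_model",
    "find_transmembrane_reactions",
    "RescalePlan",
    "rescale_to_area",
    "rescale_to_volume",
    "max_trajectory_deviation",
    "GeometryScenario",
    "apply_scenario",
    "geometry_scenarios",
]

# identifiers, excluding the exponent letter of float literals such as 1e-05
_IDENT_RE = re.compile(r"(?<![\w.])[A-Za-z_][A-Za-z0-9_]*")

# SBML L3 infix functions we translate; `log(x)` is log10, `log(b, x)` base-b.
_L3_FUNCTIONS = {
    "pow": lambda a, b: a**b,
    "power": lambda a, b: a**b,
    "exp": sympy.exp,
    "ln": sympy.log,
    "log": lambda *args: (sympy.log(args[0], 10) if len(args) == 1
                          else sympy.log(args[1], args[0])),
    "log10": lambda x: sympy.log(x, 10),
    "sqrt": sympy.sqrt,
    "root": lambda n, x: x ** (sympy.Integer(1) / n),
    "abs": sympy.Abs,
    "floor": sympy.floor,
    "ceiling": sympy.ceiling,
    "ceil": sympy.ceiling,
}

_TRANSFORMS = standard_transformations + (convert_xor,)


def _formula_to_sympy(formula: str, known: Mapping[str, sympy.Symbol]) -> sympy.Expr:
    """Parse an SBML L3 infix formula against a closed symbol table.

    Every identifier must be a known entity or a supported function;
    anything else (``time``, ``piecewise``, delay...) is rejected loudly.
    """
    idents = set(_IDENT_RE.findall(formula))
    unknown = idents - set(known) - set(_L3_FUNCTIONS)
    if unknown:
        raise UnsupportedFeatureError(
            [f"identifier '{u}' in kinetic law '{formula}'" for u in sorted(unknown)]
        )
    local = dict(known)
    local.update(_L3_FUNCTIONS)
    try:
        return parse_expr(formula, local_dict=local, transformations=_TRANSFORMS,
                          evaluate=True)
    except Exception as exc:
        raise UnsupportedFeatureError([f"kinetic law '{formula}' ({exc})"]) from exc


class _L3Printer(StrPrinter):
    """sympy → SBML L3 infix: `^` for powers, `ln` for the natural log."""

    def _print_Pow(self, expr, rational=False):
        from sympy.printing.precedence import PRECEDENCE

        base = self.parenthesize(expr.base, PRECEDENCE["Pow"])
        exp = self.parenthesize(expr.exp, PRECEDENCE["Pow"])
        return f"{base}^{exp}"

    def _print_log(self, expr):
        if len(expr.args) == 1:
            return f"ln({self._print(expr.args[0])})"
        return f"log({self._print(expr.args[1])}, {self._print(expr.args[0])})"


def _sympy_to_l3(expr: sympy.Expr) -> str:
    return _L3Printer({"full_prec": True}).doprint(expr)


@dataclass
class SBMLSpeciesView:
    id: str
    compartment: str
    initial_amount: float | None
    initial_concentration: float | None
    substance_only: bool
    boundary: bool
    constant: bool


@dataclass
class SBMLReactionView:
    id: str
    reactants: tuple  # ((species_id, stoichiometry), ...)
    products: tuple
    modifiers: tuple
    formula: str  # kinetic law, SBML L3 infix, in substance/time units
    local_parameters: dict
    reversible: bool


@dataclass
class SBMLModelView:
    """Editable view of the supported SBML subset.

    The original libsbml document is retained (never mutated) so that
    :func:`write_sbml` can re-export with all untouched annotation intact.
    """

    compartments: dict
    species: list
    parameters: dict
    parameter_units: dict
    assignment_rules: dict
    reactions: list
    level: int
    version: int
    model_id: str
    _doc: object = field(repr=False, default=None)

    def copy(self) -> "SBMLModelView":
        doc = self._doc
        new = copy.deepcopy(self.__class__(
            compartments=self.compartments, species=list(self.species),
            parameters=self.parameters, parameter_units=self.parameter_units,
            assignment_rules=self.assignment_rules, reactions=list(self.reactions),
            level=self.level, version=self.version, model_id=self.model_id,
            _doc=None))
        new._doc = doc.clone() if doc is not None else None
        return new

    def reaction(self, rid: str) -> SBMLReactionView:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise SBMLReadError(f"no reaction {rid!r} in model {self.model_id!r}")

    def species_by_id(self, sid: str) -> SBMLSpeciesView:
        for s in self.species:
            if s.id == sid:
                return s
        raise SBMLReadError(f"no species {sid!r} in model {self.model_id!r}")

    def symbol_table(self, reaction: SBMLReactionView | None = None) -> dict:
        names = set(self.compartments) | set(self.parameters) | \
            {s.id for s in self.species} | set(self.assignment_rules)
        if reaction is not None:
            names |= set(reaction.local_parameters)
        return {n: sympy.Symbol(n) for n in names}


def _collect_unsupported(model: "libsbml.Model") -> list[str]:
    feats = []
    if model.getNumEvents():
        feats.append(f"events ({model.getNumEvents()})")
    if model.getNumConstraints():
        feats.append("constraints")
    if model.getNumInitialAssignments():
        feats.append("initial assignments")
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        if rule.isRate():
            feats.append(f"rate rule on '{rule.getVariable()}'")
        elif rule.isAlgebraic():
            feats.append("algebraic rule")
    return feats


def read_sbml(source) -> SBMLModelView:
    """Read an SBML Level 2/3 document from a path or an XML string.

    Function definitions are expanded in place; events, algebraic/rate
    rules, constraints and initial assignments are outside the supported
    subset and raise :class:`UnsupportedFeatureError` naming them.
    """
    text = None
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        doc = libsbml.readSBMLFromFile(str(source))
    else:
        text = str(source)
        if not text.lstrip().startswith("<"):
            raise SBMLReadError(f"no such file and not an XML string: {text[:80]!r}")
        doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage().strip()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise SBMLReadError("malformed SBML: " + "; ".join(msgs[:5]))
    model = doc.getModel()
    if model is None:
        raise SBMLReadError("document contains no model")

    if model.getNumFunctionDefinitions():
        props = libsbml.ConversionProperties()
        props.addOption("expandFunctionDefinitions", True)
        if doc.convert(props) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise UnsupportedFeatureError(["function definitions (expansion failed)"])
        model = doc.getModel()

    feats = _collect_unsupported(model)
    if feats:
        raise UnsupportedFeatureError(feats)

    compartments = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        size = c.getSize() if c.isSetSize() else (c.getVolume() if c.isSetVolume() else 1.0)
        if not math.isfinite(size) or size <= 0:
            raise SBMLReadError(f"compartment {c.getId()!r} has non-positive size {size!r}")
        compartments[c.getId()] = float(size)

    species = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        amt = float(s.getInitialAmount()) if s.isSetInitialAmount() else None
        conc = float(s.getInitialConcentration()) if s.isSetInitialConcentration() else None
        if amt is None and conc is None:
            amt = 0.0
        species.append(SBMLSpeciesView(
            id=s.getId(), compartment=s.getCompartment(),
            initial_amount=amt, initial_concentration=conc,
            substance_only=bool(s.getHasOnlySubstanceUnits()),
            boundary=bool(s.getBoundaryCondition()), constant=bool(s.getConstant()),
        ))

    parameters = {}
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        parameters[p.getId()] = float(p.getValue()) if p.isSetValue() else float("nan")

    rules = {}
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        if rule.isAssignment():
            rules[rule.getVariable()] = libsbml.formulaToL3String(rule.getMath())

    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        kl = r.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise UnsupportedFeatureError([f"reaction '{r.getId()}' without a kinetic law"])
        locals_ = {}
        for j in range(kl.getNumParameters()):
            lp = kl.getParameter(j)
            locals_[lp.getId()] = float(lp.getValue())
        if hasattr(kl, "getNumLocalParameters"):
            for j in range(kl.getNumLocalParameters()):
                lp = kl.getLocalParameter(j)
                locals_[lp.getId()] = float(lp.getValue())

        def _participants(lst):
            out = []
            for k in range(lst.size()):
                ref = lst.get(k)
                st = ref.getStoichiometry()
                if not math.isfinite(st):
                    st = 1.0
                out.append((ref.getSpecies(), float(st)))
            return tuple(out)

        reactions.append(SBMLReactionView(
            id=r.getId(),
            reactants=_participants(r.getListOfReactants()),
            products=_participants(r.getListOfProducts()),
            modifiers=tuple(r.getModifier(k).getSpecies()
                            for k in range(r.getNumModifiers())),
            formula=libsbml.formulaToL3String(kl.getMath()),
            local_parameters=locals_,
            reversible=bool(r.getReversible()),
        ))

    return SBMLModelView(
        compartments=compartments, species=species, parameters=parameters,
        parameter_units={}, assignment_rules=rules, reactions=reactions,
        level=model.getLevel(), version=model.getVersion(),
        model_id=model.getId() or "model", _doc=doc,
    )


def _ensure_area_unit(model: "libsbml.Model") -> str:
    """Unit definition for µm² (created once per document)."""
    uid = "um2"
    if model.getUnitDefinition(uid) is None:
        ud = model.createUnitDefinition()
        ud.setId(uid)
        unit = ud.createUnit()
        unit.setKind(libsbml.UNIT_KIND_METRE)
        unit.setExponent(2)
        unit.setScale(-6)
        unit.setMultiplier(1.0)
    return uid


def write_sbml(view: SBMLModelView, path=None) -> str:
    """Serialize the view back to SBML, preserving untouched content.

    Returns the XML string; also writes it to ``path`` when given.
    """
    if view._doc is None:
        raise SBMLReadError("view has no backing document to serialize")
    doc = view._doc.clone()
    model = doc.getModel()
    for cid, size in view.compartments.items():
        comp = model.getCompartment(cid)
        if comp is None:
            raise SBMLReadError(f"compartment {cid!r} missing from backing document")
        comp.setSize(float(size))
    for pid, value in view.parameters.items():
        p = model.getParameter(pid)
        if p is None:
            p = model.createParameter()
            p.setId(pid)
            p.setConstant(True)
            if view.parameter_units.get(pid) == "um2":
                p.setUnits(_ensure_area_unit(model))
        p.setValue(float(value))
    for sv in view.species:
        s = model.getSpecies(sv.id)
        if sv.initial_concentration is not None:
            s.setInitialConcentration(float(sv.initial_concentration))
        elif sv.initial_amount is not None:
            s.setInitialAmount(float(sv.initial_amount))
    for rv in view.reactions:
        r = model.getReaction(rv.id)
        kl = r.getKineticLaw()
        ast = libsbml.parseL3Formula(rv.formula)
        if ast is None:
            raise SBMLReadError(f"cannot serialize kinetic law {rv.formula!r}")
        kl.setMath(ast)
        for lpid, value in rv.local_parameters.items():
            lp = kl.getParameter(lpid)
            if lp is None and hasattr(kl, "getLocalParameter"):
                lp = kl.getLocalParameter(lpid)
            if lp is not None:
                lp.setValue(float(value))
    xml = libsbml.writeSBMLToString(doc)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(xml)
    return xml


def _reaction_expr(view: SBMLModelView, rxn: SBMLReactionView,
                   substitute_rules: bool = True) -> sympy.Expr:
    expr = _formula_to_sympy(rxn.formula, view.symbol_table(rxn))
    if rxn.local_parameters:
        expr = expr.subs({sympy.Symbol(k): v for k, v in rxn.local_parameters.items()})
    if substitute_rules and view.assignment_rules:
        for _ in range(10):
            rule_syms = [s for s in expr.free_symbols if str(s) in view.assignment_rules]
            if not rule_syms:
                break
            expr = expr.subs({
                s: _formula_to_sympy(view.assignment_rules[str(s)], view.symbol_table())
                for s in rule_syms
            })
        else:
            raise UnsupportedFeatureError(["cyclic assignment rules"])
    return expr


def view_to_model(view: SBMLModelView) -> Model:
    """Build an integrable :class:`~areakin.model.Model` from the view.

    Kinetic laws become opaque amount-rate expressions; species symbols in
    them follow SBML semantics (concentration unless the species has
    ``hasOnlySubstanceUnits``).  Boundary/constant species are clamped.
    """
    compartments = [
        Compartment(cid, CompartmentGeometry(volume=size, provenance="sbml"))
        for cid, size in view.compartments.items()
    ]
    species = []
    for sv in view.species:
        species.append(Species(
            id=sv.id, compartment=sv.compartment,
            initial_amount=sv.initial_amount,
            initial_concentration=sv.initial_concentration,
            substance_only=sv.substance_only,
            boundary=sv.boundary or sv.constant,
        ))
    reactions = []
    for rv in view.reactions:
        reactions.append(Reaction(
            id=rv.id, reactants=rv.reactants, products=rv.products,
            rate_expression=_reaction_expr(view, rv),
        ))
    m = Model(compartments=compartments, species=species, reactions=reactions,
              parameters=dict(view.parameters))
    return m.validate()


def find_transmembrane_reactions(view: SBMLModelView) -> list[str]:
    """Reactions whose reactants/products live in ≥ 2 compartments."""
    out = []
    comp_of = {s.id: s.compartment for s in view.species}
    for r in view.reactions:
        comps = {comp_of[sid] for sid, _ in (*r.reactants, *r.products)}
        if len(comps) >= 2:
            out.append(r.id)
    return out


# ---------------------------------------------------------------------------
# rescaling


@dataclass
class ReactionRescale:
    reaction_id: str
    compartment_id: str
    volume_ref: float
    area_ref: float
    area_parameter: str
    scale_factor: float  # V_ref / A_ref applied to the rate constants
    scaled_parameters: dict  # param id -> (old value, new value); "<rid>:<pid>" for locals
    original_formula: str
    new_formula: str


@dataclass
class RescalePlan:
    """Record of everything a volume→area rewrite did (and how to undo it)."""

    items: list
    interface: str = "surface"

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "interface": self.interface,
            "reactions": [
                {
                    "reaction": it.reaction_id,
                    "compartment": it.compartment_id,
                    "volume_ref_um3": it.volume_ref,
                    "area_ref_um2": it.area_ref,
                    "area_parameter": it.area_parameter,
                    "constant_scale_factor": it.scale_factor,
                    "scaled_parameters": {k: list(v) for k, v in it.scaled_parameters.items()},
                    "original_formula": it.original_formula,
                    "new_formula": it.new_formula,
                }
                for it in self.items
            ],
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _factor_out(expr: sympy.Expr, view: SBMLModelView):
    """Split ``expr`` into (compartment_id, rest) if it factors as
    (compartment size) × rest; raise :class:`NotRescalableError` otherwise.

    The factor may be the compartment-size identifier itself or a numeric
    literal equal to a declared size within 1e-9 relative.
    """
    args = list(expr.args) if isinstance(expr, sympy.Mul) else [expr]
    comp_syms = {name: sympy.Symbol(name) for name in view.compartments}

    matches = []
    for i, arg in enumerate(args):
        if isinstance(arg, sympy.Symbol) and str(arg) in view.compartments:
            matches.append((i, str(arg)))
        elif arg.is_Number and not arg.is_zero:
            val = float(arg)
            hits = [cid for cid, size in view.compartments.items()
                    if math.isclose(val, size, rel_tol=1e-9)]
            if len(hits) == 1:
                matches.append((i, hits[0]))
            elif len(hits) > 1:
                raise NotRescalableError(
                    f"literal factor {val!r} matches several compartment sizes {hits}; "
                    f"cannot tell which volume the law scales with"
                )
    if not matches:
        raise NotRescalableError(
            f"kinetic law '{_sympy_to_l3(expr)}' does not contain a multiplicative "
            f"compartment-size factor"
        )
    if len(matches) > 1:
        raise NotRescalableError(
            f"kinetic law '{_sympy_to_l3(expr)}' contains several volume factors "
            f"({[cid for _, cid in matches]}); refusing to guess"
        )
    i, cid = matches[0]
    rest = sympy.Mul(*(a for j, a in enumerate(args) if j != i)) if len(args) > 1 else sympy.Integer(1)
    if comp_syms[cid] in rest.free_symbols:
        raise NotRescalableError(
            f"compartment size '{cid}' appears in the law beyond a simple "
            f"multiplicative factor"
        )
    return cid, rest


def _kinetic_parameters_in(rest: sympy.Expr, view: SBMLModelView,
                           rxn: SBMLReactionView) -> list[str]:
    sp = {s.id for s in view.species}
    comps = set(view.compartments)
    out = []
    for s in sorted(rest.free_symbols, key=lambda x: str(x)):
        name = str(s)
        if name in sp or name in comps or name in view.assignment_rules:
            continue
        if name in view.parameters or name in rxn.local_parameters:
            out.append(name)
    return out


def _is_homogeneous_deg1(rest: sympy.Expr, params: Sequence[str]) -> bool:
    t = sympy.Dummy("t", positive=True)
    scaled = rest.subs({sympy.Symbol(p): t * sympy.Symbol(p) for p in params})
    return sympy.simplify(scaled - t * rest) == 0


def _symbol_used_elsewhere(view: SBMLModelView, pid: str, own_rid: str) -> bool:
    pattern = re.compile(rf"\b{re.escape(pid)}\b")
    for r in view.reactions:
        if r.id != own_rid and pattern.search(r.formula):
            return True
    return any(pattern.search(f) for f in view.assignment_rules.values())


def _area_of(geometry, cid: str, interface: str) -> float:
    entry = geometry[cid]
    if isinstance(entry, CompartmentGeometry):
        return entry.area(interface)
    return float(entry)


def rescale_to_area(view: SBMLModelView, reaction_ids: Sequence[str] | None = None,
                    geometry: Mapping | None = None, interface: str = "surface",
                    verify: bool = True, verify_t_end: float = 10.0,
                    verify_tol: float = 1e-6):
    """Rewrite volume-scaled trans-compartment laws to explicit area scaling.

    ``geometry`` maps compartment ids to :class:`CompartmentGeometry`
    (the membrane area is looked up under ``interface``) or directly to an
    area in µm².  For every target law ``V × expr`` the compartment-size
    factor is replaced by a new area parameter (value A_ref) and the
    kinetic constants inside ``expr`` are multiplied by V_ref/A_ref, so
    the amount rate — and hence every trajectory — is unchanged at the
    reference geometry.  Returns ``(rescaled_view, plan)``.

    The constants can only be adjusted when ``expr`` is homogeneous of
    degree 1 in them (true for mass-action and permeability-type laws);
    otherwise the law is reported as not rescalable.
    """
    if geometry is None:
        raise NotRescalableError("rescale_to_area needs per-compartment geometry/areas")
    if reaction_ids is None:
        reaction_ids = find_transmembrane_reactions(view)
    new = view.copy()
    items = []
    for rid in reaction_ids:
        rxn = new.reaction(rid)
        expr = _formula_to_sympy(rxn.formula, new.symbol_table(rxn))
        cid, rest = _factor_out(expr, new)
        if cid not in geometry:
            raise NotRescalableError(
                f"reaction {rid!r} scales with compartment {cid!r} but no geometry "
                f"was supplied for it"
            )
        v_ref = new.compartments[cid]
        a_ref = _area_of(geometry, cid, interface)
        if a_ref <= 0:
            raise NotRescalableError(f"non-positive membrane area for {cid!r}")
        scale = v_ref / a_ref

        params = _kinetic_parameters_in(rest, new, rxn)
        if not params:
            raise NotRescalableError(
                f"reaction {rid!r}: no kinetic parameter to adjust in "
                f"'{_sympy_to_l3(rest)}'"
            )
        if not _is_homogeneous_deg1(rest, params):
            raise NotRescalableError(
                f"reaction {rid!r}: law is not homogeneous of degree 1 in its "
                f"parameters {params}; cannot adjust constants consistently"
            )

        scaled: dict[str, tuple[float, float]] = {}
        substitutions = {}
        for pid in params:
            if pid in rxn.local_parameters:
                old = rxn.local_parameters[pid]
                rxn.local_parameters[pid] = old * scale
                scaled[f"{rid}:{pid}"] = (old, old * scale)
            elif _symbol_used_elsewhere(new, pid, rid):
                # shared global constant: localize under a new name
                alias = f"{pid}_area"
                k = 2
                while alias in new.parameters:
                    alias = f"{pid}_area{k}"
                    k += 1
                old = new.parameters[pid]
                new.parameters[alias] = old * scale
                substitutions[sympy.Symbol(pid)] = sympy.Symbol(alias)
                scaled[alias] = (old, old * scale)
            else:
                old = new.parameters[pid]
                new.parameters[pid] = old * scale
                scaled[pid] = (old, old * scale)
        if substitutions:
            rest = rest.subs(substitutions)

        area_param = f"A_{cid}"
        k = 2
        while area_param in new.parameters and not math.isclose(
                new.parameters[area_param], a_ref, rel_tol=1e-12):
            area_param = f"A_{cid}_{k}"
            k += 1
        new.parameters[area_param] = a_ref
        new.parameter_units[area_param] = "um2"

        new_formula = _sympy_to_l3(sympy.Symbol(area_param) * rest)
        items.append(ReactionRescale(
            reaction_id=rid, compartment_id=cid, volume_ref=v_ref, area_ref=a_ref,
            area_parameter=area_param, scale_factor=scale, scaled_parameters=scaled,
            original_formula=rxn.formula, new_formula=new_formula,
        ))
        rxn.formula = new_formula

    plan = RescalePlan(items=items, interface=interface)
    if verify and items:
        dev = max_trajectory_deviation(view, new, t_end=verify_t_end, n_points=101)
        if dev > verify_tol:
            raise NotRescalableError(
                f"rescaled model deviates from the original at reference geometry "
                f"by {dev:.2e} (> {verify_tol:.0e}); the law rewrite is unsound"
            )
    return new, plan


def rescale_to_volume(view: SBMLModelView, plan: RescalePlan) -> SBMLModelView:
    """Invert a volume→area rewrite arithmetically (roles swapped).

    Constants are divided by the recorded V_ref/A_ref factor and the area
    parameter in each law is replaced by the compartment-size identifier,
    recovering the original constants to floating-point round-off.
    """
    new = view.copy()
    for it in plan.items:
        rxn = new.reaction(it.reaction_id)
        expr = _formula_to_sympy(rxn.formula, new.symbol_table(rxn))
        a_sym = sympy.Symbol(it.area_parameter)
        if a_sym not in expr.free_symbols:
            raise NotRescalableError(
                f"reaction {it.reaction_id!r} no longer references "
                f"{it.area_parameter!r}; cannot invert"
            )
        rest = sympy.cancel(expr / a_sym)
        if a_sym in rest.free_symbols:
            raise NotRescalableError(
                f"area parameter {it.area_parameter!r} is not a simple factor")
        for key in it.scaled_parameters:
            if ":" in key:
                rid, pid = key.split(":", 1)
                rxn.local_parameters[pid] = rxn.local_parameters[pid] / it.scale_factor
            else:
                new.parameters[key] = new.parameters[key] / it.scale_factor
        rxn.formula = _sympy_to_l3(sympy.Symbol(it.compartment_id) * rest)
    return new


def max_trajectory_deviation(view_a: SBMLModelView, view_b: SBMLModelView,
                             t_end: float, n_points: int = 201,
                             rtol: float = 1e-10, atol: float = 1e-14) -> float:
    """Max relative concentration deviation between two views' simulations.

    Each species is normalized by its own dynamic range in the first model
    (flat zero species compare absolutely)."""
    traj_a = integrate(view_to_model(view_a), t_end, n_points=n_points, rtol=rtol, atol=atol)
    traj_b = integrate(view_to_model(view_b), t_end, n_points=n_points, rtol=rtol, atol=atol)
    dev = 0.0
    for sid in traj_a.species:
        ca = traj_a.concentration(sid)
        cb = traj_b.concentration(sid)
        scale = max(float(np.max(np.abs(ca))), 1e-300)
        if np.max(np.abs(ca)) == 0.0:
            dev = max(dev, float(np.max(np.abs(cb))))
        else:
            dev = max(dev, float(np.max(np.abs(ca - cb))) / scale)
    return dev


# ---------------------------------------------------------------------------
# geometry scenarios


@dataclass(frozen=True)
class GeometryScenario:
    """A what-if change of compartment volumes and membrane areas.

    ``volume_factors``/``area_factors`` are either a single factor applied
    to all compartments / all area parameters, or mappings keyed by
    compartment id / area-parameter id.
    """

    name: str
    volume_factors: object = 1.0
    area_factors: object = 1.0

    @classmethod
    def identity(cls, name: str = "reference") -> "GeometryScenario":
        return cls(name=name)

    @classmethod
    def radius_scaling(cls, factor: float, name: str | None = None) -> "GeometryScenario":
        """All radii × factor: volumes × factor³, areas × factor²."""
        return cls(name=name or f"radius x{factor:g}",
                   volume_factors=factor**3, area_factors=factor**2)

    @classmethod
    def area_only(cls, factor: float, name: str | None = None) -> "GeometryScenario":
        """Membrane areas × factor with all volumes fixed (e.g. the wrinkled,
        higher surface-to-volume nuclei of cancer cells)."""
        return cls(name=name or f"area x{factor:g}", area_factors=factor)

    def volume_factor(self, cid: str) -> float:
        if isinstance(self.volume_factors, Mapping):
            return float(self.volume_factors.get(cid, 1.0))
        return float(self.volume_factors)

    def area_factor(self, pid: str) -> float:
        if isinstance(self.area_factors, Mapping):
            return float(self.area_factors.get(pid, 1.0))
        return float(self.area_factors)


def apply_scenario(view: SBMLModelView, scenario: GeometryScenario,
                   area_parameters: Sequence[str] = ()) -> SBMLModelView:
    """Scale compartment sizes (and listed area parameters) per scenario.

    Species initial concentrations are preserved; amount-specified species
    have their amounts rescaled with their compartment so the concentration
    is unchanged.
    """
    new = view.copy()
    for cid in new.compartments:
        f = scenario.volume_factor(cid)
        if f != 1.0:
            new.compartments[cid] = new.compartments[cid] * f
            for sv in new.species:
                if sv.compartment == cid and sv.initial_concentration is None:
                    sv.initial_amount = sv.initial_amount * f
    for pid in area_parameters:
        f = scenario.area_factor(pid)
        if f != 1.0:
            new.parameters[pid] = new.parameters[pid] * f
    return new


def geometry_scenarios(original_view: SBMLModelView, rescaled_view: SBMLModelView,
                       plan: RescalePlan, scenarios: Sequence[GeometryScenario],
                       t_end: float, outputs: Sequence[str] | None = None,
                       n_points: int = 1001, rtol: float = 1e-8,
                       atol: float = 1e-12) -> pd.DataFrame:
    """Compare the volume-scaled original against its area-scaled rewrite
    under geometry changes.

    For each scenario both models are simulated over [0, t_end]; the table
    reports per output species the peak concentration, peak time and final
    concentration of each model plus the percent difference (area vs
    volume).  Area factors touch only the rescaled model — the original has
    no membrane-area parameter, which is precisely its blind spot.
    """
    area_params = [it.area_parameter for it in plan.items]
    if outputs is None:
        boundary = {s.id for s in original_view.species if s.boundary or s.constant}
        outputs = [s.id for s in original_view.species if s.id not in boundary]
    rows = []
    for sc in scenarios:
        v_orig = apply_scenario(original_view, sc)
        v_area = apply_scenario(rescaled_view, sc, area_parameters=area_params)
        traj_o = integrate(view_to_model(v_orig), t_end, n_points=n_points,
                           rtol=rtol, atol=atol)
        traj_a = integrate(view_to_model(v_area), t_end, n_points=n_points,
                           rtol=rtol, atol=atol)
        for sid in outputs:
            co = traj_o.concentration(sid)
            ca = traj_a.concentration(sid)
            io, ia = int(np.argmax(co)), int(np.argmax(ca))
            row = {
                "scenario": sc.name,
                "species": sid,
                "peak_volume_model": float(co[io]),
                "peak_area_model": float(ca[ia]),
                "peak_time_volume_model": float(traj_o.times[io]),
                "peak_time_area_model": float(traj_a.times[ia]),
                "final_volume_model": float(co[-1]),
                "final_area_model": float(ca[-1]),
            }
            for what in ("peak", "final"):
                ref = row[f"{what}_volume_model"]
                row[f"{what}_pct_diff"] = (
                    100.0 * (row[f"{what}_area_model"] - ref) / ref if ref != 0 else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
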