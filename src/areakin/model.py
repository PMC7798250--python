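"""Compartmentalized reaction networks and amount-based ODE assembly.

The state vector of every model is the vector of species *amounts*
(µM·µm³ = 1e-21 mol each); concentrations are derived views obtained by
dividing by the species' own compartment volume.  Keeping the state in
amounts makes trans-compartment stoichiometry conserve mass by
construction and avoids the volume-ratio pitfalls that concentration
states invite.

Three scaling regimes are supported for mass-action reactions:

``VolumeScaling``
    amount rate = V₁·k_f·∏[S]^s − V₂·k_r·∏[P]^s, where V₁/V₂ are the
    volumes of the compartments holding the reactants/products.  This is
    the conventional — and for transport often physically wrong — choice.

``AreaScaling``
    amount rate = A·(k_af·∏[S]^s − k_ar·∏[P]^s) with A the membrane
    interface area; first-order constants then carry µm·s⁻¹ units.
    This reflects that trans-membrane flux is proportional to the number
    of transporters, i.e. (at constant density) to the membrane area.

``SingleCompartment``
    all species are treated as one well-stirred pool whose volume is the
    sum of all compartment volumes; transport degenerates to
    interconversion and geometry has no effect on the dynamics.

Imported SBML kinetic laws are carried as opaque sympy expressions
(:attr:`Reaction.rate_expression`) that evaluate directly to an amount
rate; species symbols in such expressions denote concentrations unless
the species is flagged ``substance_only``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import sympy

from .errors import ConfigurationError, ModelError
from .geometry import AMOUNT_UNIT_IN_MOL, CompartmentGeometry

__all__ = [
    "Compartment",
    "Species",
    "VolumeScaling",
    "AreaScaling",
    "SingleCompartment",
    "ScalingMode",
    "Reaction",
    "Model",
    "amount_rate",
    "assemble_rhs",
    "to_concentrations",
    "from_concentrations",
    "set_volumes",
    "AMOUNT_UNIT_IN_MOL",
]


@dataclass(frozen=True)
class Compartment:
    id: str
    geometry: CompartmentGeometry

    @property
    def volume(self) -> float:
        return self.geometry.volume


@dataclass(frozen=True)
class Species:
    """A chemical species living in one compartment.

    Exactly one of ``initial_amount`` (µM·µm³) or ``initial_concentration``
    (µM) must be given; the other is derived through the compartment
    volume.  ``boundary`` species are held constant by the integrator;
    ``substance_only`` species are referenced by amount (not concentration)
    inside expression rate laws, mirroring the SBML flag.
    """

    id: str
    compartment: str
    initial_amount: float | None = None
    initial_concentration: float | None = None
    substance_only: bool = False
    boundary: bool = False

    def __post_init__(self) -> None:
        given = [v for v in (self.initial_amount, self.initial_concentration) if v is not None]
        if len(given) != 1:
            raise ModelError(
                f"species {self.id!r}: exactly one of initial_amount / "
                f"initial_concentration must be given"
            )
        if given[0] < 0 or not math.isfinite(given[0]):
            raise ModelError(f"species {self.id!r}: initial value must be finite and >= 0")


@dataclass(frozen=True)
class VolumeScaling:
    """Scale the forward/reverse concentration rates with the reactant/
    product compartment volumes (the conventional choice)."""


@dataclass(frozen=True)
class AreaScaling:
    """Scale the concentration-difference driving term with a membrane area.

    The area is either looked up as ``interface`` in the named
    ``compartment``'s geometry, or supplied directly via ``area`` (µm²).
    """

    compartment: str | None = None
    interface: str = "surface"
    area: float | None = None

    def __post_init__(self) -> None:
        if self.area is None and self.compartment is None:
            raise ConfigurationError(
                "AreaScaling needs either a direct area value or a "
                "(compartment, interface) reference"
            )
        if self.area is not None and (not math.isfinite(self.area) or self.area < 0):
            raise ConfigurationError(f"AreaScaling area must be finite and >= 0, got {self.area}")


@dataclass(frozen=True)
class SingleCompartment:
    """Merge all compartments into one well-stirred pool."""


ScalingMode = Union[VolumeScaling, AreaScaling, SingleCompartment]


def _as_pairs(items) -> tuple[tuple[str, float], ...]:
    out = []
    for entry in items:
        if isinstance(entry, str):
            out.append((entry, 1.0))
        else:
            sid, st = entry
            out.append((str(sid), float(st)))
    return tuple(out)


@dataclass(frozen=True)
class Reaction:
    """(Possibly irreversible) mass-action reaction, or an opaque rate law.

    For mass action, ``k_f``/``k_r`` are the forward/reverse constants whose
    units depend on ``mode`` (s⁻¹ per concentration order under volume
    scaling, µm·s⁻¹ for first-order transport under area scaling).  When
    ``rate_expression`` is set it is a sympy expression evaluating directly
    to an amount rate (µM·µm³·s⁻¹) and the mass-action fields are ignored.
    """

    id: str
    reactants: Sequence = ()
    products: Sequence = ()
    k_f: float = 0.0
    k_r: float = 0.0
    mode: ScalingMode = VolumeScaling()
    rate_expression: sympy.Expr | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", _as_pairs(self.reactants))
        object.__setattr__(self, "products", _as_pairs(self.products))
        if self.rate_expression is None:
            for name in ("k_f", "k_r"):
                v = float(getattr(self, name))
                if not math.isfinite(v) or v < 0:
                    raise ModelError(f"reaction {self.id!r}: {name} must be finite and >= 0")
                object.__setattr__(self, name, v)

    @property
    def reversible(self) -> bool:
        return self.rate_expression is not None or self.k_r > 0

    @property
    def equilibrium_constant(self) -> float:
        """K_eq = k_f / k_r for reversible mass-action reactions."""
        if self.rate_expression is not None or self.k_r <= 0:
            raise ModelError(f"reaction {self.id!r} has no mass-action equilibrium constant")
        return self.k_f / self.k_r


@dataclass
class Model:
    """Compartments, species, reactions and named scalar parameters.

    The single source of truth for the ODE system; use
    :func:`assemble_rhs` to obtain the d(amounts)/dt callable.
    """

    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise ModelError(f"unknown compartment {cid!r}")

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise ModelError(f"unknown species {sid!r}")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ModelError(f"unknown reaction {rid!r}")

    def compartment_of(self, sid: str) -> Compartment:
        return self.compartment(self.species_by_id(sid).compartment)

    def volume_of(self, sid: str) -> float:
        return self.compartment_of(sid).volume

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def total_volume(self) -> float:
        return sum(c.volume for c in self.compartments)

    def initial_amounts(self) -> np.ndarray:
        out = np.empty(len(self.species))
        for i, s in enumerate(self.species):
            if s.initial_amount is not None:
                out[i] = s.initial_amount
            else:
                out[i] = s.initial_concentration * self.volume_of(s.id)
        return out

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    # -- validation ------------------------------------------------------
    def validate(self) -> "Model":
        if not self.compartments:
            raise ModelError("a model needs at least one compartment")
        for seq, kind in ((self.compartments, "compartment"),
                          (self.species, "species"),
                          (self.reactions, "reaction")):
            ids = [x.id for x in seq]
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ModelError(f"duplicate {kind} id(s): {dupes}")
        comp_ids = {c.id for c in self.compartments}
        sp_ids = {s.id for s in self.species}
        for s in self.species:
            if s.compartment not in comp_ids:
                raise ModelError(f"species {s.id!r} references unknown compartment {s.compartment!r}")
        for r in self.reactions:
            for sid, st in (*r.reactants, *r.products):
                if sid not in sp_ids:
                    raise ModelError(f"reaction {r.id!r} references unknown species {sid!r}")
                if st <= 0:
                    raise ModelError(f"reaction {r.id!r}: stoichiometry of {sid!r} must be > 0")
            if isinstance(r.mode, AreaScaling):
                _resolve_area(r, self)  # raises ConfigurationError if unresolvable
            if r.rate_expression is not None:
                known = sp_ids | comp_ids | set(self.parameters)
                unknown = {str(x) for x in r.rate_expression.free_symbols} - known
                if unknown:
                    raise ModelError(
                        f"reaction {r.id!r}: rate expression references unknown "
                        f"symbols {sorted(unknown)}"
                    )
        return self


def _resolve_area(reaction: Reaction, model: Model) -> float:
    mode = reaction.mode
    if mode.area is not None:
        return mode.area
    geom = model.compartment(mode.compartment).geometry
    try:
        return geom.area(mode.interface)
    except Exception as exc:
        raise ConfigurationError(
            f"reaction {reaction.id!r}: compartment {mode.compartment!r} does not "
            f"expose interface {mode.interface!r}"
        ) from exc


def _scaling_volumes(reaction: Reaction, model: Model) -> tuple[float, float]:
    """(V_forward, V_reverse) for volume scaling: the compartment volumes of
    the (first) reactant and product; one-sided reactions reuse the other side."""
    v_f = model.volume_of(reaction.reactants[0][0]) if reaction.reactants else None
    v_r = model.volume_of(reaction.products[0][0]) if reaction.products else None
    if v_f is None and v_r is None:
        raise ModelError(f"reaction {reaction.id!r} has no participants")
    return (v_f if v_f is not None else v_r, v_r if v_r is not None else v_f)


def amount_rate(reaction: Reaction, state: Mapping[str, float], model: Model) -> float:
    """Net amount rate (µM·µm³·s⁻¹ = 1e-21 mol·s⁻¹) of one reaction.

    ``state`` maps species ids to amounts; concentrations are formed with
    each species' own compartment volume (or the pooled volume under
    :class:`SingleCompartment`).
    """
    participants = [sid for sid, _ in (*reaction.reactants, *reaction.products)]
    for sid in participants:
        if sid not in state:
            raise ModelError(f"state does not cover species {sid!r}")
        if state[sid] < 0:
            raise ModelError(f"negative amount for species {sid!r}: {state[sid]}")

    if reaction.rate_expression is not None:
        subs: dict[sympy.Symbol, float] = {}
        for sym in reaction.rate_expression.free_symbols:
            name = str(sym)
            if name in state:
                sp = model.species_by_id(name)
                subs[sym] = state[name] if sp.substance_only else state[name] / model.volume_of(name)
            elif name in model.parameters:
                subs[sym] = model.parameters[name]
            else:
                subs[sym] = model.compartment(name).volume
        return float(reaction.rate_expression.subs(subs))

    mode = reaction.mode
    if isinstance(mode, SingleCompartment):
        pool = model.total_volume
        conc = lambda sid: state[sid] / pool  # noqa: E731
    else:
        conc = lambda sid: state[sid] / model.volume_of(sid)  # noqa: E731

    fwd = reaction.k_f * math.prod(conc(sid) ** st for sid, st in reaction.reactants)
    rev = reaction.k_r * math.prod(conc(sid) ** st for sid, st in reaction.products)

    if isinstance(mode, AreaScaling):
        return _resolve_area(reaction, model) * (fwd - rev)
    if isinstance(mode, SingleCompartment):
        return model.total_volume * (fwd - rev)
    v_f, v_r = _scaling_volumes(reaction, model)
    return v_f * fwd - v_r * rev


def _compile_reaction(reaction: Reaction, model: Model,
                      idx: Mapping[str, int], volumes: np.ndarray) -> Callable:
    """Compile one reaction into rate(amounts) -> float."""
    if reaction.rate_expression is not None:
        syms = sorted(reaction.rate_expression.free_symbols, key=lambda s: s.name)
        consts = {}
        sp_syms = []
        for sym in syms:
            name = str(sym)
            if name in idx:
                sp_syms.append(sym)
            elif name in model.parameters:
                consts[sym] = model.parameters[name]
            else:
                consts[sym] = model.compartment(name).volume
        expr = reaction.rate_expression.subs(consts) if consts else reaction.rate_expression
        fn = sympy.lambdify(sp_syms, expr, modules=["numpy", "math"])
        positions = np.array([idx[str(s)] for s in sp_syms], dtype=int)
        scale = np.array(
            [1.0 if model.species_by_id(str(s)).substance_only else 1.0 / volumes[idx[str(s)]]
             for s in sp_syms]
        )

        def rate(n: np.ndarray) -> float:
            return float(fn(*(n[positions] * scale)))

        return rate

    re_idx = np.array([idx[sid] for sid, _ in reaction.reactants], dtype=int)
    re_st = np.array([st for _, st in reaction.reactants])
    pr_idx = np.array([idx[sid] for sid, _ in reaction.products], dtype=int)
    pr_st = np.array([st for _, st in reaction.products])
    k_f, k_r = reaction.k_f, reaction.k_r
    mode = reaction.mode

    if isinstance(mode, SingleCompartment):
        v_re = np.full(len(re_idx), model.total_volume)
        v_pr = np.full(len(pr_idx), model.total_volume)
        scale_f = scale_r = model.total_volume
    elif isinstance(mode, AreaScaling):
        v_re = volumes[re_idx]
        v_pr = volumes[pr_idx]
        scale_f = scale_r = _resolve_area(reaction, model)
    else:
        v_re = volumes[re_idx]
        v_pr = volumes[pr_idx]
        scale_f, scale_r = _scaling_volumes(reaction, model)

    def rate(n: np.ndarray) -> float:
        fwd = k_f * np.prod((n[re_idx] / v_re) ** re_st) if k_f else 0.0
        rev = k_r * np.prod((n[pr_idx] / v_pr) ** pr_st) if k_r else 0.0
        return scale_f * fwd - scale_r * rev

    return rate


def assemble_rhs(model: Model) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the ODE right-hand side d(amounts)/dt = f(t, amounts).

    The net stoichiometry column of each reaction multiplies its amount
    rate, so any species set closed under transport/interconversion has a
    conserved total by construction.  Boundary species rows are zeroed.
    """
    model.validate()
    n_sp = len(model.species)
    idx = {s.id: i for i, s in enumerate(model.species)}
    volumes = np.array([model.volume_of(s.id) for s in model.species])
    boundary = np.array([s.boundary for s in model.species])

    stoich = np.zeros((n_sp, len(model.reactions)))
    rate_fns = []
    for j, r in enumerate(model.reactions):
        for sid, st in r.reactants:
            stoich[idx[sid], j] -= st
        for sid, st in r.products:
            stoich[idx[sid], j] += st
        rate_fns.append(_compile_reaction(r, model, idx, volumes))

    def rhs(t: float, n: np.ndarray) -> np.ndarray:
        rates = np.array([fn(n) for fn in rate_fns]) if rate_fns else np.zeros(0)
        dn = stoich @ rates if rate_fns else np.zeros(n_sp)
        if boundary.any():
            dn[boundary] = 0.0
        return dn

    return rhs


def to_concentrations(state: Mapping[str, float], model: Model) -> dict[str, float]:
    """Amounts -> concentrations, dividing by each species' own compartment volume."""
    return {sid: amount / model.volume_of(sid) for sid, amount in state.items()}


def from_concentrations(conc: Mapping[str, float], model: Model) -> dict[str, float]:
    """Concentrations -> amounts (exact inverse of :func:`to_concentrations`)."""
    return {sid: c * model.volume_of(sid) for sid, c in conc.items()}


def set_volumes(model: Model, geometry: Mapping[str, CompartmentGeometry],
                preserve: str = "concentration") -> Model:
    """Return a model with updated compartment geometry, rate constants untouched.

    How the behaviour shifts is then entirely determined by each reaction's
    scaling mode — which is the point of keeping the constants fixed.  By
    default species initial *concentrations* are preserved (amounts are
    recomputed from the new volumes); pass ``preserve="amount"`` to keep
    amounts instead.
    """
    if preserve not in ("concentration", "amount"):
        raise ModelError(f"preserve must be 'concentration' or 'amount', got {preserve!r}")
    new = model.copy()
    comp_map = {c.id: c for c in new.compartments}
    for cid, geom in geometry.items():
        if cid not in comp_map:
            raise ModelError(f"unknown compartment {cid!r} in set_volumes")
    new.compartments = [
        Compartment(c.id, geometry[c.id]) if c.id in geometry else c
        for c in new.compartments
    ]
    if preserve == "concentration":
        species = []
        for s in new.species:
            if s.initial_amount is not None and s.compartment in geometry:
                old_v = model.volume_of(s.id)
                species.append(replace(s, initial_amount=None,
                                       initial_concentration=s.initial_amount / old_v))
            else:
                species.append(s)
        new.species = species
    else:
        species = []
        for s in new.species:
            if s.initial_concentration is not None and s.compartment in geometry:
                old_v = model.volume_of(s.id)
                species.append(replace(s, initial_concentration=None,
                                       initial_amount=s.initial_concentration * old_v))
            else:
                species.append(s)
        new.species = species
    return new.validate()
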