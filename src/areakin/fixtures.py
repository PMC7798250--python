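"""Synthetic inputs: geometry series, reference tables and toy SBML models.

Everything every analysis stage needs can be generated here without any
download: the root-cell developmental series, the HeLa compartment-size
table (recomputed from the published cross-section measurements), small
randomized SBML transport documents for the rescaling machinery, a
nucleocytoplasmic shuttle template for sensitivity/robustness checks, and
random two-compartment exchange models used as closed-form test oracles.

All randomized generators are deterministic under their seed: the same
seed yields byte-identical documents.
"""

from __future__ import annotations

from dataclasses import dataclass

import libsbml
import numpy as np
import pandas as pd

from .errors import AreakinError
from .geometry import CuboidGeometry, sphere_from_cross_section, sphere_from_volume
from .model import (AreaScaling, Compartment, Model, Reaction, Species,
                    VolumeScaling)
from .root_transport import TransitionScenario

__all__ = [
    "FixtureSpec",
    "make_root_series",
    "make_hela_geometry",
    "HELA_PRINTED",
    "make_toy_sbml",
    "make_shuttle_model",
    "make_random_exchange",
]

ZONES = ("meristematic", "transition", "elongation", "maturation")


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic generators.

    Defaults encode the study conditions: root epidermis cells elongating
    from 8 µm to 220 µm at constant 5 µm width/depth, and toy SBML models
    with cytosol/nucleus-like compartment sizes and first-order transport
    constants in the 0.05–0.5 s⁻¹ range.
    """

    seed: int = 0
    zone_lengths: tuple = (8.0, 30.0, 90.0, 220.0)
    width: float = 5.0
    depth: float = 5.0
    cytosol_volume_range: tuple = (500.0, 5000.0)   # µm³
    nucleus_volume_range: tuple = (50.0, 500.0)     # µm³
    rate_constant_range: tuple = (0.05, 0.5)        # s⁻¹
    initial_concentration_range: tuple = (0.5, 2.0)  # µM
    template: str = "reversible"  # or "irreversible"

    def __post_init__(self) -> None:
        if len(self.zone_lengths) != 4:
            raise AreakinError("zone_lengths must list the four developmental zones")
        if any(l2 <= l1 for l1, l2 in zip(self.zone_lengths, self.zone_lengths[1:])):
            raise AreakinError("zone_lengths must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_root_series(spec: FixtureSpec | None = None) -> list[TransitionScenario]:
    """Four developmental transitions of adjacent root epidermis cells.

    Transport runs from the older (larger) cell to the younger one, so the
    (upstream, downstream) zone pairs along the root axis are
    (transition, meristematic), (transition, transition),
    (elongation, transition) and (maturation, elongation); widths and
    depths are constant across zones.
    """
    spec = spec or FixtureSpec()
    lengths = dict(zip(ZONES, spec.zone_lengths))
    pairs = [
        (1, "transition", "meristematic"),
        (2, "transition", "transition"),
        (3, "elongation", "transition"),
        (4, "maturation", "elongation"),
    ]
    cells = {
        zone: CuboidGeometry(length=lengths[zone], width=spec.width, depth=spec.depth)
        for zone in ZONES
    }
    return [
        TransitionScenario(label=label, upstream_zone=up, downstream_zone=down,
                           upstream=cells[up], downstream=cells[down])
        for label, up, down in pairs
    ]


#: Published HeLa compartment measurements (µm², µm³): inputs are the nuclear
#: cross-sections of growing cells and the volumes of the original shuttle
#: model; the printed derived values serve as the comparison column.
HELA_PRINTED = {
    "columns": ("original", "small", "medium", "large"),
    "cell_volume": (1.8e4, 2.2e3, 3.7e3, 5.2e3),
    "nuclear_cross_section": (None, 155.0, 200.0, 245.0),
    "nuclear_volume": (1.2e4, 1.45e3, 2.13e3, 2.88e3),
    "nuclear_surface": (2533.88, 619.28, 800.23, 979.79),
}


def make_hela_geometry() -> pd.DataFrame:
    """Recompute the HeLa nuclear volumes/surfaces from their inputs.

    Growing cells: the nucleus is a sphere whose great-circle cross-section
    was measured, so volume and surface follow from r = sqrt(A_cs/π).  The
    original model column states only the nuclear volume; its surface
    follows from r = (3V/4π)^(1/3).  The returned frame carries the
    computed values, the published ones and their relative deviation
    (expected to sit well below 0.2%, reflecting only the intermediate
    rounding of the published pathway).
    """
    rows = []
    for j, col in enumerate(HELA_PRINTED["columns"]):
        cs = HELA_PRINTED["nuclear_cross_section"][j]
        if cs is None:
            sphere = sphere_from_volume(HELA_PRINTED["nuclear_volume"][j])
            derived = {"nuclear_surface": sphere.surface_area}
        else:
            sphere = sphere_from_cross_section(cs)
            derived = {"nuclear_volume": sphere.volume,
                       "nuclear_surface": sphere.surface_area}
        for quantity in ("cell_volume", "nuclear_cross_section",
                         "nuclear_volume", "nuclear_surface"):
            printed = HELA_PRINTED[quantity][j]
            computed = derived.get(quantity, printed)
            rel = (abs(computed - printed) / printed
                   if printed not in (None, 0) and computed is not None else np.nan)
            rows.append({
                "cell": col,
                "quantity": quantity,
                "computed": computed,
                "published": printed,
                "rel_deviation": rel,
                "derived": quantity in derived,
            })
    return pd.DataFrame(rows)


def _check(status, what: str) -> None:
    if status is not None and isinstance(status, int) and status < 0:
        raise AreakinError(f"libsbml call failed while building {what}")


def make_toy_sbml(spec: FixtureSpec | None = None, seed: int | None = None) -> str:
    """A minimal two-compartment SBML L3 transport model (XML string).

    One species pair S (cytosol) / P (nucleus) linked by a reversible
    first-order transport whose kinetic law is scaled with the *nuclear
    volume* — the convention found in published shuttling models and the
    form the rescaler rewrites.  Constants and sizes are drawn uniformly
    from the spec's ranges; identical seeds yield byte-identical documents.
    """
    spec = spec or FixtureSpec()
    if seed is not None:
        spec = FixtureSpec(seed=seed, template=spec.template)
    rng = spec.rng()
    v_cyt = float(rng.uniform(*spec.cytosol_volume_range))
    v_nuc = float(rng.uniform(*spec.nucleus_volume_range))
    k_f = float(rng.uniform(*spec.rate_constant_range))
    k_r = float(rng.uniform(*spec.rate_constant_range))
    s0 = float(rng.uniform(*spec.initial_concentration_range))

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("toy_transport")
    for cid, size in (("cytosol", v_cyt), ("nucleus", v_nuc)):
        c = model.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(size)
        c.setSpatialDimensions(3)
    for sid, comp, conc in (("S", "cytosol", s0), ("P", "nucleus", 0.0)):
        s = model.createSpecies()
        s.setId(sid)
        s.setCompartment(comp)
        s.setInitialConcentration(conc)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
    for pid, value in (("kf", k_f), ("kr", k_r)):
        p = model.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
    r = model.createReaction()
    r.setId("transport")
    r.setReversible(spec.template == "reversible")
    sr = r.createReactant()
    sr.setSpecies("S")
    sr.setStoichiometry(1.0)
    sr.setConstant(True)
    sp = r.createProduct()
    sp.setSpecies("P")
    sp.setStoichiometry(1.0)
    sp.setConstant(True)
    kl = r.createKineticLaw()
    formula = "nucleus * (kf * S - kr * P)" if spec.template == "reversible" \
        else "nucleus * kf * S"
    ast = libsbml.parseL3Formula(formula)
    _check(kl.setMath(ast), "kinetic law")
    return libsbml.writeSBMLToString(doc)


def make_shuttle_model(total_concentration: float = 5.0) -> Model:
    """Nucleocytoplasmic shuttle template (RanGTP-like cycle).

    A GTP-bound form T is produced in the nucleus (exchange, first order,
    0.5 s⁻¹), permeates the nuclear envelope into the cytoplasm, is
    hydrolysed there to the GDP-bound form D (1 s⁻¹), which permeates back
    into the nucleus.  Both permeation steps are diffusive area-scaled
    fluxes across the nuclear envelope (surface of a 1.2·10⁴ µm³ spherical
    nucleus, ≈2535 µm²) with permeabilities of order 10⁻² µm·s⁻¹ — slow
    relative to the conversion capacity, so the steady state is
    transport-limited.  In that regime the nuclear T level is strongly
    sensitive to either permeability alone but nearly invariant when both
    are scaled concomitantly, the robustness signature probed by the
    sensitivity analysis.

    All Ran starts as cytoplasmic D at ``total_concentration`` µM.
    """
    nucleus = sphere_from_volume(1.2e4).to_compartment(interface="envelope")
    from .geometry import CompartmentGeometry

    cytoplasm = CompartmentGeometry(volume=6.0e3, provenance="cell minus nucleus")
    envelope = AreaScaling(compartment="nucleus", interface="envelope")
    m = Model(
        compartments=[Compartment("nucleus", nucleus),
                      Compartment("cytoplasm", cytoplasm)],
        species=[
            Species("T_nuc", "nucleus", initial_concentration=0.0),
            Species("T_cyt", "cytoplasm", initial_concentration=0.0),
            Species("D_nuc", "nucleus", initial_concentration=0.0),
            Species("D_cyt", "cytoplasm", initial_concentration=total_concentration),
        ],
        reactions=[
            Reaction("T_export", reactants=["T_nuc"], products=["T_cyt"],
                     k_f=0.01, k_r=0.01, mode=envelope),
            Reaction("D_import", reactants=["D_cyt"], products=["D_nuc"],
                     k_f=0.02, k_r=0.02, mode=envelope),
            Reaction("hydrolysis", reactants=["T_cyt"], products=["D_cyt"],
                     k_f=1.0, mode=VolumeScaling()),
            Reaction("exchange", reactants=["D_nuc"], products=["T_nuc"],
                     k_f=0.5, mode=VolumeScaling()),
        ],
    )
    return m.validate()


def make_random_exchange(rng: np.random.Generator, mode: str = "area"):
    """Random two-compartment reversible exchange plus its linear-algebra data.

    Returns ``(model, a, b)`` where the amount ODE is
    n₁' = −a·n₁ + b·n₂, n₂' = a·n₁ − b·n₂, so the matrix exponential of
    [[−a, b], [a, −b]] is an independent closed-form oracle for the
    integrator (relaxation rate λ = a + b).
    """
    from .geometry import CompartmentGeometry
    from .model import SingleCompartment

    v1 = float(rng.uniform(10.0, 5000.0))
    v2 = float(rng.uniform(10.0, 5000.0))
    c0 = float(rng.uniform(0.2, 3.0))
    c0_p = float(rng.uniform(0.0, 1.0))
    if mode == "area":
        area = float(rng.uniform(1.0, 500.0))
        k_af = float(rng.uniform(0.05, 5.0))
        k_ar = float(rng.uniform(0.05, 5.0))
        scaling = AreaScaling(area=area)
        a = area * k_af / v1
        b = area * k_ar / v2
        k_f, k_r = k_af, k_ar
    elif mode == "volume":
        k_f = float(rng.uniform(0.01, 2.0))
        k_r = float(rng.uniform(0.01, 2.0))
        scaling = VolumeScaling()
        a, b = k_f, k_r
    elif mode == "single":
        k_f = float(rng.uniform(0.01, 2.0))
        k_r = float(rng.uniform(0.01, 2.0))
        scaling = SingleCompartment()
        a, b = k_f, k_r
        v2 = v1  # one pool: both species share it
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "single":
        compartments = [Compartment("pool", CompartmentGeometry(volume=v1))]
        comp_s = comp_p = "pool"
    else:
        compartments = [Compartment("c1", CompartmentGeometry(volume=v1)),
                        Compartment("c2", CompartmentGeometry(volume=v2))]
        comp_s, comp_p = "c1", "c2"
    m = Model(
        compartments=compartments,
        species=[Species("S", comp_s, initial_concentration=c0),
                 Species("P", comp_p, initial_concentration=c0_p)],
        reactions=[Reaction("exchange", reactants=["S"], products=["P"],
                            k_f=k_f, k_r=k_r, mode=scaling)],
    )
    return m.validate(), a, b
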