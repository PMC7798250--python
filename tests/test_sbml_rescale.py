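"""SBML import/export and the volume -> area kinetic-law rewrite."""

import numpy as np
import pytest

from areakin.errors import (NotRescalableError, SBMLReadError,
                            UnsupportedFeatureError)
from areakin.fixtures import FixtureSpec, make_toy_sbml
from areakin.geometry import sphere_from_volume
from areakin.sbml_rescale import (GeometryScenario, apply_scenario,
                                  find_transmembrane_reactions,
                                  geometry_scenarios, max_trajectory_deviation,
                                  read_sbml, rescale_to_area, rescale_to_volume,
                                  view_to_model, write_sbml)
from areakin.simulate import integrate

SINGLE_COMPARTMENT_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="onecomp">
    <listOfCompartments>
      <compartment id="c" size="2" constant="true" spatialDimensions="3"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" initialConcentration="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" initialConcentration="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k" value="0.4" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="conv" reversible="false">
        <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
        <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
          <apply><times/><ci>c</ci><ci>k</ci><ci>A</ci></apply>
        </math></kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

EVENT_DOC = SINGLE_COMPARTMENT_DOC.replace(
    "</listOfReactions>",
    """</listOfReactions>
    <listOfEvents>
      <event id="e1" useValuesFromTriggerTime="true">
        <trigger initialValue="true" persistent="true">
          <math xmlns="http://www.w3.org/1998/Math/MathML"><true/></math>
        </trigger>
        <listOfEventAssignments>
          <eventAssignment variable="k">
            <math xmlns="http://www.w3.org/1998/Math/MathML"><cn>1</cn></math>
          </eventAssignment>
        </listOfEventAssignments>
      </event>
    </listOfEvents>""",
)


@pytest.fixture()
def toy_view():
    return read_sbml(make_toy_sbml(FixtureSpec(seed=7)))


@pytest.fixture()
def toy_geometry(toy_view):
    return {"nucleus": sphere_from_volume(toy_view.compartments["nucleus"]).to_compartment()}


def test_round_trip_preserves_simulation(toy_view, tmp_path):
    path = tmp_path / "toy.xml"
    write_sbml(toy_view, path)
    again = read_sbml(path)
    assert again.compartments == pytest.approx(toy_view.compartments)
    assert max_trajectory_deviation(toy_view, again, t_end=40.0) < 1e-9


def test_events_are_rejected_by_name():
    with pytest.raises(UnsupportedFeatureError, match="events"):
        read_sbml(EVENT_DOC)


def test_malformed_xml_is_rejected():
    with pytest.raises(SBMLReadError):
        read_sbml("<sbml>not really</sbml>")


def test_find_transmembrane_reactions(toy_view):
    assert find_transmembrane_reactions(toy_view) == ["transport"]
    assert find_transmembrane_reactions(read_sbml(SINGLE_COMPARTMENT_DOC)) == []


def test_toy_model_simulates_like_closed_form(toy_view):
    """dnS/dt = -V_nuc (kf [S] - kr [P]): check against the 2-state solution."""
    from conftest import two_state_solution

    m = view_to_model(toy_view)
    v_cyt = toy_view.compartments["cytosol"]
    v_nuc = toy_view.compartments["nucleus"]
    kf, kr = toy_view.parameters["kf"], toy_view.parameters["kr"]
    a = v_nuc * kf / v_cyt  # amount-rate coefficients of the law
    b = kr
    lam = a + b
    traj = integrate(m, 10.0 / lam, n_points=300, rtol=1e-10, atol=1e-14)
    n0 = m.initial_amounts()
    exact = two_state_solution(traj.times, n0[0], n0[1], a, b)
    assert np.max(np.abs(traj.amounts - exact)) < 1e-6 * n0.sum()


def test_rescale_adjusts_constants_and_preserves_behavior(toy_view, toy_geometry):
    rescaled, plan = rescale_to_area(toy_view, geometry=toy_geometry, verify=True,
                                     verify_t_end=50.0)
    item = plan.items[0]
    v_ref = toy_view.compartments["nucleus"]
    a_ref = toy_geometry["nucleus"].area("surface")
    assert item.scale_factor == pytest.approx(v_ref / a_ref, rel=1e-12)
    assert rescaled.parameters["A_nucleus"] == pytest.approx(a_ref, rel=1e-12)
    for pid in ("kf", "kr"):
        assert rescaled.parameters[pid] == pytest.approx(
            toy_view.parameters[pid] * v_ref / a_ref, rel=1e-12)
    assert "A_nucleus" in rescaled.reaction("transport").formula
    assert max_trajectory_deviation(toy_view, rescaled, t_end=60.0) < 1e-6


def test_rescale_with_matching_area_keeps_constants(toy_view):
    v_nuc = toy_view.compartments["nucleus"]
    rescaled, plan = rescale_to_area(toy_view, geometry={"nucleus": v_nuc},
                                     verify=False)
    assert plan.items[0].scale_factor == pytest.approx(1.0)
    assert rescaled.parameters["kf"] == toy_view.parameters["kf"]
    assert rescaled.parameters["kr"] == toy_view.parameters["kr"]


def test_rescale_back_recovers_constants(toy_view, toy_geometry):
    rescaled, plan = rescale_to_area(toy_view, geometry=toy_geometry, verify=False)
    back = rescale_to_volume(rescaled, plan)
    for pid in ("kf", "kr"):
        assert abs(back.parameters[pid] - toy_view.parameters[pid]) \
            <= 1e-12 * toy_view.parameters[pid]
    assert "nucleus" in back.reaction("transport").formula
    assert max_trajectory_deviation(toy_view, back, t_end=40.0) < 1e-9


def test_unfactorable_laws_raise(toy_view, toy_geometry):
    rxn = toy_view.reaction("transport")
    rxn.formula = "kf * S - kr * P"  # no volume factor at all
    with pytest.raises(NotRescalableError, match="compartment-size factor"):
        rescale_to_area(toy_view, geometry=toy_geometry, verify=False)
    rxn.formula = "cytosol * nucleus * kf * S"  # two volume factors
    with pytest.raises(NotRescalableError, match="several volume factors"):
        rescale_to_area(toy_view, geometry=toy_geometry, verify=False)
    rxn.formula = "nucleus^2 * kf * S"  # size enters beyond a simple factor
    with pytest.raises(NotRescalableError):
        rescale_to_area(toy_view, geometry=toy_geometry, verify=False)


def test_literal_volume_factor_is_recognized():
    doc = read_sbml(SINGLE_COMPARTMENT_DOC)
    # same structure, but the law spells the size as the literal 2
    rxn = doc.reaction("conv")
    rxn.formula = "2 * k * A"
    rescaled, plan = rescale_to_area(doc, reaction_ids=["conv"],
                                     geometry={"c": 8.0}, verify=False)
    assert plan.items[0].compartment_id == "c"
    assert plan.items[0].scale_factor == pytest.approx(2.0 / 8.0)
    assert rescaled.parameters["k"] == pytest.approx(0.4 * 0.25, rel=1e-12)


def test_non_homogeneous_law_is_refused(toy_view, toy_geometry):
    # quadratic in the rate constant: no consistent constant adjustment exists
    toy_view.reaction("transport").formula = "nucleus * kf^2 * S"
    with pytest.raises(NotRescalableError, match="homogeneous"):
        rescale_to_area(toy_view, geometry=toy_geometry, verify=False)


def test_identity_scenario_reports_zero_differences(toy_view, toy_geometry):
    rescaled, plan = rescale_to_area(toy_view, geometry=toy_geometry, verify=False)
    report = geometry_scenarios(toy_view, rescaled, plan,
                                [GeometryScenario.identity()], t_end=60.0,
                                n_points=1001)
    assert np.allclose(report["peak_pct_diff"], 0.0, atol=1e-6)
    assert np.allclose(report["final_pct_diff"], 0.0, atol=1e-6)


def test_area_only_scenario_leaves_volume_model_untouched(toy_view, toy_geometry):
    """Growing the membrane area cannot move a model in which the area is not
    a parameter — only the area-scaled version responds."""
    rescaled, plan = rescale_to_area(toy_view, geometry=toy_geometry, verify=False)
    scenario = GeometryScenario.area_only(1.5)
    v_orig = apply_scenario(toy_view, scenario)
    assert v_orig.compartments == toy_view.compartments
    assert v_orig.parameters == toy_view.parameters
    v_area = apply_scenario(rescaled, scenario,
                            area_parameters=[plan.items[0].area_parameter])
    assert v_area.parameters["A_nucleus"] == pytest.approx(
        1.5 * rescaled.parameters["A_nucleus"])
    # the area model's relaxation really speeds up
    dev = max_trajectory_deviation(rescaled, v_area, t_end=60.0)
    assert dev > 1e-3


def test_volume_growth_separates_the_models(toy_view, toy_geometry):
    """After rescaling, any strict volume increase at fixed membrane area makes
    the original and rescaled models diverge."""
    rescaled, plan = rescale_to_area(toy_view, geometry=toy_geometry, verify=False)
    scenario = GeometryScenario(name="volumes x2", volume_factors=2.0)
    v_orig = apply_scenario(toy_view, scenario)
    v_area = apply_scenario(rescaled, scenario)  # area params untouched
    dev = max_trajectory_deviation(v_orig, v_area, t_end=120.0)
    assert dev > 1e-2
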