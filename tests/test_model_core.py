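"""Rate-law assembly under the three scaling regimes, and amount bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from areakin.errors import ConfigurationError, ModelError
from areakin.geometry import AMOUNT_UNIT_IN_MOL, CompartmentGeometry
from areakin.model import (AreaScaling, Compartment, Model, Reaction,
                           SingleCompartment, Species, VolumeScaling,
                           amount_rate, assemble_rhs, from_concentrations,
                           set_volumes, to_concentrations)


def two_cell_model(v1=2.0, v2=3.0, area=4.0, mode="area", k_f=1.0, k_r=1.0,
                   c1=1.0, c2=0.0):
    if mode == "area":
        scaling = AreaScaling(area=area)
    elif mode == "volume":
        scaling = VolumeScaling()
    else:
        scaling = SingleCompartment()
    return Model(
        compartments=[Compartment("c1", CompartmentGeometry(volume=v1)),
                      Compartment("c2", CompartmentGeometry(volume=v2))],
        species=[Species("S", "c1", initial_concentration=c1),
                 Species("P", "c2", initial_concentration=c2)],
        reactions=[Reaction("r", reactants=["S"], products=["P"],
                            k_f=k_f, k_r=k_r, mode=scaling)],
    ).validate()


def test_area_rate_zero_membrane():
    m = two_cell_model(area=0.0)
    rate = amount_rate(m.reactions[0], {"S": 5.0, "P": 1.0}, m)
    assert rate == 0.0


def test_volume_rate_symmetric_equilibrium():
    m = two_cell_model(v1=2.0, v2=2.0, mode="volume", k_f=0.7, k_r=0.7)
    # equal concentrations in equal volumes: net rate vanishes
    rate = amount_rate(m.reactions[0], {"S": 3.0, "P": 3.0}, m)
    assert rate == pytest.approx(0.0, abs=1e-15)


def test_area_rate_unit_bookkeeping():
    """A = 1 µm², k = 1 µm/s, [S] = 1 µM, [P] = 0 gives 1 amount unit/s,
    i.e. 1e-21 mol/s in SI."""
    m = two_cell_model(v1=1.0, v2=1.0, area=1.0, k_f=1.0, k_r=1.0)
    rate = amount_rate(m.reactions[0], {"S": 1.0, "P": 0.0}, m)
    assert rate == pytest.approx(1.0, rel=1e-15)
    assert rate * AMOUNT_UNIT_IN_MOL == pytest.approx(1e-21, rel=1e-15)


def test_area_equilibrium_state_is_rhs_root():
    m = two_cell_model(v1=2.0, v2=5.0, area=3.0, k_f=0.8, k_r=0.4)
    # [S] = [P] * k_ar/k_af makes the area-scaled driving term vanish
    p_conc = 1.3
    s_conc = p_conc * 0.4 / 0.8
    rhs = assemble_rhs(m)
    dn = rhs(0.0, np.array([s_conc * 2.0, p_conc * 5.0]))
    assert np.allclose(dn, 0.0, atol=1e-14)


def test_empty_reaction_list_gives_zero_vector():
    m = two_cell_model()
    m.reactions = []
    rhs = assemble_rhs(m)
    assert np.allclose(rhs(0.0, np.array([1.0, 2.0])), 0.0)


@settings(max_examples=60, deadline=None)
@given(
    mode=st.sampled_from(["area", "volume", "single"]),
    n1=st.floats(min_value=0.0, max_value=100.0),
    n2=st.floats(min_value=0.0, max_value=100.0),
    k_f=st.floats(min_value=0.0, max_value=10.0),
    k_r=st.floats(min_value=0.0, max_value=10.0),
)
def test_transport_conserves_total_amount(mode, n1, n2, k_f, k_r):
    """d(nS)/dt + d(nP)/dt = 0 at every state, for every scaling mode."""
    m = two_cell_model(mode=mode, k_f=k_f, k_r=k_r)
    rhs = assemble_rhs(m)
    dn = rhs(0.0, np.array([n1, n2]))
    assert dn.sum() == pytest.approx(0.0, abs=1e-12 * max(1.0, abs(dn[0])))


@settings(max_examples=60, deadline=None)
@given(
    v1=st.floats(min_value=0.1, max_value=1e3),
    v2=st.floats(min_value=0.1, max_value=1e3),
    area=st.floats(min_value=0.1, max_value=1e3),
    k_af=st.floats(min_value=0.01, max_value=10.0),
    k_ar=st.floats(min_value=0.01, max_value=10.0),
    n1=st.floats(min_value=0.0, max_value=50.0),
    n2=st.floats(min_value=0.0, max_value=50.0),
)
def test_mode_equivalence_at_reference_geometry(v1, v2, area, k_af, k_ar, n1, n2):
    """With k_f = k_af·A/V1 and k_r = k_ar·A/V2 the volume- and area-scaled
    amount rates agree at every state — at that geometry."""
    m_area = two_cell_model(v1=v1, v2=v2, area=area, mode="area", k_f=k_af, k_r=k_ar)
    m_vol = two_cell_model(v1=v1, v2=v2, mode="volume",
                           k_f=k_af * area / v1, k_r=k_ar * area / v2)
    state = {"S": n1, "P": n2}
    r_area = amount_rate(m_area.reactions[0], state, m_area)
    r_vol = amount_rate(m_vol.reactions[0], state, m_vol)
    assert r_vol == pytest.approx(r_area, rel=1e-12, abs=1e-12)


def test_concentration_round_trip():
    m = two_cell_model(v1=2.0, v2=3.0)
    amounts = {"S": 2.0, "P": 4.5}
    conc = to_concentrations(amounts, m)
    assert conc["S"] == pytest.approx(1.0)  # 2 amount units in 2 µm³ -> 1 µM
    assert conc["P"] == pytest.approx(1.5)
    back = from_concentrations(conc, m)
    assert back["S"] == pytest.approx(amounts["S"], rel=1e-15)
    assert back["P"] == pytest.approx(amounts["P"], rel=1e-15)
    assert to_concentrations({"S": 0.0, "P": 0.0}, m) == {"S": 0.0, "P": 0.0}


def test_set_volumes_volume_mode_rate_scales_with_volume():
    """Doubling all volumes at fixed concentrations doubles the volume-scaled
    amount rate, while the area-scaled rate is untouched at fixed A."""
    conc_state = {"S": 1.0, "P": 0.25}
    m_vol = two_cell_model(v1=2.0, v2=3.0, mode="volume", k_f=0.5, k_r=0.25)
    m_area = two_cell_model(v1=2.0, v2=3.0, area=4.0, mode="area", k_f=0.5, k_r=0.25)
    doubled = {
        "c1": CompartmentGeometry(volume=4.0),
        "c2": CompartmentGeometry(volume=6.0),
    }
    for m, expect_factor in ((m_vol, 2.0), (m_area, 1.0)):
        before = amount_rate(m.reactions[0], from_concentrations(conc_state, m), m)
        grown = set_volumes(m, doubled)
        after = amount_rate(grown.reactions[0], from_concentrations(conc_state, grown), grown)
        assert after == pytest.approx(expect_factor * before, rel=1e-12)


def test_set_volumes_preserves_concentrations_by_default():
    m = two_cell_model(v1=2.0, v2=3.0, c1=1.5)
    grown = set_volumes(m, {"c1": CompartmentGeometry(volume=20.0)})
    n = grown.initial_amounts()
    assert n[0] == pytest.approx(1.5 * 20.0)
    kept = set_volumes(m, {"c1": CompartmentGeometry(volume=20.0)}, preserve="amount")
    assert kept.initial_amounts()[0] == pytest.approx(m.initial_amounts()[0])


def test_set_volumes_identity_is_noop():
    m = two_cell_model()
    same = set_volumes(m, {"c1": CompartmentGeometry(volume=2.0)})
    assert np.allclose(same.initial_amounts(), m.initial_amounts())
    assert same.compartment("c1").volume == 2.0


def test_validation_errors():
    with pytest.raises(ModelError):
        Species("S", "c1")  # neither amount nor concentration
    with pytest.raises(ModelError):
        Species("S", "c1", initial_amount=1.0, initial_concentration=1.0)
    m = two_cell_model()
    m.species.append(Species("S", "c1", initial_amount=0.0))
    with pytest.raises(ModelError, match="duplicate"):
        m.validate()
    # area mode pointing at an interface the compartment does not expose
    bad = Model(
        compartments=[Compartment("c1", CompartmentGeometry(volume=1.0))],
        species=[Species("S", "c1", initial_amount=0.0),
                 Species("P", "c1", initial_amount=0.0)],
        reactions=[Reaction("r", reactants=["S"], products=["P"], k_f=1.0,
                            mode=AreaScaling(compartment="c1", interface="nope"))],
    )
    with pytest.raises(ConfigurationError):
        bad.validate()


def test_amount_rate_rejects_negative_and_missing_state():
    m = two_cell_model()
    with pytest.raises(ModelError, match="negative"):
        amount_rate(m.reactions[0], {"S": -1.0, "P": 0.0}, m)
    with pytest.raises(ModelError, match="cover"):
        amount_rate(m.reactions[0], {"S": 1.0}, m)
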