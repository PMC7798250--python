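"""The two-root-cell transport comparison across implementations."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from areakin.errors import CalibrationError, GeometryError
from areakin.fixtures import FixtureSpec, make_root_series
from areakin.geometry import CuboidGeometry
from areakin.model import SingleCompartment
from areakin.root_transport import (MODE_AREA, MODE_SINGLE, MODE_VOLUME, MODES,
                                    TransitionScenario, build_transport_model,
                                    calibrate_to_scenario1, relaxation_rate,
                                    run_comparison)
from areakin.simulate import equilibrium_metrics, integrate


def test_scenario_requires_shared_contact_face():
    with pytest.raises(GeometryError, match="contact face"):
        TransitionScenario(label=1, upstream_zone="a", downstream_zone="b",
                           upstream=CuboidGeometry(10.0, 5.0, 5.0),
                           downstream=CuboidGeometry(10.0, 4.0, 5.0))


def test_build_transport_model_initials(scenario1):
    for mode in MODES:
        m = build_transport_model(scenario1, mode, 1.0, 1.0)
        x1 = m.species_by_id("X1")
        x2 = m.species_by_id("X2")
        assert x1.initial_concentration == 1.0
        assert x2.initial_concentration == 0.0
    pooled = build_transport_model(scenario1, MODE_SINGLE, 1.0, 1.0)
    assert len(pooled.compartments) == 1
    assert pooled.compartments[0].volume == pytest.approx(
        scenario1.upstream_volume + scenario1.downstream_volume)
    assert isinstance(pooled.reactions[0].mode, SingleCompartment)


def test_area_mode_equalizes_concentrations(scenario1):
    """Symmetric permeabilities: area scaling equilibrates the concentrations
    while the amounts split as V1 : V2."""
    m = build_transport_model(scenario1, MODE_AREA, 0.8, 0.8)
    lam = relaxation_rate(scenario1, MODE_AREA, 0.8, 0.8)
    traj = integrate(m, 16.0 / lam, n_points=800, rtol=1e-10, atol=1e-14)
    met = equilibrium_metrics(traj)
    assert met.equilibrium_concentrations["X1"] == pytest.approx(
        met.equilibrium_concentrations["X2"], rel=1e-6)
    n_end = traj.amounts[-1]
    assert n_end[0] / n_end[1] == pytest.approx(
        scenario1.upstream_volume / scenario1.downstream_volume, rel=1e-6)


def test_calibration_matches_reference_trajectories(scenario1):
    """All three implementations reproduce the same X1 relaxation at the
    reference transition (the calibration contract)."""
    params = calibrate_to_scenario1(1.0, 1.0, scenario1, verify=True, tol=1e-6)
    k_f, k_r = params.for_mode(MODE_VOLUME)
    a = scenario1.interface_area
    assert k_f == pytest.approx(a / scenario1.upstream_volume, rel=1e-12)
    assert k_r == pytest.approx(a / scenario1.downstream_volume, rel=1e-12)
    # volume and area models agree on BOTH species at the reference geometry
    lam = relaxation_rate(scenario1, MODE_AREA, 1.0, 1.0)
    t_area = integrate(build_transport_model(scenario1, MODE_AREA, 1.0, 1.0),
                       12.0 / lam, n_points=300, rtol=1e-10, atol=1e-14)
    t_vol = integrate(build_transport_model(scenario1, MODE_VOLUME, k_f, k_r),
                      12.0 / lam, n_points=300, rtol=1e-10, atol=1e-14)
    assert np.max(np.abs(t_area.concentrations - t_vol.concentrations)) < 1e-8


def test_calibration_at_unit_geometry_keeps_constants():
    """When V1 = V2 = A numerically, the volume-mode constants equal the
    area-mode permeabilities."""
    cell = CuboidGeometry(length=1.0, width=2.0, depth=3.0)  # V = 6 = w·d·L, A = 6
    sc = TransitionScenario(label=1, upstream_zone="z", downstream_zone="z",
                            upstream=cell, downstream=cell)
    assert sc.interface_area == pytest.approx(cell.volume)
    params = calibrate_to_scenario1(0.7, 0.4, sc, verify=False)
    assert params.for_mode(MODE_VOLUME) == pytest.approx((0.7, 0.4), rel=1e-12)


def test_calibration_rejects_nonpositive_constants(scenario1):
    with pytest.raises(CalibrationError):
        calibrate_to_scenario1(0.0, 1.0, scenario1)


def test_comparison_grid_and_signatures(root_scenarios, calibrated):
    comparison = run_comparison(root_scenarios, calibrated)
    summary = comparison.summary_frame()
    assert len(summary) == 4 * 3 * 2  # scenarios x modes x species

    # area scaling: reaching equilibrium is delayed as the cells grow
    t95 = [comparison.metrics[(s.label, MODE_AREA)].time_to_fraction["X1"]
           for s in root_scenarios]
    assert all(t2 > t1 for t1, t2 in zip(t95, t95[1:]))

    # pooled model: geometry drops out entirely
    ref = comparison.trajectories[(1, MODE_SINGLE)].concentrations
    for s in root_scenarios[1:]:
        other = comparison.trajectories[(s.label, MODE_SINGLE)].concentrations
        assert np.max(np.abs(other - ref)) < 1e-9

    # volume scaling: the equilibrium ratio follows volume-scaled mass action,
    # shifting with V2/V1 across scenarios while the timescale does not move
    k_f, k_r = calibrated.for_mode(MODE_VOLUME)
    for s in root_scenarios:
        met = comparison.metrics[(s.label, MODE_VOLUME)]
        ratio = (met.equilibrium_concentrations["X1"]
                 / met.equilibrium_concentrations["X2"])
        expected = (s.downstream_volume / s.upstream_volume) * (k_r / k_f)
        assert ratio == pytest.approx(expected, rel=1e-6)
    t95_vol = [comparison.metrics[(s.label, MODE_VOLUME)].time_to_fraction["X1"]
               for s in root_scenarios]
    assert max(t95_vol) / min(t95_vol) < 1.01


def test_scenario4_equilibria_diverge_across_modes(root_scenarios, calibrated):
    """After the reference calibration, the largest transition separates the
    implementations: the area model shifts [X1]_eq (volume scaling pins it at
    k_r/(k_f+k_r) regardless of geometry) and the pooled model's [X2]_eq stays
    at its reference value while the volume model's moves with V1/V2."""
    comparison = run_comparison(root_scenarios, calibrated)
    eq4 = {mode: comparison.metrics[(4, mode)].equilibrium_concentrations
           for mode in MODES}
    assert abs(eq4[MODE_AREA]["X1"] - eq4[MODE_VOLUME]["X1"]) > 1e-3
    assert abs(eq4[MODE_SINGLE]["X2"] - eq4[MODE_VOLUME]["X2"]) > 1e-3
    assert abs(eq4[MODE_AREA]["X2"] - eq4[MODE_SINGLE]["X2"]) > 1e-3


@seed(20260927)
@settings(max_examples=15, deadline=None)
@given(
    k_af=st.floats(min_value=0.1, max_value=10.0),
    k_ar=st.floats(min_value=0.1, max_value=10.0),
    width=st.floats(min_value=2.0, max_value=10.0),
    l0=st.floats(min_value=4.0, max_value=15.0),
    growth=st.floats(min_value=1.5, max_value=4.0),
)
def test_signatures_hold_for_any_positive_parameters(k_af, k_ar, width, l0, growth):
    """The three qualitative signatures are parameter-free properties of the
    scaling modes, not of the default constants."""
    lengths = tuple(l0 * growth**i for i in range(4))
    spec = FixtureSpec(zone_lengths=lengths, width=width, depth=width)
    scenarios = make_root_series(spec)
    params = calibrate_to_scenario1(k_af, k_ar, scenarios[0], verify=False)
    comparison = run_comparison(scenarios, params, n_points=301)
    t95 = [comparison.metrics[(s.label, MODE_AREA)].time_to_fraction["X1"]
           for s in scenarios]
    assert all(t2 > t1 for t1, t2 in zip(t95, t95[1:]))
    lam_vol = [1.0 / comparison.metrics[(s.label, MODE_VOLUME)].time_to_fraction["X1"]
               for s in scenarios]
    assert max(lam_vol) / min(lam_vol) < 1.01
    ref = comparison.trajectories[(1, MODE_SINGLE)].concentrations
    worst = max(np.max(np.abs(comparison.trajectories[(s.label, MODE_SINGLE)]
                              .concentrations - ref)) for s in scenarios[1:])
    assert worst < 1e-9
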