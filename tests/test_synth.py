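import numpy as np
import pytest

import esvpipe as ep
from esvpipe.errors import ConfigurationError, InvalidGridError
from esvpipe.importance import FACTOR_NAMES
from esvpipe.synth import (
    Scenario,
    TransitionRule,
    generate_covariates,
    generate_landuse,
    generate_terrain,
    slope_from_elevation,
)
from esvpipe.valuation import LAND_CLASSES


def test_flat_surface_has_zero_slope():
    slope = slope_from_elevation(np.full((8, 8), 700.0), 1000.0)
    np.testing.assert_allclose(slope, 0.0)


def test_planar_ramp_slope_matches_closed_form():
    # 100 m rise per 1000 m cell -> atan(0.1) = 5.7106 degrees everywhere,
    # including borders (one-sided differences are exact on a plane)
    elev = 100.0 * np.arange(10)[None, :] * np.ones((6, 1))
    slope = slope_from_elevation(elev, 1000.0)
    np.testing.assert_allclose(slope, np.degrees(np.arctan(0.1)), rtol=1e-12)


def test_terrain_deterministic_and_bounded():
    spec = ep.GridSpec(20, 20)
    e1, s1 = generate_terrain(spec, seed=5)
    e2, s2 = generate_terrain(spec, seed=5)
    np.testing.assert_array_equal(e1, e2)
    np.testing.assert_array_equal(s1, s2)
    assert e1.min() >= 0 and e1.max() <= 2000
    with pytest.raises(InvalidGridError):
        generate_terrain(ep.GridSpec(4, 3), seed=0)


def test_lapse_rate_temperature_with_zero_noise():
    spec = ep.GridSpec(5, 5)
    scenario = Scenario(temperature_noise_sd=0.0)
    elev = np.full(spec.shape, 1000.0)
    stack = generate_covariates(elev, np.zeros(spec.shape), spec, scenario, seed=0)
    np.testing.assert_allclose(stack.layers["temperature"], 8.5)  # 15 - 6.5


def test_covariate_invariants(small_bundle):
    stack = small_bundle.stacks["2000"]
    soil = (
        stack.layers["soil_silt"]
        + stack.layers["soil_clay"]
        + stack.layers["soil_sand"]
    )
    np.testing.assert_allclose(soil, 1.0, atol=1e-9)
    ndvi = stack.layers["ndvi"]
    assert ndvi.min() >= 0.0 and ndvi.max() <= 1.0
    for name in ("dist_urban", "dist_settlement", "dist_road", "dist_river"):
        dist = stack.layers[name]
        assert dist.min() == 0.0  # zero on feature cells
        assert (dist >= 0).all()
    assert (stack.layers["precipitation"] >= 300).all()
    assert (stack.layers["precipitation"] <= 1600).all()
    assert stack.layers["urbanization"].min() >= 0
    assert stack.layers["urbanization"].max() <= 1


def test_composition_closure_every_year(small_bundle):
    for comp in small_bundle.compositions.values():
        np.testing.assert_allclose(comp.fractions.sum(axis=0), 1.0, atol=1e-9)
        assert comp.fractions.min() >= -1e-12


def test_uniform_logit_gives_one_sixth():
    spec = ep.GridSpec(8, 8)
    scenario = Scenario(
        class_weights=np.zeros((6, 15)),
        intercepts=np.zeros(6),
        transition_rules=[],
    )
    elev, slope = generate_terrain(spec, seed=1)
    stack = generate_covariates(elev, slope, spec, scenario, seed=2)
    comps, _ = generate_landuse(stack, scenario, seed=3)
    for comp in comps.values():
        np.testing.assert_allclose(comp.fractions, 1.0 / 6.0, atol=1e-12)


def test_zero_probability_transition_is_identity():
    spec = ep.GridSpec(8, 8)
    scenario = Scenario(
        transition_rules=[TransitionRule("cropland", "forestland", "slope", ">", 15.0, 0.0)]
    )
    elev, slope = generate_terrain(spec, seed=1)
    stack = generate_covariates(elev, slope, spec, scenario, seed=2)
    comps, _ = generate_landuse(stack, scenario, seed=3)
    years = list(comps)
    np.testing.assert_array_equal(
        comps[years[0]].fractions, comps[years[-1]].fractions
    )


def test_forest_fraction_monotone_in_elevation():
    # single huge positive forest weight on elevation -> forest share is a
    # strictly increasing function of elevation across cells
    bundle = ep.generate_bundle(ep.GridSpec(20, 20), Scenario.strong_signal("elevation"))
    forest = bundle.compositions["2000"].fractions[LAND_CLASSES.index("forestland")]
    order = np.argsort(bundle.elevation.ravel())
    sorted_forest = forest.ravel()[order]
    assert np.all(np.diff(sorted_forest) >= -1e-12)
    assert sorted_forest[-1] > sorted_forest[0]


def test_bundle_reproducibility():
    a = ep.generate_bundle(ep.GridSpec(12, 12), Scenario(seed=9))
    b = ep.generate_bundle(ep.GridSpec(12, 12), Scenario(seed=9))
    np.testing.assert_array_equal(a.elevation, b.elevation)
    for year in a.compositions:
        np.testing.assert_array_equal(
            a.compositions[year].fractions, b.compositions[year].fractions
        )
        np.testing.assert_array_equal(
            a.stacks[year].as_matrix(), b.stacks[year].as_matrix()
        )
    assert a.truth_ranking == b.truth_ranking


def test_scenario_validation_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ConfigurationError):
        w = np.zeros((6, 15))
        w[0, 0] = np.inf
        Scenario(class_weights=w)
    with pytest.raises(ConfigurationError):
        TransitionRule("cropland", "forestland", "slope", ">", 15.0, 1.5)
    sc = Scenario(seed=4)
    sc.to_yaml(tmp_path / "scenario.yaml")
    back = Scenario.from_yaml(tmp_path / "scenario.yaml")
    np.testing.assert_array_equal(back.class_weights, sc.class_weights)
    assert back.years == sc.years
    assert back.transition_rules == sc.transition_rules


def test_truth_ranking_orders_by_weight_strength():
    sc = Scenario.strong_signal("pop_density")
    assert sc.driver_ranking()[0] == "pop_density"
    assert set(sc.driver_ranking()) == set(FACTOR_NAMES)
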