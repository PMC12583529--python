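"""Model library: published defaults, right-hand sides, coupling structure."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from osctune import MODEL_NAMES, evaluate_rhs, make_model
from osctune.models import model_from_config, model_to_config

from oracles import ORACLES, PRINTED_PARAMS

N_STATES = {
    "cell_cycle": 10,
    "fitzhugh_nagumo": 12,
    "goodwin": 10,
    "repressilator": 20,
    "predator_prey": 8,
    "van_der_pol": 12,
    "neuromechanical": 12,
}


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_state_counts_and_competitive_pair(name):
    m = make_model(name)
    assert m.n_states == N_STATES[name]
    i, j = m.competitive_pair
    assert i != j
    assert 0 <= i < m.n_states and 0 <= j < m.n_states


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_published_defaults_match_name_by_name(name):
    """Every published constant equals the coded default, name by name."""
    params = make_model(name).default_params
    for key, value in PRINTED_PARAMS[name].items():
        assert params[key] == pytest.approx(value, abs=0.0), (name, key)
    # the controls default to the antiphase-preserving baseline with
    # auxiliary feedback off
    assert params["pos"] == 0.0 and params["neg"] == 0.0
    assert params["k1"] > 0 and params["k2"] > 0


def test_make_model_override_controls():
    m = make_model("cell_cycle", {"pos": 0.0, "neg": 0.0})
    assert m.params["pos"] == 0.0 and m.params["neg"] == 0.0
    m = make_model("goodwin", {"pos": 0.5})
    assert m.params["pos"] == 0.5
    assert m.params["neg"] == make_model("goodwin").params["neg"]


def test_make_model_examples_van_der_pol():
    m = make_model("van_der_pol", {})
    assert m.params["tau"] == 3.0
    assert m.params["mu"] == 0.1
    assert m.params["a31"] == 0.15
    assert m.params["a51"] == 1.0


def test_make_model_errors():
    with pytest.raises(KeyError):
        make_model("lotka_volterra")
    with pytest.raises(KeyError):
        make_model("goodwin", {"does_not_exist": 1.0})
    with pytest.raises(ValueError):
        make_model("goodwin", {"pos": -0.1})


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_rhs_matches_independent_transcription(name, rng):
    """Second hand-transcription of the published equations as oracle."""
    m = make_model(name, {"k1": 0.8, "k2": 0.6, "pos": 0.4, "neg": 0.3})
    p = dict(m.params)
    for _ in range(100):
        y = rng.uniform(-0.5, 3.0, size=m.n_states)
        ours = evaluate_rhs(m, y)
        ref = ORACLES[name](y, p)
        scale = np.maximum(np.abs(ref), 1.0)
        assert np.max(np.abs(ours - ref) / scale) < 1e-12


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_rhs_autonomous_and_deterministic(name, rng):
    m = make_model(name)
    y = rng.uniform(0.0, 1.0, size=m.n_states)
    d1 = evaluate_rhs(m, y, t=0.0)
    d2 = evaluate_rhs(m, y, t=123.4)
    d3 = evaluate_rhs(m, y, t=0.0)
    assert np.array_equal(d1, d2)
    assert np.array_equal(d1, d3)


def test_rhs_input_validation():
    m = make_model("goodwin")
    with pytest.raises(ValueError):
        evaluate_rhs(m, np.zeros(3))
    bad = np.zeros(m.n_states)
    bad[0] = np.nan
    with pytest.raises(ValueError):
        evaluate_rhs(m, bad)


def test_fhn_nonlinearity_roots_and_sigmoid_midpoint():
    # F(V) = -V + V^3/3 vanishes at V = 0 and V = sqrt(3); with all W = 0,
    # pos = neg = 0, k1 = k2 = 0 and I_in = 0 the V-derivative reduces to -F(V)
    m = make_model("fitzhugh_nagumo", {"k1": 0.0, "k2": 0.0, "I_in": 0.0,
                                       "a31": 0.0, "a42": 0.0,
                                       "a51": 0.0, "a62": 0.0})
    for v in (0.0, math.sqrt(3.0)):
        y = np.zeros(12)
        y[:6] = v
        d = evaluate_rhs(m, y)
        assert np.allclose(d[:6], 0.0, atol=1e-12)
    # synaptic sigmoid midpoint: neuron 3 at V_th contributes a13 * 1/2
    p = make_model("fitzhugh_nagumo").params
    base = make_model("fitzhugh_nagumo", {"neg": 0.0})
    mid = make_model("fitzhugh_nagumo", {"neg": 1.0})
    y = np.zeros(12)
    y[2] = p["V_th"]  # V3 at threshold
    delta = evaluate_rhs(base, y)[0] - evaluate_rhs(mid, y)[0]
    assert delta == pytest.approx(0.5, rel=1e-12)


def test_van_der_pol_origin_fixed_point():
    m = make_model("van_der_pol", {"pos": 0.7, "neg": 0.4})
    assert np.allclose(evaluate_rhs(m, np.zeros(12)), 0.0, atol=0.0)


def test_predator_prey_carrying_capacity():
    # with no predators or companions, prey at K is a fixed point
    m = make_model("predator_prey")
    y = np.zeros(8)
    y[0] = m.params["K"]
    assert evaluate_rhs(m, y)[0] == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize(
    "name,obs_idx,partner_idx",
    [
        ("cell_cycle", 0, 1),
        ("cell_cycle", 1, 0),
        ("fitzhugh_nagumo", 0, 1),
        ("van_der_pol", 0, 1),
        ("repressilator", 10, 13),
    ],
)
def test_coupling_nullity_when_all_controls_zero(name, obs_idx, partner_idx, rng):
    """With k1 = k2 = pos = neg = 0 the competitive cross-terms vanish."""
    m = make_model(name, {"k1": 0.0, "k2": 0.0, "pos": 0.0, "neg": 0.0})
    y = rng.uniform(0.2, 1.5, size=m.n_states)
    eps = 1e-4
    y_hi = y.copy()
    y_hi[partner_idx] += eps
    sens = (evaluate_rhs(m, y_hi)[obs_idx] - evaluate_rhs(m, y)[obs_idx]) / eps
    assert sens == pytest.approx(0.0, abs=1e-9)


@given(
    cdh1=st.floats(0.1, 15.0),
    bump=st.floats(1e-3, 5.0),
)
def test_cell_cycle_inhibition_monotone(cdh1, bump):
    """More Cdh1 never increases dCycB/dt (Hill repression), and vice versa."""
    m = make_model("cell_cycle", {"k1": 1.0, "k2": 1.0})
    y = np.full(10, 2.0)
    y[1] = cdh1
    d_lo = evaluate_rhs(m, y)[0]
    y[1] = cdh1 + bump
    d_hi = evaluate_rhs(m, y)[0]
    assert d_hi <= d_lo + 1e-12
    # symmetric: CycB inhibits Cdh1
    y = np.full(10, 2.0)
    y[0] = cdh1
    d_lo = evaluate_rhs(m, y)[1]
    y[0] = cdh1 + bump
    d_hi = evaluate_rhs(m, y)[1]
    assert d_hi <= d_lo + 1e-12


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_config_round_trip_is_lossless(name):
    import yaml

    m = make_model(name, {"k1": 0.123456789012345, "pos": 1e-17})
    cfg = model_to_config(m)
    restored = model_from_config(yaml.safe_load(yaml.safe_dump(cfg)))
    assert restored.params == m.params
    assert restored.name == m.name
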