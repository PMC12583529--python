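"""Integrator contracts: accuracy oracles, determinism, burn-in policy."""

import numpy as np
import pytest

from osctune import (
    IntegrationError,
    Trajectory,
    estimate_burn_in,
    integrate,
    make_model,
)
from osctune.models import ModelSpec
from osctune.params import ParameterSet
from osctune.signals import FixtureSpec, generate_fixture

_NULL = ParameterSet({"k1": 0.0, "k2": 0.0, "pos": 0.0, "neg": 0.0})


def _toy_model(name, state_names, rhs, pair=(0, 0)):
    return ModelSpec(
        name=name,
        state_names=state_names,
        competitive_pair=pair,
        params=_NULL,
        rhs=rhs,
    )


def test_linear_decay_matches_closed_form():
    m = _toy_model("decay", ("x",), lambda t, y: -y)
    traj = integrate(m, horizon=1.0, dt_out=0.01, y0=np.array([1.0]),
                     burn_in="none")
    assert abs(traj.states[-1, 0] - np.exp(-1.0)) < 1e-6


def test_harmonic_oscillator_conserves_energy():
    m = _toy_model(
        "harmonic", ("x", "y"),
        lambda t, y: np.array([y[1], -y[0]]), pair=(0, 1),
    )
    traj = integrate(m, horizon=100.0, dt_out=0.05, y0=np.array([1.0, 0.0]),
                     burn_in="none")
    energy = traj.states[:, 0] ** 2 + traj.states[:, 1] ** 2
    assert np.max(np.abs(energy - 1.0)) < 1e-5


def test_integration_is_bitwise_deterministic():
    m = make_model("goodwin")
    a = integrate(m, horizon=200.0, dt_out=0.1, seed=7)
    b = integrate(m, horizon=200.0, dt_out=0.1, seed=7)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.times, b.times)
    assert a.transient_cutoff == b.transient_cutoff


def test_different_seeds_draw_different_initial_conditions():
    m = make_model("goodwin")
    a = integrate(m, horizon=10.0, dt_out=0.1, seed=1, burn_in="none")
    b = integrate(m, horizon=10.0, dt_out=0.1, seed=2, burn_in="none")
    assert not np.array_equal(a.states[0], b.states[0])
    assert np.all((a.states[0] >= 0.0) & (a.states[0] <= 1.0))


def test_blowup_reports_integration_error():
    m = _toy_model("blowup", ("x",), lambda t, y: y**2)
    with pytest.raises(IntegrationError):
        integrate(m, horizon=10.0, dt_out=0.01, y0=np.array([1.0]))


def test_invalid_arguments_rejected():
    m = make_model("goodwin")
    with pytest.raises(ValueError):
        integrate(m, horizon=-1.0)
    with pytest.raises(ValueError):
        integrate(m, horizon=10.0, dt_out=0.0)


def test_burn_in_steady_sinusoid_cuts_early():
    traj = generate_fixture(FixtureSpec(kind="sinusoid", duration=400.0, dt=0.1))
    cut = estimate_burn_in(traj)
    assert cut <= 0.1 * len(traj.times)


def test_burn_in_decaying_envelope_waits_out_transient():
    decay = 30.0
    traj = generate_fixture(
        FixtureSpec(
            kind="decaying_transient", duration=600.0, dt=0.1,
            decay_time=decay, transient_scale=1.0,
        )
    )
    cut = estimate_burn_in(traj)
    # the 1% amplitude-stabilization rule cannot trigger before the envelope
    # has decayed for ~3 time constants
    assert traj.times[cut] >= 3.0 * decay


def test_burn_in_constant_signal_falls_back_to_half():
    traj = generate_fixture(FixtureSpec(kind="constant", duration=400.0, dt=0.1))
    cut = estimate_burn_in(traj)
    assert cut == len(traj.times) // 2


def test_burn_in_requires_enough_samples():
    traj = generate_fixture(FixtureSpec(kind="sinusoid", duration=5.0, dt=0.1))
    with pytest.raises(ValueError):
        estimate_burn_in(traj)


def test_trajectory_validates_shapes():
    with pytest.raises(ValueError):
        Trajectory(
            times=np.arange(5.0),
            states=np.zeros((4, 2)),
            model_name="bad",
            state_names=("a", "b"),
            competitive_pair=(0, 1),
            params=_NULL,
            seed=0,
        )


def test_step_halving_consistency_on_cell_cycle():
    """Halved output step and tighter tolerances move amplitude and
    frequency by < 0.5% at the default antiphase configuration."""
    from osctune import summarize_oscillation

    m = make_model("cell_cycle")
    coarse = integrate(m, horizon=500.0, dt_out=0.25, seed=3,
                       rtol=1e-6, atol=1e-9)
    fine = integrate(m, horizon=500.0, dt_out=0.125, seed=3,
                     rtol=1e-8, atol=1e-11)
    s_c = summarize_oscillation(coarse, "CycB")
    s_f = summarize_oscillation(fine, "CycB")
    assert s_c.is_oscillatory and s_f.is_oscillatory
    assert abs(s_c.amplitude - s_f.amplitude) / s_f.amplitude < 0.005
    assert abs(s_c.frequency - s_f.frequency) / s_f.frequency < 0.005


def test_limit_cycle_independent_of_seed():
    """Five seeds land on the same cell-cycle attractor (within 1%)."""
    from osctune import summarize_oscillation

    amps, freqs = [], []
    m = make_model("cell_cycle")
    for seed in range(1, 6):
        traj = integrate(m, horizon=500.0, seed=seed, rtol=1e-6, atol=1e-9)
        s = summarize_oscillation(traj, "CycB")
        assert s.is_oscillatory
        amps.append(s.amplitude)
        freqs.append(s.frequency)
    assert (max(amps) - min(amps)) / np.mean(amps) < 0.01
    assert (max(freqs) - min(freqs)) / np.mean(freqs) < 0.01
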