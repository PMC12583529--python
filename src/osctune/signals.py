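"""Synthetic oscillatory signals with analytically known features.

These fixtures exercise the feature-extraction code independently of the ODE
models: every generated trace carries its ground-truth amplitude, frequency
and pairwise correlation in ``Trajectory.meta["truth"]``, exact when
``noise_sd = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sawtooth

from .integrate import Trajectory
from .params import ParameterSet

__all__ = ["FixtureSpec", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "sinusoid",
    "relaxation",
    "constant",
    "decaying_transient",
    "two_tone",
    "antiphase_pair",
)

_NULL_PARAMS = ParameterSet({"k1": 0.0, "k2": 0.0, "pos": 0.0, "neg": 0.0})


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic trace (or pair of traces).

    ``amplitude``/``frequency``/``phase`` describe the primary component;
    ``offset`` shifts the mean.  ``two_tone`` adds a secondary component
    (``amplitude2``, ``frequency2``); ``decaying_transient`` multiplies an
    extra transient of relative size ``transient_scale`` decaying with time
    constant ``decay_time``; ``antiphase_pair`` emits a second channel
    shifted by ``pair_phase`` (π for exact antiphase).
    """

    kind: str
    amplitude: float = 1.0
    frequency: float = 0.05
    phase: float = 0.0
    offset: float = 0.0
    noise_sd: float = 0.0
    duration: float = 400.0
    dt: float = 0.1
    seed: int = 0
    amplitude2: float = 0.0
    frequency2: float = 0.0
    decay_time: float = 0.0
    transient_scale: float = 1.0
    pair_phase: float = np.pi

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; one of {FIXTURE_KINDS}"
            )
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_fixture(spec: FixtureSpec) -> Trajectory:
    """Deterministically generate the trace(s) described by ``spec``.

    The returned trajectory has ``transient_cutoff = 0`` (fixtures carry no
    burn-in unless the kind itself models one) and ground truth in
    ``meta["truth"]`` with keys ``amplitude``, ``frequency``,
    ``is_oscillatory`` and, for pairs, ``correlation``.
    """
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    w = 2.0 * np.pi * spec.frequency
    rng = np.random.default_rng(spec.seed)
    truth: dict = {
        "amplitude": spec.amplitude,
        "frequency": spec.frequency,
        "is_oscillatory": True,
    }
    names: tuple[str, ...] = ("x",)

    if spec.kind == "sinusoid":
        x = spec.offset + spec.amplitude * np.sin(w * t + spec.phase)
        channels = [x]
    elif spec.kind == "relaxation":
        # asymmetric sawtooth: fast rise, slow fall; amplitude is half range
        x = spec.offset + spec.amplitude * sawtooth(w * t + spec.phase, width=0.1)
        channels = [x]
    elif spec.kind == "constant":
        x = np.full_like(t, spec.offset)
        channels = [x]
        truth.update(amplitude=0.0, frequency=0.0, is_oscillatory=False)
    elif spec.kind == "decaying_transient":
        envelope = 1.0 + spec.transient_scale * np.exp(-t / max(spec.decay_time, 1e-12))
        x = spec.offset + spec.amplitude * envelope * np.sin(w * t + spec.phase)
        channels = [x]
        truth["decay_time"] = spec.decay_time
    elif spec.kind == "two_tone":
        x = (
            spec.offset
            + spec.amplitude * np.sin(w * t + spec.phase)
            + spec.amplitude2 * np.sin(2.0 * np.pi * spec.frequency2 * t)
        )
        channels = [x]
        truth["dominant_frequency"] = (
            spec.frequency if spec.amplitude >= spec.amplitude2 else spec.frequency2
        )
    else:  # antiphase_pair
        x = spec.offset + spec.amplitude * np.sin(w * t + spec.phase)
        y = spec.offset + spec.amplitude * np.sin(w * t + spec.phase + spec.pair_phase)
        channels = [x, y]
        names = ("x", "y")
        truth["correlation"] = float(np.cos(spec.pair_phase))

    if spec.noise_sd > 0:
        channels = [c + rng.normal(0.0, spec.noise_sd, size=t.shape) for c in channels]

    states = np.column_stack(channels)
    pair = (0, 1) if len(channels) == 2 else (0, 0)
    return Trajectory(
        times=t,
        states=states,
        model_name=f"fixture_{spec.kind}",
        state_names=names,
        competitive_pair=pair,
        params=_NULL_PARAMS,
        seed=spec.seed,
        transient_cutoff=0,
        meta={"truth": truth, "spec": vars(spec).copy()},
    )
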