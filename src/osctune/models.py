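"""Seven competitive biological oscillator models.

Each model couples two oscillatory subsystems through mutual inhibition
(controls ``k1``, ``k2``) and decorates the competing pair with auxiliary
positive and negative feedback loops (controls ``pos``, ``neg``):

``cell_cycle``
    Ten-species mammalian cell-cycle network built around the CycB/Cdh1
    antagonism, with Cdc25/Cdc14 positive loops and E2F/CycE negative loops.
``fitzhugh_nagumo``
    Six FitzHugh-Nagumo neurons; neurons 1 and 2 mutually inhibit, neurons
    3/4 close negative loops and 5/6 close positive loops onto them.
``goodwin``
    Plant circadian clock (LHY/TOC1 mutual repression) written as two
    extended Goodwin oscillators with PRR/LNK/RVE modulators.
``repressilator``
    Two three-gene repressilator rings whose reporter proteins degrade each
    other, plus four auxiliary regulator genes.
``predator_prey``
    Two predator-prey patches with competing predators, parasitic (negative)
    and mutualistic (positive) companion species.
``van_der_pol``
    Six Van der Pol units modelling mutually inhibitory brain regions with
    excitatory/inhibitory companions.
``neuromechanical``
    Two neuron-muscle loops with mechanically coupled, mutually inhibiting
    muscles, gap-junction interneurons and mechanical positive feedback.

Inhibitory edges receive their negative sign internally, so all four
controls are supplied as nonnegative magnitudes.

The right-hand-side cores are written to be ``numba``-compilable (they fall
back to plain NumPy when numba is unavailable), which keeps large parameter
sweeps desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Callable, Mapping

import numpy as np

from .params import ParameterSet

try:  # compiled cores; pure-NumPy fallback keeps results identical
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover - numba is normally present
    def _jit(func):
        return func

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "make_model",
    "evaluate_rhs",
    "model_to_config",
    "model_from_config",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named ODE system with its parameters and competing observables.

    ``rhs`` is the time-derivative map ``f(t, y) -> dy/dt`` with the
    parameters already bound; all models are autonomous so ``t`` is unused.
    ``competitive_pair`` indexes the two mutually inhibited observables in
    ``state_names``.
    """

    name: str
    state_names: tuple[str, ...]
    competitive_pair: tuple[int, int]
    params: ParameterSet
    rhs: Callable[[float, np.ndarray], np.ndarray] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def default_params(self) -> ParameterSet:
        return self.params


@_jit
def _hill_act(x, theta, n):
    """Activating Hill term x^n / (theta^n + x^n), with x clamped at 0.

    The clamp guards against transiently negative states raising a negative
    base to a large power; it is applied inside the regulatory term only,
    never to the integrated state.
    """
    if x < 0.0:
        x = 0.0
    xn = x**n
    return xn / (theta**n + xn)


@_jit
def _switch(x, th):
    """Steep threshold switch 1 / (1 + exp((th - x)/0.01)), overflow-safe."""
    z = (th - x) * 100.0
    if z > 500.0:
        return 0.0
    if z < -500.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# cell cycle
# ---------------------------------------------------------------------------

_CELL_CYCLE_STATES = (
    "CycB", "Cdh1", "APC", "Cdc20", "Plk1",
    "Emi1", "E2F", "CycE", "Cdc25", "Cdc14",
)

_CELL_CYCLE_DEFAULTS = {
    "k1": 1.0, "k2": 1.0, "pos": 0.0, "neg": 0.0,
    "tau1": 7.0, "tau2": 11.5,
    "ks_CycB": 10.0, "ka_CycB": 10.0, "ka_CycB_p": 10.0,
    "kd_CycB": 1.0, "kd_CycB_p": 10.0, "kd_CycB_pp": 10.0,
    "ks_Cdh1": 10.0, "ka_Cdh1": 10.0,
    "kd_Cdh1": 1.0, "kd_Cdh1_p": 10.0, "kd_Cdh1_pp": 10.0, "ki_Cdh1": 10.0,
    "ka_APC": 1.0, "kd_APC": 1.0,
    "ka_Cdc20": 1.0, "kd_Cdc20": 1.0,
    "ks_Plk1": 10.0, "kd_Plk1": 1.0,
    "ks_Emi1": 10.0, "kd_Emi1": 1.0, "kd_Emi1_p": 10.0,
    "ks_E2F": 10.0, "kd_E2F": 1.0, "kd_E2F_p": 10.0,
    "ks_CycE": 10.0, "kd_CycE": 5.0, "kd_CycE_p": 5.0,
    "ka_Cdc25": 1.0, "kd_Cdc25": 1.0,
    "ka_Cdc14": 1.0, "kd_Cdc14": 1.0,
    "n": 4.0,
    "th_CycB": 5.0, "th_Cdh1": 5.0, "th_Cdc25": 5.0, "th_Cdc20": 5.0,
    "th_Cdc14": 5.0, "th_Plk1": 5.0, "th_Emi1": 5.0, "th_APC": 5.0,
    "th_E2F": 5.0, "th_CycE": 5.0,
    "APC_tot": 22.0, "Cdc20_tot": 22.0, "Cdc25_tot": 22.0, "Cdc14_tot": 22.0,
}

_CC_ORDER = (
    "k1", "k2", "pos", "neg", "tau1", "tau2", "n",
    "ks_CycB", "ka_CycB", "ka_CycB_p", "kd_CycB", "kd_CycB_p", "kd_CycB_pp",
    "ks_Cdh1", "ka_Cdh1", "kd_Cdh1", "kd_Cdh1_p", "kd_Cdh1_pp", "ki_Cdh1",
    "ka_APC", "kd_APC", "ka_Cdc20", "kd_Cdc20",
    "ks_Plk1", "kd_Plk1", "ks_Emi1", "kd_Emi1", "kd_Emi1_p",
    "ks_E2F", "kd_E2F", "kd_E2F_p", "ks_CycE", "kd_CycE", "kd_CycE_p",
    "ka_Cdc25", "kd_Cdc25", "ka_Cdc14", "kd_Cdc14",
    "th_CycB", "th_Cdh1", "th_Cdc25", "th_Cdc20", "th_Cdc14",
    "th_Plk1", "th_Emi1", "th_APC", "th_E2F", "th_CycE",
    "APC_tot", "Cdc20_tot", "Cdc25_tot", "Cdc14_tot",
)


@_jit
def _cell_cycle_core(t, y, c):
    k1 = c[0]; k2 = c[1]; kp = c[2]; kn = c[3]
    tau1 = c[4]; tau2 = c[5]; n = c[6]
    (CycB, Cdh1, APC, Cdc20, Plk1, Emi1, E2F, CycE, Cdc25, Cdc14) = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8], y[9],
    )
    th_CycB = c[38]; th_Cdh1 = c[39]; th_Cdc25 = c[40]; th_Cdc20 = c[41]
    th_Cdc14 = c[42]; th_Plk1 = c[43]; th_Emi1 = c[44]; th_APC = c[45]
    th_E2F = c[46]; th_CycE = c[47]
    d = np.empty(10)
    d[0] = (
        c[7] - c[10] * CycB
        + c[8] * _hill_act(kp * Cdc25, th_Cdc25, n)
        + c[9] * _hill_act(E2F, th_E2F, n)
        - (
            c[11] * _hill_act(Cdc20, th_Cdc20, n)
            + c[12] * _hill_act(k1 * Cdh1, th_Cdh1, n)
        )
        * CycB
    ) / tau1
    d[1] = (
        c[13] - c[15] * Cdh1
        + c[14] * _hill_act(kp * Cdc14, th_Cdc14, n)
        - (
            c[16] * _hill_act(Emi1, th_Emi1, n)
            + c[17] * _hill_act(kn * CycE, th_CycE, n)
            + c[18] * _hill_act(k2 * CycB, th_CycB, n)
        )
        * Cdh1
    ) / tau2
    d[2] = (c[19] * _hill_act(CycB, th_CycB, n) * (c[48] - APC) - c[20] * APC) / tau1
    d[3] = (
        c[21] * _hill_act(APC, th_APC, n) * (c[49] - Cdc20) - c[22] * Cdc20
    ) / tau1
    d[4] = (
        c[23] - c[24] * Cdh1 - c[16] * _hill_act(Cdh1, th_Cdh1, n) * Plk1
    ) / tau2
    d[5] = (
        c[25] - c[26] * Emi1 - c[27] * _hill_act(Plk1, th_Plk1, n) * Emi1
    ) / tau2
    d[6] = (c[28] - (c[29] + c[30] * _hill_act(kn * CycB, th_CycB, n)) * E2F) / tau1
    d[7] = (c[31] - (c[32] - c[33] * _hill_act(Cdh1, th_Cdh1, n)) * CycE) / tau2
    d[8] = (
        c[34] * _hill_act(CycB, th_CycB, n) * (c[50] - Cdc25) - c[35] * Cdc25
    ) / tau1
    d[9] = (
        c[36] * _hill_act(Cdh1, th_Cdh1, n) * (c[51] - Cdc14) - c[15] * Cdc14
    ) / tau2
    return d


def _cell_cycle_rhs(p: Mapping[str, float]):
    c = np.array([p[k] for k in _CC_ORDER])
    return lambda t, y: _cell_cycle_core(t, y, c)


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo network
# ---------------------------------------------------------------------------

_FHN_STATES = tuple(f"V{i}" for i in range(1, 7)) + tuple(
    f"W{i}" for i in range(1, 7)
)

# V_th and theta_th appear in the synaptic sigmoid but carry no published
# value; V_th = 0 centres the sigmoid on the cubic nullcline's inflection and
# theta_th = 0.5 gives a graded synapse over the ~[-2, 2] voltage swing.
_FHN_DEFAULTS = {
    "k1": 1.0, "k2": 1.0, "pos": 0.0, "neg": 0.0,
    "C": 1.0, "L": 12.5, "E": 0.7, "R": 0.8, "I_in": 1.0,
    "a31": 1.0, "a42": 1.0, "a51": 0.9, "a62": 0.9,
    "V_th": 0.0, "theta_th": 0.5,
}


def _fhn_coupling(p: Mapping[str, float]) -> np.ndarray:
    # a[i, j]: effect of neuron j+1 on neuron i+1; inhibitory edges negative
    a = np.zeros((6, 6))
    a[0, 1] = -p["k1"]
    a[1, 0] = -p["k2"]
    a[2, 0] = p["a31"]
    a[3, 1] = p["a42"]
    a[4, 0] = p["a51"]
    a[5, 1] = p["a62"]
    a[0, 2] = -p["neg"]
    a[1, 3] = -p["neg"]
    a[0, 4] = p["pos"]
    a[1, 5] = p["pos"]
    return a


@_jit
def _fhn_core(t, y, a, C, L, E, R, I_in, V_th, th):
    V = y[:6]
    W = y[6:]
    z = np.clip(-(V - V_th) / th, -500.0, 500.0)
    S = 1.0 / (1.0 + np.exp(z))
    I = I_in + a @ S
    d = np.empty(12)
    d[:6] = (I - (-V + V**3 / 3.0) - W) / C
    d[6:] = (E - R * W + V) / L
    return d


def _fhn_rhs(p: Mapping[str, float]):
    a = _fhn_coupling(p)
    C, L, E, R = p["C"], p["L"], p["E"], p["R"]
    I_in, V_th, th = p["I_in"], p["V_th"], p["theta_th"]
    return lambda t, y: _fhn_core(t, y, a, C, L, E, R, I_in, V_th, th)


# ---------------------------------------------------------------------------
# Goodwin plant-clock oscillator
# ---------------------------------------------------------------------------

_GOODWIN_STATES = (
    "X1_LHY_mRNA", "Y1_LHY", "Z1_PRR9", "U1_PRR7", "W1_LNK1",
    "X2_TOC1_mRNA", "Y2_TOC1", "Z2_GI", "U2_RVE6", "W2_PRR5",
)

_GOODWIN_DEFAULTS = {
    "k1": 1.0, "k2": 1.0, "pos": 0.0, "neg": 0.0,
    "n": 9.0,
    "v1": 1.0, "v2": 0.2, "v3": 1.0, "v4": 0.2, "v5": 1.0, "v6": 0.2,
    "v7": 0.3, "v8": 0.2, "v9": 0.3, "v10": 0.2, "v11": 0.2, "v12": 0.2,
    "v13": 1.0, "v14": 0.2, "v15": 0.2, "v16": 0.2, "v17": 0.3, "v18": 0.2,
    "v19": 0.3, "v20": 0.2, "v21": 0.3,
}

_GOODWIN_ORDER = ("k1", "k2", "pos", "neg", "n") + tuple(
    f"v{i}" for i in range(1, 22)
)


@_jit
def _goodwin_core(t, y, c):
    k1 = c[0]; k2 = c[1]; vp = c[2]; vn = c[3]; n = c[4]
    X1, Y1, Z1, U1, W1 = y[0], y[1], y[2], y[3], y[4]
    X2, Y2, Z2, U2, W2 = y[5], y[6], y[7], y[8], y[9]
    Z1c = Z1 if Z1 > 0.0 else 0.0
    Z2c = Z2 if Z2 > 0.0 else 0.0
    Y2c = Y2 if Y2 > 0.0 else 0.0
    d = np.empty(10)
    d[0] = c[5] / (1.0 + Z1c**n) - c[6] * X1
    d[1] = (c[7] + vp * W1) * X1 - (c[8] + k1 * Y2 + vn * U1) * Y1
    d[2] = c[9] * Y1 - c[10] * Z1
    d[3] = c[11] * Y1 - c[12] * U1
    d[4] = c[13] * Y1 - c[14] * W1
    d[5] = c[15] * Z2c**n / (1.0 + Z2c**n) - c[16] * X2
    d[6] = (c[17] + vp * W2 + c[25] * U2) * X2 - (c[18] + k2 * Y1) * Y2
    d[7] = c[19] / (1.0 + Y2c**n) - c[20] * Z2
    d[8] = c[21] / (1.0 + (vn * Y2c) ** n) - c[22] * U2
    d[9] = c[23] * Z2 - c[24] * W2
    return d


def _goodwin_rhs(p: Mapping[str, float]):
    c = np.array([p[k] for k in _GOODWIN_ORDER])
    return lambda t, y: _goodwin_core(t, y, c)


# ---------------------------------------------------------------------------
# interlinked repressilators
# ---------------------------------------------------------------------------

_REPRESSILATOR_STATES = tuple(f"X{i}" for i in range(1, 11)) + tuple(
    f"Y{i}" for i in range(1, 11)
)

_REPRESSILATOR_DEFAULTS = {
    "k1": 1.0, "k2": 1.0, "pos": 0.0, "neg": 0.0,
    "tau": 1.0, "n": 5.0, "alpha": 1.0, "beta": 0.1, "v0": 1.0,
    "b21": 1.0, "b32": 1.0, "b13": 1.0, "b54": 1.0, "b65": 1.0, "b46": 1.0,
    "a71": 1.0, "a84": 1.0, "a91": 1.0, "a104": 1.0,
}


def _repressilator_matrices(p: Mapping[str, float]):
    A = np.zeros((10, 10))  # activation a[i, j]: gene j+1 activates gene i+1
    B = np.zeros((10, 10))  # repression b[i, j]
    Cm = np.zeros((10, 10))  # degradation enhancement c[i, j]
    A[6, 0] = p["a71"]
    A[7, 3] = p["a84"]
    A[8, 0] = p["a91"]
    A[9, 3] = p["a104"]
    A[0, 8] = p["pos"]
    A[3, 9] = p["pos"]
    B[1, 0] = p["b21"]
    B[2, 1] = p["b32"]
    B[0, 2] = p["b13"]
    B[4, 3] = p["b54"]
    B[5, 4] = p["b65"]
    B[3, 5] = p["b46"]
    Cm[0, 3] = p["k1"]
    Cm[3, 0] = p["k2"]
    Cm[0, 6] = p["neg"]
    Cm[3, 7] = p["neg"]
    return A, B, Cm


@_jit
def _repressilator_core(t, y, A, B, Cm, tau, n, alpha, beta, v0):
    d = np.empty(20)
    for i in range(10):
        act = 0.0
        rep = 1.0
        Ci = 0.0
        for j in range(10):
            Yj = y[10 + j]
            Yc = Yj if Yj > 0.0 else 0.0
            if A[i, j] != 0.0:
                ay = (A[i, j] * Yc) ** n
                act += ay / (1.0 + ay)
            if B[i, j] != 0.0:
                rep *= 1.0 / (1.0 + (B[i, j] * Yc) ** n)
            Ci += Cm[i, j] * Yj
        H = (v0 + act) * rep
        d[i] = (-y[i] + H) / tau
        d[10 + i] = (alpha * y[i] - beta * (1.0 + Ci) * y[10 + i]) / tau
    return d


def _repressilator_rhs(p: Mapping[str, float]):
    A, B, Cm = _repressilator_matrices(p)
    tau, n = p["tau"], p["n"]
    alpha, beta, v0 = p["alpha"], p["beta"], p["v0"]
    return lambda t, y: _repressilator_core(t, y, A, B, Cm, tau, n, alpha, beta, v0)


# ---------------------------------------------------------------------------
# predator-prey patches
# ---------------------------------------------------------------------------

_PREDATOR_PREY_STATES = ("X1", "Y1", "X2", "Y2", "Y3", "Y4", "Y5", "Y6")

_PREDATOR_PREY_DEFAULTS = {
    "k1": 1.0, "k2": 1.0, "pos": 0.0, "neg": 0.0,
    "alpha": 1.0, "beta": 1.0, "h": 0.5, "K": 1.0,
    "gamma": 0.45, "delta": 0.2, "omega1": 0.1, "omega2": 0.5,
}

_PP_ORDER = (
    "k1", "k2", "pos", "neg",
    "alpha", "beta", "h", "K", "gamma", "delta", "omega1", "omega2",
)


@_jit
def _predator_prey_core(t, y, c):
    k1 = c[0]; k2 = c[1]; kp = c[2]; kn = c[3]
    al = c[4]; be = c[5]; h = c[6]; K = c[7]
    ga = c[8]; de = c[9]; w1 = c[10]; w2 = c[11]
    X1, Y1, X2, Y2, Y3, Y4, Y5, Y6 = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7],
    )
    f1 = X1 / (X1 + h)
    f2 = X2 / (X2 + h)
    d = np.empty(8)
    d[0] = al * X1 * (1.0 - X1 / K) - be * f1 * Y1
    d[1] = ga * f1 * Y1 + kp * Y1 * Y5 - k1 * Y1 * Y2 - kn * Y1 * Y3 - de * Y1
    d[2] = al * X2 * (1.0 - X2 / K) - be * f2 * Y2
    d[3] = ga * f2 * Y2 + kp * Y2 * Y6 - k2 * Y1 * Y2 - kn * Y2 * Y4 - de * Y2
    d[4] = al * Y3 * (1.0 - Y3 / K) + w1 * Y1 * Y3 - de * Y3
    # the Y4/Y6 growth terms reuse Y3/Y5 in their logistic parts, as
    # published; see docs/methods.md
    d[5] = al * Y3 * (1.0 - Y3 / K) + w1 * Y2 * Y4 - de * Y4
    d[6] = al * Y5 * (1.0 - Y5 / K) + w2 * Y1 * Y5 - de * Y5
    d[7] = al * Y5 * (1.0 - Y5 / K) + w2 * Y2 * Y6 - de * Y6
    return d


def _predator_prey_rhs(p: Mapping[str, float]):
    c = np.array([p[k] for k in _PP_ORDER])
    return lambda t, y: _predator_prey_core(t, y, c)


# ---------------------------------------------------------------------------
# Van der Pol brain regions
# ---------------------------------------------------------------------------

_VDP_STATES = tuple(f"x{i}" for i in range(1, 7)) + tuple(
    f"y{i}" for i in range(1, 7)
)

# Antiphase-preserving competition default: the linearly coupled pair has an
# unbounded antisymmetric mode for k ≳ 0.5, so the "high mutual inhibition"
# baseline sits at k = 0.3, well inside the bounded antiphase regime.
_VDP_DEFAULTS = {
    "k1": 0.3, "k2": 0.3, "pos": 0.0, "neg": 0.0,
    "tau": 3.0, "mu": 0.1,
    "a31": 0.15, "a42": 0.15, "a51": 1.0, "a62": 0.1,
}


def _vdp_coupling(p: Mapping[str, float]) -> np.ndarray:
    a = np.zeros((6, 6))
    a[0, 1] = -p["k1"]
    a[1, 0] = -p["k2"]
    a[0, 2] = -p["neg"]
    a[1, 3] = -p["neg"]
    a[0, 4] = p["pos"]
    a[1, 5] = p["pos"]
    a[2, 0] = p["a31"]
    a[3, 1] = p["a42"]
    a[4, 0] = p["a51"]
    a[5, 1] = p["a62"]
    return a


@_jit
def _vdp_core(t, y, a, tau, mu):
    x = y[:6]
    v = y[6:]
    C = a @ x
    d = np.empty(12)
    d[:6] = (v + C) / tau
    d[6:] = (-x + mu * (1.0 - x**2) * v) / tau
    return d


def _vdp_rhs(p: Mapping[str, float]):
    a = _vdp_coupling(p)
    tau, mu = p["tau"], p["mu"]
    return lambda t, y: _vdp_core(t, y, a, tau, mu)


# ---------------------------------------------------------------------------
# neuromechanical oscillator
# ---------------------------------------------------------------------------

_NEUROMECH_STATES = (
    "x1", "y1", "z1", "x2", "y2", "z2",
    "x3", "x4", "z3", "z4", "x5", "x6",
)

# Antiphase-preserving competition default: at k = 1 the muscle pair is
# bistable between a small non-antiphase cycle and the antiphase limit
# cycle; k = 2 selects the antiphase cycle from random initial conditions.
_NEUROMECH_DEFAULTS = {
    "k1": 2.0, "k2": 2.0, "pos": 0.0, "neg": 0.0,
    "tau": 0.25,
    "v1": 20.0, "v2": 0.2, "v3": 1.0, "v4": 2.0, "v5": 0.5,
    "u_in": 1.0, "E_ex": 2.0, "E_inh": -2.0, "L_max": 2.0,
    "N_th1": 0.5, "N_th2": -0.5, "P_th1": 0.1, "P_th2": -0.1,
    "L_th": 0.01, "V_th": 0.5,
}

_NM_ORDER = (
    "k1", "k2", "pos", "neg", "tau",
    "v1", "v2", "v3", "v4", "v5",
    "u_in", "E_ex", "E_inh", "L_max",
    "N_th1", "N_th2", "P_th1", "P_th2", "L_th", "V_th",
)


@_jit
def _neuromech_core(t, y, c):
    k1 = c[0]; k2 = c[1]; kp = c[2]; kn = c[3]; tau = c[4]
    v1 = c[5]; v2 = c[6]; v3 = c[7]; v4 = c[8]; v5 = c[9]
    u_in = c[10]; E_ex = c[11]; E_inh = c[12]; L_max = c[13]
    N1 = c[14]; N2 = c[15]; P1 = c[16]; P2 = c[17]; L_th = c[18]; V_th = c[19]
    x1, y1, z1, x2, y2, z2 = y[0], y[1], y[2], y[3], y[4], y[5]
    x3, x4, z3, z4, x5, x6 = y[6], y[7], y[8], y[9], y[10], y[11]
    u_neg11 = (E_inh - x1) * _switch(z1, N1) + (E_ex - x1) * (1.0 - _switch(z1, N2))
    u_pos11 = (E_ex - x1) * _switch(z1, P1) + (E_inh - x1) * (1.0 - _switch(z1, P2))
    u_neg22 = (E_inh - x2) * _switch(z2, N1) + (E_ex - x2) * (1.0 - _switch(z2, N2))
    u_pos22 = (E_ex - x2) * _switch(z2, P1) + (E_inh - x2) * (1.0 - _switch(z2, P2))
    u_neg31 = (E_inh - x3) * _switch(z1, N1) + (E_ex - x3) * (1.0 - _switch(z1, N2))
    u_neg42 = (E_inh - x4) * _switch(z2, N1) + (E_ex - x4) * (1.0 - _switch(z2, N2))
    d = np.empty(12)
    d[0] = (-x1 + v1 * u_neg11 + v2 * u_pos11 + v3 * (x3 - x1) + u_in) / tau
    d[1] = (
        -y1
        + v4 * (E_ex - y1) * _switch(x1, V_th)
        + (E_ex - y1) * _switch(x3, V_th)
        + (E_inh - y1) * _switch(x6, V_th)
    ) / tau
    d[2] = (
        -z1
        + (L_max - z1) * _switch(y1, V_th)
        - k1 * z2 * _switch(z2, L_th)
        - kp * z3
    ) / tau
    d[3] = (-x2 + v1 * u_neg22 + v2 * u_pos22 + v3 * (x4 - x2) + u_in) / tau
    d[4] = (
        -y2
        + (E_ex - y2) * _switch(x2, V_th)
        + (E_ex - y2) * _switch(x4, V_th)
        + (E_inh - y2) * _switch(x5, V_th)
    ) / tau
    d[5] = (
        -z2
        + (L_max - z2) * _switch(y2, V_th)
        - k2 * z1 * _switch(z1, L_th)
        - kp * z4
    ) / tau
    d[6] = (-x3 + kn * u_neg31 + v3 * (x1 - x3)) / tau
    d[7] = (-x4 + kn * u_neg42 + v3 * (x2 - x4)) / tau
    d[8] = (-z3 - v5 * z1) / tau
    d[9] = (-z4 - v5 * z2) / tau
    d[10] = (-x5 + (E_ex - x5) * _switch(x1, V_th)) / tau
    d[11] = (-x6 + (E_ex - x6) * _switch(x2, V_th)) / tau
    return d


def _neuromech_rhs(p: Mapping[str, float]):
    c = np.array([p[k] for k in _NM_ORDER])
    return lambda t, y: _neuromech_core(t, y, c)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, dict] = {
    "cell_cycle": {
        "states": _CELL_CYCLE_STATES,
        "pair": (0, 1),
        "defaults": _CELL_CYCLE_DEFAULTS,
        "factory": _cell_cycle_rhs,
    },
    "fitzhugh_nagumo": {
        "states": _FHN_STATES,
        "pair": (0, 1),
        "defaults": _FHN_DEFAULTS,
        "factory": _fhn_rhs,
    },
    "goodwin": {
        "states": _GOODWIN_STATES,
        "pair": (1, 6),
        "defaults": _GOODWIN_DEFAULTS,
        "factory": _goodwin_rhs,
    },
    "repressilator": {
        "states": _REPRESSILATOR_STATES,
        "pair": (10, 13),
        "defaults": _REPRESSILATOR_DEFAULTS,
        "factory": _repressilator_rhs,
    },
    "predator_prey": {
        "states": _PREDATOR_PREY_STATES,
        "pair": (1, 3),
        "defaults": _PREDATOR_PREY_DEFAULTS,
        "factory": _predator_prey_rhs,
    },
    "van_der_pol": {
        "states": _VDP_STATES,
        "pair": (0, 1),
        "defaults": _VDP_DEFAULTS,
        "factory": _vdp_rhs,
    },
    "neuromechanical": {
        "states": _NEUROMECH_STATES,
        "pair": (2, 5),
        "defaults": _NEUROMECH_DEFAULTS,
        "factory": _neuromech_rhs,
    },
}

MODEL_NAMES = tuple(_REGISTRY)


def make_model(name: str, overrides: Mapping[str, float] | None = None) -> ModelSpec:
    """Build a :class:`ModelSpec` from published defaults plus ``overrides``.

    Parameters
    ----------
    name
        One of :data:`MODEL_NAMES`.
    overrides
        Partial parameter map; keys must be valid parameter names of the
        model.  The four controls (``k1``, ``k2``, ``pos``, ``neg``) are
        ordinary keys here.

    Raises
    ------
    KeyError
        Unknown model name or unknown parameter key.
    ValueError
        Negative strength control.
    """
    try:
        entry = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None
    params = ParameterSet(entry["defaults"])
    if overrides:
        params = params.with_overrides(overrides)
    return ModelSpec(
        name=name,
        state_names=entry["states"],
        competitive_pair=entry["pair"],
        params=params,
        rhs=entry["factory"](params),
    )


def evaluate_rhs(model: ModelSpec, state, t: float = 0.0) -> np.ndarray:
    """Evaluate the model's time derivative at ``state``.

    All models are autonomous; ``t`` is accepted for interface symmetry and
    has no effect.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (model.n_states,):
        raise ValueError(
            f"state has shape {y.shape}, expected ({model.n_states},) "
            f"for model {model.name!r}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite entries")
    return np.asarray(model.rhs(t, y), dtype=float)


def model_to_config(model: ModelSpec) -> dict:
    """Flat key-value representation (lossless to full float precision)."""
    return {"model": model.name, "params": model.params.to_dict()}


def model_from_config(config: Mapping) -> ModelSpec:
    """Inverse of :func:`model_to_config`."""
    return make_model(config["model"], config.get("params", {}))
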