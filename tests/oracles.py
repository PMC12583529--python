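"""Independent oracles for the model library.

``PRINTED_PARAMS`` re-transcribes every published constant of the seven
models, and the ``oracle_*`` functions re-derive each right-hand side
directly from the published equations in plain, unoptimized Python.  Both
are kept deliberately separate from the package implementation so they can
serve as a second, independent transcription.
"""

from __future__ import annotations

import math

import numpy as np

# --------------------------------------------------------------------------
# published constants, name by name (controls k1/k2/pos/neg excluded: their
# published role is the swept variable, not a fixed constant)
# --------------------------------------------------------------------------

PRINTED_PARAMS: dict[str, dict[str, float]] = {
    "cell_cycle": {
        "tau1": 7, "tau2": 11.5,
        "ks_CycB": 10, "ka_CycB": 10, "kd_CycB": 1,
        "kd_CycB_p": 10, "kd_CycB_pp": 10, "ka_CycB_p": 10,
        "ks_Cdh1": 10, "ka_Cdh1": 10, "kd_Cdh1": 1,
        "kd_Cdh1_p": 10, "kd_Cdh1_pp": 10, "ki_Cdh1": 10,
        "ka_APC": 1, "kd_APC": 1, "ka_Cdc20": 1, "kd_Cdc20": 1,
        "ks_Plk1": 10, "kd_Plk1": 1,
        "ks_Emi1": 10, "kd_Emi1": 1, "kd_Emi1_p": 10,
        "ka_Cdc25": 1, "kd_Cdc25": 1, "ka_Cdc14": 1, "kd_Cdc14": 1,
        "ks_E2F": 10, "kd_E2F": 1, "kd_E2F_p": 10,
        "ks_CycE": 10, "kd_CycE": 5, "kd_CycE_p": 5,
        "n": 4,
        "th_CycB": 5, "th_Cdh1": 5, "th_Cdc25": 5, "th_Cdc20": 5,
        "th_Cdc14": 5, "th_Plk1": 5, "th_Emi1": 5, "th_APC": 5,
        "th_E2F": 5, "th_CycE": 5,
        "APC_tot": 22, "Cdc20_tot": 22, "Cdc25_tot": 22, "Cdc14_tot": 22,
    },
    "fitzhugh_nagumo": {
        "C": 1, "L": 12.5, "E": 0.7, "R": 0.8, "I_in": 1,
        "a31": 1, "a42": 1, "a51": 0.9, "a62": 0.9,
    },
    "goodwin": {
        "n": 9,
        "v1": 1, "v2": 0.2, "v3": 1, "v4": 0.2, "v5": 1, "v6": 0.2,
        "v7": 0.3, "v8": 0.2, "v9": 0.3, "v10": 0.2, "v11": 0.2,
        "v12": 0.2, "v13": 1, "v14": 0.2, "v15": 0.2, "v16": 0.2,
        "v17": 0.3, "v18": 0.2, "v19": 0.3, "v20": 0.2, "v21": 0.3,
    },
    "repressilator": {
        "tau": 1, "n": 5, "alpha": 1, "beta": 0.1, "v0": 1,
        "b21": 1, "b32": 1, "b13": 1, "b54": 1, "b65": 1, "b46": 1,
        "a71": 1, "a84": 1, "a91": 1, "a104": 1,
    },
    "predator_prey": {
        "alpha": 1, "beta": 1, "h": 0.5, "K": 1,
        "gamma": 0.45, "delta": 0.2, "omega1": 0.1, "omega2": 0.5,
    },
    "van_der_pol": {
        "tau": 3, "mu": 0.1,
        "a31": 0.15, "a42": 0.15, "a51": 1, "a62": 0.1,
    },
    "neuromechanical": {
        "tau": 0.25, "v1": 20, "v2": 0.2, "v3": 1, "v4": 2, "v5": 0.5,
        "u_in": 1, "E_ex": 2, "E_inh": -2, "L_max": 2,
        "N_th1": 0.5, "N_th2": -0.5, "P_th1": 0.1, "P_th2": -0.1,
        "L_th": 0.01, "V_th": 0.5,
    },
}


def _hill_up(x, th, n):
    x = max(x, 0.0)
    return x**n / (th**n + x**n)


def oracle_cell_cycle(y, p):
    k1, k2, kp, kn = p["k1"], p["k2"], p["pos"], p["neg"]
    t1, t2, n = p["tau1"], p["tau2"], p["n"]
    CycB, Cdh1, APC, Cdc20, Plk1, Emi1, E2F, CycE, Cdc25, Cdc14 = y
    dCycB = (
        p["ks_CycB"] - p["kd_CycB"] * CycB
        + p["ka_CycB"] * _hill_up(kp * Cdc25, p["th_Cdc25"], n)
        + p["ka_CycB_p"] * _hill_up(E2F, p["th_E2F"], n)
        - (p["kd_CycB_p"] * _hill_up(Cdc20, p["th_Cdc20"], n)
           + p["kd_CycB_pp"] * _hill_up(k1 * Cdh1, p["th_Cdh1"], n)) * CycB
    ) / t1
    dCdh1 = (
        p["ks_Cdh1"] - p["kd_Cdh1"] * Cdh1
        + p["ka_Cdh1"] * _hill_up(kp * Cdc14, p["th_Cdc14"], n)
        - (p["kd_Cdh1_p"] * _hill_up(Emi1, p["th_Emi1"], n)
           + p["kd_Cdh1_pp"] * _hill_up(kn * CycE, p["th_CycE"], n)
           + p["ki_Cdh1"] * _hill_up(k2 * CycB, p["th_CycB"], n)) * Cdh1
    ) / t2
    dAPC = (p["ka_APC"] * _hill_up(CycB, p["th_CycB"], n) * (p["APC_tot"] - APC)
            - p["kd_APC"] * APC) / t1
    dCdc20 = (p["ka_Cdc20"] * _hill_up(APC, p["th_APC"], n) * (p["Cdc20_tot"] - Cdc20)
              - p["kd_Cdc20"] * Cdc20) / t1
    dPlk1 = (p["ks_Plk1"] - p["kd_Plk1"] * Cdh1
             - p["kd_Cdh1_p"] * _hill_up(Cdh1, p["th_Cdh1"], n) * Plk1) / t2
    dEmi1 = (p["ks_Emi1"] - p["kd_Emi1"] * Emi1
             - p["kd_Emi1_p"] * _hill_up(Plk1, p["th_Plk1"], n) * Emi1) / t2
    dE2F = (p["ks_E2F"]
            - (p["kd_E2F"] + p["kd_E2F_p"] * _hill_up(kn * CycB, p["th_CycB"], n))
            * E2F) / t1
    dCycE = (p["ks_CycE"]
             - (p["kd_CycE"] - p["kd_CycE_p"] * _hill_up(Cdh1, p["th_Cdh1"], n))
             * CycE) / t2
    dCdc25 = (p["ka_Cdc25"] * _hill_up(CycB, p["th_CycB"], n) * (p["Cdc25_tot"] - Cdc25)
              - p["kd_Cdc25"] * Cdc25) / t1
    dCdc14 = (p["ka_Cdc14"] * _hill_up(Cdh1, p["th_Cdh1"], n) * (p["Cdc14_tot"] - Cdc14)
              - p["kd_Cdh1"] * Cdc14) / t2
    return np.array([dCycB, dCdh1, dAPC, dCdc20, dPlk1,
                     dEmi1, dE2F, dCycE, dCdc25, dCdc14])


def oracle_fitzhugh_nagumo(y, p):
    V, W = y[:6], y[6:]

    def S(x):
        return 1.0 / (1.0 + math.exp(-(x - p["V_th"]) / p["theta_th"]))

    a = np.zeros((6, 6))
    a[0, 1], a[1, 0] = -p["k1"], -p["k2"]
    a[2, 0], a[3, 1] = p["a31"], p["a42"]
    a[4, 0], a[5, 1] = p["a51"], p["a62"]
    a[0, 2], a[1, 3] = -p["neg"], -p["neg"]
    a[0, 4], a[1, 5] = p["pos"], p["pos"]
    d = np.empty(12)
    for i in range(6):
        I = p["I_in"] + sum(a[i, j] * S(V[j]) for j in range(6))
        F = -V[i] + V[i] ** 3 / 3.0
        d[i] = (I - F - W[i]) / p["C"]
        d[6 + i] = (p["E"] - p["R"] * W[i] + V[i]) / p["L"]
    return d


def oracle_goodwin(y, p):
    X1, Y1, Z1, U1, W1, X2, Y2, Z2, U2, W2 = y
    n, vp, vn = p["n"], p["pos"], p["neg"]
    k1, k2 = p["k1"], p["k2"]
    v = {i: p[f"v{i}"] for i in range(1, 22)}
    Z1c, Z2c, Y2c = max(Z1, 0.0), max(Z2, 0.0), max(Y2, 0.0)
    return np.array([
        v[1] / (1 + Z1c**n) - v[2] * X1,
        (v[3] + vp * W1) * X1 - (v[4] + k1 * Y2 + vn * U1) * Y1,
        v[5] * Y1 - v[6] * Z1,
        v[7] * Y1 - v[8] * U1,
        v[9] * Y1 - v[10] * W1,
        v[11] * Z2c**n / (1 + Z2c**n) - v[12] * X2,
        (v[13] + vp * W2 + v[21] * U2) * X2 - (v[14] + k2 * Y1) * Y2,
        v[15] / (1 + Y2c**n) - v[16] * Z2,
        v[17] / (1 + (vn * Y2c) ** n) - v[18] * U2,
        v[19] * Z2 - v[20] * W2,
    ])


def oracle_repressilator(y, p):
    X, Y = y[:10], y[10:]
    n, tau = p["n"], p["tau"]
    A = {(7, 1): p["a71"], (8, 4): p["a84"], (9, 1): p["a91"],
         (10, 4): p["a104"], (1, 9): p["pos"], (4, 10): p["pos"]}
    B = {(2, 1): p["b21"], (3, 2): p["b32"], (1, 3): p["b13"],
         (5, 4): p["b54"], (6, 5): p["b65"], (4, 6): p["b46"]}
    Cmat = {(1, 4): p["k1"], (4, 1): p["k2"], (1, 7): p["neg"], (4, 8): p["neg"]}
    d = np.empty(20)
    for i in range(1, 11):
        act = sum(
            (g * max(Y[j - 1], 0.0)) ** n / (1 + (g * max(Y[j - 1], 0.0)) ** n)
            for (ii, j), g in A.items() if ii == i
        )
        rep = 1.0
        for (ii, j), g in B.items():
            if ii == i:
                rep *= 1.0 / (1 + (g * max(Y[j - 1], 0.0)) ** n)
        Ci = sum(g * Y[j - 1] for (ii, j), g in Cmat.items() if ii == i)
        H = (p["v0"] + act) * rep
        d[i - 1] = (-X[i - 1] + H) / tau
        d[10 + i - 1] = (
            p["alpha"] * X[i - 1] - p["beta"] * (1 + Ci) * Y[i - 1]
        ) / tau
    return d


def oracle_predator_prey(y, p):
    X1, Y1, X2, Y2, Y3, Y4, Y5, Y6 = y
    al, be, h, K = p["alpha"], p["beta"], p["h"], p["K"]
    ga, de = p["gamma"], p["delta"]
    w1, w2 = p["omega1"], p["omega2"]
    kp, kn, k1, k2 = p["pos"], p["neg"], p["k1"], p["k2"]
    return np.array([
        al * X1 * (1 - X1 / K) - be * X1 / (X1 + h) * Y1,
        ga * X1 / (X1 + h) * Y1 + kp * Y1 * Y5 - k1 * Y1 * Y2 - kn * Y1 * Y3 - de * Y1,
        al * X2 * (1 - X2 / K) - be * X2 / (X2 + h) * Y2,
        ga * X2 / (X2 + h) * Y2 + kp * Y2 * Y6 - k2 * Y1 * Y2 - kn * Y2 * Y4 - de * Y2,
        al * Y3 * (1 - Y3 / K) + w1 * Y1 * Y3 - de * Y3,
        al * Y3 * (1 - Y3 / K) + w1 * Y2 * Y4 - de * Y4,
        al * Y5 * (1 - Y5 / K) + w2 * Y1 * Y5 - de * Y5,
        al * Y5 * (1 - Y5 / K) + w2 * Y2 * Y6 - de * Y6,
    ])


def oracle_van_der_pol(y, p):
    x, v = y[:6], y[6:]
    a = np.zeros((6, 6))
    a[0, 1], a[1, 0] = -p["k1"], -p["k2"]
    a[0, 2], a[1, 3] = -p["neg"], -p["neg"]
    a[0, 4], a[1, 5] = p["pos"], p["pos"]
    a[2, 0], a[3, 1] = p["a31"], p["a42"]
    a[4, 0], a[5, 1] = p["a51"], p["a62"]
    d = np.empty(12)
    for i in range(6):
        Ci = sum(a[i, j] * x[j] for j in range(6))
        d[i] = (v[i] + Ci) / p["tau"]
        d[6 + i] = (-x[i] + p["mu"] * (1 - x[i] ** 2) * v[i]) / p["tau"]
    return d


def oracle_neuromechanical(y, p):
    x1, y1, z1, x2, y2, z2, x3, x4, z3, z4, x5, x6 = y
    tau = p["tau"]
    Eex, Einh, Lmax = p["E_ex"], p["E_inh"], p["L_max"]

    def S(x, th):
        z = (th - x) / 0.01
        if z > 500:
            return 0.0
        if z < -500:
            return 1.0
        return 1.0 / (1.0 + math.exp(z))

    N1, N2 = p["N_th1"], p["N_th2"]
    P1, P2 = p["P_th1"], p["P_th2"]
    Lth, Vth = p["L_th"], p["V_th"]
    u_neg11 = (Einh - x1) * S(z1, N1) + (Eex - x1) * (1 - S(z1, N2))
    u_pos11 = (Eex - x1) * S(z1, P1) + (Einh - x1) * (1 - S(z1, P2))
    u_neg22 = (Einh - x2) * S(z2, N1) + (Eex - x2) * (1 - S(z2, N2))
    u_pos22 = (Eex - x2) * S(z2, P1) + (Einh - x2) * (1 - S(z2, P2))
    u_neg31 = (Einh - x3) * S(z1, N1) + (Eex - x3) * (1 - S(z1, N2))
    u_neg42 = (Einh - x4) * S(z2, N1) + (Eex - x4) * (1 - S(z2, N2))
    return np.array([
        (-x1 + p["v1"] * u_neg11 + p["v2"] * u_pos11 + p["v3"] * (x3 - x1)
         + p["u_in"]) / tau,
        (-y1 + p["v4"] * (Eex - y1) * S(x1, Vth) + (Eex - y1) * S(x3, Vth)
         + (Einh - y1) * S(x6, Vth)) / tau,
        (-z1 + (Lmax - z1) * S(y1, Vth) - p["k1"] * z2 * S(z2, Lth)
         - p["pos"] * z3) / tau,
        (-x2 + p["v1"] * u_neg22 + p["v2"] * u_pos22 + p["v3"] * (x4 - x2)
         + p["u_in"]) / tau,
        (-y2 + (Eex - y2) * S(x2, Vth) + (Eex - y2) * S(x4, Vth)
         + (Einh - y2) * S(x5, Vth)) / tau,
        (-z2 + (Lmax - z2) * S(y2, Vth) - p["k2"] * z1 * S(z1, Lth)
         - p["pos"] * z4) / tau,
        (-x3 + p["neg"] * u_neg31 + p["v3"] * (x1 - x3)) / tau,
        (-x4 + p["neg"] * u_neg42 + p["v3"] * (x2 - x4)) / tau,
        (-z3 - p["v5"] * z1) / tau,
        (-z4 - p["v5"] * z2) / tau,
        (-x5 + (Eex - x5) * S(x1, Vth)) / tau,
        (-x6 + (Eex - x6) * S(x2, Vth)) / tau,
    ])


ORACLES = {
    "cell_cycle": oracle_cell_cycle,
    "fitzhugh_nagumo": oracle_fitzhugh_nagumo,
    "goodwin": oracle_goodwin,
    "repressilator": oracle_repressilator,
    "predator_prey": oracle_predator_prey,
    "van_der_pol": oracle_van_der_pol,
    "neuromechanical": oracle_neuromechanical,
}
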