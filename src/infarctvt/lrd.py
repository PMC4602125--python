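"""Luo-Rudy dynamic (LRd) ventricular action-potential model.

Guinea-pig ventricular myocyte membrane kinetics: fast sodium current,
L-type calcium current (GHK flux with calcium-dependent inactivation),
rapid and slow delayed-rectifier potassium currents, inward rectifier,
plateau potassium current, Na/Ca exchanger, Na/K pump, nonspecific
Ca-activated current, sarcolemmal Ca pump, background currents, and a
two-compartment sarcoplasmic reticulum (network + junctional) with
calcium-induced calcium release, uptake, leak and translocation.

The baseline constants follow the published dynamic model and its
delayed-rectifier update; they are pinned here as a versioned constants
block and are not tuned by this package.  Gray-zone (GZ) electrical
remodeling is expressed as four multiplicative scales on the maximal
conductances/permeabilities of I_Na, I_Ca(L), I_Kr and I_Ks.

Two implementations live side by side:

* a transparent NumPy reference (:func:`compute_rates`) used by tests and
  for single-cell studies, and
* a numba-compiled node kernel in :mod:`infarctvt.monodomain` built from
  lookup tables produced by :func:`build_lookup_tables`, used by the
  tissue solver.  The two are cross-checked in the test suite.

Units: mV, ms, mM, µA/µF (currents normalised by membrane capacitance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# Physical constants and cell geometry
# ---------------------------------------------------------------------------

R_GAS = 8.314  # J/(mol K)
TEMP = 310.0  # K
FARADAY = 96485.0  # C/mol
RTF = R_GAS * TEMP * 1000.0 / FARADAY  # mV (≈26.71)

# extracellular concentrations, mM
NA_O = 140.0
K_O = 4.5
CA_O = 1.8

# cell geometry (cylinder 100 µm x 11 µm radius)
V_CELL = 3.801e-5  # µL
A_CAP = 1.534e-4  # cm², capacitive membrane area
V_MYO = 0.68 * V_CELL
V_NSR = 0.0552 * V_CELL
V_JSR = 0.0048 * V_CELL
CM = 1.0  # µF/cm²

# conversion from µA/µF to mM/ms for a monovalent ion in the myoplasm:
# I*Cm*Acap [µA] -> mol flux I*Cm*Acap*1e-6/F [mol/s] -> mM/ms over V_MYO
#   (µA/µF)*(µF/cm²)*(cm²) = µA = 1e-6 C/s; /F -> 1e-6 mol/s·(1/96485)
#   per litre: /(V_MYO µL * 1e-6 L/µL); per ms: *1e-3
CURRENT_TO_MM_MYO = A_CAP * CM / (FARADAY * V_MYO) * 1e-3  # mM/ms per µA/µF, z=1

# maximal conductances / permeabilities
G_NA = 16.0  # mS/µF
P_CA = 5.4e-4  # cm/s
P_CA_NA = 6.75e-7
P_CA_K = 1.93e-7
GAMMA_CAI, GAMMA_CAO = 1.0, 0.341
GAMMA_NAI, GAMMA_NAO = 0.75, 0.75
GAMMA_KI, GAMMA_KO = 0.75, 0.75
KM_FCA = 6.0e-4  # mM, Ca-dependent inactivation of I_CaL
G_KR_BAR = 0.02614 * np.sqrt(K_O / 5.4)
G_KS_BAR = 0.433
PR_NAK = 0.01833  # Na permeability ratio of I_Ks reversal
G_K1_BAR = 0.75 * np.sqrt(K_O / 5.4)
G_KP = 0.0183
I_NAK_BAR = 1.5
KM_NAI = 10.0
KM_KO = 1.5
C_NACA = 0.00025
ETA_NACA = 0.35
KSAT_NACA = 0.0001
P_NS_CA = 1.75e-7
KM_NS_CA = 1.2e-3
I_PCA_BAR = 1.15
KM_PCA = 5.0e-4
G_CAB = 0.003016
G_NAB = 0.00141

# calcium buffering
TRPN_BAR, KM_TRPN = 0.070, 0.0005
CMDN_BAR, KM_CMDN = 0.050, 0.00238
CSQN_BAR, KM_CSQN = 10.0, 0.8

# sarcoplasmic reticulum
I_UP_BAR = 0.00875  # mM/ms
KM_UP = 0.00092
CA_NSR_MAX = 15.0
TAU_TR = 180.0  # ms
# Ca-induced Ca release: flux gated by a voltage-threshold trigger with
# rise/decay time constants (see docs/methods.md for the rationale)
G_REL_BAR = 22.0  # ms^-1, scaled by (1-e^{-t/tau_on}) e^{-t/tau_off}
TAU_REL_ON = 2.0
TAU_REL_OFF = 2.0
REL_TRIGGER_V = -35.0  # mV, upward crossing starts a release episode
REL_EPISODE_REFRACTORY = 50.0  # ms before a new trigger is accepted

# state vector layout (shared with the numba kernel)
STATE_NAMES = (
    "v", "m", "h", "j", "d", "f", "xr", "xs",
    "nai", "ki", "cai", "cajsr", "cansr", "trel",
)
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: quiescent steady state, obtained by relaxing the model for 1000 s from
#: a polarised initial guess (reproducible via :func:`relax_to_rest`).
RESTING_STATE = np.array([
    -8.9398643679e+01,   # v
    7.3937312580e-04,    # m
    9.9436105095e-01,    # h
    9.9609767148e-01,    # j
    2.9783396039e-06,    # d
    9.9876380341e-01,    # f
    1.1700786174e-04,    # xr
    4.3077074172e-03,    # xs
    1.2224229818e+01,    # nai
    1.3687294054e+02,    # ki
    1.0779106064e-04,    # cai
    1.5732214119e+00,    # cajsr
    1.5732200688e+00,    # cansr
    1.0e6,               # trel (ms since last CICR trigger)
])


@dataclass(frozen=True)
class GZRemodeling:
    """Gray-zone ionic remodeling: multiplicative scales on maximal currents.

    Defaults reproduce peri-infarct border-zone electrophysiology: peak
    I_Na reduced to 38%, peak I_Ca(L) to 31%, I_Kr to 30% and I_Ks to 20%
    of their normal values, producing slower upstroke, lower AP peak and
    longer AP duration than normal myocardium.
    """

    sodium_scale: float = 0.38
    l_type_calcium_scale: float = 0.31
    ikr_scale: float = 0.30
    iks_scale: float = 0.20

    def __post_init__(self) -> None:
        for name in ("sodium_scale", "l_type_calcium_scale", "ikr_scale", "iks_scale"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sodium_scale, self.l_type_calcium_scale,
                self.ikr_scale, self.iks_scale)


NO_REMODELING = GZRemodeling(1.0, 1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Gate kinetics (voltage dependent rates / steady states / time constants)
# ---------------------------------------------------------------------------

def gate_rates(v):
    """Alpha/beta (or inf/tau) for every gate at voltage ``v`` (mV).

    Returns a dict of (inf, tau) pairs keyed by gate name.
    """
    v = np.asarray(v, dtype=float)

    # I_Na activation m
    dvm = v + 47.13
    am = np.where(np.abs(dvm) < 1e-6, 3.2, 0.32 * dvm / (1.0 - np.exp(-0.1 * dvm)))
    bm = 0.08 * np.exp(-v / 11.0)

    # I_Na inactivation h, j (piecewise at -40 mV)
    lo = v < -40.0
    ah = np.where(lo, 0.135 * np.exp((80.0 + v) / -6.8), 0.0)
    bh = np.where(
        lo,
        3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
        1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1))),
    )
    aj = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    bj = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )

    # I_CaL activation d / inactivation f
    dvd = v + 10.0
    dinf = 1.0 / (1.0 + np.exp(-dvd / 6.24))
    taud = np.where(
        np.abs(dvd) < 1e-6,
        dinf / (0.035 * 6.24) * 1.0,  # limit of d_inf(1-e^{-x})/ (0.035*6.24*x) as x->0
        dinf * (1.0 - np.exp(-dvd / 6.24)) / (0.035 * dvd),
    )
    finf = 1.0 / (1.0 + np.exp((v + 35.06) / 8.6)) + 0.6 / (1.0 + np.exp((50.0 - v) / 20.0))
    tauf = 1.0 / (0.0197 * np.exp(-((0.0337 * (v + 10.0)) ** 2)) + 0.02)

    # I_Kr activation xr
    xrinf = 1.0 / (1.0 + np.exp(-(v + 21.5) / 7.5))
    a_xr = np.where(np.abs(v + 14.2) < 1e-6, 0.00138 / 0.123,
                    0.00138 * (v + 14.2) / (1.0 - np.exp(-0.123 * (v + 14.2))))
    b_xr = np.where(np.abs(v + 38.9) < 1e-6, 0.00061 / 0.145,
                    0.00061 * (v + 38.9) / (np.exp(0.145 * (v + 38.9)) - 1.0))
    tauxr = 1.0 / (a_xr + b_xr)

    # I_Ks activation xs
    xsinf = 1.0 / (1.0 + np.exp(-(v - 1.5) / 16.7))
    a_xs = np.where(np.abs(v + 30.0) < 1e-6, 7.19e-5 / 0.148,
                    7.19e-5 * (v + 30.0) / (1.0 - np.exp(-0.148 * (v + 30.0))))
    b_xs = np.where(np.abs(v + 30.0) < 1e-6, 1.31e-4 / 0.0687,
                    1.31e-4 * (v + 30.0) / (np.exp(0.0687 * (v + 30.0)) - 1.0))
    tauxs = 1.0 / (a_xs + b_xs)

    out = {}
    for name, (a, b) in {"m": (am, bm), "h": (ah, bh), "j": (aj, bj)}.items():
        tau = 1.0 / (a + b)
        out[name] = (a * tau, tau)
    out["d"] = (dinf, taud)
    out["f"] = (finf, tauf)
    out["xr"] = (xrinf, tauxr)
    out["xs"] = (xsinf, tauxs)
    return out


def _ghk_factors(v, z, gamma_i, gamma_o, conc_o, perm):
    """GHK flux split as I = A(v)*C_i - B(v) (µA/µF per mM of C_i for A)."""
    v = np.asarray(v, dtype=float)
    zv = z * v / RTF
    small = np.abs(zv) < 1e-6
    ez = np.exp(np.where(small, 0.0, zv))
    # P·z²·V·F²/RT = P·z·F·(zVF/RT); with P in cm/s, concentrations in mM
    # (1e-6 mol/cm³) and Cm = 1 µF/cm², the A/cm²->µA/µF factors cancel.
    pref = perm * (z * FARADAY) * zv
    lim = perm * (z * FARADAY)
    denom = np.where(small, 1.0, ez - 1.0)
    A = np.where(small, lim * gamma_i, pref * gamma_i * ez / denom)
    B = np.where(small, lim * gamma_o * conc_o, pref * gamma_o * conc_o / denom)
    return A, B


def membrane_currents(state, scales=(1.0, 1.0, 1.0, 1.0)):
    """All membrane currents (µA/µF) for state array(s).

    ``state`` has shape (..., N_STATES); returns a dict of currents plus the
    reversal potentials.  ``scales`` = (Na, CaL, Kr, Ks) multipliers.
    """
    s = np.asarray(state, dtype=float)
    v = s[..., IDX["v"]]
    m, h, j = s[..., IDX["m"]], s[..., IDX["h"]], s[..., IDX["j"]]
    d, f = s[..., IDX["d"]], s[..., IDX["f"]]
    xr, xs = s[..., IDX["xr"]], s[..., IDX["xs"]]
    nai, ki, cai = s[..., IDX["nai"]], s[..., IDX["ki"]], s[..., IDX["cai"]]

    sc_na, sc_cal, sc_kr, sc_ks = scales

    ena = RTF * np.log(NA_O / nai)
    ek = RTF * np.log(K_O / ki)
    eks = RTF * np.log((K_O + PR_NAK * NA_O) / (ki + PR_NAK * nai))
    eca = 0.5 * RTF * np.log(CA_O / cai)

    ina = sc_na * G_NA * m ** 3 * h * j * (v - ena)

    fca = 1.0 / (1.0 + cai / KM_FCA)
    a_ca, b_ca = _ghk_factors(v, 2, GAMMA_CAI, GAMMA_CAO, CA_O, P_CA)
    a_cana, b_cana = _ghk_factors(v, 1, GAMMA_NAI, GAMMA_NAO, NA_O, P_CA_NA)
    a_cak, b_cak = _ghk_factors(v, 1, GAMMA_KI, GAMMA_KO, K_O, P_CA_K)
    icabar = a_ca * cai - b_ca
    ica = sc_cal * d * f * fca * icabar
    icana = sc_cal * d * f * fca * (a_cana * nai - b_cana)
    icak = sc_cal * d * f * fca * (a_cak * ki - b_cak)

    rkr = 1.0 / (1.0 + np.exp((v + 9.0) / 22.4))
    ikr = sc_kr * G_KR_BAR * xr * rkr * (v - ek)

    gks = G_KS_BAR * (1.0 + 0.6 / (1.0 + (3.8e-5 / np.maximum(cai, 1e-12)) ** 1.4))
    iks = sc_ks * gks * xs * xs * (v - eks)

    dvk1 = v - ek
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (dvk1 - 59.215)))
    bk1 = (0.49124 * np.exp(0.08032 * (dvk1 + 5.476))
           + np.exp(0.06175 * (dvk1 - 594.31))) / (1.0 + np.exp(-0.5143 * (dvk1 + 4.753)))
    ik1 = G_K1_BAR * ak1 / (ak1 + bk1) * dvk1

    kp = 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))
    ikp = G_KP * kp * dvk1

    ev = np.exp(v / RTF)
    eev = np.exp((ETA_NACA - 1.0) * v / RTF)
    num = eev * (ev * nai ** 3 * CA_O - NA_O ** 3 * cai)
    den = 1.0 + KSAT_NACA * eev * (ev * nai ** 3 * CA_O + NA_O ** 3 * cai)
    inaca = C_NACA * num / den

    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                  + 0.0365 * sigma * np.exp(-v / RTF))
    inak = I_NAK_BAR * fnak / (1.0 + (KM_NAI / nai) ** 1.5) * K_O / (K_O + KM_KO)

    cans_gate = 1.0 / (1.0 + (KM_NS_CA / np.maximum(cai, 1e-12)) ** 3)
    a_nsna, b_nsna = _ghk_factors(v, 1, GAMMA_NAI, GAMMA_NAO, NA_O, P_NS_CA)
    a_nsk, b_nsk = _ghk_factors(v, 1, GAMMA_KI, GAMMA_KO, K_O, P_NS_CA)
    insna = cans_gate * (a_nsna * nai - b_nsna)
    insk = cans_gate * (a_nsk * ki - b_nsk)

    ipca = I_PCA_BAR * cai / (cai + KM_PCA)
    icab = G_CAB * (v - eca)
    inab = G_NAB * (v - ena)

    return {
        "ina": ina, "ica": ica, "icana": icana, "icak": icak,
        "ikr": ikr, "iks": iks, "ik1": ik1, "ikp": ikp,
        "inaca": inaca, "inak": inak, "insna": insna, "insk": insk,
        "ipca": ipca, "icab": icab, "inab": inab,
        "ena": ena, "ek": ek, "eks": eks, "eca": eca,
    }


def total_current(state, scales=(1.0, 1.0, 1.0, 1.0)):
    c = membrane_currents(state, scales)
    return (c["ina"] + c["ica"] + c["icana"] + c["icak"] + c["ikr"] + c["iks"]
            + c["ik1"] + c["ikp"] + c["inaca"] + c["inak"] + c["insna"]
            + c["insk"] + c["ipca"] + c["icab"] + c["inab"])


def _buffer_factor_myo(cai):
    return 1.0 / (1.0 + TRPN_BAR * KM_TRPN / (KM_TRPN + cai) ** 2
                  + CMDN_BAR * KM_CMDN / (KM_CMDN + cai) ** 2)


def _buffer_factor_jsr(cajsr):
    return 1.0 / (1.0 + CSQN_BAR * KM_CSQN / (KM_CSQN + cajsr) ** 2)


def step_cell(state, dt, istim=0.0, scales=(1.0, 1.0, 1.0, 1.0)):
    """Advance one or more independent cells by one time step.

    Rush-Larsen update for the gates, forward Euler for voltage and
    concentrations.  ``istim`` is a depolarising stimulus in µA/µF
    (positive depolarises).  Returns a new state array.
    """
    s = np.array(state, dtype=float, copy=True)
    v = s[..., IDX["v"]]
    cur = membrane_currents(s, scales)
    rates = gate_rates(v)

    for g in ("m", "h", "j", "d", "f", "xr", "xs"):
        inf, tau = rates[g]
        s[..., IDX[g]] = inf + (s[..., IDX[g]] - inf) * np.exp(-dt / tau)

    nai, ki = s[..., IDX["nai"]], s[..., IDX["ki"]]
    cai = s[..., IDX["cai"]]
    cajsr, cansr = s[..., IDX["cajsr"]], s[..., IDX["cansr"]]
    trel = s[..., IDX["trel"]]

    # CICR trigger: upward crossing of the release threshold
    itot = (cur["ina"] + cur["ica"] + cur["icana"] + cur["icak"] + cur["ikr"]
            + cur["iks"] + cur["ik1"] + cur["ikp"] + cur["inaca"] + cur["inak"]
            + cur["insna"] + cur["insk"] + cur["ipca"] + cur["icab"] + cur["inab"])
    dv = dt * (-(itot) + istim)
    v_new = v + dv
    trig = (v < REL_TRIGGER_V) & (v_new >= REL_TRIGGER_V) & (trel > REL_EPISODE_REFRACTORY)
    trel = np.where(trig, 0.0, trel + dt)

    grel = G_REL_BAR * (1.0 - np.exp(-trel / TAU_REL_ON)) * np.exp(-trel / TAU_REL_OFF)
    irel = grel * (cajsr - cai)  # mM/ms, JSR volume reference
    iup = I_UP_BAR * cai / (cai + KM_UP)
    ileak = I_UP_BAR / CA_NSR_MAX * cansr
    itr = (cansr - cajsr) / TAU_TR

    ina_tot = (cur["ina"] + cur["icana"] + cur["insna"] + cur["inab"]
               + 3.0 * cur["inaca"] + 3.0 * cur["inak"])
    # the stimulus charge is booked against K+ so pacing conserves mass
    ik_tot = (cur["ikr"] + cur["iks"] + cur["ik1"] + cur["ikp"] + cur["icak"]
              + cur["insk"] - 2.0 * cur["inak"]) - np.asarray(istim)
    ica_mem = cur["ica"] + cur["icab"] + cur["ipca"] - 2.0 * cur["inaca"]

    s[..., IDX["nai"]] = nai - dt * ina_tot * CURRENT_TO_MM_MYO
    s[..., IDX["ki"]] = ki - dt * ik_tot * CURRENT_TO_MM_MYO

    bmyo = _buffer_factor_myo(cai)
    dcai = bmyo * (-ica_mem * CURRENT_TO_MM_MYO / 2.0
                   + irel * V_JSR / V_MYO
                   + (ileak - iup) * V_NSR / V_MYO)
    s[..., IDX["cai"]] = np.maximum(cai + dt * dcai, 1e-9)

    bjsr = _buffer_factor_jsr(cajsr)
    s[..., IDX["cajsr"]] = np.maximum(cajsr + dt * bjsr * (itr * V_NSR / V_JSR - irel), 1e-9)
    s[..., IDX["cansr"]] = np.maximum(cansr + dt * (iup - ileak - itr), 1e-9)

    s[..., IDX["v"]] = v_new
    s[..., IDX["trel"]] = trel
    return s


# ---------------------------------------------------------------------------
# Single-cell utilities
# ---------------------------------------------------------------------------

def initial_state() -> np.ndarray:
    """Copy of the packaged quiescent resting state."""
    return RESTING_STATE.copy()


def relax_to_rest(duration_ms=1000.0, dt=0.02, state=None):
    """Integrate an unstimulated cell; returns the final state."""
    s = RESTING_STATE.copy() if state is None else np.array(state, dtype=float)
    n = int(round(duration_ms / dt))
    for _ in range(n):
        s = step_cell(s, dt)
    return s


def pace_cell(n_beats, cycle_length_ms, dt=0.02, stim_amp=80.0, stim_dur=1.0,
              scales=(1.0, 1.0, 1.0, 1.0), state=None, record_last=True):
    """Pace a single cell; returns (final_state, t, v) for the last beat."""
    s = initial_state() if state is None else np.array(state, dtype=float)
    steps_per_beat = int(round(cycle_length_ms / dt))
    stim_steps = int(round(stim_dur / dt))
    ts, vs = [], []
    for beat in range(n_beats):
        rec = record_last and beat == n_beats - 1
        for k in range(steps_per_beat):
            istim = stim_amp if k < stim_steps else 0.0
            s = step_cell(s, dt, istim=istim, scales=scales)
            if rec:
                ts.append(beat * cycle_length_ms + (k + 1) * dt)
                vs.append(s[IDX["v"]])
    return s, np.asarray(ts), np.asarray(vs)


def ap_metrics(t, v):
    """Peak voltage, max upstroke velocity (mV/ms) and APD90 (ms) of one AP."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(dvdt))
    v_rest = v[0]
    v_peak = float(np.max(v))
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    i_peak = int(np.argmax(v))
    below = np.nonzero(v[i_peak:] <= v90)[0]
    apd90 = float(t[i_peak + below[0]] - t[i_up]) if below.size else float("nan")
    return {"peak": v_peak, "max_dvdt": float(dvdt[i_up]), "apd90": apd90,
            "t_upstroke": float(t[i_up])}


# ---------------------------------------------------------------------------
# Lookup tables for the tissue kernel
# ---------------------------------------------------------------------------

LUT_VMIN = -150.0
LUT_VMAX = 100.0
LUT_DV = 0.01

# row order of the table built below (gate rows hold inf and exp(-dt/tau))
LUT_ROWS = (
    "m_inf", "m_edt", "h_inf", "h_edt", "j_inf", "j_edt",
    "d_inf", "d_edt", "f_inf", "f_edt", "xr_inf", "xr_edt", "xs_inf", "xs_edt",
    "a_ca", "b_ca", "a_cana", "b_cana", "a_cak", "b_cak",
    "a_ns", "b_nsna", "b_nsk",
    "rkr", "kp", "fnak", "ev", "eev", "k1_frac",
)
LUT_IDX = {name: i for i, name in enumerate(LUT_ROWS)}


def build_lookup_tables(dt):
    """Voltage-indexed tables of gate updates and GHK/exchanger factors.

    Returned with shape (n_voltages, n_rows) so one voltage's entries are
    contiguous in memory.  ``k1_frac`` is tabulated against (v - E_K)
    rather than v; the kernel indexes it with that argument on the same
    grid.
    """
    v = np.arange(LUT_VMIN, LUT_VMAX + LUT_DV / 2, LUT_DV)
    tab = np.empty((len(LUT_ROWS), v.size), dtype=np.float64)
    rates = gate_rates(v)
    for g in ("m", "h", "j", "d", "f", "xr", "xs"):
        inf, tau = rates[g]
        tab[LUT_IDX[f"{g}_inf"]] = inf
        tab[LUT_IDX[f"{g}_edt"]] = np.exp(-dt / tau)

    a, b = _ghk_factors(v, 2, GAMMA_CAI, GAMMA_CAO, CA_O, P_CA)
    tab[LUT_IDX["a_ca"]], tab[LUT_IDX["b_ca"]] = a, b
    a, b = _ghk_factors(v, 1, GAMMA_NAI, GAMMA_NAO, NA_O, P_CA_NA)
    tab[LUT_IDX["a_cana"]], tab[LUT_IDX["b_cana"]] = a, b
    a, b = _ghk_factors(v, 1, GAMMA_KI, GAMMA_KO, K_O, P_CA_K)
    tab[LUT_IDX["a_cak"]], tab[LUT_IDX["b_cak"]] = a, b
    a, b = _ghk_factors(v, 1, GAMMA_NAI, GAMMA_NAO, NA_O, P_NS_CA)
    tab[LUT_IDX["a_ns"]], tab[LUT_IDX["b_nsna"]] = a, b
    _, b = _ghk_factors(v, 1, GAMMA_KI, GAMMA_KO, K_O, P_NS_CA)
    tab[LUT_IDX["b_nsk"]] = b

    tab[LUT_IDX["rkr"]] = 1.0 / (1.0 + np.exp((v + 9.0) / 22.4))
    tab[LUT_IDX["kp"]] = 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    tab[LUT_IDX["fnak"]] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                                  + 0.0365 * sigma * np.exp(-v / RTF))
    tab[LUT_IDX["ev"]] = np.exp(v / RTF)
    tab[LUT_IDX["eev"]] = np.exp((ETA_NACA - 1.0) * v / RTF)

    dvk1 = v  # argument is v - E_K
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (dvk1 - 59.215)))
    bk1 = (0.49124 * np.exp(0.08032 * (dvk1 + 5.476))
           + np.exp(0.06175 * (dvk1 - 594.31))) / (1.0 + np.exp(-0.5143 * (dvk1 + 4.753)))
    tab[LUT_IDX["k1_frac"]] = ak1 / (ak1 + bk1)
    return np.ascontiguousarray(tab.T)
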