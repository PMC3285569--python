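"""Human atrial myocyte electrophysiology.

Implements the Courtemanche–Ramirez–Nattel (CRN) ionic model of the human
atrial action potential with two standing modifications used throughout this
package: the inward-rectifier conductance g_K1 is scaled by 1.75 to bring the
resting potential and action potential duration closer to experimental
values, and the intracellular K+ and Na+ concentrations are held fixed
(139.0 mM and 11.2 mM) to eliminate slow drift over long simulations.

Chronic-AF electrical remodeling is represented by graded conductance
reductions: at the full level, I_CaL is reduced by 70% and I_to and I_Kur by
50% each; intermediate levels scale those percentage changes linearly by a
fraction ``f_E`` in [0, 1].

State layout (21 variables, see ``STATE_NAMES``): membrane voltage, the 15
Hodgkin–Huxley-type gates, the two fixed ionic concentrations, and the
three-compartment calcium subsystem (myoplasm, network SR uptake store,
junctional SR release store).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "CellParams",
    "STATE_NAMES",
    "NSTATE",
    "make_baseline_params",
    "apply_electrical_remodeling",
    "derivatives",
    "step_cell",
    "rest_state",
    "IntegrationFailure",
]

# ---------------------------------------------------------------------------
# Physical constants and fixed model geometry (CRN values)
# ---------------------------------------------------------------------------

R_GAS = 8.3143          # J mol^-1 K^-1
TEMP = 310.0            # K
FARADAY = 96.4867       # C mmol^-1
RT_F = R_GAS * TEMP / FARADAY

CM = 100.0              # pF, membrane capacitance
V_CELL = 20100.0        # um^3
V_I = 13668.0           # um^3, myoplasmic volume
V_UP = 1109.52          # um^3, network SR
V_REL = 96.48           # um^3, junctional SR

KO = 5.4                # mM
NAO = 140.0             # mM
CAO = 1.8               # mM

# buffering
CMDN_MAX, KM_CMDN = 0.05, 0.00238
TRPN_MAX, KM_TRPN = 0.07, 0.0005
CSQN_MAX, KM_CSQN = 10.0, 0.8

CA_UP_MAX = 15.0        # mM
K_UP = 0.00092          # mM
K_REL = 30.0            # ms^-1
TAU_TR = 180.0          # ms
TAU_U = 8.0             # ms
TAU_F_CA = 2.0          # ms
K_Q10 = 3.0             # Ito/IKur gating rate scale

# NaCa exchanger / NaK pump constants
KM_NA_I = 10.0          # mM (pump)
KM_K_O = 1.5            # mM (pump)
KM_NA = 87.5            # mM (exchanger)
KM_CA = 1.38            # mM (exchanger)
K_SAT = 0.1
GAMMA = 0.35
SIGMA_NAK = (math.exp(NAO / 67.3) - 1.0) / 7.0

# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "f_ca", "u", "v", "w",
    "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)
NSTATE = len(STATE_NAMES)

_IV = 0
_ICA_I = 18

# Published CRN initial conditions (used as the starting point for the
# rest-state relaxation; the fixed K_i/Na_i equal these values already).
_CRN_INIT = np.array([
    -81.18,        # V
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # f_ca
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.2,          # Na_i (fixed)
    139.0,         # K_i  (fixed)
    1.013e-4,      # Ca_i
    1.488,         # Ca_up
    1.488,         # Ca_rel
])

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

# parameter-vector indices (flat float64 array consumed by the jitted
# kernels); entries 15+ are derived constants folded in by ``to_array``
P_GNA, P_GK1, P_GTO, P_GKUR, P_GKR, P_GKS, P_GCAL, P_GBCA, P_GBNA, \
    P_INAK, P_INACA, P_IPCA, P_IUP, P_KI, P_NAI, \
    P_ENA, P_EK, P_NAKF, P_NCA1, P_NCA2 = range(20)
NPARAM = 20

K1_SCALE = 1.75
FIXED_K_I = 139.0
FIXED_NA_I = 11.2


@dataclass(frozen=True)
class CellParams:
    """Maximal conductances / transporter maxima of the modified CRN model.

    Conductances are in nS/pF; pump and exchanger maxima in pA/pF
    (I_NaCa_max in pA/pF scaled by its concentration terms); I_up_max in
    mM/ms. ``g_Kur`` is a multiplicative scale on the voltage-dependent
    I_Kur conductance. ``f_E`` records the electrical-remodeling fraction
    that produced this parameter set.
    """

    g_Na: float = 7.8
    g_K1: float = 0.09 * K1_SCALE
    g_to: float = 0.1652
    g_Kur: float = 1.0
    g_Kr: float = 0.029411765
    g_Ks: float = 0.12941176
    g_CaL: float = 0.12375
    g_bCa: float = 0.001131
    g_bNa: float = 0.0006744375
    i_NaK_max: float = 0.59933874
    i_NaCa_max: float = 1600.0
    i_pCa_max: float = 0.275
    i_up_max: float = 0.005
    K_i: float = FIXED_K_I
    Na_i: float = FIXED_NA_I
    f_E: float = 0.0
    scale_K1: float = K1_SCALE

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K1", "g_to", "g_Kur", "g_Kr", "g_Ks",
                     "g_CaL", "g_bCa", "g_bNa", "i_NaK_max", "i_NaCa_max",
                     "i_pCa_max", "i_up_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.f_E <= 1.0:
            raise ValueError("f_E must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        p = np.empty(NPARAM)
        p[P_GNA] = self.g_Na
        p[P_GK1] = self.g_K1
        p[P_GTO] = self.g_to
        p[P_GKUR] = self.g_Kur
        p[P_GKR] = self.g_Kr
        p[P_GKS] = self.g_Ks
        p[P_GCAL] = self.g_CaL
        p[P_GBCA] = self.g_bCa
        p[P_GBNA] = self.g_bNa
        p[P_INAK] = self.i_NaK_max
        p[P_INACA] = self.i_NaCa_max
        p[P_IPCA] = self.i_pCa_max
        p[P_IUP] = self.i_up_max
        p[P_KI] = self.K_i
        p[P_NAI] = self.Na_i
        # derived constants (fixed-concentration contract)
        p[P_ENA] = RT_F * math.log(NAO / self.Na_i)
        p[P_EK] = RT_F * math.log(KO / self.K_i)
        p[P_NAKF] = (self.i_NaK_max * (KO / (KO + KM_K_O))
                     / (1.0 + (KM_NA_I / self.Na_i) ** 1.5))
        denom = (KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO)
        p[P_NCA1] = self.i_NaCa_max * self.Na_i ** 3 * CAO / denom
        p[P_NCA2] = self.i_NaCa_max * NAO ** 3 / denom
        return p


def make_baseline_params() -> CellParams:
    """Modified CRN parameters: g_K1 x 1.75, fixed K_i/Na_i, no remodeling."""
    return CellParams()


def apply_electrical_remodeling(params: CellParams, f_E: float) -> CellParams:
    """Scale I_CaL, I_to and I_Kur conductances for a remodeling fraction.

    ``f_E = 1`` applies the full chronic-AF changes (I_CaL -70%, I_to -50%,
    I_Kur -50%); intermediate fractions downscale the percentage changes
    linearly. Other parameters are untouched.
    """
    if not 0.0 <= f_E <= 1.0:
        raise ValueError(f"f_E must lie in [0, 1], got {f_E}")
    return replace(
        params,
        g_CaL=params.g_CaL * (1.0 - 0.70 * f_E),
        g_to=params.g_to * (1.0 - 0.50 * f_E),
        g_Kur=params.g_Kur * (1.0 - 0.50 * f_E),
        f_E=f_E,
    )


class IntegrationFailure(RuntimeError):
    """Raised when the membrane state leaves its physiological envelope."""


# ---------------------------------------------------------------------------
# Right-hand side (jitted)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _rhs(y, dy, p, i_stim):
    """Time derivatives of the modified CRN model.

    ``i_stim`` is a depolarizing stimulus in current-per-capacitance units
    (pA/pF == A/F); it adds directly to dV/dt. K_i and Na_i derivatives are
    forced to zero (fixed-concentration contract).
    """
    V = y[0]
    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]
    d = y[10]; f = y[11]; f_ca = y[12]
    u = y[13]; v = y[14]; w = y[15]
    Na_i = y[16]; K_i = y[17]
    Ca_i = y[18]; Ca_up = y[19]; Ca_rel = y[20]

    E_Na = RT_F * math.log(NAO / Na_i)
    E_K = RT_F * math.log(KO / K_i)
    E_Ca = 0.5 * RT_F * math.log(CAO / Ca_i)

    # --- fast sodium current -------------------------------------------
    i_Na = p[P_GNA] * m * m * m * h * jj * (V - E_Na)

    if abs(V + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (V + 47.13) / (1.0 - math.exp(-0.1 * (V + 47.13)))
    b_m = 0.08 * math.exp(-V / 11.0)

    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        a_j = ((-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        b_j = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))

    # --- inward rectifier ----------------------------------------------
    i_K1 = p[P_GK1] * (V - E_K) / (1.0 + math.exp(0.07 * (V + 80.0)))

    # --- transient outward ---------------------------------------------
    i_to = p[P_GTO] * oa * oa * oa * oi * (V - E_K)
    a_oa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / ((a_oa + b_oa) * K_Q10)
    oa_inf = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    tau_oi = 1.0 / ((a_oi + b_oi) * K_Q10)
    oi_inf = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))

    # --- ultrarapid delayed rectifier ----------------------------------
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    i_Kur = p[P_GKUR] * g_kur * ua * ua * ua * ui * (V - E_K)
    a_ua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / ((a_ua + b_ua) * K_Q10)
    ua_inf = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / ((a_ui + b_ui) * K_Q10)
    ui_inf = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))

    # --- rapid delayed rectifier ---------------------------------------
    i_Kr = p[P_GKR] * xr * (V - E_K) / (1.0 + math.exp((V + 15.0) / 22.4))
    if abs(V + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 3e-4 * (V + 14.1) / (1.0 - math.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-10:
        b_xr = 3.7862e-4
    else:
        b_xr = 7.3898e-5 * (V - 3.3328) / (math.exp((V - 3.3328) / 5.1237) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    xr_inf = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))

    # --- slow delayed rectifier ----------------------------------------
    i_Ks = p[P_GKS] * xs * xs * (V - E_K)
    if abs(V - 19.9) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * (V - 19.9) / (1.0 - math.exp(-(V - 19.9) / 17.0))
        b_xs = 3.5e-5 * (V - 19.9) / (math.exp((V - 19.9) / 9.0) - 1.0)
    tau_xs = 0.5 / (a_xs + b_xs)
    xs_inf = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))

    # --- L-type calcium ------------------------------------------------
    i_CaL = p[P_GCAL] * d * f * f_ca * (V - 65.0)
    d_inf = 1.0 / (1.0 + math.exp(-(V + 10.0) / 8.0))
    if abs(V + 10.0) < 1e-10:
        tau_d = 1.0 / (6.24 * 0.07)
    else:
        e1 = math.exp(-(V + 10.0) / 6.24)
        tau_d = (1.0 - e1) / (0.035 * (V + 10.0) * (1.0 + e1))
    f_inf = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * math.exp(-(0.0337 * 0.0337) * (V + 10.0) * (V + 10.0)) + 0.02)
    f_ca_inf = 1.0 / (1.0 + Ca_i / 0.00035)

    # --- pumps, exchangers, background ---------------------------------
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RT_F)
                   + 0.0365 * SIGMA_NAK * math.exp(-V / RT_F))
    i_NaK = (p[P_INAK] * f_nak * (KO / (KO + KM_K_O))
             / (1.0 + (KM_NA_I / Na_i) ** 1.5))
    expg = math.exp(GAMMA * V / RT_F)
    expg1 = math.exp((GAMMA - 1.0) * V / RT_F)
    i_NaCa = (p[P_INACA]
              * (expg * Na_i ** 3 * CAO - expg1 * NAO ** 3 * Ca_i)
              / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO)
                 * (1.0 + K_SAT * expg1)))
    i_bCa = p[P_GBCA] * (V - E_Ca)
    i_bNa = p[P_GBNA] * (V - E_Na)
    i_pCa = p[P_IPCA] * Ca_i / (0.0005 + Ca_i)

    # --- SR calcium fluxes ---------------------------------------------
    i_rel = K_REL * u * u * v * w * (Ca_rel - Ca_i)
    i_tr = (Ca_up - Ca_rel) / TAU_TR
    i_up = p[P_IUP] / (1.0 + K_UP / Ca_i)
    i_up_leak = p[P_IUP] * Ca_up / CA_UP_MAX

    fn = 1e-12 * V_REL * i_rel - (5e-13 / FARADAY) * (0.5 * i_CaL - 0.2 * i_NaCa) * CM
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    w_inf = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))
    if abs(V - 7.9) < 1e-10:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        e2 = math.exp(-(V - 7.9) / 5.0)
        tau_w = 6.0 * (1.0 - e2) / ((1.0 + 0.3 * e2) * (V - 7.9))

    # --- assemble -------------------------------------------------------
    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL
             + i_pCa + i_NaK + i_NaCa + i_bNa + i_bCa)
    dy[0] = -i_ion + i_stim
    dy[1] = a_m * (1.0 - m) - b_m * m
    dy[2] = a_h * (1.0 - h) - b_h * h
    dy[3] = a_j * (1.0 - jj) - b_j * jj
    dy[4] = (oa_inf - oa) / tau_oa
    dy[5] = (oi_inf - oi) / tau_oi
    dy[6] = (ua_inf - ua) / tau_ua
    dy[7] = (ui_inf - ui) / tau_ui
    dy[8] = (xr_inf - xr) / tau_xr
    dy[9] = (xs_inf - xs) / tau_xs
    dy[10] = (d_inf - d) / tau_d
    dy[11] = (f_inf - f) / tau_f
    dy[12] = (f_ca_inf - f_ca) / TAU_F_CA
    dy[13] = (u_inf - u) / TAU_U
    dy[14] = (v_inf - v) / tau_v
    dy[15] = (w_inf - w) / tau_w
    dy[16] = 0.0   # Na_i fixed
    dy[17] = 0.0   # K_i fixed
    b1 = ((2.0 * i_NaCa - i_pCa - i_CaL - i_bCa) * CM / (2.0 * FARADAY * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / ((Ca_i + KM_TRPN) * (Ca_i + KM_TRPN))
          + CMDN_MAX * KM_CMDN / ((Ca_i + KM_CMDN) * (Ca_i + KM_CMDN)))
    dy[18] = b1 / b2
    dy[19] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[20] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN
                               / ((Ca_rel + KM_CSQN) * (Ca_rel + KM_CSQN)))


# ---------------------------------------------------------------------------
# Voltage-grid lookup tables for the V-dependent rate functions
# ---------------------------------------------------------------------------
#
# All purely voltage-dependent gating quantities (steady states and inverse
# time constants) and current shape factors are pre-tabulated on a fine
# voltage grid and linearly interpolated inside the reaction kernel. The
# exact right-hand side (`_rhs`) remains the reference path used by
# ``derivatives`` and the fixed-fine-step oracles.

V_TAB_MIN = -100.0
V_TAB_MAX = 70.0
V_TAB_STEP = 0.01
N_TAB_V = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1

(T_MINF, T_MRT, T_HINF, T_HRT, T_JINF, T_JRT,
 T_OAINF, T_OART, T_OIINF, T_OIRT,
 T_UAINF, T_UART, T_UIINF, T_UIRT,
 T_XRINF, T_XRRT, T_XSINF, T_XSRT,
 T_DINF, T_DRT, T_FINF, T_FRT,
 T_WINF, T_WRT,
 T_K1V, T_GKURV, T_KRV, T_FNAK, T_EXPG, T_EXPG1) = range(30)
N_TABLES = 30


def _build_tables() -> np.ndarray:
    V = V_TAB_MIN + V_TAB_STEP * np.arange(N_TAB_V)
    tab = np.empty((N_TABLES, N_TAB_V))
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        x = V + 47.13
        a_m = np.where(np.abs(x) < 1e-9, 3.2, 0.32 * x / (1.0 - np.exp(-0.1 * x)))
        b_m = 0.08 * np.exp(-V / 11.0)
        dep = V >= -40.0
        a_h = np.where(dep, 0.0, 0.135 * np.exp(-(V + 80.0) / 6.8))
        b_h = np.where(dep,
                       1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
                       3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V))
        a_j = np.where(dep, 0.0,
                       (-1.2714e5 * np.exp(0.2444 * V)
                        - 3.474e-5 * np.exp(-0.04391 * V)) * (V + 37.78)
                       / (1.0 + np.exp(0.311 * (V + 79.23))))
        b_j = np.where(dep,
                       0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
                       0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))))
        a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
        b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
        oa_inf = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
        a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
        b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
        oi_inf = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
        ua_inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
        a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
        b_ui = np.exp((V - 158.0) / 16.0)
        ui_inf = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
        x = V + 14.1
        a_xr = np.where(np.abs(x) < 1e-9, 0.0015,
                        3e-4 * x / (1.0 - np.exp(-x / 5.0)))
        x = V - 3.3328
        b_xr = np.where(np.abs(x) < 1e-9, 3.7862e-4,
                        7.3898e-5 * x / (np.exp(x / 5.1237) - 1.0))
        xr_inf = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
        x = V - 19.9
        a_xs = np.where(np.abs(x) < 1e-9, 6.8e-4,
                        4e-5 * x / (1.0 - np.exp(-x / 17.0)))
        b_xs = np.where(np.abs(x) < 1e-9, 3.15e-4,
                        3.5e-5 * x / (np.exp(x / 9.0) - 1.0))
        xs_inf = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
        d_inf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
        x = V + 10.0
        e1 = np.exp(-x / 6.24)
        tau_d = np.where(np.abs(x) < 1e-9, 1.0 / (6.24 * 0.07),
                         (1.0 - e1) / (0.035 * x * (1.0 + e1)))
        f_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
        tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
        w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
        x = V - 7.9
        e2 = np.exp(-x / 5.0)
        tau_w = np.where(np.abs(x) < 1e-9, 6.0 * 0.2 / 1.3,
                         6.0 * (1.0 - e2) / ((1.0 + 0.3 * e2) * x))

        tab[T_MINF] = a_m / (a_m + b_m); tab[T_MRT] = a_m + b_m
        tab[T_HINF] = a_h / (a_h + b_h); tab[T_HRT] = a_h + b_h
        tab[T_JINF] = a_j / (a_j + b_j); tab[T_JRT] = a_j + b_j
        tab[T_OAINF] = oa_inf; tab[T_OART] = (a_oa + b_oa) * K_Q10
        tab[T_OIINF] = oi_inf; tab[T_OIRT] = (a_oi + b_oi) * K_Q10
        tab[T_UAINF] = ua_inf; tab[T_UART] = (a_oa + b_oa) * K_Q10
        tab[T_UIINF] = ui_inf; tab[T_UIRT] = (a_ui + b_ui) * K_Q10
        tab[T_XRINF] = xr_inf; tab[T_XRRT] = a_xr + b_xr
        tab[T_XSINF] = xs_inf; tab[T_XSRT] = 2.0 * (a_xs + b_xs)
        tab[T_DINF] = d_inf; tab[T_DRT] = 1.0 / tau_d
        tab[T_FINF] = f_inf; tab[T_FRT] = 1.0 / tau_f
        tab[T_WINF] = w_inf; tab[T_WRT] = 1.0 / tau_w
        tab[T_K1V] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
        tab[T_GKURV] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
        tab[T_KRV] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
        tab[T_FNAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RT_F)
                             + 0.0365 * SIGMA_NAK * np.exp(-V / RT_F))
        tab[T_EXPG] = np.exp(GAMMA * V / RT_F)
        tab[T_EXPG1] = np.exp((GAMMA - 1.0) * V / RT_F)
    assert np.all(np.isfinite(tab))
    # transposed layout: one voltage index spans a contiguous row
    return np.ascontiguousarray(tab.T)


RATE_TABLES = _build_tables()


@njit(cache=True, fastmath=True)
def _rhs_vec(SA, D, p, istim, tab, I0, FR):
    """Vectorized right-hand side over all nodes.

    ``SA`` and ``D`` are state and derivative arrays in (NSTATE, n) layout;
    ``I0``/``FR`` are integer/fractional lookup-index scratch vectors. The
    per-equation loops are simple enough for SIMD code generation.
    """
    n = SA.shape[1]
    V = SA[0]
    for i in range(n):
        vq = (V[i] - V_TAB_MIN) / V_TAB_STEP
        if vq < 0.0:
            vq = 0.0
        elif vq > N_TAB_V - 1.001:
            vq = N_TAB_V - 1.001
        i0 = int(vq)
        I0[i] = i0
        FR[i] = vq - i0
    # gate derivatives: dx/dt = (x_inf - x) * rate, tables interleaved
    for g in range(12):
        ci = 2 * g          # T_*INF column
        cr = 2 * g + 1      # T_*RT column
        row = _GATE_ROWS[g]
        X = SA[row]
        DX = D[row]
        for i in range(n):
            j0 = I0[i]
            fr = FR[i]
            inf = tab[j0, ci] + fr * (tab[j0 + 1, ci] - tab[j0, ci])
            rt = tab[j0, cr] + fr * (tab[j0 + 1, cr] - tab[j0, cr])
            DX[i] = (inf - X[i]) * rt
    for i in range(n):
        j0 = I0[i]
        fr = FR[i]
        k1v = tab[j0, T_K1V] + fr * (tab[j0 + 1, T_K1V] - tab[j0, T_K1V])
        gkur = tab[j0, T_GKURV] + fr * (tab[j0 + 1, T_GKURV] - tab[j0, T_GKURV])
        krv = tab[j0, T_KRV] + fr * (tab[j0 + 1, T_KRV] - tab[j0, T_KRV])
        fnak = tab[j0, T_FNAK] + fr * (tab[j0 + 1, T_FNAK] - tab[j0, T_FNAK])
        expg = tab[j0, T_EXPG] + fr * (tab[j0 + 1, T_EXPG] - tab[j0, T_EXPG])
        expg1 = tab[j0, T_EXPG1] + fr * (tab[j0 + 1, T_EXPG1] - tab[j0, T_EXPG1])
        v_ = V[i]
        Ca_i = SA[18, i]; Ca_up = SA[19, i]; Ca_rel = SA[20, i]
        E_Ca = 0.5 * RT_F * math.log(CAO / Ca_i)
        i_Na = p[P_GNA] * SA[1, i] ** 3 * SA[2, i] * SA[3, i] * (v_ - p[P_ENA])
        i_K1 = p[P_GK1] * (v_ - p[P_EK]) * k1v
        i_to = p[P_GTO] * SA[4, i] ** 3 * SA[5, i] * (v_ - p[P_EK])
        i_Kur = p[P_GKUR] * gkur * SA[6, i] ** 3 * SA[7, i] * (v_ - p[P_EK])
        i_Kr = p[P_GKR] * SA[8, i] * (v_ - p[P_EK]) * krv
        i_Ks = p[P_GKS] * SA[9, i] ** 2 * (v_ - p[P_EK])
        i_CaL = p[P_GCAL] * SA[10, i] * SA[11, i] * SA[12, i] * (v_ - 65.0)
        i_NaK = p[P_NAKF] * fnak
        i_NaCa = (expg * p[P_NCA1] - expg1 * Ca_i * p[P_NCA2]) \
            / (1.0 + K_SAT * expg1)
        i_bCa = p[P_GBCA] * (v_ - E_Ca)
        i_bNa = p[P_GBNA] * (v_ - p[P_ENA])
        i_pCa = p[P_IPCA] * Ca_i / (0.0005 + Ca_i)
        i_rel = K_REL * SA[13, i] ** 2 * SA[14, i] * SA[15, i] * (Ca_rel - Ca_i)
        i_tr = (Ca_up - Ca_rel) / TAU_TR
        i_up = p[P_IUP] / (1.0 + K_UP / Ca_i)
        i_up_leak = p[P_IUP] * Ca_up / CA_UP_MAX
        fn = (1e-12 * V_REL * i_rel
              - (5e-13 / FARADAY) * (0.5 * i_CaL - 0.2 * i_NaCa) * CM)
        u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
        v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
        D[0, i] = -(i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL
                    + i_pCa + i_NaK + i_NaCa + i_bNa + i_bCa) + istim[i]
        D[12, i] = (1.0 / (1.0 + Ca_i / 0.00035) - SA[12, i]) / TAU_F_CA
        D[13, i] = (u_inf - SA[13, i]) / TAU_U
        D[14, i] = (v_inf - SA[14, i]) / (1.91 + 2.09 * u_inf)
        D[16, i] = 0.0
        D[17, i] = 0.0
        b1 = ((2.0 * i_NaCa - i_pCa - i_CaL - i_bCa) * CM
              / (2.0 * FARADAY * V_I)
              + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
        b2 = (1.0 + TRPN_MAX * KM_TRPN / ((Ca_i + KM_TRPN) * (Ca_i + KM_TRPN))
              + CMDN_MAX * KM_CMDN / ((Ca_i + KM_CMDN) * (Ca_i + KM_CMDN)))
        D[18, i] = b1 / b2
        D[19, i] = i_up - i_up_leak - i_tr * V_REL / V_UP
        D[20, i] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN
                                     / ((Ca_rel + KM_CSQN) * (Ca_rel + KM_CSQN)))


# state rows of the 12 tabulated voltage gates, in table order
# (m, h, j, oa, oi, ua, ui, xr, xs, d, f, w)
_GATE_ROWS = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15], dtype=np.int64)


@njit(cache=True, fastmath=True)
def _rhs_tab(y, dy, p, i_stim, tab, lk_scratch):
    """Table-interpolated right-hand side (same model as ``_rhs``)."""
    V = y[0]
    vq = (V - V_TAB_MIN) / V_TAB_STEP
    if vq < 0.0:
        vq = 0.0
    elif vq > N_TAB_V - 1.001:
        vq = N_TAB_V - 1.001
    i0 = int(vq)
    fr = vq - i0

    r0 = tab[i0]
    r1 = tab[i0 + 1]
    lk = lk_scratch  # caller-provided scratch (N_TABLES,) for the lerped rates
    for q in range(N_TABLES):
        lk[q] = r0[q] + fr * (r1[q] - r0[q])

    Ca_i = y[18]; Ca_up = y[19]; Ca_rel = y[20]
    E_Ca = 0.5 * RT_F * math.log(CAO / Ca_i)

    i_Na = p[P_GNA] * y[1] * y[1] * y[1] * y[2] * y[3] * (V - p[P_ENA])
    i_K1 = p[P_GK1] * (V - p[P_EK]) * lk[T_K1V]
    i_to = p[P_GTO] * y[4] * y[4] * y[4] * y[5] * (V - p[P_EK])
    i_Kur = p[P_GKUR] * lk[T_GKURV] * y[6] * y[6] * y[6] * y[7] * (V - p[P_EK])
    i_Kr = p[P_GKR] * y[8] * (V - p[P_EK]) * lk[T_KRV]
    i_Ks = p[P_GKS] * y[9] * y[9] * (V - p[P_EK])
    i_CaL = p[P_GCAL] * y[10] * y[11] * y[12] * (V - 65.0)
    i_NaK = p[P_NAKF] * lk[T_FNAK]
    expg1 = lk[T_EXPG1]
    i_NaCa = (lk[T_EXPG] * p[P_NCA1] - expg1 * Ca_i * p[P_NCA2]) \
        / (1.0 + K_SAT * expg1)
    i_bCa = p[P_GBCA] * (V - E_Ca)
    i_bNa = p[P_GBNA] * (V - p[P_ENA])
    i_pCa = p[P_IPCA] * Ca_i / (0.0005 + Ca_i)

    i_rel = K_REL * y[13] * y[13] * y[14] * y[15] * (Ca_rel - Ca_i)
    i_tr = (Ca_up - Ca_rel) / TAU_TR
    i_up = p[P_IUP] / (1.0 + K_UP / Ca_i)
    i_up_leak = p[P_IUP] * Ca_up / CA_UP_MAX

    fn = 1e-12 * V_REL * i_rel - (5e-13 / FARADAY) * (0.5 * i_CaL - 0.2 * i_NaCa) * CM
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau_v_inv = 1.0 / (1.91 + 2.09 * u_inf)
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))

    i_ion = (i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL
             + i_pCa + i_NaK + i_NaCa + i_bNa + i_bCa)
    dy[0] = -i_ion + i_stim
    dy[1] = (lk[T_MINF] - y[1]) * lk[T_MRT]
    dy[2] = (lk[T_HINF] - y[2]) * lk[T_HRT]
    dy[3] = (lk[T_JINF] - y[3]) * lk[T_JRT]
    dy[4] = (lk[T_OAINF] - y[4]) * lk[T_OART]
    dy[5] = (lk[T_OIINF] - y[5]) * lk[T_OIRT]
    dy[6] = (lk[T_UAINF] - y[6]) * lk[T_UART]
    dy[7] = (lk[T_UIINF] - y[7]) * lk[T_UIRT]
    dy[8] = (lk[T_XRINF] - y[8]) * lk[T_XRRT]
    dy[9] = (lk[T_XSINF] - y[9]) * lk[T_XSRT]
    dy[10] = (lk[T_DINF] - y[10]) * lk[T_DRT]
    dy[11] = (lk[T_FINF] - y[11]) * lk[T_FRT]
    dy[12] = (1.0 / (1.0 + Ca_i / 0.00035) - y[12]) / TAU_F_CA
    dy[13] = (u_inf - y[13]) / TAU_U
    dy[14] = (v_inf - y[14]) * tau_v_inv
    dy[15] = (lk[T_WINF] - y[15]) * lk[T_WRT]
    dy[16] = 0.0
    dy[17] = 0.0
    b1 = ((2.0 * i_NaCa - i_pCa - i_CaL - i_bCa) * CM / (2.0 * FARADAY * V_I)
          + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / ((Ca_i + KM_TRPN) * (Ca_i + KM_TRPN))
          + CMDN_MAX * KM_CMDN / ((Ca_i + KM_CMDN) * (Ca_i + KM_CMDN)))
    dy[18] = b1 / b2
    dy[19] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[20] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN
                               / ((Ca_rel + KM_CSQN) * (Ca_rel + KM_CSQN)))


# default adaptive sub-stepping bounds (ms) and voltage increment cap (mV)
DV_MAX = 0.2
DT_SUB_MIN = 1e-4
DT_SUB_MAX = 0.01


@njit(cache=True, fastmath=True)
def _react(y, p, dt_outer, i_stim, dv_max, dt_min, dt_max, tab, dy, lk_scratch):
    """Advance one cell by ``dt_outer`` with adaptive forward-Euler sub-steps.

    Sub-steps are sized so the voltage increment stays below ``dv_max``,
    bounded to [dt_min, dt_max]. Gates are clipped to [0, 1] after each
    sub-step. Returns 0 on success, 1 on a non-physiological state.
    """
    t = 0.0
    while t < dt_outer - 1e-12:
        _rhs_tab(y, dy, p, i_stim, tab, lk_scratch)
        dv = abs(dy[0])
        dt_sub = dt_max
        if dv * dt_sub > dv_max:
            dt_sub = dv_max / dv
            if dt_sub < dt_min:
                dt_sub = dt_min
        if t + dt_sub > dt_outer:
            dt_sub = dt_outer - t
        for k in range(NSTATE):
            y[k] += dt_sub * dy[k]
        for k in range(1, 16):
            if y[k] < 0.0:
                y[k] = 0.0
            elif y[k] > 1.0:
                y[k] = 1.0
        t += dt_sub
    if not math.isfinite(y[0]) or y[0] > 100.0 or y[0] < -150.0:
        return 1
    return 0


@njit(cache=True, fastmath=True)
def _integrate_single(y, p, n_steps, dt_outer,
                      stim_start, stim_end, stim_amp, period,
                      rec_every, rec_buf, dv_max, dt_min, dt_max, tab):
    """Drive one cell for ``n_steps`` outer steps with optional periodic
    stimulation; records V every ``rec_every`` steps into ``rec_buf``."""
    dy = np.empty(NSTATE)
    lk = np.empty(N_TABLES)
    nrec = 0
    for s in range(n_steps):
        t = s * dt_outer
        i_stim = 0.0
        if period > 0.0:
            phase = t % period
            if stim_start <= phase < stim_end:
                i_stim = stim_amp
        if _react(y, p, dt_outer, i_stim, dv_max, dt_min, dt_max, tab,
                  dy, lk) != 0:
            return -1
        if rec_every > 0 and (s + 1) % rec_every == 0:
            rec_buf[nrec] = y[0]
            nrec += 1
    return nrec


@njit(cache=True)
def _integrate_fixed_exact(y, p, n_steps, dt,
                           stim_t0, stim_t1, stim_amp,
                           rec_every, rec_buf):
    """Fixed-step forward Euler on the exact (non-tabulated) right-hand
    side; the reference for the adaptive integrator's accuracy oracle.
    Records V every ``rec_every`` steps."""
    dy = np.empty(NSTATE)
    nrec = 0
    for s in range(n_steps):
        t = s * dt
        i_stim = stim_amp if stim_t0 <= t < stim_t1 else 0.0
        _rhs(y, dy, p, i_stim)
        for k in range(NSTATE):
            y[k] += dt * dy[k]
        for k in range(1, 16):
            if y[k] < 0.0:
                y[k] = 0.0
            elif y[k] > 1.0:
                y[k] = 1.0
        if rec_every > 0 and (s + 1) % rec_every == 0:
            rec_buf[nrec] = y[0]
            nrec += 1
    return nrec


# ---------------------------------------------------------------------------
# Public single-cell API
# ---------------------------------------------------------------------------

def derivatives(state: np.ndarray, params: CellParams,
                i_stim: float = 0.0) -> np.ndarray:
    """Time derivatives of the full state vector (K_i/Na_i entries are 0)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (NSTATE,):
        raise ValueError(f"state must have shape ({NSTATE},)")
    if not np.all(np.isfinite(y)) or not math.isfinite(i_stim):
        raise ValueError("non-finite state or stimulus")
    dy = np.empty(NSTATE)
    _rhs(y, dy, params.to_array(), i_stim)
    return dy


def step_cell(state: np.ndarray, params: CellParams, dt_outer: float = 0.01,
              i_stim: float = 0.0, dv_max: float = DV_MAX,
              dt_min: float = DT_SUB_MIN, dt_max: float = DT_SUB_MAX) -> np.ndarray:
    """Advance a single cell by one outer step with adaptive sub-stepping."""
    y = np.array(state, dtype=float)
    if _react(y, params.to_array(), dt_outer, i_stim, dv_max, dt_min,
              dt_max, RATE_TABLES, np.empty(NSTATE), np.empty(N_TABLES)) != 0:
        raise IntegrationFailure(f"membrane voltage left envelope: V={y[0]:.1f} mV")
    return y


_REST_CACHE: dict[bytes, np.ndarray] = {}


def rest_state(params: CellParams, t_relax: float = 100_000.0) -> np.ndarray:
    """Quiescent steady state, by unstimulated relaxation from the published
    initial conditions (default 100 s). Cached per parameter set."""
    key = params.to_array().tobytes() + np.float64(t_relax).tobytes()
    if key not in _REST_CACHE:
        y = _CRN_INIT.copy()
        y[16] = params.Na_i
        y[17] = params.K_i
        n = int(round(t_relax / 0.01))
        rec = np.empty(0)
        out = _integrate_single(y, params.to_array(), n, 0.01,
                                0.0, 0.0, 0.0, 0.0, 0, rec,
                                DV_MAX, DT_SUB_MIN, DT_SUB_MAX, RATE_TABLES)
        if out < 0:
            raise IntegrationFailure("rest-state relaxation diverged")
        _REST_CACHE[key] = y
    return _REST_CACHE[key].copy()
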