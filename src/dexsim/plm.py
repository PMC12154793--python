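"""Pump–leak model (PLM) of cell volume and membrane voltage.

A single cell with fixed membrane area exchanges Na⁺, K⁺ and Cl⁻ with the
bath through passive (Goldman–Hodgkin–Katz) leaks and an electrogenic
Na⁺/K⁺-ATPase pump with 3 Na⁺ out : 2 K⁺ in stoichiometry.  Water
permeability is assumed much higher than ion permeability, so the volume is
slaved to osmotic balance: at every instant

    w = (n_Na + n_K + n_Cl + x_i) / c_o

where the n's are intracellular ion amounts, x_i the trapped impermeant
amount and c_o the bath osmolarity.  Voltage follows from the net
intracellular charge over the (constant) membrane capacitance,

    V = F·(n_Na + n_K − n_Cl + z·x_i) / C_m .

The three ion amounts are the only dynamic variables.  Because charge
relaxation (~μs at physiological capacitance) is many orders of magnitude
faster than volume equilibration, the system is integrated with a stiff
implicit solver (LSODA) rather than explicit stepping.

The pump flux is first-order in intracellular Na⁺, which makes the pump
shut itself off when the cell runs out of sodium (e.g. NaCl-free media).
Numeric defaults (permeabilities, capacitance, geometry) are package
defaults chosen to give physiological behavior and are exercised only
qualitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .physchem import CONSTANTS, MV, NORMAL_MEDIA, T_DEFAULT, MediaComposition

__all__ = [
    "PLMParameters",
    "PLMState",
    "PLMTrace",
    "SCENARIO_MEDIA",
    "passive_flux",
    "default_initial_state",
    "plm_run",
    "detect_steady_state",
    "calibrate_pump_rate",
    "run_fig4_scenarios",
]

_UMAX = 60.0  # cap on F·V/RT inside exponentials (|V| ≲ 1.5 V, unphysical)


@dataclass(frozen=True)
class PLMParameters:
    """PLM parameters (SI units internally).

    P_Na, P_K, P_Cl : membrane permeabilities (m/s)
    pump_rate : Na⁺/K⁺-ATPase turnover scale (m/s); the pump extrudes
        3·pump_rate·A·[Na⁺]_i and imports 2·pump_rate·A·[Na⁺]_i per second
    C_m : whole-cell membrane capacitance (F)
    area : membrane area (m²), held constant
    w0 : nominal initial cell volume (m³)
    x_i : trapped intracellular impermeant amount (mol); None means
        "derive from the initial-state closure"
    z : impermeant mean charge
    t_end : default total simulated time (s)
    flux_law : "ghk" (Goldman-type voltage factor) or "linear"
    """

    P_Na: float = 0.1e-6
    P_K: float = 1.0e-6
    P_Cl: float = 0.2e-6
    pump_rate: float = 0.0
    C_m: float = 4.836e-12
    area: float = 4.836e-10
    w0: float = 1e-15
    x_i: float | None = None
    z: float = -1.0
    T: float = T_DEFAULT
    t_end: float = 2000.0
    flux_law: str = "ghk"
    rtol: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("P_Na", "P_K", "P_Cl", "pump_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.C_m <= 0 or self.area <= 0 or self.w0 <= 0:
            raise ValueError("C_m, area and w0 must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.flux_law not in ("ghk", "linear"):
            raise ValueError("flux_law must be 'ghk' or 'linear'")


@dataclass(frozen=True)
class PLMState:
    """Intracellular ion amounts (mol), volume (m³), voltage (mV), time (s)."""

    n_Na: float
    n_K: float
    n_Cl: float
    w: float
    V: float
    t: float = 0.0


@dataclass(frozen=True)
class PLMTrace:
    """Time course of a PLM run plus the closure constants used."""

    t: np.ndarray            # (n,) s
    n_Na: np.ndarray         # (n,) mol
    n_K: np.ndarray
    n_Cl: np.ndarray
    w: np.ndarray            # (n,) m³
    V: np.ndarray            # (n,) mV
    x_i: float
    media: MediaComposition
    reached_steady_state: bool | None = None

    @property
    def final_state(self) -> PLMState:
        return PLMState(self.n_Na[-1], self.n_K[-1], self.n_Cl[-1],
                        self.w[-1], self.V[-1], self.t[-1])


def _ghk_factor(u: np.ndarray | float) -> np.ndarray | float:
    """u/(1 − e^{−u}), continuous through u = 0."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-8
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 + u / 2.0,
                   safe / (1.0 - np.exp(-np.clip(safe, -_UMAX, _UMAX))))
    return out if out.ndim else float(out)


def passive_flux(q: int, c_i: float, c_o: float, P: float, V: float,
                 T: float = T_DEFAULT, area: float = 1.0,
                 law: str = "ghk") -> float:
    """Passive electrodiffusive flux of an ion (mol/s, positive into cell).

    ``q`` is the ion valence, concentrations in mM (≡ mol/m³), ``P`` in m/s,
    ``V`` in mV.  The flux vanishes exactly at the Nernst equilibrium
    c_i = c_o·e^{−q·FV/RT} and follows the sign of the electrochemical
    gradient.  ``law="ghk"`` applies the Goldman constant-field voltage
    factor; ``law="linear"`` uses the bare concentration driving force.
    """
    if c_i < 0 or c_o < 0:
        raise ValueError("concentrations must be non-negative")
    u = np.clip(q * CONSTANTS.F * V * MV / (CONSTANTS.R * T), -_UMAX, _UMAX)
    drive = c_i - c_o * math.exp(-u)
    factor = _ghk_factor(u) if law == "ghk" else 1.0
    return -P * area * factor * drive


def default_initial_state(
        params: PLMParameters, media: MediaComposition = NORMAL_MEDIA,
        V0: float = -60.0, c_Na0: float = 12.0, c_Cl0: float = 10.0,
) -> tuple[PLMState, PLMParameters]:
    """Initial state consistent with osmotic balance and capacitive charge.

    Intracellular K⁺ takes up the cation balance; the impermeant amount x_i
    is chosen so that electroneutrality (up to the capacitive charge at
    ``V0``) and osmotic equality with ``media`` both hold at t = 0.
    Returns the state and a copy of ``params`` with ``x_i`` filled in.
    """
    c_o = media.osmolarity
    c_K0 = c_o / 2.0 - c_Na0
    if c_K0 <= 0:
        raise ValueError("bath osmolarity too low for the default ion split")
    dq = params.C_m * V0 * MV / (CONSTANTS.F * params.w0)  # mol/m³ equivalent
    X = c_Na0 + c_K0 - c_Cl0 - dq      # impermeant concentration, z = −1
    if X <= 0:
        raise ValueError("initial closure gives non-positive impermeant")
    x_i = X * params.w0
    w = (c_Na0 + c_K0 + c_Cl0 + X) * params.w0 / c_o
    state = PLMState(n_Na=c_Na0 * params.w0, n_K=c_K0 * params.w0,
                     n_Cl=c_Cl0 * params.w0, w=w, V=V0, t=0.0)
    return state, replace(params, x_i=x_i)


def _rhs_factory(params: PLMParameters, media: MediaComposition):
    F, R, T = CONSTANTS.F, CONSTANTS.R, params.T
    c_o = media.osmolarity
    x_i, z = params.x_i, params.z
    A = params.area

    def rhs(t, y):
        n_Na, n_K, n_Cl = y
        w = (n_Na + n_K + n_Cl + x_i) / c_o
        V = F * (n_Na + n_K - n_Cl + z * x_i) / params.C_m  # volts
        u = np.clip(F * V / (R * T), -_UMAX, _UMAX)
        phi = _ghk_factor(u) if params.flux_law == "ghk" else 1.0
        phim = _ghk_factor(-u) if params.flux_law == "ghk" else 1.0
        c_Na, c_K, c_Cl = n_Na / w, n_K / w, n_Cl / w
        j_Na = -params.P_Na * A * phi * (c_Na - media.Na_o * math.exp(-u))
        j_K = -params.P_K * A * phi * (c_K - media.K_o * math.exp(-u))
        j_Cl = -params.P_Cl * A * phim * (c_Cl - media.Cl_o * math.exp(u))
        j_pump = params.pump_rate * A * c_Na
        return [j_Na - 3.0 * j_pump, j_K + 2.0 * j_pump, j_Cl]

    return rhs


def plm_run(params: PLMParameters, media: MediaComposition,
            initial: PLMState | None = None, t_end: float | None = None,
            n_eval: int = 201) -> PLMTrace:
    """Integrate the PLM and return the trace.

    If ``initial`` is None (or ``params.x_i`` unset) a default initial state
    is built from the normal reference media, so that the same cell can be
    transferred into perturbed media.
    """
    if initial is None or params.x_i is None:
        initial, params = default_initial_state(params)
    t_end = params.t_end if t_end is None else t_end
    rhs = _rhs_factory(params, media)
    y0 = [initial.n_Na, initial.n_K, initial.n_Cl]
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=params.rtol, atol=1e-20)
    if not sol.success:
        raise RuntimeError(f"PLM integration failed: {sol.message}")
    n_Na, n_K, n_Cl = sol.y
    if np.min(sol.y) < -1e-12 * params.w0:
        raise RuntimeError("negative ion amount encountered; tighten rtol")
    c_o = media.osmolarity
    w = (n_Na + n_K + n_Cl + params.x_i) / c_o
    V = CONSTANTS.F * (n_Na + n_K - n_Cl + params.z * params.x_i) \
        / params.C_m / MV  # mV
    return PLMTrace(t=sol.t, n_Na=n_Na, n_K=n_K, n_Cl=n_Cl, w=w, V=V,
                    x_i=params.x_i, media=media)


def detect_steady_state(trace_t: PLMTrace, trace_10t: PLMTrace,
                        tol: float = 1e-4) -> bool:
    """True iff final volume and voltage agree between a run and a run 10×
    longer (relative change < ``tol``; voltage scaled by max(|V|, 1 mV))."""
    a, b = trace_t.final_state, trace_10t.final_state
    dw = abs(b.w - a.w) / abs(a.w)
    dV = abs(b.V - a.V) / max(abs(a.V), abs(b.V), 1.0)
    return bool(dw < tol and dV < tol)


def _steady_voltage(params: PLMParameters, media: MediaComposition,
                    pump_rate: float) -> float:
    p = replace(params, pump_rate=pump_rate)
    return plm_run(p, media, n_eval=2).final_state.V


def calibrate_pump_rate(params: PLMParameters,
                        media: MediaComposition = NORMAL_MEDIA,
                        V_target: float = -48.0,
                        bracket: tuple[float, float] = (1e-9, 1e-5),
                        tol_mV: float = 0.1) -> float:
    """Pump rate whose steady-state voltage in ``media`` equals ``V_target``.

    Root-finds on a log grid over ``bracket`` (m/s).  Raises with the
    achievable voltage range if the target is outside it.
    """
    if params.x_i is None:
        _, params = default_initial_state(params, media)
    rates = np.geomspace(bracket[0], bracket[1], 9)
    volts = np.array([_steady_voltage(params, media, r) for r in rates])
    err = volts - V_target
    idx = np.nonzero(np.diff(np.sign(err)))[0]
    if idx.size == 0:
        raise ValueError(
            f"V_target = {V_target} mV unreachable; achievable steady-state "
            f"range over bracket is [{volts.min():.1f}, {volts.max():.1f}] mV")
    lo, hi = rates[idx[0]], rates[idx[0] + 1]
    rate = brentq(lambda r: _steady_voltage(params, media, r) - V_target,
                  lo, hi, xtol=1e-14, rtol=1e-10)
    if abs(_steady_voltage(params, media, rate) - V_target) > tol_mV:
        raise RuntimeError("pump-rate calibration did not reach tolerance")
    return float(rate)


#: media presets for the perturbation battery
SCENARIO_MEDIA: dict[str, MediaComposition] = {
    "normal": NORMAL_MEDIA,
    "osmolyte_100": NORMAL_MEDIA.with_added_osmolyte(100.0),
    "sucrose_substitution": MediaComposition(Na_o=0.0, K_o=4.0, Cl_o=4.0,
                                             s_o=256.0),
    "gluconate_substitution": MediaComposition(Na_o=128.0, K_o=4.0, Cl_o=4.0,
                                               g_o=128.0),
}


def run_fig4_scenarios(params: PLMParameters | None = None,
                       pump_rate: float | None = None):
    """Steady-state volume/voltage battery over media × pump on/off.

    Returns a DataFrame with percent volume change and voltage relative to
    the calibrated pump-on normal-media baseline, plus a steady-state flag
    from the 10×-time criterion.  The initial cell is closed against normal
    media and carried into each perturbed bath.
    """
    import pandas as pd

    params = PLMParameters() if params is None else params
    initial, params = default_initial_state(params)
    if pump_rate is None:
        pump_rate = calibrate_pump_rate(params)

    rows = []
    baseline_w = None
    for name, media in SCENARIO_MEDIA.items():
        for pump in ("on", "off"):
            p = replace(params, pump_rate=pump_rate if pump == "on" else 0.0)
            tr1 = plm_run(p, media, initial=initial, n_eval=2)
            tr10 = plm_run(p, media, initial=initial,
                           t_end=10.0 * p.t_end, n_eval=2)
            steady = detect_steady_state(tr1, tr10)
            final = tr10.final_state
            if name == "normal" and pump == "on":
                baseline_w = final.w
            rows.append({"scenario": name, "pump": pump,
                         "w": final.w, "V_mV": final.V, "steady": steady})
    out = pd.DataFrame(rows)
    out["volume_pct_change"] = 100.0 * (out["w"] / baseline_w - 1.0)
    return out[["scenario", "pump", "volume_pct_change", "V_mV", "steady"]]
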