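"""Physical constants, static-gradient encoding physics, and closed-form
electrochemical/osmotic relations.

Interfaces use the units customary in low-field diffusion NMR and cell
physiology: concentrations in mM, voltages in mV, times in ms, gradients in
T/m, diffusivities in μm²/ms, b-values in ms/μm².  All conversions to SI
happen inside this module so that no unit factors are scattered elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Constants",
    "CONSTANTS",
    "MediaComposition",
    "EncodingGeometry",
    "NORMAL_MEDIA",
    "b_value",
    "length_scales",
    "vant_hoff_pressure",
    "chloride_partition_ratio",
    "steady_state_cell_volume",
    "recovery_osmolarity",
]

#: default absolute temperature (K) used throughout unless overridden
T_DEFAULT = 298.0

# -- centralized unit conversions (SI <-> interface units) -------------------
MS = 1e-3          # ms   -> s
MV = 1e-3          # mV   -> V
UM2_PER_MS = 1e-9  # μm²/ms -> m²/s
PER_M2_S_TO_MS_PER_UM2 = 1e-9   # s/m² -> ms/μm²
M_TO_UM = 1e6      # m -> μm
PA_TO_KPA = 1e-3   # Pa -> kPa
MM = 1.0           # mM == mol/m³ (numerically identical)


@dataclass(frozen=True)
class Constants:
    """Fundamental constants.

    F : Faraday constant (C/mol)
    R : molar gas constant (J/(mol·K))
    gamma : gyromagnetic ratio (rad s⁻¹ T⁻¹); default is ¹H
    """

    F: float = 96485.33212
    R: float = 8.31446261815324
    gamma: float = 2.6752218744e8

    def __post_init__(self) -> None:
        if self.F <= 0 or self.R <= 0 or self.gamma <= 0:
            raise ValueError("physical constants must be strictly positive")


CONSTANTS = Constants()


@dataclass(frozen=True)
class MediaComposition:
    """Bath (extracellular fluid) composition in mM.

    ``s_o`` is an uncharged membrane-impermeant osmolyte (e.g. sucrose);
    ``g_o`` is a monovalent anionic impermeant osmolyte (e.g. gluconate).
    The bath must be electroneutral: Na_o + K_o = Cl_o + g_o.
    """

    Na_o: float
    K_o: float
    Cl_o: float
    s_o: float = 0.0
    g_o: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Na_o", "K_o", "Cl_o", "s_o", "g_o"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not math.isclose(self.Na_o + self.K_o, self.Cl_o + self.g_o,
                            rel_tol=0.0, abs_tol=1e-9):
            raise ValueError(
                "bath is not electroneutral: Na_o + K_o must equal Cl_o + g_o"
            )

    @property
    def osmolarity(self) -> float:
        """Total bath osmolarity c_o = Na_o + K_o + Cl_o + g_o + s_o (mM)."""
        return self.Na_o + self.K_o + self.Cl_o + self.g_o + self.s_o

    def with_added_osmolyte(self, s_o: float) -> "MediaComposition":
        """Return a copy with ``s_o`` (mM) of uncharged osmolyte added."""
        return MediaComposition(self.Na_o, self.K_o, self.Cl_o,
                                self.s_o + s_o, self.g_o)


#: 128 mM NaCl + 4 mM KCl bath used as the reference condition
NORMAL_MEDIA = MediaComposition(Na_o=128.0, K_o=4.0, Cl_o=132.0)


@dataclass(frozen=True)
class EncodingGeometry:
    """Static-gradient spin-echo encoding geometry.

    g : static gradient (T/m), tau : half-echo time (ms),
    D0 : free-water diffusivity (μm²/ms).
    """

    g: float = 15.3
    tau: float = 0.0
    D0: float = 2.15

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("gradient strength g must be positive")
        if self.tau < 0:
            raise ValueError("half-echo time tau must be non-negative")
        if self.D0 <= 0:
            raise ValueError("free diffusivity D0 must be positive")


def b_value(g: float, tau: float, gamma: float = CONSTANTS.gamma) -> float:
    """Diffusion weighting b = (2/3)·γ²·g²·τ³ of a static-gradient spin echo.

    Parameters
    ----------
    g : static gradient (T/m)
    tau : half-echo time (ms)
    gamma : gyromagnetic ratio (rad s⁻¹ T⁻¹)

    Returns
    -------
    b in ms/μm².
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if g <= 0:
        raise ValueError("g must be positive")
    tau_s = tau * MS
    b_si = (2.0 / 3.0) * gamma**2 * g**2 * tau_s**3  # s/m²
    return b_si * PER_M2_S_TO_MS_PER_UM2


def length_scales(D0: float, g: float, tau: float,
                  gamma: float = CONSTANTS.gamma) -> tuple[float, float]:
    """Dephasing and diffusion length scales of an SGSE encoding.

    ℓg = (D0/(γ g))^(1/3) is roughly the distance over which diffusing
    spins dephase by 2π; ℓd = sqrt(D0·τ) is the free diffusion length over
    the half-echo time.  Both are returned in μm.
    """
    if D0 <= 0 or g <= 0:
        raise ValueError("D0 and g must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    D0_si = D0 * UM2_PER_MS
    lg = (D0_si / (gamma * g)) ** (1.0 / 3.0) * M_TO_UM
    ld = math.sqrt(D0_si * tau * MS) * M_TO_UM
    return lg, ld


def vant_hoff_pressure(c: float, T: float = T_DEFAULT) -> float:
    """Ideal osmotic pressure π = c·R·T of a solute at concentration c.

    c in mM, T in K; returns kPa.  Real cytoplasm deviates from ideality,
    so this is an order-of-magnitude estimate.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return c * MM * CONSTANTS.R * T * PA_TO_KPA


def chloride_partition_ratio(V: float, T: float = T_DEFAULT) -> float:
    """Nernst partition ratio Cl_i/Cl_o = exp(F·V/(R·T)) for chloride.

    V in mV (negative = intracellular negative), T in K.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(CONSTANTS.F * V * MV / (CONSTANTS.R * T))


def steady_state_cell_volume(x: float, z: float, c_o: float, Cl_o: float,
                             V: float, T: float = T_DEFAULT) -> float:
    """Steady-state cell volume w = (1−z)·x / (c_o − 2·Cl_o·exp(FV/RT)).

    x is the amount of trapped intracellular impermeant (arbitrary mol
    units; w comes out in corresponding volume units since only ratios
    matter), z its mean charge, c_o the bath osmolarity (mM), Cl_o the bath
    chloride (mM) and V the membrane voltage (mV).  A non-positive
    denominator means the pump/leak balance admits no stable volume.
    """
    denom = c_o - 2.0 * Cl_o * chloride_partition_ratio(V, T)
    if denom <= 0:
        raise ValueError(
            "no stable volume: c_o - 2*Cl_i is non-positive "
            f"(denominator = {denom:.4g} mM)"
        )
    return (1.0 - z) * x / denom


def recovery_osmolarity(Cl_o: float, V_on: float, V_off: float,
                        T: float = T_DEFAULT) -> float:
    """Added osmolyte concentration that restores the pump-on cell volume.

    s_o = −2·Cl_o·[exp(F·V_on/RT) − exp(F·V_off/RT)] equates the
    steady-state volume at the depolarized voltage ``V_off`` (pump
    inhibited) with the volume at ``V_on``.  Cl_o in mM, voltages in mV;
    returns mOsm.
    """
    return -2.0 * Cl_o * (chloride_partition_ratio(V_on, T)
                          - chloride_partition_ratio(V_off, T))
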