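"""Steady-state extracellular volume-fraction (fo) solver.

The tissue is modeled as cells (ICS) plus extracellular space (ECS) sharing
a fixed total volume ``w_tot``.  Intracellular impermeants (amount ``x_i``,
mean charge ``z``) drive osmotic swelling that is opposed by chloride
partitioning at the membrane voltage V; a small amount of uncharged
impermeant trapped in the ECS (``x_o``) keeps fo strictly positive.  The
steady-state fraction solves the fixed point

    fo = 1 − (1−z)·x_i / { w_tot·[ c_o(s_o) − 2·Cl_o·e^{FV/RT} + x_o/(fo·w_tot) ] }

with c_o(s_o) = Na_o + K_o + Cl_o + s_o the bath osmolarity including any
added uncharged osmolyte s_o.  Multiplying through by fo turns this into a
quadratic, which is solved in closed form; a damped fixed-point iteration
is kept as a fallback (the naive iteration oscillates at depolarized V).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .physchem import (CONSTANTS, MV, NORMAL_MEDIA, T_DEFAULT,
                       MediaComposition, chloride_partition_ratio,
                       steady_state_cell_volume)

__all__ = [
    "VolumeModelParams",
    "FoSolution",
    "calibrate_reference_geometry",
    "solve_fo",
    "impermeant_osmolarities",
]


@dataclass(frozen=True)
class VolumeModelParams:
    """Parameters of the fixed-total-volume osmotic model.

    ``x_i`` and ``x_o`` are impermeant amounts in arbitrary but consistent
    mol units (all outputs depend only on ratios); ``w_tot`` is the total
    ECS+ICS volume in the matching volume unit, normally obtained from
    :func:`calibrate_reference_geometry`.
    """

    x_i: float = 1.0
    z: float = -1.0
    x_o: float = 1.0 / 50.0
    Cl_o: float = 132.0
    c_base: float = NORMAL_MEDIA.osmolarity   # Na_o + K_o + Cl_o at s_o = 0
    T: float = T_DEFAULT
    fo_init: float = 0.3
    w_tot: float | None = None

    def __post_init__(self) -> None:
        if self.x_i <= 0:
            raise ValueError("x_i must be positive")
        if self.x_o < 0:
            raise ValueError("x_o must be non-negative")
        if not 0.0 < self.fo_init < 1.0:
            raise ValueError("fo_init must lie in (0, 1)")
        if self.z > 0:
            raise ValueError("impermeant mean charge z must be <= 0")
        if self.w_tot is not None and self.w_tot <= 0:
            raise ValueError("w_tot must be positive")

    @classmethod
    def calibrated(cls, media: MediaComposition = NORMAL_MEDIA,
                   V_ref: float = -48.0, fo_init: float = 0.3,
                   x_i: float = 1.0, xo_ratio: float = 1.0 / 50.0,
                   z: float = -1.0, T: float = T_DEFAULT) -> "VolumeModelParams":
        """Build parameters with ``w_tot`` calibrated at a reference state."""
        p = cls(x_i=x_i, z=z, x_o=x_i * xo_ratio, Cl_o=media.Cl_o,
                c_base=media.osmolarity, T=T, fo_init=fo_init)
        return replace(p, w_tot=calibrate_reference_geometry(
            x_i, z, media, V_ref, fo_init, T=T))


@dataclass(frozen=True)
class FoSolution:
    """ECS fraction fo, ICS fraction fi = 1−fo, and the osmolarities of the
    trapped ECS and ICS impermeants (mM)."""

    fo: float
    fi: float
    osm_ecs_impermeant: float
    osm_ics_impermeant: float


def calibrate_reference_geometry(x_i: float, z: float,
                                 media: MediaComposition = NORMAL_MEDIA,
                                 V_ref: float = -48.0, fo_init: float = 0.3,
                                 T: float = T_DEFAULT) -> float:
    """Total ECS+ICS volume implied by a reference cell volume and ECS fraction.

    The cell volume at the reference condition (``media``, ``V_ref``) is the
    closed-form steady-state volume; ``w_tot`` then follows from assigning
    that cell an initial ECS fraction: w_tot = w_ref / (1 − fo_init).
    """
    if not 0.0 <= fo_init < 1.0:
        raise ValueError("fo_init must lie in [0, 1)")
    w_ref = steady_state_cell_volume(x_i, z, media.osmolarity, media.Cl_o,
                                     V_ref, T)
    return w_ref / (1.0 - fo_init)


def _donnan_term(params: VolumeModelParams, s_o: float, V: float) -> float:
    """B = c_o(s_o) − 2·Cl_o·exp(FV/RT) (mM)."""
    return (params.c_base + s_o
            - 2.0 * params.Cl_o * chloride_partition_ratio(V, params.T))


def solve_fo(params: VolumeModelParams, s_o: float, V: float) -> FoSolution:
    """Steady-state ECS fraction at added osmolyte ``s_o`` (mOsm) and
    membrane voltage ``V`` (mV).

    Solves B·fo² + (C − B + A)·fo − C = 0 with A = (1−z)·x_i/w_tot,
    B = c_o(s_o) − 2·Cl_o·e^{FV/RT}, C = x_o/w_tot, and returns the root in
    (0, 1).  Falls back to damped iteration plus bisection when B ≤ 0.
    """
    if params.w_tot is None:
        raise ValueError("params not calibrated: w_tot is unset; "
                         "use VolumeModelParams.calibrated(...)")
    if s_o < 0:
        raise ValueError("s_o must be non-negative")
    A = (1.0 - params.z) * params.x_i / params.w_tot
    B = _donnan_term(params, s_o, V)
    C = params.x_o / params.w_tot

    roots: list[float] = []
    if B > 0:
        disc = (C - B + A) ** 2 + 4.0 * B * C
        sq = np.sqrt(disc)
        for r in ((-(C - B + A) + sq) / (2.0 * B),
                  (-(C - B + A) - sq) / (2.0 * B)):
            if 0.0 < r < 1.0:
                roots.append(float(r))
        if len(roots) > 1:
            warnings.warn("two admissible fo roots; returning the branch "
                          "continuous with the large-s_o limit",
                          RuntimeWarning, stacklevel=2)
        if roots:
            fo = max(roots)
        else:
            fo = _bisect_fo(A, B, C)
    else:
        fo = _bisect_fo(A, B, C)
    return _solution(params, fo)


def _residual(fo: float, A: float, B: float, C: float) -> float:
    """fo minus the RHS of the defining fixed point."""
    return fo - (1.0 - A / (B + C / fo))


def _bisect_fo(A: float, B: float, C: float, tol: float = 1e-12) -> float:
    """Damped-iteration/bisection fallback on the fixed-point residual."""
    lo, hi = 1e-15, 1.0 - 1e-15
    flo, fhi = _residual(lo, A, B, C), _residual(hi, A, B, C)
    if flo * fhi > 0:
        raise ValueError(
            "no steady-state fo in (0, 1): residual does not change sign "
            f"(residual({lo:.1e}) = {flo:.3g}, residual(1-) = {fhi:.3g})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = _residual(mid, A, B, C)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _solution(params: VolumeModelParams, fo: float) -> FoSolution:
    osm_ecs, osm_ics = impermeant_osmolarities(params, fo)
    return FoSolution(fo=fo, fi=1.0 - fo,
                      osm_ecs_impermeant=osm_ecs,
                      osm_ics_impermeant=osm_ics)


def impermeant_osmolarities(params: VolumeModelParams,
                            fo: float) -> tuple[float, float]:
    """Osmolarities (mM) of ECS-trapped and ICS impermeants at fraction fo:
    x_o/(fo·w_tot) and x_i/((1−fo)·w_tot)."""
    if params.w_tot is None:
        raise ValueError("params not calibrated: w_tot is unset")
    if not 0.0 < fo < 1.0:
        raise ValueError("fo must lie strictly inside (0, 1)")
    osm_ecs = params.x_o / (fo * params.w_tot)
    osm_ics = params.x_i / ((1.0 - fo) * params.w_tot)
    return osm_ecs, osm_ics
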