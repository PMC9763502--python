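"""Cell-wall deposition: geometry, saturated rates, and carbohydrate response.

Cells are cuboid with fixed axial and tangential lengths; only the radial
length changes.  The saturated wall-growth rate scales with lumen volume (a
proxy for the amount of wall-building machinery) and with Boltzmann-Arrhenius
temperature kinetics; realized growth follows Michaelis-Menten kinetics in
the cytoplasmic carbohydrate concentration.  Proliferating and enlarging
cells build primary wall only, capped at the primary-wall mass for their
current size; thickening cells deposit secondary wall until the lumen
occludes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "WallDemand",
    "cell_volume",
    "primary_wall_volume",
    "lumen_volume",
    "arrhenius_wall_factor",
    "max_wall_growth",
    "wall_growth_rate",
]


@dataclass(frozen=True)
class WallDemand:
    """Per-cell saturated wall-growth demand for the transport solver."""

    dM_max: float  # carbohydrate-saturated wall growth rate, mg cell^-1 day^-1
    cap_applied: bool = False  # primary-wall limit was active

    def __post_init__(self) -> None:
        if self.dM_max < 0:
            raise ValueError(f"dM_max must be >= 0, got {self.dM_max}")


def cell_volume(L_r: float, params: ModelParams) -> float:
    """Total cell volume V_c = La * Lt * L_r / 1e12, ml."""
    if L_r < 0:
        raise ValueError(f"radial length must be >= 0, got {L_r}")
    return params.La * params.Lt * L_r / 1.0e12


def primary_wall_volume(L_r: float, params: ModelParams) -> float:
    """Volume of a complete primary wall around a cell of radial length L_r, ml.

    V_wp = V_c - (La - 2Wp)(Lt - 2Wp)(L_r - 2Wp)/1e12, floored at V_c for
    cells thinner than two wall thicknesses.
    """
    V_c = cell_volume(L_r, params)
    inner = (
        (params.La - 2.0 * params.Wp)
        * (params.Lt - 2.0 * params.Wp)
        * (L_r - 2.0 * params.Wp)
        / 1.0e12
    )
    return V_c - max(inner, 0.0)


def lumen_volume(L_r: float, M: float, params: ModelParams) -> float:
    """Lumen volume V_l = V_c - M/rho, ml.

    Raises if the wall volume exceeds the cell volume, which signals an
    integration bug upstream.
    """
    V_c = cell_volume(L_r, params)
    V_w = M / params.rho
    if V_w > V_c * (1.0 + 1e-12):
        raise ValueError(f"wall volume {V_w:.3e} ml exceeds cell volume {V_c:.3e} ml")
    return max(V_c - V_w, 0.0)


def arrhenius_wall_factor(T: float, params: ModelParams) -> float:
    """Boltzmann-Arrhenius factor exp((Eaw/k)(1/T0 - 1/T)) for wall building."""
    if T <= 0:
        raise ValueError(f"temperature must be positive (K), got {T}")
    return math.exp((params.Eaw / params.k_B) * (1.0 / params.T0 - 1.0 / T))


def max_wall_growth(
    V_l: float, T: float, stage: str, L_r: float, M: float, params: ModelParams
) -> WallDemand:
    """Carbohydrate-saturated wall growth rate dM_max (mg day^-1).

    dM_max = omega * V_l * Arrhenius(T); for *stage* ``"primary"`` it is
    additionally limited to the remaining primary-wall headroom
    rho * V_wp - M (floored at zero).  *stage* ``"secondary"`` has no cap
    beyond lumen occlusion, which enters through V_l.
    """
    if V_l < 0:
        raise ValueError(f"lumen volume must be >= 0, got {V_l}")
    if stage not in ("primary", "secondary"):
        raise ValueError(f"unknown wall stage: {stage!r}")
    dM_max = params.omega * V_l * arrhenius_wall_factor(T, params)
    cap_applied = False
    if stage == "primary":
        headroom = max(params.rho * primary_wall_volume(L_r, params) - M, 0.0)
        if headroom < dM_max:
            dM_max = headroom
            cap_applied = True
    return WallDemand(dM_max=dM_max, cap_applied=cap_applied)


def wall_growth_rate(theta: float, dM_max: float, params: ModelParams) -> float:
    """Realized wall growth dM = dM_max * theta / (theta + Km), mg day^-1."""
    if theta < 0:
        raise ValueError(f"concentration must be >= 0, got {theta}")
    return dM_max * theta / (theta + params.Km)
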