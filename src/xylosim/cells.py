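"""Cell state, temperature-driven enlargement, and stochastic division.

Radial enlargement follows Boltzmann-Arrhenius kinetics.  Division-size
control is intermediate between a sizer (divide at a critical size) and an
adder (divide after a critical added increment), with asymmetric division:
the smaller daughter subsequently grows faster, maintaining size homeostasis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import ModelParams

__all__ = [
    "Role",
    "Status",
    "Cell",
    "enlargement_rate",
    "radial_increment",
    "division_length",
    "divide",
    "initial_division_fate",
]

#: Clamp applied to the division-asymmetry noise Z_a for numerical stability.
ZA_CLAMP = 0.49


class Role(str, Enum):
    INITIAL = "initial"
    XYLEM = "xylem"


class Status(str, Enum):
    PROLIFERATING = "proliferating"
    ENLARGING = "enlarging"
    THICKENING = "thickening"
    MATURE = "mature"


_STATUS_RANK = {
    Status.PROLIFERATING: 0,
    Status.ENLARGING: 1,
    Status.THICKENING: 2,
    Status.MATURE: 3,
}


@dataclass
class Cell:
    """One tracked cell in a radial file.

    Attributes
    ----------
    L_r : current radial length, um
    L_r_b : radial length at birth, um
    epsilon : growth dependence on relative birth size (1 for a symmetric
        daughter; the smaller sibling has epsilon > 1)
    L_r_d : length at which the cell will divide, um (proliferation only)
    M : cell-wall mass, mg
    theta : cytoplasmic carbohydrate concentration, mg ml^-1
    birth_order : global formation index within the file
    """

    id: int
    role: Role
    status: Status
    L_r: float
    L_r_b: float
    epsilon: float
    L_r_d: float
    M: float
    theta: float
    birth_order: int
    year_born: int

    @property
    def rank(self) -> int:
        return _STATUS_RANK[self.status]

    def advance_status(self, new: Status) -> None:
        """Move to *new* status only if it is a forward transition."""
        if _STATUS_RANK[new] > self.rank:
            self.status = new


def enlargement_rate(T: float, params: ModelParams) -> float:
    """Relative radial growth rate mu (um um^-1 day^-1) at temperature T (K).

    mu = mu0 * exp((Ea/k) * (1/T0 - 1/T)); strictly increasing in T.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive (K), got {T}")
    return params.mu0 * math.exp((params.Ea / params.k_B) * (1.0 / params.T0 - 1.0 / T))


def radial_increment(L_r: float, mu: float, epsilon: float) -> float:
    """Daily radial increment dL_r = L_r * (e^(epsilon*mu) - 1), um."""
    if L_r <= 0:
        raise ValueError(f"radial length must be positive, got {L_r}")
    return L_r * (math.exp(epsilon * mu) - 1.0)


def division_length(L_r_b: float, Z: float, params: ModelParams) -> float:
    """Length at which a cell born at L_r_b will divide (um).

    L_r_d = f * L_r_b + chi_b * (2 - f + Z); f interpolates between a pure
    sizer (f = 0) and a pure adder (f = 1).
    """
    return params.f * L_r_b + params.chi_b * (2.0 - params.f + Z)


def _make_daughter(
    cell_id: int,
    L_r_b: float,
    alpha_b: float,
    Z: float,
    mother: Cell,
    params: ModelParams,
) -> Cell:
    return Cell(
        id=cell_id,
        role=Role.XYLEM,
        status=Status.PROLIFERATING,
        L_r=L_r_b,
        L_r_b=L_r_b,
        epsilon=1.0 - params.g_asym * alpha_b,
        L_r_d=division_length(L_r_b, Z, params),
        M=0.0,  # assigned by the caller (mass split in proportion to length)
        theta=mother.theta,
        birth_order=0,  # assigned by the caller
        year_born=mother.year_born,
    )


def divide(
    mother: Cell, rng: np.random.Generator, params: ModelParams, id_start: int = 0
) -> tuple[Cell, Cell]:
    """Split a proliferating mother at/above its division length.

    Birth lengths are L * (0.5 - Z_a) and L * (0.5 + Z_a) where L is the
    mother's length at division and Z_a ~ N(0, sigma_a) clamped to +/-0.49;
    each daughter receives its asymmetry-conditioned growth factor epsilon
    and a fresh stochastic division length.  Wall mass is partitioned in
    proportion to birth length, so both length and mass are conserved.
    """
    if mother.status is not Status.PROLIFERATING:
        raise ValueError("only proliferating cells divide")
    if mother.L_r < mother.L_r_d:
        raise ValueError(
            f"division below threshold: L_r={mother.L_r:.3f} < L_r_d={mother.L_r_d:.3f}"
        )
    Z_a = float(np.clip(rng.normal(0.0, params.sigma_a), -ZA_CLAMP, ZA_CLAMP))
    L = mother.L_r
    L_a_b = L * (0.5 - Z_a)
    L_b_b = L * (0.5 + Z_a)
    # degree of asymmetry relative to the sister: (L_b - L_b_sis)/(L_b + L_b_sis)
    alpha_a = (L_a_b - L_b_b) / L
    alpha_b = -alpha_a
    Z_1 = float(rng.normal(0.0, params.sigma))
    Z_2 = float(rng.normal(0.0, params.sigma))
    da = _make_daughter(id_start, L_a_b, alpha_a, Z_1, mother, params)
    db = _make_daughter(id_start + 1, L_b_b, alpha_b, Z_2, mother, params)
    da.M = mother.M * (L_a_b / L)
    db.M = mother.M * (L_b_b / L)
    return da, db


def initial_division_fate(rng: np.random.Generator, params: ModelParams) -> str:
    """Fate of the initial's non-initial daughter: 'phloem' or 'xylem'.

    Phloem with probability f_phloem; phloem daughters leave the tracked
    file (only xylem-forming cells are modelled explicitly).
    """
    return "phloem" if rng.random() < params.f_phloem else "xylem"
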