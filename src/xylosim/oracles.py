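"""Test-support fixtures and brute-force oracles.

These helpers are deliberately independent of the production code paths
they verify: the transport fixed point lives in :mod:`xylosim.transport`
(Picard iteration vs. Brent), while here are constructed ring fixtures, a
single-cell closed form, a day-by-day dormancy enactment, and a lineage
enactment of the division rules.  They ship with the package so the
verification suite can be re-run by users.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import RingRecord
from .params import ModelParams

__all__ = [
    "make_two_block_ring",
    "random_demand_set",
    "single_cell_theta_closed_form",
    "dormancy_release_day_oracle",
    "lineage_oracle",
]


def make_two_block_ring(
    n_early: int,
    n_late: int,
    densities: tuple[float, float] = (0.4, 0.9),
    lengths: tuple[float, float] = (35.0, 15.0),
    params: ModelParams | None = None,
    year: int = 0,
    file_id: int = 0,
) -> RingRecord:
    """Deterministic synthetic ring: a block of low-density 'earlywood'
    cells followed by a block of high-density 'latewood' cells.

    Densities are in g cm^-3 and lengths in um; wall masses are back-computed
    so the requested densities are exact.
    """
    params = params or ModelParams()
    if n_early < 0 or n_late < 0:
        raise ValueError("cell counts must be non-negative")
    L = np.array([lengths[0]] * n_early + [lengths[1]] * n_late)
    d = np.array([densities[0]] * n_early + [densities[1]] * n_late)
    V_c = params.La * params.Lt * L / 1.0e12
    M = d * 1.0e3 * V_c  # g cm^-3 -> mg ml^-1 times volume
    return RingRecord(
        year=year,
        file_id=file_id,
        L_r=L,
        M=M,
        birth_order=np.arange(n_early + n_late),
    )


def random_demand_set(n: int, seed: int, span_orders: float = 4.0) -> np.ndarray:
    """Reproducible random saturated demands spanning *span_orders* orders of
    magnitude (mg day^-1), for transport oracle-equivalence tests."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return 10.0 ** rng.uniform(-6.0, -6.0 + span_orders, size=n)


def single_cell_theta_closed_form(dM_max: float, theta_p: float, eta: float, Km: float) -> float:
    """Equilibrium concentration for a single Michaelis-Menten sink.

    Balancing (theta_p - theta)/eta = dM_max * theta/(theta + Km) gives
    theta^2 + (Km + eta*dM_max - theta_p) * theta - theta_p * Km = 0; the
    positive root is the physical solution.
    """
    b = Km + eta * dM_max - theta_p
    c = -theta_p * Km
    return (-b + math.sqrt(b * b - 4.0 * c)) / 2.0


def dormancy_release_day_oracle(
    temps_by_doy: dict[int, float], cd_at_doy32: float, dd_start_doy: int = 32
) -> int | None:
    """Brute-force day-by-day enactment of the spring release rule.

    Walks DOY 32..182 accumulating degree-days max(T, 0) and chill days
    (T < 0), testing dd >= 15 + 4401.8*exp(-0.042*cd) each day.  Returns the
    release DOY or None.
    """
    cd = cd_at_doy32
    dd = 0.0
    for doy in range(dd_start_doy, 183):
        t = temps_by_doy.get(doy, 0.0)
        if t < 0.0:
            cd += 1.0
        dd += max(t, 0.0)
        if dd >= 15.0 + 4401.8 * math.exp(-0.042 * cd):
            return doy
    return None


def lineage_oracle(
    n_generations: int, seed: int, params: ModelParams | None = None
) -> np.ndarray:
    """Enact the division-size rules on a single lineage, brute force.

    Starting from one cell at the mean birth size, repeatedly grow to the
    stochastic division length and keep one random daughter; returns the
    array of birth lengths visited.  Used to check the long-run fixed point
    of the sizer-adder rule (mean division length ~ 2 * chi_b).
    """
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    L_b = params.chi_b
    births = []
    for _ in range(n_generations):
        Z = rng.normal(0.0, params.sigma)
        L_d = params.f * L_b + params.chi_b * (2.0 - params.f + Z)
        Z_a = float(np.clip(rng.normal(0.0, params.sigma_a), -0.49, 0.49))
        frac = 0.5 - Z_a if rng.random() < 0.5 else 0.5 + Z_a
        L_b = max(L_d, 0.0) * frac
        births.append(L_b)
    return np.asarray(births)
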