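"""Equilibrium carbohydrate distribution along a radial file.

Carbohydrates diffuse from the phloem (constant concentration theta_p) along
the living cells of a file, each of which consumes at a Michaelis-Menten rate
set by its saturated wall-growth demand.  Diffusion between adjacent cells is
proportional to the concentration difference divided by a constant
resistance eta, and is assumed fast relative to wall building, so the profile
is in equilibrium each day.  At equilibrium the flux into any cell equals the
summed wall growth of that cell and all cells further from the phloem; the
innermost living cell's wall is impermeable.  The unknown innermost
concentration is found with Brent's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams
from .walls import WallDemand

__all__ = ["TransportSolution", "solve_equilibrium", "fixed_point_oracle"]


@dataclass(frozen=True)
class TransportSolution:
    """Equilibrium concentrations and realized wall growth for one file-day.

    ``theta`` and ``dM`` are ordered from the cell adjacent to the phloem
    inward; ``flux_in`` is the total carbohydrate flux from the phloem
    (mg day^-1).
    """

    theta: np.ndarray
    dM: np.ndarray
    flux_in: float
    iterations: int


def _as_dmax(demands) -> list[float]:
    out = []
    for d in demands:
        v = d.dM_max if isinstance(d, WallDemand) else float(d)
        if v < 0:
            raise ValueError("demands must be non-negative")
        out.append(float(v))
    return out


def _sweep(theta_n: float, dmax: list[float], theta_p: float, eta: float, Km: float):
    """Reconstruct the profile outward from a trial innermost concentration.

    Returns (theta list phloem->inward, dM list, reconstructed phloem
    boundary concentration).
    """
    n = len(dmax)
    theta = [0.0] * n
    dM = [0.0] * n
    t = max(theta_n, 0.0)
    cum = 0.0
    for j in range(n - 1, -1, -1):
        theta[j] = t
        m = dmax[j] * t / (t + Km) if t > 0.0 else 0.0
        dM[j] = m
        cum += m
        t = t + eta * cum
    return theta, dM, t


def solve_equilibrium(demands, theta_p: float, eta: float, params: ModelParams) -> TransportSolution:
    """Solve the daily source-sink equilibrium for one radial file.

    *demands* are per-living-cell saturated rates ordered from the cell
    adjacent to the phloem inward.  The innermost concentration theta_n is
    bracketed in [0, theta_p]: the reconstructed phloem boundary is 0 at
    theta_n = 0 and >= theta_p at theta_n = theta_p, so a root always exists
    and is unique (the boundary value is strictly increasing in theta_n).
    """
    dmax = _as_dmax(demands)
    n = len(dmax)
    if n < 1:
        raise ValueError("need at least one living cell")
    if theta_p < 0:
        raise ValueError("theta_p must be >= 0")
    Km = params.Km
    if theta_p == 0.0 or all(v == 0.0 for v in dmax):
        theta = np.full(n, theta_p)
        return TransportSolution(theta=theta, dM=np.zeros(n), flux_in=0.0, iterations=0)

    def residual(theta_n: float) -> float:
        return _sweep(theta_n, dmax, theta_p, eta, Km)[2] - theta_p

    try:
        root, info = brentq(
            residual, 0.0, theta_p, xtol=1e-14, rtol=8.9e-16, maxiter=200, full_output=True
        )
    except ValueError as exc:  # pragma: no cover - bracket holds by construction
        raise RuntimeError(
            f"transport bracket failure: theta_p={theta_p}, eta={eta}, demands={dmax}"
        ) from exc
    _, dM, _ = _sweep(root, dmax, theta_p, eta, Km)
    # rebuild the profile inward from the phloem so the boundary condition
    # holds exactly and the flux from the phloem, (theta_p - theta_1)/eta,
    # equals the total wall growth identically rather than to the
    # root-finding residual
    theta = np.empty(n)
    tails = np.cumsum(dM[::-1])[::-1]
    t = theta_p
    for j in range(n):
        t = max(t - eta * tails[j], 0.0)
        theta[j] = t
    flux_in = (theta_p - theta[0]) / eta
    return TransportSolution(
        theta=theta, dM=np.asarray(dM), flux_in=flux_in, iterations=int(info.iterations)
    )


def fixed_point_oracle(
    demands,
    theta_p: float,
    eta: float,
    params: ModelParams,
    damping: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> TransportSolution:
    """Damped Picard iteration on the full concentration vector.

    Independent verification route for :func:`solve_equilibrium`: iterate
    theta_i <- theta_{i-1} - eta * sum_{k>=i} dM_k(theta) (with theta_0 the
    phloem) under damping until the profile is stationary.  The default
    damping is scaled from a Lipschitz bound of the update map (slope of the
    Michaelis-Menten sink is at most dM_max/Km) so the iteration contracts
    even for stiff demand sets.  Test use only.
    """
    dmax = np.asarray(_as_dmax(demands))
    n = len(dmax)
    if n < 1:
        raise ValueError("need at least one living cell")
    Km = params.Km
    if damping is None:
        lipschitz = eta / Km * float(np.sum(np.arange(1, n + 1) * dmax[::-1]))
        damping = min(0.5, 1.0 / (1.0 + lipschitz))
    theta = np.full(n, theta_p, dtype=float)
    check_delta, check_every = np.inf, 2000
    for it in range(1, max_iter + 1):
        dM = dmax * theta / (theta + Km)
        # cumulative demand inward of (and including) each cell
        tail = np.cumsum(dM[::-1])[::-1]
        drops = eta * tail
        new = theta_p - np.cumsum(drops)
        new = np.clip(new, 0.0, theta_p)
        delta = np.max(np.abs(new - theta))
        if it % check_every == 0:
            # the clip at zero can trap the iteration in a limit cycle;
            # halve the step whenever a checkpoint shows no progress
            if delta > 0.5 * check_delta:
                damping = max(damping * 0.5, 1e-7)
            check_delta = delta
        theta = (1.0 - damping) * theta + damping * new
        if delta < tol:
            dM = dmax * theta / (theta + Km)
            return TransportSolution(
                theta=theta, dM=dM, flux_in=float(dM.sum()), iterations=it
            )
    raise RuntimeError("fixed-point oracle failed to converge")
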