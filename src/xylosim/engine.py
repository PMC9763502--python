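"""Daily simulation engine: radial files, annual cycle, and ensembles.

Each radial file is an ordered column of cells, index 0 (the cambial
initial) adjacent to the phloem and indices increasing inward.  Every day
cells are classified into developmental zones by the distance of their
centre from the inner phloem edge, enlarged and divided (when not dormant),
and supplied with carbohydrates by the equilibrium transport solve; wall
mass is then deposited.  At the end of each year all cells outside the
proliferation zone are finalized into the annual ring and the remaining
cambial cells are carried over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cells import Cell, Role, Status, divide, division_length, initial_division_fate
from .climate import ClimateDay
from .params import ModelParams, ScenarioConfig
from .transport import solve_equilibrium
from .walls import (
    arrhenius_wall_factor,
    cell_volume,
    lumen_volume,
    max_wall_growth,
    primary_wall_volume,
)
from .zones import ZoneModel, ZoneState

__all__ = ["RadialFile", "RingRecord", "initialize_file", "step_day", "step_year", "run_ensemble"]

CELSIUS_TO_KELVIN = 273.15


class SimulationError(RuntimeError):
    """An internal invariant was violated during integration."""


@dataclass
class RingRecord:
    """One finalized annual ring of one radial file.

    Per-cell arrays are ordered along the ring coordinate: index 0 is the
    earliest-formed (innermost, earlywood) side.
    """

    year: int
    file_id: int
    L_r: np.ndarray  # final radial lengths, um
    M: np.ndarray  # final wall masses, mg
    birth_order: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.L_r)

    @property
    def ring_width(self) -> float:
        return float(self.L_r.sum())

    @property
    def ring_mass(self) -> float:
        return float(self.M.sum())

    def volumes(self, params: ModelParams) -> np.ndarray:
        """Per-cell volumes V_c, ml."""
        return params.La * params.Lt * self.L_r / 1.0e12

    def densities(self, params: ModelParams) -> np.ndarray:
        """Per-cell mass densities, g cm^-3."""
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(self.L_r > 0, self.M / self.volumes(params) / 1.0e3, 0.0)
        return d

    def positions(self) -> np.ndarray:
        """Cell mid-point distances from the ring start (earlywood side), um."""
        ends = np.cumsum(self.L_r)
        return ends - self.L_r / 2.0


@dataclass
class RadialFile:
    """Ordered cells of one radial file plus its private RNG stream."""

    file_id: int
    cells: list[Cell]
    rng: np.random.Generator
    next_id: int = 0
    next_birth_order: int = 0
    mass_to_phloem: float = 0.0  # cumulative mass lost with discarded phloem daughters
    flux_in_total: float = 0.0  # cumulative carbohydrate import from the phloem, mg
    warnings: list[str] = field(default_factory=list)

    def centers(self) -> list[float]:
        """Distance of each cell's centre from the inner phloem edge, um."""
        out = []
        pos = 0.0
        for c in self.cells:
            out.append(pos + c.L_r / 2.0)
            pos += c.L_r
        return out

    def total_mass(self) -> float:
        return sum(c.M for c in self.cells)


def initialize_file(
    file_id: int,
    seed,
    params: ModelParams,
    z_p_day1: float,
    year: int = 0,
) -> RadialFile:
    """Build the initial cambium of one file.

    100 provisional cells with radial lengths chi_b*(1 + Z_a) each divide
    once; the second daughter of each division is discarded and the
    remaining daughters are kept only while they fall inside the
    proliferation zone on DOY 1 (width *z_p_day1*, the dormant width).  Each
    retained cell receives its growth factor epsilon and stochastic division
    length; cell 0 is the initial.  New cells start with a complete primary
    wall for their size.
    """
    rng = np.random.default_rng(seed)
    daughters = []
    for _ in range(100):
        Z_a0 = float(np.clip(rng.normal(0.0, params.sigma_a), -0.49, 0.49))
        L_mother = params.chi_b * (1.0 + Z_a0)
        Z_a = float(np.clip(rng.normal(0.0, params.sigma_a), -0.49, 0.49))
        L_b = L_mother * (0.5 - Z_a)
        alpha_b = -2.0 * Z_a  # asymmetry relative to the (discarded) sister
        Z = float(rng.normal(0.0, params.sigma))
        daughters.append((L_b, 1.0 - params.g_asym * alpha_b, division_length(L_b, Z, params)))

    cells: list[Cell] = []
    pos = 0.0
    for L_b, eps, L_d in daughters:
        if pos + L_b / 2.0 > z_p_day1:
            break
        cells.append(
            Cell(
                id=len(cells),
                role=Role.INITIAL if not cells else Role.XYLEM,
                status=Status.PROLIFERATING,
                L_r=L_b,
                L_r_b=L_b,
                epsilon=eps,
                L_r_d=L_d,
                M=params.rho * primary_wall_volume(L_b, params),
                theta=params.theta_p,
                birth_order=0,
                year_born=year,
            )
        )
        pos += L_b
    if not cells:
        raise SimulationError(
            f"file {file_id}: no cells fit in the DOY-1 proliferation zone (z_p={z_p_day1:.1f} um)"
        )
    # deeper cells are the older material: birth order increases outward->0
    n = len(cells)
    for i, c in enumerate(cells):
        c.birth_order = n - 1 - i
    return RadialFile(
        file_id=file_id, cells=cells, rng=rng, next_id=n, next_birth_order=n
    )


def _effective_temps(day: ClimateDay, scenario: ScenarioConfig) -> tuple[float, float, float]:
    """(T for proliferation-zone enlargement, T for enlargement-zone
    enlargement, T for wall building), in K, after scenario overrides."""
    base = day.t_mean if scenario.fixed_temp_C is None else scenario.fixed_temp_C
    targets = scenario.delta_T_targets
    dt = scenario.delta_T_K
    t_prolif = base + (dt if targets & {"enlargement_rate", "proliferation_zone_cells"} else 0.0)
    t_enlarge = base + (dt if targets & {"enlargement_rate", "enlargement_zone_cells"} else 0.0)
    t_wall = base + (dt if "thickening_rate" in targets else 0.0)
    return (
        t_prolif + CELSIUS_TO_KELVIN,
        t_enlarge + CELSIUS_TO_KELVIN,
        t_wall + CELSIUS_TO_KELVIN,
    )


def step_day(
    file: RadialFile,
    zone_state: ZoneState,
    day: ClimateDay,
    scenario: ScenarioConfig,
    params: ModelParams,
) -> None:
    """Advance one radial file by one day (in place).

    Sub-steps: classify cells by zone; enlarge (unless dormant); divide
    proliferating cells at/above their division length; build per-cell wall
    demands; solve the carbohydrate equilibrium (or bypass it under sugar
    saturation); deposit wall mass; mature cells beyond the thickening zone.
    """
    z_p, z_e, z_t = zone_state.z_p, zone_state.z_e, zone_state.z_t
    T_prolif_K, T_enl_K, T_wall_K = _effective_temps(day, scenario)

    # (1) classify by centre distance (forward-only transitions)
    centers = file.centers()
    for c, x in zip(file.cells, centers):
        if c.status is Status.MATURE:
            continue
        if x <= z_p:
            new = Status.PROLIFERATING
        elif x <= z_e:
            new = Status.ENLARGING
        else:
            new = Status.THICKENING
        c.advance_status(new)

    # (2) enlargement of proliferation- and enlargement-zone cells
    if not zone_state.dormant:
        mu_prolif = params.mu0 * math.exp(
            (params.Ea / params.k_B) * (1.0 / params.T0 - 1.0 / T_prolif_K)
        )
        mu_enl = params.mu0 * math.exp(
            (params.Ea / params.k_B) * (1.0 / params.T0 - 1.0 / T_enl_K)
        )
        for c in file.cells:
            if c.status is Status.PROLIFERATING:
                c.L_r *= math.exp(c.epsilon * mu_prolif)
            elif c.status is Status.ENLARGING:
                c.L_r *= math.exp(c.epsilon * mu_enl)

        # (3) division of proliferating cells that reached threshold
        i = 0
        while i < len(file.cells):
            c = file.cells[i]
            if c.status is Status.PROLIFERATING and c.L_r >= c.L_r_d:
                da, db = divide(c, file.rng, params, id_start=file.next_id)
                file.next_id += 2
                da.year_born = db.year_born = day.year
                # inward daughter forms first along the ring coordinate
                db.birth_order = file.next_birth_order
                da.birth_order = file.next_birth_order + 1
                file.next_birth_order += 2
                if c.role is Role.INITIAL:
                    # outer daughter remains the initial; the other goes to
                    # phloem (discarded) or becomes a xylem mother cell
                    da.role = Role.INITIAL
                    if initial_division_fate(file.rng, params) == "phloem":
                        file.mass_to_phloem += db.M
                        file.cells[i : i + 1] = [da]
                        i += 1
                        continue
                file.cells[i : i + 1] = [da, db]
                i += 2
            else:
                i += 1

    # (5) wall-growth demands for living cells and transport solve
    living = [c for c in file.cells if c.status is not Status.MATURE]
    if any(c.status is Status.MATURE for c in file.cells[: len(living)]):
        raise SimulationError(
            f"file {file.file_id} day {day.year}-{day.doy}: mature cell outward of a living cell"
        )
    wall_factor = arrhenius_wall_factor(T_wall_K, params)
    demands = []
    for c in living:
        if c.status is Status.THICKENING:
            V_l = lumen_volume(c.L_r, c.M, params)
            demands.append(params.omega * V_l * wall_factor)
        elif zone_state.dormant:
            demands.append(0.0)  # primary-wall growth pauses with dormancy
        else:
            V_l = lumen_volume(c.L_r, c.M, params)
            dM_max = params.omega * V_l * wall_factor
            headroom = max(params.rho * primary_wall_volume(c.L_r, params) - c.M, 0.0)
            demands.append(min(dM_max, headroom))

    if living:
        if scenario.sugar_saturation:
            for c, dM in zip(living, demands):
                c.M += dM
                c.theta = params.theta_p
            file.flux_in_total += sum(demands)
        elif any(d > 0.0 for d in demands):
            sol = solve_equilibrium(demands, params.theta_p, params.eta, params)
            for c, th, dM in zip(living, sol.theta, sol.dM):
                c.theta = float(th)
                c.M += dM
            file.flux_in_total += float(sol.dM.sum())
        else:
            for c in living:
                c.theta = params.theta_p

    # (7) cells beyond the thickening zone lose their protoplasm
    centers = file.centers()
    for c, x in zip(file.cells, centers):
        if x > z_t:
            c.advance_status(Status.MATURE)


def finalize_year(file: RadialFile, zone_state: ZoneState, year: int) -> RingRecord:
    """Close the annual ring: cells outside the proliferation zone are
    finalized (innermost first = earlywood side) and removed; proliferation
    -zone cells, including the initial, are carried over."""
    centers = file.centers()
    keep, ring = [], []
    for c, x in zip(file.cells, centers):
        if x <= zone_state.z_p and c.status in (Status.PROLIFERATING, Status.ENLARGING):
            keep.append(c)
        else:
            ring.append(c)
    if not keep or keep[0].role is not Role.INITIAL:
        raise SimulationError(f"file {file.file_id}: initial lost at year {year} boundary")
    n_unfinished = sum(1 for c in ring if c.status is not Status.MATURE)
    if n_unfinished:
        file.warnings.append(f"{year}: {n_unfinished} cells finalized before maturing")
    ring.reverse()  # innermost (earliest-formed) cell first along the ring
    file.cells = keep
    return RingRecord(
        year=year,
        file_id=file.file_id,
        L_r=np.array([c.L_r for c in ring]),
        M=np.array([c.M for c in ring]),
        birth_order=np.array([c.birth_order for c in ring], dtype=int),
    )


def step_year(
    file: RadialFile,
    zone_states: list[ZoneState],
    climate_year: list[ClimateDay],
    scenario: ScenarioConfig,
    params: ModelParams,
) -> RingRecord:
    """Run one file through one year of pre-computed zone states and close
    the ring."""
    if len(zone_states) != len(climate_year):
        raise ValueError("zone state and climate sequences differ in length")
    for zs, day in zip(zone_states, climate_year):
        step_day(file, zs, day, scenario, params)
    return finalize_year(file, zone_states[-1], climate_year[-1].year)


def growing_season_cell_count(
    n_files: int,
    climate: list[ClimateDay],
    scenario: ScenarioConfig,
    params: ModelParams,
    latitude: float,
    seed: int,
    spinup_years: int = 0,
) -> float:
    """Mean number of cells per radial file averaged over growing-season days.

    The growing season of a year runs from dormancy release to the autumn
    dormancy DOY; the count includes every cell of the developing ring (the
    cambial cells plus all derivatives not yet shed to the sapwood).
    Averaged over files, growing-season days, and post-spin-up years; used
    for paired temperature-response experiments.
    """
    zone_model = ZoneModel(
        params,
        latitude,
        fixed_zone_widths_doy=scenario.fixed_zone_widths_doy,
        autumn_dormancy=scenario.autumn_dormancy,
    )
    zone_states: list[ZoneState] = []
    zs = ZoneState()
    for day in climate:
        zs = zone_model.step(zs, day)
        zone_states.append(zs)
    year_slices: list[tuple[int, slice]] = []
    start = 0
    for i in range(1, len(climate) + 1):
        if i == len(climate) or climate[i].year != climate[start].year:
            year_slices.append((climate[start].year, slice(start, i)))
            start = i
    seeds = np.random.SeedSequence(seed).spawn(n_files)
    means = []
    for f in range(n_files):
        file = initialize_file(f, seeds[f], params, zone_states[0].z_p)
        for j, (year, sl) in enumerate(year_slices):
            counts = []
            for z, day in zip(zone_states[sl], climate[sl]):
                step_day(file, z, day, scenario, params)
                if z.release_doy is not None and z.release_doy <= min(day.doy, 365) <= params.dorm_doy:
                    counts.append(len(file.cells))
            finalize_year(file, zone_states[sl][-1], year)
            if j >= spinup_years and counts:
                means.append(float(np.mean(counts)))
    return float(np.mean(means))


def run_ensemble(
    n_files: int,
    climate: list[ClimateDay],
    scenario: ScenarioConfig,
    params: ModelParams,
    latitude: float,
    seed: int,
    spinup_years: int = 0,
) -> tuple[list[list[RingRecord]], list[ZoneState]]:
    """Simulate an ensemble of independent radial files.

    Returns (rings, zone_states): ``rings[f]`` is the list of annual
    RingRecords of file *f* for the post-spin-up years, and ``zone_states``
    the daily zone/dormancy trajectory shared by all files.  Per-file RNG
    streams are spawned deterministically from *seed*, so results are
    bit-reproducible.
    """
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    zone_model = ZoneModel(
        params,
        latitude,
        fixed_zone_widths_doy=scenario.fixed_zone_widths_doy,
        autumn_dormancy=scenario.autumn_dormancy,
    )
    # shared deterministic zone/dormancy trajectory
    zone_states: list[ZoneState] = []
    zs = ZoneState()
    forcing = climate
    if scenario.dormancy_forcing_uses_anomaly and scenario.delta_T_K:
        from dataclasses import replace as _replace

        forcing = [_replace(d, t_mean=d.t_mean + scenario.delta_T_K) for d in climate]
    for day in forcing:
        zs = zone_model.step(zs, day)
        zone_states.append(zs)

    # split by calendar year
    year_slices: list[tuple[int, slice]] = []
    start = 0
    for i in range(1, len(climate) + 1):
        if i == len(climate) or climate[i].year != climate[start].year:
            year_slices.append((climate[start].year, slice(start, i)))
            start = i

    seeds = np.random.SeedSequence(seed).spawn(n_files)
    rings: list[list[RingRecord]] = []
    for f in range(n_files):
        file = initialize_file(f, seeds[f], params, zone_states[0].z_p)
        records = []
        for j, (year, sl) in enumerate(year_slices):
            rec = step_year(file, zone_states[sl], climate[sl], scenario, params)
            if j >= spinup_years:
                records.append(rec)
        rings.append(records)
    return rings, zone_states
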