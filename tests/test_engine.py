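import copy

import numpy as np
import pytest

from xylosim.cells import Status
from xylosim.climate import ClimateDay
from xylosim.engine import (
    SimulationError,
    finalize_year,
    growing_season_cell_count,
    initialize_file,
    run_ensemble,
    step_day,
)
from xylosim.params import ModelParams, ScenarioConfig
from xylosim.zones import ZoneModel, ZoneState

LAT = 64.35


def zone_trajectory(climate, params, **kw):
    zm = ZoneModel(params, LAT, **kw)
    zs = ZoneState()
    out = []
    for d in climate:
        zs = zm.step(zs, d)
        out.append(zs)
    return out


class TestInitializeFile:
    def test_retained_count_matches_protocol(self, params):
        # dormant-zone width ~69 um over ~4.4 um mean daughter length
        zs = ZoneState()
        from xylosim.zones import zone_widths
        from xylosim.climate import daylength

        z_p = zone_widths(daylength(LAT, 1), 1, True, params, LAT)[0]
        counts = [len(initialize_file(i, i, params, z_p).cells) for i in range(20)]
        assert all(8 <= c <= 25 for c in counts)
        assert np.mean(counts) == pytest.approx(z_p / (params.chi_b / 2), rel=0.3)

    def test_cells_fit_inside_zone_with_traits(self, params):
        f = initialize_file(0, 42, params, 65.0)
        pos = 0.0
        for c in f.cells:
            assert pos + c.L_r / 2 <= 65.0
            pos += c.L_r
            assert c.L_r_d > 0 and c.epsilon > 0
            assert c.status is Status.PROLIFERATING
        assert f.cells[0].role.value == "initial"

    def test_degenerate_zone_raises(self, params):
        with pytest.raises(SimulationError):
            initialize_file(0, 42, params, 0.5)

    def test_seed_determinism(self, params):
        a = initialize_file(0, 7, params, 65.0)
        b = initialize_file(0, 7, params, 65.0)
        c = initialize_file(0, 8, params, 65.0)
        assert [x.L_r for x in a.cells] == [x.L_r for x in b.cells]
        assert [x.L_r for x in a.cells] != [x.L_r for x in c.cells]


class TestStepDay:
    def _active_state(self, params):
        return ZoneState(dormant=False, z_p=100.0, z_e=400.0, z_t=950.0, last_doy=169)

    def test_dormant_day_freezes_growth_zones(self, params, default_scenario):
        f = initialize_file(0, 3, params, 65.0)
        state = ZoneState(dormant=True, z_p=65.0, z_e=65.0, z_t=65.0, last_doy=9)
        before = [(c.L_r, c.M) for c in f.cells]
        day = ClimateDay(1995, 10, 15.0, 6.0)
        step_day(f, state, day, default_scenario, params)
        after = [(c.L_r, c.M) for c in f.cells]
        assert before == after

    def test_thickening_continues_during_dormancy(self, params, default_scenario):
        f = initialize_file(0, 3, params, 65.0)
        # push one cell into the thickening band by shrinking the zones
        state = ZoneState(dormant=True, z_p=20.0, z_e=20.0, z_t=500.0, last_doy=250)
        day = ClimateDay(1995, 251, 10.0, 10.0)
        masses_before = [c.M for c in f.cells]
        step_day(f, state, day, default_scenario, params)
        thick = [c for c in f.cells if c.status is Status.THICKENING]
        assert thick
        assert sum(c.M for c in f.cells) > sum(masses_before)

    def test_daily_mass_gain_equals_phloem_flux(self, params, default_scenario):
        f = initialize_file(0, 5, params, 65.0)
        state = self._active_state(params)
        day = ClimateDay(1995, 170, 14.0, 21.0)
        m0 = f.total_mass()
        flux0 = f.flux_in_total
        step_day(f, state, day, default_scenario, params)
        gain = f.total_mass() - m0 + f.mass_to_phloem
        assert gain == pytest.approx(f.flux_in_total - flux0, abs=1e-9)

    def test_growth_and_division_on_warm_day(self, params, default_scenario):
        f = initialize_file(0, 5, params, 65.0)
        state = self._active_state(params)
        n0 = len(f.cells)
        total0 = sum(c.L_r for c in f.cells)
        for doy in range(170, 200):
            state = ZoneState(
                dormant=False, z_p=100.0, z_e=400.0, z_t=950.0, last_doy=doy - 1
            )
            step_day(f, state, ClimateDay(1995, doy, 15.0, 21.0), default_scenario, params)
        assert len(f.cells) > n0
        assert sum(c.L_r for c in f.cells) > total0

    def test_statuses_ordered_along_file(self, params, default_scenario, short_climate):
        zstates = zone_trajectory(short_climate, params)
        f = initialize_file(0, 11, params, zstates[0].z_p)
        rank_seq = []
        for zs, day in zip(zstates[:730], short_climate[:730]):
            step_day(f, zs, day, default_scenario, params)
            ranks = [c.rank for c in f.cells]
            assert ranks == sorted(ranks), f"statuses out of order on {day.year}-{day.doy}"

    def test_monotone_cell_state(self, params, default_scenario, short_climate):
        zstates = zone_trajectory(short_climate, params)
        f = initialize_file(0, 13, params, zstates[0].z_p)
        prev = {}
        for zs, day in zip(zstates[:730], short_climate[:730]):
            step_day(f, zs, day, default_scenario, params)
            for c in f.cells:
                if c.id in prev:
                    L_old, M_old = prev[c.id]
                    assert c.L_r >= L_old - 1e-12
                    assert c.M >= M_old - 1e-12
                prev[c.id] = (c.L_r, c.M)


class TestAnnualCycle:
    def test_permanent_dormancy_gives_empty_ring(self, params, default_scenario):
        f = initialize_file(0, 5, params, 65.0)
        state = ZoneState(dormant=True, z_p=65.0, z_e=65.0, z_t=65.0)
        n0 = len(f.cells)
        ring = finalize_year(f, state, 1995)
        assert ring.n_cells == 0
        assert len(f.cells) == n0

    def test_ring_partition_no_cell_in_two_rings(self, params, short_climate):
        rings, _ = run_ensemble(2, short_climate, ScenarioConfig(), params, LAT, seed=3)
        for recs in rings:
            seen = set()
            for ring in recs:
                ids = {(ring.year, i) for i in range(ring.n_cells)}
                orders = set(ring.birth_order.tolist())
                assert not (orders & seen), "birth order reused across rings"
                seen |= orders

    def test_ring_size_order_of_magnitude(self, params, short_climate):
        # boreal default run produces rings of some tens of cells per file
        rings, _ = run_ensemble(3, short_climate, ScenarioConfig(), params, LAT, seed=3,
                                spinup_years=2)
        counts = [r.n_cells for recs in rings for r in recs]
        assert all(20 <= c <= 90 for c in counts)

    def test_ring_density_bounded_by_wall_density(self, params, short_climate):
        rings, _ = run_ensemble(2, short_climate, ScenarioConfig(), params, LAT, seed=3,
                                spinup_years=2)
        for recs in rings:
            for ring in recs:
                dens = ring.densities(params)
                assert np.all(dens <= params.rho / 1000.0 + 1e-9)
                assert np.all(dens >= 0)

    def test_mass_closure_over_full_run(self, params, short_climate, default_scenario):
        zstates = zone_trajectory(short_climate, params)
        f = initialize_file(0, 21, params, zstates[0].z_p)
        m_init = f.total_mass()
        ring_mass = 0.0
        year_start = 0
        for i, (zs, day) in enumerate(zip(zstates, short_climate)):
            step_day(f, zs, day, default_scenario, params)
            if i + 1 == len(short_climate) or short_climate[i + 1].year != day.year:
                ring = finalize_year(f, zs, day.year)
                ring_mass += ring.ring_mass
        lhs = m_init + f.flux_in_total
        rhs = ring_mass + f.total_mass() + f.mass_to_phloem
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_ensemble_bit_reproducibility(self, params, short_climate):
        a, _ = run_ensemble(3, short_climate, ScenarioConfig(), params, LAT, seed=9)
        b, _ = run_ensemble(3, short_climate, ScenarioConfig(), params, LAT, seed=9)
        for ra, rb in zip(a, b):
            for x, y in zip(ra, rb):
                assert np.array_equal(x.L_r, y.L_r)
                assert np.array_equal(x.M, y.M)
        c, _ = run_ensemble(3, short_climate, ScenarioConfig(), params, LAT, seed=10)
        assert not np.array_equal(a[0][-1].L_r, c[0][-1].L_r)

    def test_files_are_independent(self, params, short_climate):
        # file 0 of a 1-file ensemble matches file 0 of a 3-file ensemble
        a, _ = run_ensemble(1, short_climate, ScenarioConfig(), params, LAT, seed=9)
        b, _ = run_ensemble(3, short_climate, ScenarioConfig(), params, LAT, seed=9)
        for x, y in zip(a[0], b[0]):
            assert np.array_equal(x.L_r, y.L_r)

    def test_growing_season_count_positive_and_reproducible(self, params, short_climate):
        n1 = growing_season_cell_count(
            2, short_climate, ScenarioConfig(), params, LAT, seed=4, spinup_years=2
        )
        n2 = growing_season_cell_count(
            2, short_climate, ScenarioConfig(), params, LAT, seed=4, spinup_years=2
        )
        assert n1 == n2
        assert 10 <= n1 <= 90
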