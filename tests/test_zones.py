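import math

import numpy as np
import pytest

from xylosim.climate import ClimateDay, daylength, synthesize_climate
from xylosim.oracles import dormancy_release_day_oracle
from xylosim.params import ModelParams
from xylosim.zones import (
    ZoneModel,
    ZoneState,
    dormancy_release_threshold,
    update_dormancy,
    zone_widths,
)

LAT = 64.35


class TestZoneWidths:
    def test_post_midsummer_direct_evaluation(self, params):
        # raw linear responses at 20 h daylength, after the DOY-185 switch
        z_p, z_e, z_t = zone_widths(20.0, 200, False, params, LAT)
        assert z_p == pytest.approx(-50.9 + 7.47 * 20.0, abs=1e-9)  # 98.5
        assert z_t == pytest.approx(-427.0 + 68.8 * 20.0, abs=1e-9)  # 949
        assert z_e == pytest.approx(-744.0 + 51.7 * 20.0, abs=1e-9)  # 290

    def test_ordering_enforced_outward(self, params):
        # late autumn: raw z_e falls below z_p and is raised to it
        dl = 10.0
        z_p, z_e, z_t = zone_widths(dl, 280, False, params, LAT)
        assert -744.0 + 51.7 * dl < z_p
        assert z_e == z_p
        assert z_t >= z_e >= z_p >= 0.0

    def test_proliferation_frozen_before_midsummer(self, params):
        # non-dormant early season: z_p pinned at its DOY-185 (maximum) value
        dl185 = daylength(LAT, 185)
        expected = -50.9 + 7.47 * dl185
        for doy, dl in [(140, 17.0), (160, 20.5), (184, 21.0)]:
            z_p, _, _ = zone_widths(dl, doy, False, params, LAT)
            assert z_p == pytest.approx(expected)

    def test_proliferation_dormant_width(self, params):
        dl231 = daylength(LAT, params.dorm_doy)
        expected = -50.9 + 7.47 * dl231
        z_p, _, _ = zone_widths(5.0, 300, True, params, LAT)
        assert z_p == pytest.approx(expected)

    def test_early_enlargement_zone_is_linear_in_doy(self, params):
        # before DOY 185 the enlargement-only zone extends the post-185
        # seasonal trend linearly in time
        vals = []
        for doy in (120, 150, 180):
            _, z_e, _ = zone_widths(18.0, doy, False, params, LAT)
            vals.append(z_e)
        assert vals[0] == pytest.approx(1257.0 - 5.01 * 120)
        diffs = np.diff(vals)
        assert diffs[0] == pytest.approx(-5.01 * 30, abs=1e-9)
        assert diffs[1] == pytest.approx(-5.01 * 30, abs=1e-9)

    def test_cap_at_24h_daylength_value(self, params):
        # north of the Arctic circle widths saturate at their 24-h values
        z_p24, z_e24, z_t24 = zone_widths(24.0, 200, False, params, LAT)
        z_p, z_e, z_t = zone_widths(24.0, 200, False, params, 70.0)
        assert (z_p, z_e, z_t) == (z_p24, z_e24, z_t24)
        assert z_t == pytest.approx(-427.0 + 68.8 * 24.0)

    def test_affine_slope_in_daylength(self, params):
        # finite-difference slope matches the regression slope below the cap
        h = 0.01
        for dl in (16.0, 18.0, 20.0):
            z1 = zone_widths(dl, 200, False, params, LAT)
            z2 = zone_widths(dl + h, 200, False, params, LAT)
            assert (z2[0] - z1[0]) / h == pytest.approx(7.47, rel=1e-6)
            assert (z2[1] - z1[1]) / h == pytest.approx(51.7, rel=1e-6)
            assert (z2[2] - z1[2]) / h == pytest.approx(68.8, rel=1e-6)


class TestReleaseThreshold:
    def test_derived_values(self):
        assert dormancy_release_threshold(0.0) == pytest.approx(4416.8)
        assert dormancy_release_threshold(50.0) == pytest.approx(
            15.0 + 4401.8 * math.exp(-2.1), rel=1e-12
        )

    def test_asymptote_and_monotonicity(self):
        assert dormancy_release_threshold(600.0) == pytest.approx(15.0, abs=1e-6)
        cds = np.linspace(0, 300, 40)
        vals = [dormancy_release_threshold(c) for c in cds]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_cd_rejected(self):
        with pytest.raises(ValueError):
            dormancy_release_threshold(-1.0)


def _run_days(state, days, params):
    for d in days:
        state = update_dormancy(state, d, params)
    return state


def _make_days(year, temps_by_doy, lat=LAT):
    return [
        ClimateDay(year, doy, temps_by_doy(doy), daylength(lat, doy)) for doy in range(1, 366)
    ]


class TestDormancy:
    def test_never_released_when_frozen(self, params):
        days = _make_days(1995, lambda doy: -5.0)
        state = _run_days(ZoneState(), days, params)
        assert state.dormant and state.release_doy is None

    def test_release_matches_brute_force_oracle(self, params):
        # mild winter then a steady +10 C spring from DOY 32
        def temps(doy):
            return -3.0 if doy < 32 or doy >= 280 else 10.0

        days = _make_days(1995, temps)
        state = ZoneState(cd=100.0)  # carried chilling from a prior autumn
        state = _run_days(state, days, params)
        # the 31 January chill days join the carried 100 before forcing starts
        expected = dormancy_release_day_oracle({d: temps(d) for d in range(32, 366)}, 131.0)
        assert expected is not None
        assert state.release_doy == expected

    def test_reimposed_on_dormancy_doy(self, params):
        days = _make_days(1995, lambda doy: 15.0)
        state = ZoneState(cd=150.0)
        for d in days:
            state = update_dormancy(state, d, params)
            if d.doy == params.dorm_doy:
                assert state.dormant
            if state.release_doy and state.release_doy <= d.doy < params.dorm_doy:
                assert not state.dormant

    def test_release_only_first_half_of_year(self, params):
        # warmth arriving only after midsummer cannot release dormancy
        days = _make_days(1995, lambda doy: 20.0 if doy > 183 else -1.0)
        state = _run_days(ZoneState(cd=150.0), days, params)
        assert state.release_doy is None

    def test_release_monotone_in_chill_days(self, params):
        def temps(doy):
            return -3.0 if doy < 60 or doy >= 280 else 0.1 * (doy - 60)

        days = _make_days(1995, temps)
        release = []
        for cd0 in (0.0, 20.0, 60.0, 120.0, 200.0):
            state = _run_days(ZoneState(cd=cd0), days, params)
            release.append(state.release_doy or 999)
        assert all(a >= b for a, b in zip(release, release[1:]))

    def test_out_of_order_days_rejected(self, params):
        state = ZoneState()
        d1 = ClimateDay(1995, 100, 1.0, 12.0)
        d3 = ClimateDay(1995, 102, 1.0, 12.0)
        state = update_dormancy(state, d1, params)
        with pytest.raises(ValueError):
            update_dormancy(state, d3, params)

    def test_chill_window_partition(self, params):
        # chill days accumulate only from DOY 306 through DOY 31
        state = ZoneState()
        days = _make_days(1995, lambda doy: -5.0)
        cds = []
        for d in days:
            state = update_dormancy(state, d, params)
            cds.append(state.cd)
        assert cds[31 - 1] == 31.0  # all of January counted
        assert cds[200 - 1] == cds[32 - 1]  # nothing added Feb-Oct
        # the counter resets when the new chilling season opens on DOY 306
        assert cds[306 - 1] == 1.0
        assert cds[365 - 1] == 365 - 306 + 1


class TestZoneModel:
    def test_at_most_one_release_per_year(self, params):
        clim = synthesize_climate(LAT, range(1990, 1994), seed=11)
        zm = ZoneModel(params, LAT)
        zs = ZoneState()
        releases = {}
        for d in clim:
            zs = zm.step(zs, d)
            if zs.release_doy is not None:
                releases.setdefault(d.year, set()).add(zs.release_doy)
        for year, r in releases.items():
            assert len(r) == 1
            assert max(r) <= 182

    def test_frozen_widths_constant_all_year(self, params):
        clim = synthesize_climate(LAT, [1995], seed=11)
        zm = ZoneModel(params, LAT, fixed_zone_widths_doy=171)
        zs = ZoneState()
        widths = set()
        for d in clim:
            zs = zm.step(zs, d)
            widths.add((zs.z_p, zs.z_e, zs.z_t))
        assert len(widths) == 1

    def test_no_autumn_dormancy_stays_active(self, params):
        clim = synthesize_climate(LAT, [1994, 1995], seed=11)
        zm = ZoneModel(params, LAT, autumn_dormancy=False)
        zs = ZoneState()
        released = False
        for d in clim:
            zs = zm.step(zs, d)
            if not zs.dormant:
                released = True
            if released:
                assert not zs.dormant
        assert released
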