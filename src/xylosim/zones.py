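"""Developmental-zone widths and dormancy phenology.

The proliferation, enlargement-only and wall-thickening zone widths (distance
of each zone's inner edge from the inner phloem edge, um) respond linearly to
daylength, with regime rules around DOY 185 and a cap at each zone's 24-h
daylength value.  The proliferation and enlargement-only zones enter dormancy
on a fixed DOY in late summer and are released in spring by a
chilling-conditioned degree-day sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .climate import ClimateDay, daylength
from .params import ModelParams

__all__ = ["ZoneState", "ZoneModel", "zone_widths", "dormancy_release_threshold", "update_dormancy"]


@dataclass(frozen=True)
class ZoneState:
    """Dormancy flags, phenology accumulators, and current zone widths."""

    dormant: bool = True
    cd: float = 0.0  # chill-day count since DOY 306
    dd: float = 0.0  # degree-day sum since DOY 32, C day
    release_doy: Optional[int] = None  # DOY of dormancy release this year
    z_p: float = 0.0
    z_e: float = 0.0
    z_t: float = 0.0
    last_doy: Optional[int] = None


def dormancy_release_threshold(cd: float) -> float:
    """Degree-day sum required for dormancy release after *cd* chill days.

    dd_req = 15 + 4401.8 * exp(-0.042 * cd); strictly decreasing with an
    asymptote of 15 C day.
    """
    if cd < 0:
        raise ValueError(f"chill-day count must be >= 0, got {cd}")
    return 15.0 + 4401.8 * math.exp(-0.042 * cd)


def zone_widths(
    dl: float,
    doy: int,
    dormant: bool,
    params: ModelParams,
    latitude: float,
) -> tuple[float, float, float]:
    """Zone inner-edge distances (z_p, z_e, z_t) in um for one day.

    Raw widths are z_k = a_k + b_k * dl with dl in hours.  Regime rules:

    * the proliferation zone uses the DOY-185 daylength on earlier non-dormant
      days (its assumed seasonal maximum) and the DOY-231 daylength while
      dormant;
    * the enlargement-only zone follows its daylength regression from DOY
      185 and, before that, a linear extension in time of that line's
      seasonal rate of change (intercept in um, slope in um per day);
    * each width is capped at its value at 24 h daylength;
    * the ordering z_t >= z_e >= z_p is enforced by raising outer widths to
      the inner ones.
    """
    if not 0.0 <= dl <= 24.0:
        raise ValueError(f"daylength out of range: {dl}")
    zc = params.zone_coeffs
    doy = min(int(doy), 365)

    if dormant:
        dl_p = daylength(latitude, params.dorm_doy)
    elif doy < 185:
        dl_p = daylength(latitude, 185)
    else:
        dl_p = dl
    z_p = min(zc.a_p + zc.b_p * dl_p, zc.a_p + zc.b_p * 24.0)

    if doy < 185:
        # linear extension in time of the post-DOY-185 rate of change:
        # the early-season pair is an intercept (um) and slope (um per day
        # of year), matching the post-185 line's time derivative
        z_e = zc.a_e_early + zc.b_e_early * doy
    else:
        z_e = min(zc.a_e_late + zc.b_e_late * dl, zc.a_e_late + zc.b_e_late * 24.0)

    z_t = min(zc.a_t + zc.b_t * dl, zc.a_t + zc.b_t * 24.0)

    z_p = max(z_p, 0.0)
    z_e = max(z_e, z_p)
    z_t = max(z_t, z_e)
    return z_p, z_e, z_t


def update_dormancy(state: ZoneState, day: ClimateDay, params: ModelParams) -> ZoneState:
    """Advance dormancy flags and phenology accumulators by one day.

    Chill days (T < 0 C) are counted in the window from DOY 306 through
    DOY 31 of the following year; degree-days (sum of max(T, 0)) accumulate
    from DOY 32, resetting each year.  Dormancy
    is released on the first day with doy <= 182 whose degree-day sum reaches
    the chilling-conditioned requirement, and re-imposed on DOY 231.
    Days must be supplied in calendar order.
    """
    doy = min(day.doy, 365)
    if state.last_doy is not None and doy not in (state.last_doy + 1, 1) and not (
        state.last_doy >= 365 and doy == 1
    ):
        raise ValueError(f"days out of calendar order: {state.last_doy} -> {doy}")

    cd, dd = state.cd, state.dd
    dormant, release_doy = state.dormant, state.release_doy

    if doy == 1:
        release_doy = None
    if doy == params.chill_start_doy:
        cd = 0.0
    if doy == params.dd_start_doy:
        dd = 0.0

    # chilling window runs DOY 306 through DOY 31; forcing starts DOY 32
    in_chill_window = doy >= params.chill_start_doy or doy < params.dd_start_doy
    if in_chill_window and day.t_mean < 0.0:
        cd += 1.0
    if dormant and doy >= params.dd_start_doy:
        dd += max(day.t_mean, 0.0)

    if dormant and params.dd_start_doy <= doy <= 182 and dd >= dormancy_release_threshold(cd):
        dormant = False
        release_doy = doy
    if doy == params.dorm_doy:
        dormant = True

    return replace(state, dormant=dormant, cd=cd, dd=dd, release_doy=release_doy, last_doy=doy)


class ZoneModel:
    """Daily zone-width and dormancy driver for one site.

    Wraps :func:`zone_widths` and :func:`update_dormancy`, with optional
    scenario overrides: freezing the zone widths at a fixed DOY's values and
    disabling autumn dormancy entry.
    """

    def __init__(
        self,
        params: ModelParams,
        latitude: float,
        fixed_zone_widths_doy: Optional[int] = None,
        autumn_dormancy: bool = True,
    ):
        self.params = params
        self.latitude = latitude
        self.autumn_dormancy = autumn_dormancy
        self._frozen: Optional[tuple[float, float, float]] = None
        if fixed_zone_widths_doy is not None:
            dl = daylength(latitude, fixed_zone_widths_doy)
            self._frozen = zone_widths(dl, fixed_zone_widths_doy, False, params, latitude)

    def step(self, state: ZoneState, day: ClimateDay) -> ZoneState:
        """Update dormancy then set the day's zone widths."""
        new = update_dormancy(state, day, self.params)
        if not self.autumn_dormancy and not state.dormant:
            # spring release logic untouched; once released, dormancy is
            # never re-imposed
            new = replace(new, dormant=False)
        if self._frozen is not None:
            z_p, z_e, z_t = self._frozen
        else:
            z_p, z_e, z_t = zone_widths(
                day.daylength, day.doy, new.dormant, self.params, self.latitude
            )
        return replace(new, z_p=z_p, z_e=z_e, z_t=z_t)
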