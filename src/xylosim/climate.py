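"""Daily climate forcing: temperature series and astronomical daylength.

Forcing can come from a user CSV (columns ``date,t_mean_C``) or from a seeded
synthetic generator emulating boreal seasonality (seasonal cosine plus AR(1)
daily noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClimateDay", "daylength", "read_forcing", "synthesize_climate", "write_forcing"]


@dataclass(frozen=True)
class ClimateDay:
    """One day of forcing."""

    year: int
    doy: int  # 1-based day of year
    t_mean: float  # daily mean air temperature, deg C
    daylength: float  # hours, in [0, 24]

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy out of range: {self.doy}")
        if not 0.0 <= self.daylength <= 24.0:
            raise ValueError(f"daylength out of range: {self.daylength}")


def daylength(latitude: float, doy: int) -> float:
    """Hours of daylight at *latitude* (degrees) on day-of-year *doy*.

    Standard solar-declination / hour-angle astronomy with declination
    23.44 deg * sin(orbital angle) and the conventional apparent
    sunrise/sunset horizon (solar altitude -0.833 deg, accounting for
    refraction and the solar disc); clamped to 0 h (polar night) or 24 h
    (midnight sun).  Accuracy of a few tenths of an hour, which suffices for
    the linear zone-width responses.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude out of range: {latitude}")
    # DOY 366 is treated as DOY 365 so leap days never shift thresholds.
    doy = min(int(doy), 365)
    # solar declination, radians (spring equinox near DOY 81, summer
    # solstice at DOY 172)
    decl = math.radians(23.44) * math.sin(2.0 * math.pi * (doy - 80.7) / 365.25)
    lat = math.radians(latitude)
    horizon = math.radians(-0.833)
    cos_h = (math.sin(horizon) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    if cos_h <= -1.0:
        return 24.0
    if cos_h >= 1.0:
        return 0.0
    return 24.0 / math.pi * math.acos(cos_h)


def read_forcing(path, latitude: float) -> list[ClimateDay]:
    """Read a daily temperature CSV and attach computed daylengths.

    The CSV must have columns ``date`` (ISO-8601) and ``t_mean_C`` with
    contiguous calendar days.
    """
    df = pd.read_csv(path)
    missing = {"date", "t_mean_C"} - set(df.columns)
    if missing:
        raise ValueError(f"forcing CSV lacks column(s): {sorted(missing)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in forcing CSV: {exc}") from exc
    temps = pd.to_numeric(df["t_mean_C"], errors="coerce")
    if temps.isna().any():
        bad = df.loc[temps.isna(), "date"].iloc[0]
        raise ValueError(f"non-numeric temperature at {bad}")
    deltas = dates.diff().dropna()
    gaps = deltas[deltas != pd.Timedelta(days=1)]
    if len(gaps):
        i = gaps.index[0]
        raise ValueError(
            f"forcing series not contiguous: gap between {dates[i - 1].date()} and {dates[i].date()}"
        )
    return [
        ClimateDay(
            year=int(d.year),
            doy=int(d.dayofyear),
            t_mean=float(t),
            daylength=daylength(latitude, int(d.dayofyear)),
        )
        for d, t in zip(dates, temps)
    ]


def write_forcing(path, days: list[ClimateDay], year_origin: int | None = None) -> None:
    """Write ClimateDay records to the ``date,t_mean_C`` CSV dialect."""
    origin = year_origin if year_origin is not None else days[0].year
    dates = pd.to_datetime(
        [f"{origin + (d.year - days[0].year)}" for d in days]
    ) + pd.to_timedelta([d.doy - 1 for d in days], unit="D")
    pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "t_mean_C": [d.t_mean for d in days]}).to_csv(
        path, index=False
    )


def synthesize_climate(
    latitude: float,
    years,
    seed: int,
    mean_C: float = 1.0,
    amplitude_K: float = 14.0,
    ar1_phi: float = 0.7,
    noise_sd_K: float = 3.0,
    peak_doy: int = 200,
) -> list[ClimateDay]:
    """Generate a synthetic daily boreal temperature series.

    t_mean(d) = mean_C + amplitude_K * cos(2*pi*(doy - peak_doy)/365.25)
    plus stationary AR(1) noise with coefficient *ar1_phi* and innovation SD
    *noise_sd_K*.  Defaults emulate the seasonality of boreal Sweden
    (annual mean ~1 C, July mean ~15 C).  Uses 365-day years (no leap days).
    Reproducible bit-for-bit for a fixed seed.
    """
    if amplitude_K < 0:
        raise ValueError("amplitude_K must be >= 0")
    if not 0.0 <= ar1_phi < 1.0:
        raise ValueError("ar1_phi must lie in [0, 1)")
    years = list(years)
    rng = np.random.default_rng(seed)
    n = 365 * len(years)
    doys = np.tile(np.arange(1, 366), len(years))
    seasonal = mean_C + amplitude_K * np.cos(2.0 * np.pi * (doys - peak_doy) / 365.25)
    eps = rng.normal(0.0, noise_sd_K, size=n)
    noise = np.empty(n)
    # start the AR(1) process at its stationary distribution
    prev = (
        rng.normal(0.0, noise_sd_K / math.sqrt(1.0 - ar1_phi**2))
        if noise_sd_K > 0
        else 0.0
    )
    for i in range(n):
        prev = ar1_phi * prev + eps[i]
        noise[i] = prev
    temps = seasonal + noise
    out = []
    i = 0
    for year in years:
        for doy in range(1, 366):
            out.append(
                ClimateDay(
                    year=year,
                    doy=doy,
                    t_mean=float(temps[i]),
                    daylength=daylength(latitude, doy),
                )
            )
            i += 1
    return out
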