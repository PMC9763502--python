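"""Model constants and run configuration.

All quantities use the fixed unit convention of the model: lengths in
micrometres, masses in milligrams, volumes in millilitres, concentrations in
mg ml^-1, rates per day, temperatures in degrees Celsius in forcing data and
Kelvin inside Arrhenius expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ZoneCoefficients",
    "ModelParams",
    "ScenarioConfig",
    "RunSettings",
    "load_config",
    "save_config",
    "ConfigError",
]

#: Boltzmann constant, eV K^-1.
K_BOLTZMANN = 8.617e-5

#: Reference temperature for Arrhenius expressions, K.
T0_KELVIN = 283.15

#: Valid targets for an additive temperature anomaly.
DELTA_T_TARGETS = frozenset(
    {
        "enlargement_rate",
        "thickening_rate",
        "proliferation_zone_cells",
        "enlargement_zone_cells",
    }
)


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration input."""


@dataclass(frozen=True)
class ZoneCoefficients:
    """Intercepts (um) and slopes of the linear zone-width responses.

    Slopes are um per hour of daylength, except the early-season
    enlargement-only pair (``a_e_early``, ``b_e_early``), which is a line in
    day-of-year (um, um day^-1): before DOY 185 the enlargement-only zone
    follows a linear extension in time of the post-185 line's seasonal rate
    of change.
    """

    a_p: float = -50.9
    b_p: float = 7.47
    a_e_late: float = -744.0  # DOY >= 185
    b_e_late: float = 51.7
    a_e_early: float = 1257.0  # DOY < 185
    b_e_early: float = -5.01
    a_t: float = -427.0
    b_t: float = 68.8


@dataclass(frozen=True)
class ModelParams:
    """Calibrated and literature model constants.

    Defaults are the published calibration for boreal Scots pine; every field
    can be overridden from a config file.
    """

    #: Resistance to carbohydrate diffusion between cells, day ml^-1.
    eta: float = 4360.0
    #: Relative radial growth rate of a cell at T0, um um^-1 day^-1.
    mu0: float = 0.0570
    #: Normalised rate of cell-wall mass growth (rate at T0), mg ml^-1 day^-1.
    omega: float = 19.4
    #: Effective activation energy for cell enlargement, eV.
    Ea: float = 0.374
    #: Effective activation energy for wall building, eV.
    Eaw: float = 1.43
    #: Effective Michaelis constant for wall building, mg ml^-1.
    Km: float = 5.1
    #: Mode of cell-size regulation (0 = sizer, 1 = adder), dimensionless.
    f: float = 0.48
    #: Strength of growth dependence on division asymmetry, dimensionless.
    g_asym: float = 0.43
    #: Cell axial length, um.
    La: float = 2680.0
    #: Cell-wall mass density, mg ml^-1.
    rho: float = 1.54e3
    #: SD of division-asymmetry noise Z_a, dimensionless.
    sigma_a: float = 0.105
    #: SD of birth-size noise Z, dimensionless.
    sigma: float = 0.227
    #: Cell tangential length, um.
    Lt: float = 50.1
    #: Primary cell-wall thickness, um.
    Wp: float = 0.8
    #: Mean cell radial length at birth, um.
    chi_b: float = 8.8
    #: Phloem carbohydrate concentration, mg ml^-1.
    theta_p: float = 95.0
    #: Probability that the initial's non-initial daughter is phloem.
    f_phloem: float = 0.315
    #: Zone-width regression coefficients.
    zone_coeffs: ZoneCoefficients = field(default_factory=ZoneCoefficients)
    #: Reference temperature, K.
    T0: float = T0_KELVIN
    #: Boltzmann constant, eV K^-1.
    k_B: float = K_BOLTZMANN
    #: DOY on which the proliferation and enlargement-only zones go dormant.
    dorm_doy: int = 231
    #: DOY from which chill days are counted.
    chill_start_doy: int = 306
    #: DOY from which degree-days are summed.
    dd_start_doy: int = 32

    def __post_init__(self) -> None:
        positive = (
            "eta",
            "mu0",
            "omega",
            "Ea",
            "Eaw",
            "Km",
            "La",
            "rho",
            "sigma_a",
            "sigma",
            "Lt",
            "Wp",
            "chi_b",
            "theta_p",
            "T0",
            "k_B",
        )
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"parameter {name!r} must be strictly positive, got {value}")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigError(f"f must lie in [0, 1], got {self.f}")
        if not 0.0 <= self.f_phloem <= 1.0:
            raise ConfigError(f"f_phloem must lie in [0, 1], got {self.f_phloem}")
        if not (2.0 * self.Wp < self.La and 2.0 * self.Wp < self.Lt):
            raise ConfigError("primary wall thickness Wp must satisfy 2*Wp < La and 2*Wp < Lt")
        if self.g_asym < 0:
            raise ConfigError(f"g_asym must be non-negative, got {self.g_asym}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Switches for the in-silico experiments.

    The default-constructed instance is the full model.  ``fixed_temp_C``
    replaces the air temperature used for enlargement and wall-thickening
    kinetics with a constant; ``fixed_zone_widths_doy`` freezes the three
    developmental zone widths at their values on that DOY for the whole year;
    ``sugar_saturation`` removes the carbohydrate constraint on wall growth
    (dM = dM_max); ``delta_T_K`` adds a temperature anomaly to the processes
    named in ``delta_T_targets``.  Dormancy forcing always uses the
    unmodified climate unless ``dormancy_forcing_uses_anomaly`` is set.
    """

    fixed_temp_C: Optional[float] = None
    fixed_zone_widths_doy: Optional[int] = None
    autumn_dormancy: bool = True
    sugar_saturation: bool = False
    delta_T_K: float = 0.0
    delta_T_targets: frozenset[str] = frozenset()
    dormancy_forcing_uses_anomaly: bool = False

    def __post_init__(self) -> None:
        targets = frozenset(self.delta_T_targets)
        object.__setattr__(self, "delta_T_targets", targets)
        unknown = targets - DELTA_T_TARGETS
        if unknown:
            raise ConfigError(f"unknown delta_T_targets: {sorted(unknown)}")
        if (self.delta_T_K != 0.0) != bool(targets):
            raise ConfigError("delta_T_targets must be non-empty iff delta_T_K != 0")
        if self.fixed_zone_widths_doy is not None and not 1 <= self.fixed_zone_widths_doy <= 366:
            raise ConfigError("fixed_zone_widths_doy must be a valid DOY")


@dataclass(frozen=True)
class RunSettings:
    """Ensemble-level run configuration."""

    latitude: float = 64.35
    n_files: int = 100
    year_start: int = 1951
    year_end: int = 1995
    spinup_years: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ConfigError("latitude must lie in [-90, 90]")
        if self.n_files < 1:
            raise ConfigError("n_files must be >= 1")
        if self.year_end < self.year_start:
            raise ConfigError("year_end must be >= year_start")


_SECTIONS = {
    "params": ModelParams,
    "scenario": ScenarioConfig,
    "run": RunSettings,
}


def _build(cls, mapping: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    kwargs = dict(mapping)
    if cls is ModelParams and "zone_coeffs" in kwargs:
        zc = kwargs["zone_coeffs"]
        if not isinstance(zc, dict):
            raise ConfigError("zone_coeffs must be a mapping")
        zc_known = {f.name for f in fields(ZoneCoefficients)}
        zc_unknown = set(zc) - zc_known
        if zc_unknown:
            raise ConfigError(f"unknown key(s) in zone_coeffs: {sorted(zc_unknown)}")
        kwargs["zone_coeffs"] = ZoneCoefficients(**zc)
    if cls is ScenarioConfig and "delta_T_targets" in kwargs:
        kwargs["delta_T_targets"] = frozenset(kwargs["delta_T_targets"])
    return cls(**kwargs)


def load_config(path) -> tuple[ModelParams, ScenarioConfig, RunSettings]:
    """Read a YAML config file and return (params, scenario, run settings).

    The file may contain any subset of the top-level sections ``params``,
    ``scenario`` and ``run``; absent keys take the published defaults.
    Unknown keys are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    out = []
    for section, cls in _SECTIONS.items():
        mapping = raw.get(section, {}) or {}
        if not isinstance(mapping, dict):
            raise ConfigError(f"section [{section}] must be a mapping")
        out.append(_build(cls, mapping, section))
    return tuple(out)


def save_config(path, params: ModelParams, scenario: ScenarioConfig, run: RunSettings) -> None:
    """Serialize a full configuration back to YAML (round-trips load_config)."""
    doc = {
        "params": asdict(params),
        "scenario": {**asdict(scenario), "delta_T_targets": sorted(scenario.delta_T_targets)},
        "run": asdict(run),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
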