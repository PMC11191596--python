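"""CSV profile and YAML site-configuration I/O with unit validation.

Exchange format conventions
---------------------------
Profiles travel as plain CSV with a ``<measurand>_<unit>`` header grammar,
e.g. ``depth_m,ch4_mmol_m3,so4_mmol_m3``.  The canonical concentration unit
throughout the package is mmol m^-3 (numerically identical to umol L^-1);
columns declared in ``umol_L`` are accepted, exposed as mmol m^-3, and
flagged as converted.  Depth coordinates are positive downward: porewater
depths from the sediment-water interface (0 = SWI), water-column depths
from the sea surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    CoastalCH4Warning,
    SchemaError,
    UnitError,
    ValidationError,
)

#: Units accepted in column headers.  ``umol_L`` is converted on read.
UNIT_WHITELIST = frozenset(
    {"m", "s", "mmol_m3", "umol_L", "permil", "C", "psu", "frac", "ppb", "m_s"}
)

#: Non-canonical unit -> (canonical unit, multiplicative factor).
_CANONICAL = {"umol_L": ("mmol_m3", 1.0)}

PHASES = ("porewater", "watercolumn")


def split_column(name: str) -> tuple[str, str]:
    """Split ``ch4_umol_L`` into ``("ch4", "umol_L")``; raise UnitError otherwise."""
    for unit in sorted(UNIT_WHITELIST, key=len, reverse=True):
        suffix = "_" + unit
        if name.endswith(suffix) and len(name) > len(suffix):
            return name[: -len(suffix)], unit
    raise UnitError(f"column {name!r} has no recognised unit suffix "
                    f"(whitelist: {sorted(UNIT_WHITELIST)})")


@dataclass
class ProfileTable:
    """A depth-indexed measurement table for one phase.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``depth`` (m) plus one column per measurand, already in
        canonical units.
    units : dict
        Measurand name -> canonical unit string.
    phase : str
        ``"porewater"`` or ``"watercolumn"``.
    converted : frozenset
        Measurands whose values were converted from a non-canonical unit
        on read.  Conversion is applied exactly once; re-converting is
        refused (see :meth:`convert_units`).
    meta : dict
        Free-form provenance (synthetic ground truth, source path, ...).
    """

    data: pd.DataFrame
    units: dict[str, str]
    phase: str
    converted: frozenset = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if "depth" not in self.data.columns:
            raise SchemaError("profile has no 'depth' column")
        self._check_depths()

    def _check_depths(self) -> None:
        z = np.asarray(self.data["depth"], dtype=float)
        bad = np.flatnonzero(np.diff(z) <= 0)
        if bad.size:
            rows = ", ".join(f"{i}->{i + 1} ({z[i]} -> {z[i + 1]} m)" for i in bad)
            raise ValidationError(f"depths must be strictly increasing; offending rows: {rows}")

    @property
    def depth(self) -> np.ndarray:
        return np.asarray(self.data["depth"], dtype=float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise SchemaError(f"profile has no column {name!r} "
                              f"(available: {[c for c in self.data.columns if c != 'depth']})")
        return np.asarray(self.data[name], dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def convert_units(self, name: str, unit: str) -> "ProfileTable":
        """Convert one column declared in a non-canonical unit.

        Idempotence guard: converting a column that was already converted is
        detected and refused, so values can never be scaled twice.
        """
        if name in self.converted:
            raise UnitError(f"column {name!r} was already converted to canonical units; "
                            "refusing to convert twice")
        if unit not in _CANONICAL:
            raise UnitError(f"no canonical conversion known for unit {unit!r}")
        canonical, factor = _CANONICAL[unit]
        data = self.data.copy()
        data[name] = data[name] * factor
        units = dict(self.units)
        units[name] = canonical
        return replace(self, data=data, units=units,
                       converted=self.converted | {name})


def read_profile(path: str | Path, phase: str) -> ProfileTable:
    """Read and validate a CSV depth profile.

    The header row declares measurands and units (``depth_m,ch4_mmol_m3``).
    Concentrations reported in umol L^-1 are exposed as mmol m^-3 (the two
    are numerically identical) and flagged in ``converted``.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    names: list[str] = []
    units: dict[str, str] = {}
    for col in raw.columns:
        name, unit = split_column(str(col).strip())
        names.append(name)
        units[name] = unit
    raw.columns = names
    if "depth" not in names:
        raise SchemaError(f"{path.name}: no depth column found in header {list(raw.columns)}")
    if units["depth"] != "m":
        raise UnitError(f"{path.name}: depth must be in m, got {units['depth']!r}")
    table = ProfileTable(data=raw, units=units, phase=phase,
                         meta={"source": str(path)})
    for name, unit in list(units.items()):
        if unit in _CANONICAL:
            table = table.convert_units(name, unit)
    return table


def write_profile(table: ProfileTable, path: str | Path) -> Path:
    """Write a profile back to CSV with the header grammar of :func:`read_profile`.

    Numeric values round-trip bit-exactly (shortest-repr float formatting).
    """
    path = Path(path)
    header = [f"{name}_{table.units.get(name, 'm' if name == 'depth' else 'mmol_m3')}"
              for name in table.data.columns]
    out = table.data.copy()
    out.columns = header
    out.to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class SiteConfig:
    """Scalar metadata for one site.

    Units: water_depth m; concentrations mmol m^-3; wind m s^-1; mixing
    ratio ppb (dry-air mole fraction); temperature degC; salinity practical;
    chamber volume m^3 and area m^2.
    """

    site_id: str
    water_depth: float
    bottom_water_O2: float = 0.0
    bottom_water_sulfide: float = 0.0
    wind_speed_u10: float = 5.0
    atm_ch4_mixing_ratio: float = 1900.0
    surface_T: float = 10.0
    surface_S: float = 4.5
    chamber_volume: float | None = None
    chamber_area: float | None = None

    def __post_init__(self) -> None:
        if self.water_depth <= 0:
            raise ConfigError(f"water_depth must be > 0 m, got {self.water_depth}")
        for key in ("bottom_water_O2", "bottom_water_sulfide",
                    "atm_ch4_mixing_ratio", "wind_speed_u10"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0, got {getattr(self, key)}")
        if (self.chamber_volume is not None) != (self.chamber_area is not None):
            raise ConfigError("chamber_volume and chamber_area must be given together")
        if self.chamber_area is not None and self.chamber_area <= 0:
            raise ConfigError(f"chamber_area must be > 0 m^2, got {self.chamber_area}")


_REQUIRED_CONFIG_KEYS = ("site_id", "water_depth")


def read_site_config(path: str | Path) -> SiteConfig:
    """Read one site's YAML configuration, applying documented defaults.

    Defaults: wind 5 m s^-1, atmospheric CH4 1900 ppb, surface 10 degC and
    salinity 4.5 (brackish).  A warning notes every defaulted key.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path.name}: expected a YAML mapping, got {type(cfg).__name__}")
    return site_config_from_mapping(cfg, origin=path.name)


def site_config_from_mapping(cfg: Mapping, origin: str = "<config>") -> SiteConfig:
    missing = [k for k in _REQUIRED_CONFIG_KEYS if k not in cfg]
    if missing:
        raise ConfigError(f"{origin}: missing required key(s): {', '.join(missing)}")
    known = {f for f in SiteConfig.__dataclass_fields__}
    unknown = [k for k in cfg if k not in known]
    if unknown:
        raise ConfigError(f"{origin}: unknown key(s): {', '.join(unknown)}")
    defaulted = sorted(k for k in known - set(cfg)
                       if k not in ("chamber_volume", "chamber_area"))
    if defaulted:
        warnings.warn(f"{origin}: defaults applied for {', '.join(defaulted)}",
                      CoastalCH4Warning, stacklevel=2)
    return SiteConfig(**{k: cfg[k] for k in cfg})


def profile_from_arrays(depth: Iterable[float], phase: str,
                        meta: dict | None = None,
                        **columns: Iterable[float]) -> ProfileTable:
    """Build a ProfileTable from arrays already in canonical units.

    Column keyword names are bare measurands (``ch4``, ``so4``, ``o2``,
    ``h2s``, ``d13c``, ``dd``, ``temp``, ``sal``, ``porosity``).
    """
    units = {"depth": "m"}
    default_units = {"temp": "C", "sal": "psu", "porosity": "frac",
                     "d13c": "permil", "dd": "permil"}
    data = {"depth": np.asarray(list(depth), dtype=float)}
    for name, values in columns.items():
        data[name] = np.asarray(list(values), dtype=float)
        units[name] = default_units.get(name, "mmol_m3")
    return ProfileTable(data=pd.DataFrame(data), units=units, phase=phase,
                        meta=meta or {})
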