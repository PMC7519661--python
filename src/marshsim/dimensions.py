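"""Physical dimensions, unit conversions, and observation records.

The similitude analysis works in a four-dimensional (M, L, T, K) dimension
system: mass, length, time, temperature.  Exponents are kept as exact
rationals so that dimensional bookkeeping in the pi engine is exact.

Seven quantities enter the analysis: the daytime net CO2 uptake flux
(``nee``, µmol/m²/s), photosynthetically active radiation (``par``,
µmol/m²/s), soil temperature (``st``, °C -> K), porewater salinity (``ss``,
ppt -> g/m³), atmospheric pressure (``pa``, millibar -> g/m/s²), the
specific heat of wet soil (``cp``, a constant 1.48 J/g/K), and the
measurement time scale (``t``, s).  Note the deliberate bookkeeping choice
that µmol (gas amounts) and g (salinity, pressure) are both carried under
the single mass dimension M with no mole-to-gram conversion — the derived
dimensionless groups depend on this convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Optional

import pandas as pd
import yaml

__all__ = [
    "DimensionVector",
    "PhysicalVariable",
    "ObservationPanel",
    "PanelValidationError",
    "VARIABLES",
    "CP_WET_SOIL",
    "to_si",
    "from_si",
    "panel_to_si",
    "panel_from_si",
    "read_panels",
    "write_panels",
    "variables_from_yaml",
    "variables_to_yaml",
]

#: Specific heat of wet soil in SI units (J/g/K); 1.48 kJ/kg/K numerically
#: unchanged by the kJ/kg -> J/g conversion.
CP_WET_SOIL = 1.48


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x)


@dataclass(frozen=True)
class DimensionVector:
    """Exact rational exponents of (M, L, T, K)."""

    m: Fraction = Fraction(0)
    l: Fraction = Fraction(0)
    t: Fraction = Fraction(0)
    k: Fraction = Fraction(0)

    def __post_init__(self):
        for name in ("m", "l", "t", "k"):
            object.__setattr__(self, name, _frac(getattr(self, name)))

    def __add__(self, other: "DimensionVector") -> "DimensionVector":
        return DimensionVector(self.m + other.m, self.l + other.l,
                               self.t + other.t, self.k + other.k)

    def __sub__(self, other: "DimensionVector") -> "DimensionVector":
        return DimensionVector(self.m - other.m, self.l - other.l,
                               self.t - other.t, self.k - other.k)

    def scale(self, q) -> "DimensionVector":
        q = _frac(q)
        return DimensionVector(self.m * q, self.l * q, self.t * q, self.k * q)

    @property
    def is_zero(self) -> bool:
        return self.m == 0 and self.l == 0 and self.t == 0 and self.k == 0

    def as_tuple(self) -> tuple:
        # Row order (M, L, T, K) used throughout the dimension matrices.
        return (self.m, self.l, self.t, self.k)


DIMENSIONLESS = DimensionVector()


@dataclass(frozen=True)
class PhysicalVariable:
    """A named quantity with its unit-conversion rule and dimension.

    ``si = scale * original + offset``; the affine offset is only ever used
    for temperature (°C -> K).  The conversion is invertible for any nonzero
    scale.
    """

    name: str
    original_unit: str
    si_unit: str
    scale: float = 1.0
    offset: float = 0.0
    dimension: DimensionVector = field(default_factory=DimensionVector)

    def __post_init__(self):
        if self.scale == 0:
            raise ValueError(f"{self.name}: conversion scale must be nonzero")
        if self.offset != 0 and self.dimension != DimensionVector(k=1):
            raise ValueError(
                f"{self.name}: affine offsets are only permitted for temperature"
            )

    def to_si(self, value: float) -> float:
        return self.scale * value + self.offset

    def from_si(self, value: float) -> float:
        return (value - self.offset) / self.scale


#: The variable system of the salt-marsh analysis, including the constants
#: cp (specific heat of wet soil) and t (measurement time scale).
VARIABLES: Mapping[str, PhysicalVariable] = {
    "nee": PhysicalVariable("nee", "umol/m2/s", "umol/m2/s",
                            dimension=DimensionVector(1, -2, -1, 0)),
    "par": PhysicalVariable("par", "umol/m2/s", "umol/m2/s",
                            dimension=DimensionVector(1, -2, -1, 0)),
    "st": PhysicalVariable("st", "degC", "K", scale=1.0, offset=273.15,
                           dimension=DimensionVector(0, 0, 0, 1)),
    "ss": PhysicalVariable("ss", "ppt", "g/m3", scale=1000.0,
                           dimension=DimensionVector(1, -3, 0, 0)),
    "pa": PhysicalVariable("pa", "millibar", "g/m/s2", scale=100000.0,
                           dimension=DimensionVector(1, -1, -2, 0)),
    "cp": PhysicalVariable("cp", "kJ/kg/K", "J/g/K",
                           dimension=DimensionVector(0, 2, -2, -1)),
    "t": PhysicalVariable("t", "s", "s",
                          dimension=DimensionVector(0, 0, 1, 0)),
}


class PanelValidationError(ValueError):
    """Raised when an observation record fails validation; names the field."""


@dataclass(frozen=True)
class ObservationPanel:
    """One instantaneous observation at a site.

    Fields are in original units (nee/par µmol/m²/s, st °C, ss ppt,
    pa millibar, optional at °C) unless produced by :func:`to_si`.
    The flux follows the uptake-positive convention; negative values pass
    validation with a warning but are excluded from regime analysis
    downstream (the log transform requires positivity).
    """

    site: str
    timestamp: Optional[pd.Timestamp]
    nee: float
    par: float
    st: float
    ss: float
    pa: float
    at: Optional[float] = None

    def validate(self) -> "ObservationPanel":
        for name in ("nee", "par", "st", "ss", "pa"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise PanelValidationError(f"field '{name}' is missing or non-finite")
        if self.par <= 0:
            raise PanelValidationError("field 'par' must be positive")
        if self.ss < 0:
            raise PanelValidationError("field 'ss' must be non-negative")
        if self.pa <= 0:
            raise PanelValidationError("field 'pa' must be positive")
        if self.nee < 0:
            warnings.warn(
                f"record at site {self.site!r}: negative uptake flux "
                f"({self.nee}); allowed but excluded from regime analysis",
                stacklevel=2,
            )
        return self


def to_si(panel: ObservationPanel, variables: Mapping[str, PhysicalVariable] = VARIABLES
          ) -> ObservationPanel:
    """Convert a validated record to SI units (st in K, ss in g/m³, pa in g/m/s²).

    nee and par are numerically unchanged (µmol/m²/s is already the working
    unit).  ``from_si`` inverts the conversion.
    """
    panel.validate()
    return replace(
        panel,
        st=variables["st"].to_si(panel.st),
        ss=variables["ss"].to_si(panel.ss),
        pa=variables["pa"].to_si(panel.pa),
    )


def from_si(panel: ObservationPanel, variables: Mapping[str, PhysicalVariable] = VARIABLES
            ) -> ObservationPanel:
    """Inverse of :func:`to_si`."""
    return replace(
        panel,
        st=variables["st"].from_si(panel.st),
        ss=variables["ss"].from_si(panel.ss),
        pa=variables["pa"].from_si(panel.pa),
    )


# ---------------------------------------------------------------------------
# DataFrame-level panel handling

_CSV_COLUMNS = {
    "nee_umol_m2_s": "nee",
    "par_umol_m2_s": "par",
    "st_c": "st",
    "ss_ppt": "ss",
    "pa_mbar": "pa",
    "at_c": "at",
}
_REQUIRED = ["site", "timestamp", "nee_umol_m2_s", "par_umol_m2_s",
             "st_c", "ss_ppt", "pa_mbar"]


def read_panels(path) -> pd.DataFrame:
    """Read a panel CSV (header ``site,timestamp,nee_umol_m2_s,...``).

    Timestamps are parsed as naive local clock time (the study convention is
    Eastern Standard Time with no DST adjustment).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {', '.join(missing)}")
    df = df.rename(columns=_CSV_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_panels(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={v: k for k, v in _CSV_COLUMNS.items()})
    out.to_csv(path, index=False)


def panel_to_si(df: pd.DataFrame,
                variables: Mapping[str, PhysicalVariable] = VARIABLES) -> pd.DataFrame:
    """Vectorized :func:`to_si` over a panel DataFrame (columns nee, par, st, ss, pa)."""
    for name in ("nee", "par", "st", "ss", "pa"):
        col = df[name]
        if col.isna().any() or not col.map(math.isfinite).all():
            bad = int(col.isna().sum() + (~col.dropna().map(math.isfinite)).sum())
            raise PanelValidationError(
                f"field '{name}' has {bad} missing or non-finite value(s)")
    out = df.copy()
    out["st"] = variables["st"].to_si(df["st"])
    out["ss"] = variables["ss"].to_si(df["ss"])
    out["pa"] = variables["pa"].to_si(df["pa"])
    return out


def panel_from_si(df: pd.DataFrame,
                  variables: Mapping[str, PhysicalVariable] = VARIABLES) -> pd.DataFrame:
    out = df.copy()
    out["st"] = variables["st"].from_si(df["st"])
    out["ss"] = variables["ss"].from_si(df["ss"])
    out["pa"] = variables["pa"].from_si(df["pa"])
    return out


# ---------------------------------------------------------------------------
# Variable-definition serialization (name -> unit, scale, offset, dimension)

def variables_from_yaml(path) -> dict:
    """Load a variable-definition map from YAML.

    Schema per variable: ``{unit, si_unit, scale, offset, dimension: [m,l,t,k]}``
    with dimension entries given as ints or 'p/q' fraction strings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        dim = DimensionVector(*(Fraction(str(x)) for x in spec["dimension"]))
        out[name] = PhysicalVariable(
            name=name,
            original_unit=spec.get("unit", ""),
            si_unit=spec.get("si_unit", spec.get("unit", "")),
            scale=float(spec.get("scale", 1.0)),
            offset=float(spec.get("offset", 0.0)),
            dimension=dim,
        )
    return out


def variables_to_yaml(variables: Mapping[str, PhysicalVariable], path) -> None:
    raw = {
        name: {
            "unit": v.original_unit,
            "si_unit": v.si_unit,
            "scale": v.scale,
            "offset": v.offset,
            "dimension": [str(x) for x in v.dimension.as_tuple()],
        }
        for name, v in variables.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
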