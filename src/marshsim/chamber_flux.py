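"""Closed-chamber CO2 flux estimation from 1-Hz concentration series.

A transparent closed chamber (0.60 m cube, 0.36 m² footprint, 0.216 m³) is
set over the marsh surface and a cavity ring-down analyzer records the CO2
mixing ratio at 1 Hz.  The ideal gas law converts each ppm reading into the
molar amount of CO2 in the chamber; the OLS slope of amount versus time,
normalized by the chamber footprint, is the vertical flux.  Air temperature
(not soil temperature) enters the gas law.  A regression R² of at least
0.90 is required for a flux to pass quality control; fluxes are reported
regardless and flagged.

Sign convention: decreasing concentration means uptake, and fluxes are
reported uptake-positive (the sign is flipped exactly once, here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "R_GAS",
    "ChamberGeometry",
    "ChamberSeries",
    "FluxResult",
    "molar_amount",
    "compute_flux",
    "daytime_filter",
    "read_series_csv",
]

#: Universal gas constant, J/mol/K.
R_GAS = 8.314

#: Daytime filtering window (local EST, inclusive at both ends) and PAR floor.
DAYTIME_START = "08:00"
DAYTIME_END = "16:30"
PAR_MIN = 1.5


@dataclass(frozen=True)
class ChamberGeometry:
    side: float = 0.60          # m
    area: float = 0.36          # m²
    volume: float = 0.216       # m³


@dataclass
class ChamberSeries:
    """One chamber deployment: seconds from closure, ppm, air T, pressure.

    ``at_c`` and ``pa_mbar`` may be scalars or per-sample arrays.
    """

    times: np.ndarray
    co2_ppm: np.ndarray
    at_c: "np.ndarray | float"
    pa_mbar: "np.ndarray | float"
    chamber: ChamberGeometry = field(default_factory=ChamberGeometry)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        if self.times.size < 2:
            raise ValueError("chamber series needs at least 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size != self.co2_ppm.size:
            raise ValueError("times and co2_ppm lengths differ")


@dataclass(frozen=True)
class FluxResult:
    """Estimated flux (µmol/m²/s, uptake-positive) with its QC verdict."""

    flux: float
    r2: float
    n_points: int
    qc_pass: bool
    reject_reason: Optional[str] = None


def molar_amount(series: ChamberSeries) -> np.ndarray:
    """Micromoles of CO2 in the chamber at each timestep (ideal gas law).

    amount [µmol] = ppm · P[Pa] · V[m³] / (R · T[K]); the 1e-6 of the mixing
    ratio and the 1e6 of µmol cancel.
    """
    at_k = np.asarray(series.at_c, dtype=float) + 273.15
    if np.any(at_k <= 0):
        raise ValueError("air temperature at or below absolute zero")
    pa_pascal = np.asarray(series.pa_mbar, dtype=float) * 100.0
    return series.co2_ppm * pa_pascal * series.chamber.volume / (R_GAS * at_k)


def compute_flux(series: ChamberSeries, r2_min: float = 0.90,
                 min_points: int = 10, min_span: float = 60.0,
                 uptake_positive: bool = True,
                 per_height: bool = False) -> FluxResult:
    """OLS slope of molar amount vs time, normalized by the chamber footprint.

    ``per_height=True`` regresses the volumetric concentration (amount/V)
    and multiplies the slope by the chamber height instead; for a fixed
    chamber volume both routes give identical fluxes.
    """
    t = series.times
    if np.ptp(t) == 0:
        raise ValueError("degenerate series: zero time variance")
    amount = molar_amount(series)
    if np.ptp(amount) == 0:
        # Constant concentrations: zero slope, R^2 undefined.
        return FluxResult(flux=0.0, r2=float("nan"), n_points=int(t.size),
                          qc_pass=False,
                          reject_reason="R^2 undefined (zero-variance amounts)")
    if per_height:
        conc = amount / series.chamber.volume           # µmol/m³
        res = stats.linregress(t, conc)
        slope = res.slope * series.chamber.side         # µmol/m²/s per m² footprint
    else:
        res = stats.linregress(t, amount)
        slope = res.slope / series.chamber.area
    flux = -slope if uptake_positive else slope
    r2 = res.rvalue ** 2

    reason = None
    if t.size < min_points:
        reason = f"too few points ({t.size} < {min_points})"
    elif np.ptp(t) < min_span:
        reason = f"series spans {np.ptp(t):.0f} s < {min_span:.0f} s"
    elif not np.isfinite(r2):
        reason = "R^2 undefined (zero-variance amounts)"
    elif r2 < r2_min:
        reason = f"R^2 = {r2:.3f} below threshold {r2_min:.2f}"
    return FluxResult(flux=float(flux), r2=float(r2), n_points=int(t.size),
                      qc_pass=reason is None, reject_reason=reason)


def daytime_filter(panels: pd.DataFrame, start: str = DAYTIME_START,
                   end: str = DAYTIME_END, par_min: float = PAR_MIN) -> pd.DataFrame:
    """Keep daytime records: clock time in [start, end] (EST) and PAR > par_min.

    Records with missing timestamps are dropped with a warning.
    """
    import warnings

    df = panels
    missing = df["timestamp"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} record(s) with missing "
                      "timestamps", stacklevel=2)
        df = df[~missing]
    t0 = pd.Timestamp(f"2000-01-01 {start}").time()
    t1 = pd.Timestamp(f"2000-01-01 {end}").time()
    clock = pd.to_datetime(df["timestamp"]).dt.time
    keep = (clock >= t0) & (clock <= t1) & (df["par"] > par_min)
    return df[keep].reset_index(drop=True)


def read_series_csv(path, chamber: Optional[ChamberGeometry] = None) -> ChamberSeries:
    """Read one deployment CSV with header ``t_s,co2_ppm,at_c,pa_mbar``."""
    df = pd.read_csv(path)
    required = ["t_s", "co2_ppm", "at_c", "pa_mbar"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"series CSV missing columns: {', '.join(missing)}")
    return ChamberSeries(
        times=df["t_s"].to_numpy(),
        co2_ppm=df["co2_ppm"].to_numpy(),
        at_c=df["at_c"].to_numpy(),
        pa_mbar=df["pa_mbar"].to_numpy(),
        chamber=chamber or ChamberGeometry(),
    )
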