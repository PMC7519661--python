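"""Seeded generators for panel datasets and raw chamber series.

The panel generator emulates the statistical structure of the study data:
137 instantaneous daytime observations across 4 marshes over 25 sampling
days (May–October), with per-site porewater salinity centred near the
observed site means (31, 26, 31, 34 ppt), a seasonal soil-temperature arc
spanning roughly 9–26 °C, PAR between about 300 and 2100 µmol/m²/s, and
station-like atmospheric pressure (1004–1027 millibar).  The net uptake
flux follows a linear light-response nee = α·par with a multiplicative
lognormal error; the efficiency α is suppressed when the soil is cold
(below ~17 °C, temperature-limited photosynthesis regardless of salinity)
and partially suppressed when porewater is saline (above ~30 ppt) under
warm soil.  Distribution families (truncated normals, a seasonal sinusoid,
a scaled beta for PAR) are modelling choices of this generator, not
observed facts.

Every record's truth is emitted alongside the data: the drawn efficiency,
the condition tier that produced it, and the regime the *noiseless* record
occupies on the process diagram (the label the classifier should recover).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chamber_flux import ChamberGeometry, ChamberSeries
from .dimensions import CP_WET_SOIL, panel_to_si
from .regime_pipeline import BGC_SPLIT, LUE_MIN, classify

__all__ = ["GeneratorConfig", "generate_panels", "generate_chamber_series"]

_SITES = ("Sage Lot Pond", "Hamblin Pond", "Great Pond", "Eel Pond")


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the panel generator.

    Defaults reproduce the sampling design and driver envelopes of the
    field campaign; the efficiency bands bracket the regime thresholds
    (α_low below the LUE = 0.002 boundary, α_high well above it).
    """

    n_sites: int = 4
    site_names: Sequence[str] = _SITES
    n_days: int = 25
    panels_target: int = 137
    season_start: str = "2013-05-01"
    season_end: str = "2013-10-31"

    ss_site_mean: Sequence[float] = (31.0, 26.0, 31.0, 34.0)   # ppt
    ss_sd: float = 2.0
    st_min: float = 9.0                                        # °C seasonal floor
    st_max: float = 26.0                                       # °C seasonal peak
    st_noise_sd: float = 1.5
    par_min: float = 300.0                                     # µmol/m²/s
    par_max: float = 2100.0
    pa_mean: float = 1013.0                                    # millibar
    pa_sd: float = 4.0
    pa_min: float = 1004.0
    pa_max: float = 1027.0

    at_intercept: float = 6.31                                 # AT = a + b·ST + ε
    at_slope: float = 1.135
    at_noise_sd: float = 1.5

    alpha_high: tuple = (0.003, 0.01)        # warm + fresh
    alpha_mid: tuple = (0.0022, 0.003)       # warm + saline
    alpha_low: tuple = (0.0008, 0.0016)      # cold
    st_break: float = 17.0                   # °C
    ss_break: float = 30.0                   # ppt
    noise_sd: float = 0.10                   # lognormal sigma on nee

    lue_min: float = LUE_MIN
    bgc_split: float = BGC_SPLIT
    cp: float = CP_WET_SOIL

    def validate(self) -> "GeneratorConfig":
        if self.alpha_low[1] >= self.lue_min:
            raise ValueError(
                f"alpha_low upper bound {self.alpha_low[1]} must stay below "
                f"lue_min {self.lue_min}")
        if self.alpha_high[0] < self.lue_min:
            raise ValueError("alpha_high band must sit above lue_min")
        if len(self.site_names) < self.n_sites or \
                len(self.ss_site_mean) < self.n_sites:
            raise ValueError("need a name and salinity mean per site")
        return self


def _truncnorm(rng, mean, sd, lo, hi, size):
    # Resampling truncation; the bands are wide so this converges fast.
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_panels(config: Optional[GeneratorConfig] = None,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None):
    """Generate (panels, truth) DataFrames for one synthetic campaign.

    ``panels`` has the observation-panel schema in original units;
    ``truth`` carries per-record alpha, condition tier, and the noiseless
    diagram regime.
    """
    config = (config or GeneratorConfig()).validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    n = config.panels_target
    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end)
    season_days = (end - start).days
    day_offsets = np.sort(rng.choice(season_days + 1, size=config.n_days,
                                     replace=False))

    site_idx = rng.integers(0, config.n_sites, size=n)
    day_idx = rng.integers(0, config.n_days, size=n)
    frac = day_offsets[day_idx] / season_days           # 0 at May 1, 1 at Oct 31
    # Clock times inside the daytime sampling window, 08:00-16:30 EST.
    seconds = rng.integers(0, int(8.5 * 3600) + 1, size=n)
    timestamps = (start + pd.to_timedelta(day_offsets[day_idx], unit="D")
                  + pd.to_timedelta(8 * 3600 + seconds, unit="s"))

    st = np.clip(
        config.st_min + (config.st_max - config.st_min) * np.sin(np.pi * frac)
        + rng.normal(0, config.st_noise_sd, n),
        config.st_min, config.st_max)
    ss_mean = np.asarray(config.ss_site_mean)[site_idx]
    ss = _truncnorm(rng, ss_mean, config.ss_sd, 10.0, 40.0, n)
    par = config.par_min + (config.par_max - config.par_min) * rng.beta(2.0, 2.0, n)
    pa = _truncnorm(rng, config.pa_mean, config.pa_sd,
                    config.pa_min, config.pa_max, n)
    at = config.at_intercept + config.at_slope * st \
        + rng.normal(0, config.at_noise_sd, n)

    cold = st < config.st_break
    saline = ss > config.ss_break
    tier = np.where(cold, "cold", np.where(saline, "saline", "favorable"))
    alpha = np.empty(n)
    for name, band in (("favorable", config.alpha_high),
                       ("saline", config.alpha_mid),
                       ("cold", config.alpha_low)):
        mask = tier == name
        alpha[mask] = rng.uniform(band[0], band[1], mask.sum())

    nee = alpha * par * np.exp(rng.normal(0, config.noise_sd, n))

    sites = np.asarray(config.site_names)[site_idx]
    panels = pd.DataFrame({
        "site": sites, "timestamp": timestamps,
        "nee": nee, "par": par, "st": st, "ss": ss, "pa": pa, "at": at,
    })
    si = panel_to_si(panels)
    bgc = si["st"] * config.cp * si["ss"] / si["pa"]
    regime = classify(alpha, bgc, config.lue_min, config.bgc_split)
    truth = pd.DataFrame({
        "site": sites, "timestamp": timestamps,
        "alpha": alpha, "tier": tier, "bgc": bgc.to_numpy(), "regime": regime,
    })
    return panels, truth


def generate_chamber_series(true_flux: float,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            duration: float = 300.0,
                            at_c: float = 25.0,
                            pa_mbar: float = 1013.0,
                            co2_start_ppm: float = 410.0,
                            noise_sd_ppm: float = 0.4,
                            chamber: Optional[ChamberGeometry] = None):
    """1-Hz chamber series whose molar-amount slope encodes the given flux.

    Uptake-positive ``true_flux`` (µmol/m²/s) draws the chamber CO2 amount
    down at flux·area µmol/s; Gaussian ppm noise uses the analyzer precision
    (0.4 ppm) by default.  Returns (series, truth dict).
    """
    if duration < 60:
        raise ValueError("chamber deployments must span at least 60 s")
    if rng is None:
        rng = np.random.default_rng(seed)
    chamber = chamber or ChamberGeometry()
    from .chamber_flux import R_GAS

    times = np.arange(0.0, duration + 1.0)
    t_k = at_c + 273.15
    pa_pascal = pa_mbar * 100.0
    amount0 = co2_start_ppm * pa_pascal * chamber.volume / (R_GAS * t_k)  # µmol
    amount = amount0 - true_flux * chamber.area * times
    ppm = amount * R_GAS * t_k / (pa_pascal * chamber.volume)
    if noise_sd_ppm > 0:
        ppm = ppm + rng.normal(0, noise_sd_ppm, ppm.size)
    series = ChamberSeries(times=times, co2_ppm=ppm, at_c=at_c,
                           pa_mbar=pa_mbar, chamber=chamber)
    truth = {"flux": float(true_flux), "amount_slope": -true_flux * chamber.area,
             "co2_start_ppm": co2_start_ppm, "noise_sd_ppm": noise_sd_ppm}
    return series, truth
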