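"""Evaluation of the dimensionless numbers and LUE regime analysis.

Given SI-unit observation panels, this module evaluates the
light-use-efficiency number (LUE = nee/par) and the six environmental
driver numbers on every record, identifies the dominant driver by PCA on
the log10-standardized numbers, classifies each record into the high /
transitional / low LUE regime of the process diagram (thresholds
LUE = 0.002 and BGC = 0.13), compares regimes with one-way ANOVA, builds
site-level seasonal summaries, fits the air-temperature-versus-soil-
temperature regression behind the 25.6 °C air threshold, and bins the flux
response against individual drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .dimensions import CP_WET_SOIL, VARIABLES, panel_to_si
from .pi_engine import canonical_drivers

__all__ = [
    "LUE_MIN",
    "BGC_SPLIT",
    "DRIVER_COLUMNS",
    "evaluate_pis",
    "PCADriverResult",
    "pca_driver_selection",
    "classify",
    "classify_panel",
    "AnovaResult",
    "anova_pairwise",
    "site_summary",
    "ATSTResult",
    "at_st_threshold",
    "bin_response",
    "plot_process_diagram",
]

logger = logging.getLogger(__name__)

#: Regime thresholds of the process diagram.
LUE_MIN = 0.002
BGC_SPLIT = 0.13

#: The six environmental driver numbers, in reporting order.
DRIVER_COLUMNS = ["pi2", "pi3", "pi4", "bgc", "pi6", "pi7"]

#: Fixed bin widths for the response-binning plots: 1 °C, 2 ppt, 100 µmol/m²/s.
BIN_WIDTHS = {"st": 1.0, "ss": 2.0, "par": 100.0}


def evaluate_pis(si_panels: pd.DataFrame, cp: float = CP_WET_SOIL) -> pd.DataFrame:
    """Evaluate LUE and the six driver numbers on each SI-unit record.

    Records with nonpositive nee, par, or pa are excluded (the numbers must
    be positive and log-transformable); exclusions are logged.
    """
    groups = canonical_drivers(VARIABLES)
    df = si_panels
    ok = (df["par"] > 0) & (df["pa"] > 0) & (df["nee"] > 0)
    if (~ok).any():
        logger.warning("excluding %d record(s) with nonpositive nee/par/pa",
                       int((~ok).sum()))
        df = df[ok]
    data = {name: df[name].to_numpy() for name in ("nee", "par", "st", "ss", "pa")}
    out = df[[c for c in ("site", "timestamp") if c in df.columns]].copy()
    out["lue"] = groups["lue"].evaluate(data, constants={"cp": cp})
    for name in DRIVER_COLUMNS:
        out[name] = groups[name].evaluate(data, constants={"cp": cp})
    return out.reset_index(drop=True)


@dataclass
class PCADriverResult:
    """Joint PCA of the response and driver numbers in log10-z space."""

    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame          # columns PC1, PC2 (unit eigenvectors)
    angles_deg: pd.Series           # planar angle driver vs response, [0, 180]
    selected_driver: str

    @property
    def pc12_variance(self) -> float:
        return float(self.explained_variance_ratio[:2].sum())


def pca_driver_selection(pipanel: pd.DataFrame, response: str = "lue",
                         drivers: Optional[Sequence[str]] = None) -> PCADriverResult:
    """Select the dominant environmental driver number via PCA.

    All numbers are log10-transformed and z-standardized (sample sd, n−1),
    then a joint PCA is run on the response plus drivers.  The loading of
    each variable is its coordinate pair on (PC1, PC2); the selected driver
    is the one whose loading is most nearly collinear (0° or 180°) with the
    response loading.  Zero-variance columns are dropped with a warning.
    """
    drivers = list(drivers) if drivers is not None else list(DRIVER_COLUMNS)
    cols = [response] + drivers
    X = pipanel[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 records")
    if np.any(X <= 0):
        raise ValueError("all pi values must be positive for the log transform")
    logX = np.log10(X)
    sd = logX.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep[0]:
        raise ValueError(f"response column {response!r} has zero variance")
    if not keep.all():
        import warnings
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping zero-variance column(s): {dropped}", stacklevel=2)
    cols = [c for c, k in zip(cols, keep) if k]
    Z = (logX[:, keep] - logX[:, keep].mean(axis=0)) / sd[keep]

    pca = PCA(n_components=min(len(cols), Z.shape[0]))
    pca.fit(Z)
    comps = pca.components_[:2].copy()          # shape (2, n_vars)
    # Resolve the sign indeterminacy: response loading's PC1 coordinate >= 0.
    if comps[0, 0] < 0:
        comps[0] *= -1
    if comps.shape[0] > 1 and comps[1, 0] < 0:
        comps[1] *= -1
    loadings = pd.DataFrame(comps.T, index=cols, columns=["PC1", "PC2"])

    resp_vec = loadings.loc[response].to_numpy()
    angles = {}
    for name in cols[1:]:
        v = loadings.loc[name].to_numpy()
        denom = np.linalg.norm(resp_vec) * np.linalg.norm(v)
        cosang = np.clip(v @ resp_vec / denom, -1.0, 1.0) if denom > 0 else 0.0
        angles[name] = float(np.degrees(np.arccos(cosang)))
    angles = pd.Series(angles, name="angle_deg")
    # Collinearity score: distance from the nearer of 0° / 180°.
    selected = (angles.map(lambda a: min(a, 180.0 - a))).idxmin()
    return PCADriverResult(
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        angles_deg=angles,
        selected_driver=selected,
    )


def classify(lue, bgc, lue_min: float = LUE_MIN, bgc_split: float = BGC_SPLIT):
    """Regime of the process diagram for (LUE, BGC) values.

    low if LUE < lue_min; high if LUE >= lue_min and BGC <= bgc_split;
    transitional otherwise.  Boundary ties go to high, per the regime
    definitions (BGC <= 0.13 and LUE >= 0.002 is the high regime).
    """
    lue = np.asarray(lue, dtype=float)
    bgc = np.asarray(bgc, dtype=float)
    out = np.where(lue < lue_min, "low",
                   np.where(bgc <= bgc_split, "high", "transitional"))
    return out if out.shape else out.item()


def classify_panel(pipanel: pd.DataFrame, lue_min: float = LUE_MIN,
                   bgc_split: float = BGC_SPLIT) -> pd.DataFrame:
    out = pipanel.copy()
    out["regime"] = classify(out["lue"], out["bgc"], lue_min, bgc_split)
    return out


@dataclass(frozen=True)
class AnovaResult:
    pair: tuple
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def anova_pairwise(values, labels) -> list:
    """One-way ANOVA F for each pair of regimes on the given values.

    Computed from sums of squares directly: F = MSB/MSW with
    df = (1, n1 + n2 − 2); p from the F distribution.  Pairs with an empty
    group are skipped with a warning.
    """
    import warnings

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = ["high", "transitional", "low"]
    present = [r for r in order if (labels == r).any()]
    extra = [r for r in np.unique(labels) if r not in order]
    present += sorted(extra)
    results = []
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1:]]
    for r in order:
        if r not in present:
            warnings.warn(f"regime {r!r} is empty; its pairs are skipped",
                          stacklevel=2)
    for a, b in pairs:
        ga = values[labels == a]
        gb = values[labels == b]
        if ga.size < 2 or gb.size < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: group with < 2 records",
                          stacklevel=2)
            continue
        grand = np.concatenate([ga, gb]).mean()
        ssb = ga.size * (ga.mean() - grand) ** 2 + gb.size * (gb.mean() - grand) ** 2
        ssw = ((ga - ga.mean()) ** 2).sum() + ((gb - gb.mean()) ** 2).sum()
        df_b = 1
        df_w = ga.size + gb.size - 2
        if ssw == 0:
            f = np.inf if ssb > 0 else 0.0
        else:
            f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
        results.append(AnovaResult(pair=(a, b), f_stat=float(f),
                                   df_between=df_b, df_within=df_w, p_value=p))
    return results


def site_summary(panels: pd.DataFrame, cp: float = CP_WET_SOIL,
                 lue_min: float = LUE_MIN, bgc_split: float = BGC_SPLIT
                 ) -> pd.DataFrame:
    """Seasonal site summaries: mean drivers, LUE, BGC, operating regime.

    Input panels are in original units.  LUE and BGC are the ratio-of-means
    construction: computed from the seasonal mean inputs after SI
    conversion, not the mean of per-record ratios.
    """
    means = panels.groupby("site", sort=False)[["nee", "par", "st", "ss", "pa"]].mean()
    si = panel_to_si(means.reset_index())
    lue = si["nee"] / si["par"]
    bgc = si["st"] * cp * si["ss"] / si["pa"]
    out = means.copy()
    out["lue"] = lue.to_numpy()
    out["bgc"] = bgc.to_numpy()
    out["regime"] = classify(out["lue"], out["bgc"], lue_min, bgc_split)
    return out


@dataclass(frozen=True)
class ATSTResult:
    slope: float
    intercept: float
    r2: float
    st_eval: float
    at_at_threshold: float


def at_st_threshold(panels: Optional[pd.DataFrame] = None, st_eval: float = 17.0,
                    coef: Optional[tuple] = None) -> ATSTResult:
    """OLS regression AT ~ ST and its value at the soil-temperature threshold.

    With ``coef=(intercept, slope)`` a supplied model is evaluated instead
    of (or in addition to) fitting; the soil-temperature threshold of 17 °C
    maps to an air temperature near 25.6 °C under the study's regression.
    """
    if coef is not None:
        intercept, slope = coef
        r2 = np.nan
        if panels is not None and "at" in panels.columns:
            resid = panels["at"] - (intercept + slope * panels["st"])
            tot = panels["at"] - panels["at"].mean()
            r2 = 1 - float((resid ** 2).sum() / (tot ** 2).sum())
    else:
        if panels is None or "at" not in panels.columns or panels["at"].isna().all():
            raise ValueError(
                "panels must carry an 'at' column (air temperature, °C); "
                "see the panel CSV schema (at_c)")
        sub = panels.dropna(subset=["at", "st"])
        if len(sub) < 3:
            raise ValueError("need at least 3 records with AT and ST")
        res = stats.linregress(sub["st"], sub["at"])
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue ** 2
    return ATSTResult(slope=float(slope), intercept=float(intercept),
                      r2=float(r2), st_eval=float(st_eval),
                      at_at_threshold=float(intercept + slope * st_eval))


def bin_response(panels: pd.DataFrame, driver: str,
                 widths: Mapping[str, float] = BIN_WIDTHS) -> pd.DataFrame:
    """Mean flux response in fixed-width driver bins, pooling all sites.

    Bins are left-closed right-open and aligned at zero (1 °C for st, 2 ppt
    for ss, 100 µmol/m²/s for par); empty bins are omitted.
    """
    if driver not in widths:
        raise ValueError(f"driver must be one of {sorted(widths)}, got {driver!r}")
    w = widths[driver]
    left = np.floor(panels[driver] / w) * w
    grouped = panels.assign(_bin=left).groupby("_bin")
    out = grouped.agg(driver_mean=(driver, "mean"), nee_mean=("nee", "mean"),
                      n=("nee", "size"))
    out.index.name = "bin_left"
    out = out.reset_index()
    out.insert(1, "bin_right", out["bin_left"] + w)
    return out


def plot_process_diagram(pipanel: pd.DataFrame, path=None,
                         lue_min: float = LUE_MIN, bgc_split: float = BGC_SPLIT):
    """Semi-log process diagram: LUE (log y) against BGC with regime zones."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    has_site = "site" in pipanel.columns
    if has_site:
        for site, sub in pipanel.groupby("site"):
            ax.scatter(sub["bgc"], sub["lue"], s=18, alpha=0.8, label=str(site))
        ax.legend(fontsize=7)
    else:
        ax.scatter(pipanel["bgc"], pipanel["lue"], s=18, alpha=0.8)
    ax.set_yscale("log")
    xlim = ax.get_xlim()
    ylim = ax.get_ylim()
    ax.axhline(lue_min, color="k", lw=0.8, ls="--")
    ax.axvline(bgc_split, color="k", lw=0.8, ls="--")
    ax.fill_between([xlim[0], bgc_split], lue_min, ylim[1],
                    color="tab:green", alpha=0.10)
    ax.fill_between([bgc_split, xlim[1]], lue_min, ylim[1],
                    color="tab:orange", alpha=0.10)
    ax.fill_between(xlim, ylim[0], lue_min, color="tab:red", alpha=0.10)
    ax.set_xlim(xlim)
    ax.set_ylim(ylim)
    ax.set_xlabel("BGC number (st·cp·ss / pa, dimensionless)")
    ax.set_ylabel("LUE number (nee / par, dimensionless)")
    ax.set_title("LUE regimes: high (left), transitional (right), low (bottom)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
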