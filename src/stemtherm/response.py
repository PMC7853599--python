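"""Plot-level SER-temperature regression and the critical temperature scan.

Each plot's stem elongation rate is regressed on the interval mean
temperature, SER = a*T + b + e, giving a temperature-responsive slope ``a``
and an intercept. The intercept evaluated at a temperature T is the
predicted SER at T; across plots, the Pearson correlation between slope and
intercept-at-T is strongly negative at 0 deg C and strongly positive near
20 deg C, and passes through zero at the critical temperature T_crit. The
intercept at T_crit ("vigour") is the temperature-irresponsive growth
component, statistically independent of the slope by construction.

T_crit is located empirically on a 0.01 deg C grid between 1 and 22 deg C,
mirroring how it is determined from field data; the analytic zero
-cov(slope, intercept0)/var(slope) exists here as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlotResponseFit",
    "TcritScan",
    "fit_plot_response",
    "intercept_at",
    "fit_plot_responses",
    "select_growth_intervals",
    "scan_tcrit",
    "closed_form_tcrit",
    "genotype_response_summary",
]


@dataclass
class PlotResponseFit:
    """OLS fit of SER ~ T for one plot."""

    plot_id: str
    year: int
    slope: float          # mm / degC / day
    intercept0: float     # mm / day, intercept at 0 deg C
    r_squared: float
    n_intervals: int
    residual_sd: float    # mm / day
    intercept_tcrit: float = float("nan")  # set by scan_tcrit
    genotype: str | None = None


def fit_plot_response(
    ser: np.ndarray, tmean: np.ndarray, plot_id: str = "", year: int = 0
) -> PlotResponseFit:
    """Ordinary least squares of SER on interval mean temperature.

    Closed-form slope/intercept; requires >= 3 intervals and non-degenerate
    temperature variance.
    """
    ser = np.asarray(ser, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    n = len(ser)
    if n < 3:
        raise ValueError("need at least 3 intervals for the SER~T regression")
    tbar = tmean.mean()
    sxx = float(((tmean - tbar) ** 2).sum())
    if sxx <= 0:
        raise ValueError("temperature not identifiable: zero temperature variance")
    ybar = ser.mean()
    sxy = float(((tmean - tbar) * (ser - ybar)).sum())
    slope = sxy / sxx
    intercept0 = ybar - slope * tbar
    resid = ser - (intercept0 + slope * tmean)
    rss = float((resid**2).sum())
    tss = float(((ser - ybar) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    residual_sd = np.sqrt(rss / (n - 2)) if n > 2 else float("nan")
    return PlotResponseFit(
        plot_id=plot_id,
        year=year,
        slope=slope,
        intercept0=intercept0,
        r_squared=r2,
        n_intervals=n,
        residual_sd=residual_sd,
    )


def intercept_at(fit: PlotResponseFit, temperature: float) -> float:
    """Predicted SER at ``temperature``: intercept0 + slope * T."""
    return fit.intercept0 + fit.slope * temperature


def select_growth_intervals(records: pd.DataFrame, ser_floor: float = 2.0) -> pd.DataFrame:
    """Keep interior growth intervals of one plot's interval records.

    An interval enters the regression when it and both neighbours show SER
    above ``ser_floor`` (mm/day): boundary intervals straddling the start of
    stem elongation or the final plateau mix growing and non-growing days
    and are not linear in temperature, and plateau intervals carry pure
    measurement noise whose SER hovers around zero. The default floor of
    2 mm/day sits several noise standard deviations above the plateau but
    well below any active growth rate. Records must be consecutive and
    sorted.
    """
    ser = records["ser"].to_numpy(dtype=float)
    ok = ser > ser_floor
    keep = np.zeros(len(ser), dtype=bool)
    if len(ser) >= 3:
        keep[1:-1] = ok[1:-1] & ok[:-2] & ok[2:]
    return records.loc[keep]


def fit_plot_responses(
    intervals: pd.DataFrame,
    interior_only: bool = True,
    ser_floor: float = 2.0,
    min_intervals: int = 3,
) -> tuple[list[PlotResponseFit], pd.DataFrame]:
    """Fit SER ~ T for every plot in a long interval table.

    Returns the list of successful fits plus a skip report (plot_id, year,
    reason) for plots failing the preconditions. No imputation: failed plots
    are simply excluded downstream.
    """
    fits: list[PlotResponseFit] = []
    skipped = []
    for (plot, year), grp in intervals.groupby(["plot_id", "year"], sort=False):
        use = select_growth_intervals(grp, ser_floor=ser_floor) if interior_only else grp
        if len(use) < min_intervals:
            skipped.append((plot, year, "too few growth intervals"))
            continue
        try:
            f = fit_plot_response(
                use["ser"].to_numpy(), use["tmean_interval"].to_numpy(),
                plot_id=plot, year=year,
            )
        except ValueError as exc:
            skipped.append((plot, year, str(exc)))
            continue
        if "genotype" in grp.columns:
            f.genotype = grp["genotype"].iloc[0]
        fits.append(f)
    report = pd.DataFrame(skipped, columns=["plot_id", "year", "reason"])
    return fits, report


@dataclass
class TcritScan:
    """Result of the slope-intercept decorrelation scan for one year."""

    year: int
    grid: np.ndarray          # temperatures scanned
    correlations: np.ndarray  # Pearson r(slope, intercept at grid T)
    t_crit: float
    min_abs_r: float
    out_of_range: bool        # zero lies at/beyond a grid edge
    flags: list[str] = field(default_factory=list)


def _scan_correlations(slope: np.ndarray, intercept0: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """r(slope, intercept0 + slope*T) for every grid T, vectorized.

    The numerator is cov(s, b0) + T var(s), linear in T; the denominator is
    sd(s) * sd(b0 + T s).
    """
    s = slope - slope.mean()
    b = intercept0 - intercept0.mean()
    n = len(s)
    var_s = float((s**2).sum()) / n
    var_b = float((b**2).sum()) / n
    cov_sb = float((s * b).sum()) / n
    num = cov_sb + grid * var_s
    den = np.sqrt(var_s) * np.sqrt(var_b + 2.0 * grid * cov_sb + grid**2 * var_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def scan_tcrit(
    fits: list[PlotResponseFit],
    year: int | None = None,
    grid_start: float = 1.0,
    grid_stop: float = 22.0,
    grid_step: float = 0.01,
) -> TcritScan:
    """Locate T_crit as the grid temperature minimizing |r(slope, intercept)|.

    Ties break toward the lower temperature; a minimum at a grid edge is
    flagged out-of-range. Sets ``intercept_tcrit`` on every fit.
    """
    if year is not None:
        fits = [f for f in fits if f.year == year]
    slope = np.array([f.slope for f in fits], dtype=float)
    intercept0 = np.array([f.intercept0 for f in fits], dtype=float)
    finite = np.isfinite(slope) & np.isfinite(intercept0)
    slope, intercept0 = slope[finite], intercept0[finite]
    if len(slope) < 3:
        raise ValueError("need at least 3 finite plot fits for the T_crit scan")
    if np.var(slope) <= 0:
        raise ValueError("correlation undefined: all slopes identical")
    n_steps = int(round((grid_stop - grid_start) / grid_step))
    grid = grid_start + grid_step * np.arange(n_steps + 1)
    corr = _scan_correlations(slope, intercept0, grid)
    k = int(np.nanargmin(np.abs(corr)))  # argmin takes the first (lowest T) tie
    t_crit = float(grid[k])
    out_of_range = k == 0 or k == len(grid) - 1
    scan = TcritScan(
        year=year if year is not None else (fits[0].year if fits else 0),
        grid=grid,
        correlations=corr,
        t_crit=t_crit,
        min_abs_r=float(abs(corr[k])),
        out_of_range=out_of_range,
        flags=["tcrit_out_of_range"] if out_of_range else [],
    )
    for f in fits:
        f.intercept_tcrit = intercept_at(f, t_crit)
    return scan


def closed_form_tcrit(fits: list[PlotResponseFit]) -> float:
    """Analytic zero of the slope-intercept correlation: -cov(s, b0)/var(s).

    Oracle for the grid scan: the correlation numerator cov(s, b0) + T var(s)
    vanishes exactly here.
    """
    slope = np.array([f.slope for f in fits], dtype=float)
    intercept0 = np.array([f.intercept0 for f in fits], dtype=float)
    var_s = slope.var()
    if var_s <= 0:
        raise ValueError("degenerate slope variance")
    cov = ((slope - slope.mean()) * (intercept0 - intercept0.mean())).mean()
    return float(-cov / var_s)


def fits_frame(fits: list[PlotResponseFit]) -> pd.DataFrame:
    """Tabular view of plot fits (for response_fits.csv)."""
    return pd.DataFrame(
        {
            "plot_id": [f.plot_id for f in fits],
            "year": [f.year for f in fits],
            "genotype": [f.genotype for f in fits],
            "slope": [f.slope for f in fits],
            "intercept0": [f.intercept0 for f in fits],
            "intercept_tcrit": [f.intercept_tcrit for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "n_intervals": [f.n_intervals for f in fits],
            "residual_sd": [f.residual_sd for f in fits],
        }
    )


def genotype_response_summary(fits: list[PlotResponseFit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype, per-year slope and vigour (mean over replicate plots).

    Replication within genotypes levels out weak single-plot fits. Returns
    (summary, skip_report); genotypes with zero fitted plots in a year are
    listed in the skip report.
    """
    frame = fits_frame(fits)
    if frame["genotype"].isna().any():
        raise ValueError("fits must carry genotype labels for the summary")
    summary = (
        frame.groupby(["genotype", "year"], as_index=False)
        .agg(
            slope=("slope", "mean"),
            vigour=("intercept_tcrit", "mean"),
            n_plots=("plot_id", "size"),
        )
    )
    all_geno = frame["genotype"].unique()
    years = frame["year"].unique()
    full = pd.MultiIndex.from_product([all_geno, years], names=["genotype", "year"])
    present = pd.MultiIndex.from_frame(summary[["genotype", "year"]])
    missing = full.difference(present)
    skip = pd.DataFrame(list(missing), columns=["genotype", "year"])
    return summary, skip
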