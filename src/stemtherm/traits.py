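"""Growth-rate and phenology traits from canopy-height time series.

Per plot this module derives:

* stem elongation rates (SER) — average daily height increase between
  consecutive observations, mm/day;
* interval mean temperatures — the covariate of the SER-temperature
  regression;
* thermal time (growing degree-days, GDD) after sowing;
* final height (FH) as the post-elongation plateau;
* GDD_15 and GDD_95 — thermal time at the first upward crossing of 15% and
  95% of FH in the daily-interpolated normalized height curve, proxies for
  the start and end of stem elongation (SE);
* SE duration in thermal time (GDD_SE = GDD_95 - GDD_15) and calendar days
  (time_SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TemperatureSeries

__all__ = [
    "compute_ser",
    "interval_temperature",
    "accumulate_gdd",
    "detect_final_height",
    "extract_phase_timings",
    "derive_durations",
    "extract_plot_traits",
    "extract_traits_table",
    "build_interval_table",
]


def compute_ser(series: pd.DataFrame, plot_id: str | None = None) -> pd.DataFrame:
    """Interval growth records for one plot: SER = dCH/dt in mm/day.

    ``series`` needs columns date and height_m sorted by date (n >= 2 rows);
    heights are meters internally, SER is reported in mm/day. Returns one
    record per consecutive observation pair with columns interval_start,
    interval_end, delta_t (days), ser.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 observations to compute SER")
    dates = pd.DatetimeIndex(series["date"])
    if dates.duplicated().any():
        label = plot_id if plot_id is not None else "<series>"
        raise ValueError(f"duplicate observation dates in plot {label}")
    order = np.argsort(dates.values)
    dates = dates[order]
    h = series["height_m"].to_numpy(dtype=float)[order]
    dt = np.diff(dates.values).astype("timedelta64[D]").astype(float)
    ser = np.diff(h) * 1000.0 / dt
    return pd.DataFrame(
        {
            "interval_start": dates[:-1],
            "interval_end": dates[1:],
            "delta_t": dt,
            "ser": ser,
        }
    )


def interval_temperature(
    records: pd.DataFrame, temperature: TemperatureSeries
) -> np.ndarray:
    """Mean daily temperature over each half-open interval (start, end].

    Each day's mean contributes to exactly one interval — the one whose
    growth it drove. Raises if any interval day is missing from the series.
    """
    temp = pd.Series(temperature.tmean, index=temperature.dates)
    out = np.empty(len(records))
    for i, (s, e) in enumerate(zip(records["interval_start"], records["interval_end"])):
        days = pd.date_range(pd.Timestamp(s) + pd.Timedelta(days=1), e, freq="D")
        vals = temp.reindex(days)
        if vals.isna().any():
            gaps = list(days[vals.isna()].strftime("%Y-%m-%d"))
            raise ValueError(f"temperature series missing days: {gaps}")
        out[i] = vals.mean()
    return out


def accumulate_gdd(temperature: TemperatureSeries, base: float = 0.0) -> pd.Series:
    """Thermal-time map: cumulative max(tmean - base, 0) from sowing.

    Returned as a Series indexed by date; zero on the sowing day, each later
    day adding its clamped contribution. Base temperature 0 deg C is the
    wheat convention.
    """
    dates = temperature.dates
    if temperature.sowing_date not in dates:
        raise ValueError("sowing date not covered by temperature series")
    contrib = np.maximum(temperature.tmean - base, 0.0)
    start = dates.get_loc(temperature.sowing_date)
    contrib = contrib[start:].copy()
    contrib[0] = 0.0
    return pd.Series(np.cumsum(contrib), index=dates[start:], name="gdd")


@dataclass
class PlateauResult:
    fh_m: float
    plateau_date: pd.Timestamp
    flagged: bool  # True when no plateau was found (FH = max height)


def detect_final_height(
    series: pd.DataFrame, k_flat: int = 3, tol_mm: float = 5.0
) -> PlateauResult:
    """Final height as the terminal plateau of the observed series.

    The plateau starts at the first observation after which no increase
    reaches ``tol_mm`` any more; it must span at least ``k_flat``
    consecutive sub-tolerance increases to count (several consecutive
    measurements without height increase). FH is the maximum height at or
    before the plateau start, which keeps late measurement noise out of the
    estimate. A series may also be flat before growth starts, so the search
    anchors on the last real increase rather than the first flat run.
    Without a terminal plateau, FH falls back to the overall maximum and the
    result is flagged.
    """
    if len(series) < k_flat + 1:
        raise ValueError(f"need at least k_flat+1={k_flat + 1} observations")
    s = series.sort_values("date")
    h = s["height_m"].to_numpy(dtype=float) * 1000.0  # mm
    dates = pd.DatetimeIndex(s["date"])
    inc = np.diff(h)
    growing = np.nonzero(inc >= tol_mm)[0]
    start = int(growing[-1]) + 1 if len(growing) else 0
    n_flat = len(inc) - start
    if n_flat >= k_flat:
        # include the confirming flat run in the maximum: the first capped
        # observation right after the plateau start carries the final height
        return PlateauResult(
            fh_m=float(h[: start + k_flat + 1].max() / 1000.0),
            plateau_date=dates[start],
            flagged=False,
        )
    return PlateauResult(
        fh_m=float(h.max() / 1000.0), plateau_date=dates[-1], flagged=True
    )


def _daily_normalized(series: pd.DataFrame, fh_m: float) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Normalized height (% of FH) linearly interpolated to daily values."""
    s = series.sort_values("date")
    dates = pd.DatetimeIndex(s["date"])
    norm = 100.0 * s["height_m"].to_numpy(dtype=float) / fh_m
    daily = pd.date_range(dates[0], dates[-1], freq="D")
    x = (dates - dates[0]).days.to_numpy(dtype=float)
    xi = (daily - dates[0]).days.to_numpy(dtype=float)
    return daily, np.interp(xi, x, norm)


def _first_upward_crossing(
    days: pd.DatetimeIndex, values: np.ndarray, threshold: float, gdd: pd.Series
) -> float:
    """Thermal time at the first upward crossing of ``threshold`` percent.

    Crossing day d satisfies values[d-1] <= threshold < values[d]; the GDD is
    interpolated linearly within that day. Later noise-induced re-crossings
    are ignored.
    """
    g = gdd.reindex(days)
    if g.isna().any():
        raise ValueError("thermal-time map does not cover the observation dates")
    gv = g.to_numpy(dtype=float)
    above = values > threshold
    if above[0]:
        return float("nan")  # already past the threshold at first observation
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if len(idx) == 0:
        return float("nan")
    j = idx[0] + 1
    lo, hi = values[j - 1], values[j]
    w = 0.0 if hi == lo else (threshold - lo) / (hi - lo)
    return float(gv[j - 1] + w * (gv[j] - gv[j - 1]))


def extract_phase_timings(
    series: pd.DataFrame, fh_m: float, thermal_time: pd.Series
) -> tuple[float, float]:
    """GDD_15 and GDD_95: thermal time at the 15% / 95% FH crossings.

    Normalized height is interpolated to daily values on calendar days and
    the crossings mapped onto the thermal-time map. Raises ``ValueError``
    ("phase incomplete") when the series never reaches 95% of FH.
    """
    if fh_m <= 0:
        raise ValueError("fh must be positive")
    days, norm = _daily_normalized(series, fh_m)
    gdd15 = _first_upward_crossing(days, norm, 15.0, thermal_time)
    gdd95 = _first_upward_crossing(days, norm, 95.0, thermal_time)
    if np.isnan(gdd95) and not (norm > 95.0).any():
        raise ValueError("phase incomplete: series never reaches 95% of FH")
    return gdd15, gdd95


def derive_durations(
    gdd15: float, gdd95: float, thermal_time: pd.Series
) -> tuple[float, float]:
    """SE duration in thermal time and calendar days.

    GDD_SE is exactly GDD_95 - GDD_15; time_SE is the difference between the
    (fractional) days at which cumulative GDD reaches the two crossing
    values, by linear inverse interpolation of the thermal-time map.
    """
    if not gdd15 < gdd95:
        raise ValueError("gdd15 must be smaller than gdd95")
    gdd_se = gdd95 - gdd15
    gv = thermal_time.to_numpy(dtype=float)
    days = (thermal_time.index - thermal_time.index[0]).days.to_numpy(dtype=float)
    if gdd15 < gv[0] or gdd95 > gv[-1]:
        raise ValueError("crossing GDD outside the thermal-time map")
    d15, d95 = np.interp([gdd15, gdd95], gv, days)
    return float(gdd_se), float(d95 - d15)


def extract_plot_traits(
    series: pd.DataFrame,
    thermal_time: pd.Series,
    k_flat: int = 3,
    tol_mm: float = 5.0,
) -> dict:
    """All phenology traits for one plot; flags instead of hard failures.

    Returns a dict with fh_m, gdd15, gdd95, gdd_se, time_se and flags
    (no_plateau, phase_incomplete, start_missed). Incomplete phases yield
    NaN durations.
    """
    plateau = detect_final_height(series, k_flat=k_flat, tol_mm=tol_mm)
    flags = []
    if plateau.flagged:
        flags.append("no_plateau")
    gdd15 = gdd95 = gdd_se = time_se = float("nan")
    try:
        gdd15, gdd95 = extract_phase_timings(series, plateau.fh_m, thermal_time)
    except ValueError:
        flags.append("phase_incomplete")
    if np.isnan(gdd15) and "phase_incomplete" not in flags:
        flags.append("start_missed")
    if np.isfinite(gdd15) and np.isfinite(gdd95) and gdd15 < gdd95:
        gdd_se, time_se = derive_durations(gdd15, gdd95, thermal_time)
    return {
        "fh_m": plateau.fh_m,
        "gdd15": gdd15,
        "gdd95": gdd95,
        "gdd_se": gdd_se,
        "time_se": time_se,
        "flags": ";".join(flags),
    }


def extract_traits_table(
    heights: pd.DataFrame,
    thermal_times: dict[int, pd.Series],
    k_flat: int = 3,
    tol_mm: float = 5.0,
) -> pd.DataFrame:
    """Per-plot trait table for a long heights frame (plot_id, year, date, height_m)."""
    rows = []
    for (plot, year), grp in heights.groupby(["plot_id", "year"], sort=False):
        rec = extract_plot_traits(
            grp, thermal_times[year], k_flat=k_flat, tol_mm=tol_mm
        )
        rec["plot_id"] = plot
        rec["year"] = year
        if "genotype" in grp.columns:
            rec["genotype"] = grp["genotype"].iloc[0]
        rows.append(rec)
    cols = ["plot_id", "year"] + (["genotype"] if rows and "genotype" in rows[0] else [])
    cols += ["fh_m", "gdd15", "gdd95", "gdd_se", "time_se", "flags"]
    return pd.DataFrame(rows)[cols]


def build_interval_table(
    heights: pd.DataFrame, temperatures: dict[int, TemperatureSeries]
) -> pd.DataFrame:
    """SER + interval-temperature records for every plot of a long frame.

    One row per consecutive observation pair: plot_id, year, interval_start,
    interval_end, delta_t, ser, tmean_interval. Uses a per-year daily lookup
    to average temperature over each half-open interval.
    """
    out = []
    for year, temp in temperatures.items():
        h_year = heights[heights["year"] == year]
        if h_year.empty:
            continue
        tser = pd.Series(temp.tmean, index=temp.dates)
        cum = tser.cumsum()
        for plot, grp in h_year.groupby("plot_id", sort=False):
            rec = compute_ser(grp, plot_id=plot)
            # half-open (start, end] mean via cumulative sums (loop-free oracle
            # equivalence is covered in tests)
            s_idx = temp.dates.get_indexer(rec["interval_start"])
            e_idx = temp.dates.get_indexer(rec["interval_end"])
            if (s_idx < 0).any() or (e_idx < 0).any():
                raise ValueError(f"temperature series missing days for plot {plot}")
            csum = np.concatenate([[0.0], cum.to_numpy()])
            tmean_int = (csum[e_idx + 1] - csum[s_idx + 1]) / (e_idx - s_idx)
            rec.insert(0, "plot_id", plot)
            rec.insert(1, "year", year)
            if "genotype" in grp.columns:
                rec.insert(2, "genotype", grp["genotype"].iloc[0])
            rec["tmean_interval"] = tmean_int
            out.append(rec)
    return pd.concat(out, ignore_index=True)
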