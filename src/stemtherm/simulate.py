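"""Synthetic multi-year wheat field trials with known temperature-response truths.

The generator emulates the kind of data produced by a LIDAR-based field
phenotyping platform monitoring winter wheat canopy height during stem
elongation (SE): an augmented two-replicate grid layout, daily mean air
temperature from sowing through the season, twice-weekly plot-height
observations, and genotype-specific growth laws.

Growth law (the generative inverse of the analysis model): during a
genotype's SE thermal-time window the latent daily height increment is

    rate_d = max(vigour + slope * (T_d - T_crit), 0)   [mm / day]

where ``slope`` is the temperature responsiveness (mm per deg C per day),
``vigour`` the growth rate at the reference temperature ``T_crit`` (mm/day),
and ``T_d`` the daily mean temperature. Height integrates the rate from a
baseline of 10% of final height and plateaus at the final height, which is
derived from the integrated window growth so that the 15% and 95% crossings
of normalized height coincide with the window bounds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureConfig",
    "TemperatureSeries",
    "GenotypeConfig",
    "ScenarioConfig",
    "TrialData",
    "simulate_temperature",
    "layout_augmented_design",
    "draw_genotype_params",
    "measurement_schedule",
    "simulate_height_series",
    "inject_spatial_field",
    "simulate_trial",
    "write_trial_csvs",
]


# ---------------------------------------------------------------------------
# temperature


@dataclass(frozen=True)
class TemperatureConfig:
    """Seasonal sinusoid + AR(1) deviations for daily mean air temperature.

    Defaults mimic a Swiss lowland winter-wheat season (sowing mid October,
    SE from late April to late June with interval temperatures well below
    25 deg C).
    """

    annual_mean: float = 9.5       # deg C
    amplitude: float = 8.5         # deg C, seasonal half-range
    peak_doy: int = 200            # day-of-year of the warmest day
    ar1_rho: float = 0.75          # lag-1 autocorrelation of daily deviations
    noise_sd: float = 2.8          # stationary s.d. of the AR(1) deviations, deg C
    band: tuple[float, float] = (-5.0, 30.0)  # plausible clip band, deg C


@dataclass
class TemperatureSeries:
    """Daily mean air temperature for one season, anchored at sowing."""

    year: int
    sowing_date: pd.Timestamp
    dates: pd.DatetimeIndex
    tmean: np.ndarray

    def __post_init__(self) -> None:
        self.sowing_date = pd.Timestamp(self.sowing_date)
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise ValueError("dates and tmean must have equal length")
        if len(self.dates) >= 2:
            step = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (step == np.timedelta64(1, "D")).all():
                raise ValueError("temperature dates must be consecutive days")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.year, "date": self.dates, "tmean_c": self.tmean}
        )


def simulate_temperature(
    year: int,
    sowing_date: str | _date | pd.Timestamp,
    end_date: str | _date | pd.Timestamp,
    config: TemperatureConfig = TemperatureConfig(),
    seed: int | np.random.Generator = 0,
) -> TemperatureSeries:
    """Simulate a daily temperature series from sowing to ``end_date``.

    The series is the seasonal sinusoid plus stationary AR(1) deviations,
    clipped to the configured plausible band. Deterministic for a fixed seed.
    """
    sowing = pd.Timestamp(sowing_date)
    end = pd.Timestamp(end_date)
    if end <= sowing:
        raise ValueError("non-positive simulation window: end_date <= sowing_date")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dates = pd.date_range(sowing, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = config.annual_mean + config.amplitude * np.cos(
        2.0 * np.pi * (doy - config.peak_doy) / 365.25
    )
    n = len(dates)
    rho = config.ar1_rho
    innov_sd = config.noise_sd * np.sqrt(max(1.0 - rho**2, 0.0))
    z = rng.standard_normal(n)
    dev = np.empty(n)
    dev[0] = config.noise_sd * z[0]
    for i in range(1, n):
        dev[i] = rho * dev[i - 1] + innov_sd * z[i]
    tmean = np.clip(seasonal + dev, *config.band)
    return TemperatureSeries(year=year, sowing_date=sowing, dates=dates, tmean=tmean)


# ---------------------------------------------------------------------------
# layout


def layout_augmented_design(
    genotype_ids: list,
    grid_rows: int,
    grid_ranges: int,
    gap: int = 5,
) -> pd.DataFrame:
    """Place two replicates of every genotype on a (row, range) grid.

    Replicate 1 fills a block anchored at the top-left corner; replicate 2
    fills a transposed block anchored at the bottom-right corner so that the
    two blocks are offset diagonally with at least ``gap`` free ranges
    between them (the augmented-design geometry of multi-hundred-entry wheat
    trials: e.g. on a 41 x 47 grid, replicate 2 occupies ranges 27-47).

    Returns a frame with columns plot_id, genotype, replicate, row, range.
    Raises ``ValueError`` naming the required size if the grid is too small.
    """
    n = len(genotype_ids)
    if n == 0:
        raise ValueError("no genotypes to place")
    if len(set(genotype_ids)) != n:
        raise ValueError("genotype ids must be unique")
    c1 = (grid_ranges - gap) // 2
    if c1 < 1:
        raise ValueError(
            f"grid too small: need at least {gap + 2} ranges to fit two blocks "
            f"with a gap of {gap}, got {grid_ranges}"
        )
    r1 = -(-n // c1)  # block 1: r1 rows x c1 ranges
    c2 = grid_ranges - c1 - gap
    r2 = -(-n // c2)  # block 2 anchored bottom-right
    if r1 > grid_rows or r2 > grid_rows:
        need_rows = max(r1, r2)
        raise ValueError(
            f"grid too small: {n} genotypes need {need_rows} rows on blocks of "
            f"{c1}/{c2} ranges, grid has {grid_rows} rows x {grid_ranges} ranges"
        )
    records = []
    for k, g in enumerate(genotype_ids):
        row = 1 + k // c1
        rng_ = 1 + k % c1
        records.append((g, 1, row, rng_))
    row0 = grid_rows - r2  # bottom anchored
    col0 = c1 + gap  # ranges col0+1 .. grid_ranges
    for k, g in enumerate(genotype_ids):
        row = row0 + 1 + k // c2
        rng_ = col0 + 1 + k % c2
        records.append((g, 2, row, rng_))
    out = pd.DataFrame(records, columns=["genotype", "replicate", "row", "range"])
    if out.duplicated(["row", "range"]).any():
        raise ValueError("internal layout error: cell collision")  # pragma: no cover
    out.insert(
        0,
        "plot_id",
        [f"r{r:02d}c{c:02d}" for r, c in zip(out["row"], out["range"])],
    )
    return out


# ---------------------------------------------------------------------------
# genotype parameters


@dataclass(frozen=True)
class GenotypeConfig:
    """Distributions of the genotype-level ground-truth parameters.

    Rates are in mm per day; thermal time in deg C day. The genotypic
    standard deviations put the simulated variance components on the scale
    observed for European winter wheat; slope and vigour are drawn
    independently so that the slope-vigour correlation is ~0 by construction.
    ``gy_var_ratio`` is the variance of genotype-by-year deviations relative
    to the genotypic variance (one dial for all parameters).
    """

    n_genotypes: int = 330
    slope_mean: float = 1.2        # mm / degC / day
    slope_sd: float = 0.27
    vigour_mean: float = 12.0      # mm / day at T_crit
    vigour_sd: float = 0.84
    t_crit_true: float = 12.0      # deg C, reference temperature of the growth law
    start_gdd_mean: float = 870.0  # deg C day after sowing at SE onset
    start_gdd_sd: float = 35.0
    se_gdd_mean: float = 700.0     # window duration in thermal time
    se_gdd_sd: float = 24.0
    gy_var_ratio: float = 0.4
    # allele frequencies of the mutant class (dwarfing / photoperiod-insensitive)
    freq_rht_b1b: float = 0.07
    freq_rht_d1b: float = 0.58
    freq_ppd_d1a: float = 0.13
    # dwarfing alleles act through two channels: a multiplicative effect on
    # the elongation rate (visible to the SER regression as reduced vigour)
    # and an additive shift of the whole height trajectory (a shorter
    # vegetative canopy, invisible to growth rates); the photoperiod-
    # insensitive allele shortens the SE window in thermal time
    rht_b1_vigour_mult: float = 0.90
    rht_d1_vigour_mult: float = 0.93
    rht_b1_height_shift: float = -0.08   # m
    rht_d1_height_shift: float = -0.06   # m
    ppd_d1_end_shift: float = -40.0      # deg C day
    allele_effects: bool = True


def draw_genotype_params(
    config: GenotypeConfig, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw genotype-level base parameters and allele states.

    Returns one row per genotype: true_slope, true_vigour, true_start_gdd,
    true_end_gdd, and biallelic labels for Rht-B1, Rht-D1, Ppd-D1
    (wild-type / mutant).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = config.n_genotypes
    gid = [f"G{i + 1:03d}" for i in range(n)]
    slope = rng.normal(config.slope_mean, config.slope_sd, n)
    vigour = rng.normal(config.vigour_mean, config.vigour_sd, n)
    start = rng.normal(config.start_gdd_mean, config.start_gdd_sd, n)
    se = rng.normal(config.se_gdd_mean, config.se_gdd_sd, n)
    rht_b1 = np.where(rng.random(n) < config.freq_rht_b1b, "Rht-B1b", "Rht-B1a")
    rht_d1 = np.where(rng.random(n) < config.freq_rht_d1b, "Rht-D1b", "Rht-D1a")
    ppd_d1 = np.where(rng.random(n) < config.freq_ppd_d1a, "Ppd-D1a", "Ppd-D1b")
    shift = np.zeros(n)
    if config.allele_effects:
        vigour = vigour * np.where(rht_b1 == "Rht-B1b", config.rht_b1_vigour_mult, 1.0)
        vigour = vigour * np.where(rht_d1 == "Rht-D1b", config.rht_d1_vigour_mult, 1.0)
        se = se + np.where(ppd_d1 == "Ppd-D1a", config.ppd_d1_end_shift, 0.0)
        shift = shift + np.where(rht_b1 == "Rht-B1b", config.rht_b1_height_shift, 0.0)
        shift = shift + np.where(rht_d1 == "Rht-D1b", config.rht_d1_height_shift, 0.0)
    end = start + se
    if not (start < end).all():
        raise ValueError("drawn SE windows must satisfy start_gdd < end_gdd")
    return pd.DataFrame(
        {
            "genotype": gid,
            "true_slope": slope,
            "true_vigour": vigour,
            "true_start_gdd": start,
            "true_end_gdd": end,
            "true_height_shift": shift,
            "rht_b1": rht_b1,
            "rht_d1": rht_d1,
            "ppd_d1": ppd_d1,
        }
    )


# ---------------------------------------------------------------------------
# height series


def measurement_schedule(
    first_date: str | pd.Timestamp, span_days: int = 74
) -> pd.DatetimeIndex:
    """Twice-weekly observation dates: alternating 3/4-day gaps over a span.

    The default 74-day span yields 22 observations, within the 17-22 range
    of a full SE measurement campaign.
    """
    if span_days <= 0:
        raise ValueError("span_days must be positive")
    first = pd.Timestamp(first_date)
    offsets = []
    k = 0
    while True:
        for o in (7 * k, 7 * k + 3):
            if o <= span_days:
                offsets.append(o)
        if 7 * k > span_days:
            break
        k += 1
    return pd.DatetimeIndex([first + pd.Timedelta(days=o) for o in sorted(set(offsets))])


def _cumulative_gdd(temp: TemperatureSeries, base: float = 0.0) -> np.ndarray:
    """Thermal time after sowing, zero on the sowing day itself."""
    contrib = np.maximum(temp.tmean - base, 0.0)
    contrib[0] = 0.0  # sowing day does not accumulate
    return np.cumsum(contrib)


def simulate_height_series(
    genotypes: pd.DataFrame,
    layout: pd.DataFrame,
    temperature: TemperatureSeries,
    noise_sd: float = 3.0,
    schedule: pd.DatetimeIndex | None = None,
    seed: int | np.random.Generator = 0,
    t_crit_true: float = 12.0,
    baseline_frac: float = 0.10,
    end_frac: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate observed canopy-height series for every plot of a layout.

    ``genotypes`` carries the effective (per-year) parameters: columns
    genotype, true_slope, true_vigour, true_start_gdd, true_end_gdd.
    ``noise_sd`` is the additive measurement noise on observed heights in mm
    (the plot-level precision of LIDAR-derived height).

    Returns ``(heights, truth)`` where ``heights`` has one row per
    (plot, date) with height in meters, and ``truth`` has per-plot latent
    values: true_fh_m, true_gdd15, true_gdd95, plus the effective
    slope/vigour/window, and a flag for days clamped at zero growth.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if schedule is None:
        # default: start ~late April of the harvest year
        schedule = measurement_schedule(
            pd.Timestamp(year=temperature.year, month=4, day=16)
        )
    schedule = pd.DatetimeIndex(schedule)
    if schedule.min() < temperature.dates.min() or schedule.max() > temperature.dates.max():
        raise ValueError("measurement schedule outside temperature coverage")

    gdd = _cumulative_gdd(temperature)
    tmean = temperature.tmean
    dates = temperature.dates
    obs_idx = dates.get_indexer(schedule)
    if (obs_idx < 0).any():
        raise ValueError("schedule dates missing from temperature series")

    merged = layout.merge(genotypes, on="genotype", how="left", validate="m:1")
    if merged["true_slope"].isna().any():
        missing = merged.loc[merged["true_slope"].isna(), "genotype"].unique()
        raise ValueError(f"genotypes missing parameters: {list(missing)[:5]}")

    slope = merged["true_slope"].to_numpy()[:, None]
    vigour = merged["true_vigour"].to_numpy()[:, None]
    start = merged["true_start_gdd"].to_numpy()[:, None]
    end = merged["true_end_gdd"].to_numpy()[:, None]
    if "true_height_shift" in merged.columns:
        shift = merged["true_height_shift"].to_numpy() * 1000.0  # mm
    else:
        shift = np.zeros(len(merged))

    rate = vigour + slope * (tmean[None, :] - t_crit_true)  # mm/day, all days
    clamped = rate < 0.0
    rate = np.maximum(rate, 0.0)
    in_window = (gdd[None, :] >= start) & (gdd[None, :] <= end)
    window_growth = (rate * in_window).sum(axis=1)  # mm
    growth_span = end_frac - baseline_frac
    fh = window_growth / growth_span  # mm; h(end_gdd) = end_frac * fh
    h0 = baseline_frac * fh

    # latent trajectory: integrate from window start, cap, then apply the
    # rate-invisible additive shift (dwarf canopy structure), floored at 1 mm
    active = gdd[None, :] >= start
    cum = np.cumsum(rate * active, axis=1)
    latent = np.minimum(h0[:, None] + cum, fh[:, None]) + shift[:, None]  # mm
    latent = np.maximum(latent, 1.0)
    fh = fh + shift  # total final height including the structural shift

    # latent 15% / 95% crossing thermal times (sub-day linear interpolation)
    n_plots = latent.shape[0]
    true_gdd15 = np.empty(n_plots)
    true_gdd95 = np.empty(n_plots)
    for q, frac, out in ((0, 0.15, true_gdd15), (1, end_frac, true_gdd95)):
        target = frac * fh
        for p in range(n_plots):
            j = int(np.searchsorted(latent[p], target[p] + 1e-12))
            if j == 0:
                out[p] = gdd[0]
            elif j >= latent.shape[1]:
                out[p] = np.nan
            else:
                h_lo, h_hi = latent[p, j - 1], latent[p, j]
                w = 0.0 if h_hi == h_lo else (target[p] - h_lo) / (h_hi - h_lo)
                out[p] = gdd[j - 1] + w * (gdd[j] - gdd[j - 1])

    obs = latent[:, obs_idx]  # mm
    if noise_sd > 0:
        obs = obs + rng.normal(0.0, noise_sd, obs.shape)

    heights = pd.DataFrame(
        {
            "plot_id": np.repeat(merged["plot_id"].to_numpy(), len(schedule)),
            "genotype": np.repeat(merged["genotype"].to_numpy(), len(schedule)),
            "year": temperature.year,
            "date": np.tile(schedule.to_numpy(), n_plots),
            "height_m": obs.ravel() / 1000.0,
        }
    )
    truth = pd.DataFrame(
        {
            "plot_id": merged["plot_id"],
            "genotype": merged["genotype"],
            "year": temperature.year,
            "true_slope": slope.ravel(),
            "true_vigour": vigour.ravel(),
            "true_start_gdd": start.ravel(),
            "true_end_gdd": end.ravel(),
            "true_fh_m": fh / 1000.0,
            "true_gdd15": true_gdd15,
            "true_gdd95": true_gdd95,
            "clamped_days_in_window": (clamped & in_window).sum(axis=1),
        }
    )
    return heights, truth


# ---------------------------------------------------------------------------
# spatial nuisance


def inject_spatial_field(
    heights: pd.DataFrame,
    layout: pd.DataFrame,
    surface=None,
    row_sd: float = 0.0,
    range_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    proportional: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add a smooth spatial surface and random row/range effects to heights.

    ``surface`` is a callable ``f(row, range) -> offset`` (vectorized over
    numpy arrays); row/range effects are iid normal. By default the offset
    is additive in meters and constant over time. With ``proportional=True``
    the offset is a dimensionless fraction and each height is multiplied by
    (1 + offset), emulating fertility patches that speed up growth rather
    than shift the canopy level — the variant that also distorts elongation
    rates. Returns ``(modified heights, offsets)`` where ``offsets`` has one
    row per plot with the injected total offset — the ground truth the
    spatial correction should remove.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lay = layout[["plot_id", "row", "range"]].drop_duplicates("plot_id").copy()
    rows = np.sort(lay["row"].unique())
    cols = np.sort(lay["range"].unique())
    row_eff = dict(zip(rows, rng.normal(0.0, row_sd, len(rows)) if row_sd > 0 else np.zeros(len(rows))))
    col_eff = dict(zip(cols, rng.normal(0.0, range_sd, len(cols)) if range_sd > 0 else np.zeros(len(cols))))
    surf = (
        surface(lay["row"].to_numpy().astype(float), lay["range"].to_numpy().astype(float))
        if surface is not None
        else np.zeros(len(lay))
    )
    lay["offset_m"] = (
        np.asarray(surf, dtype=float)
        + lay["row"].map(row_eff).to_numpy()
        + lay["range"].map(col_eff).to_numpy()
    )
    out = heights.merge(lay[["plot_id", "offset_m"]], on="plot_id", how="left")
    if out["offset_m"].isna().any():
        raise ValueError("heights contain plots absent from layout")
    if proportional:
        out["height_m"] = out["height_m"] * (1.0 + out["offset_m"])
    else:
        out["height_m"] = out["height_m"] + out["offset_m"]
    return out.drop(columns="offset_m"), lay[["plot_id", "row", "range", "offset_m"]]


# ---------------------------------------------------------------------------
# full scenario


@dataclass(frozen=True)
class ScenarioConfig:
    """A multi-year trial scenario: cohort, layout, climate, noise."""

    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    temperature: TemperatureConfig = field(default_factory=TemperatureConfig)
    years: tuple[int, ...] = (2015, 2016, 2017)
    grid_rows: int = 41
    grid_ranges: int = 47
    gap: int = 5
    sowing_month: int = 10
    sowing_day: int = 15
    season_end_month: int = 7
    season_end_day: int = 31
    measure_start_month: int = 4
    measure_start_day: int = 16
    measure_span_days: int = 74
    noise_sd: float = 3.0          # mm, observation noise on plot height
    spatial_surface_scale: float = 0.0  # m, amplitude of an injected bowl (0 = off)
    spatial_row_sd: float = 0.0    # m
    spatial_range_sd: float = 0.0  # m
    seed: int = 0

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrialData:
    """Everything one simulated scenario produced."""

    config: ScenarioConfig
    genotypes: pd.DataFrame           # base truth per genotype
    layouts: dict[int, pd.DataFrame]  # per year
    temperatures: dict[int, TemperatureSeries]
    heights: pd.DataFrame             # long: plot_id, genotype, year, date, height_m
    truth_plots: pd.DataFrame         # per plot-year latent truth
    offsets: pd.DataFrame | None      # injected spatial offsets (None if off)

    def layout_frame(self) -> pd.DataFrame:
        frames = []
        for year, lay in self.layouts.items():
            f = lay.copy()
            f.insert(1, "year", year)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def temperature_frame(self) -> pd.DataFrame:
        return pd.concat([t.frame() for t in self.temperatures.values()], ignore_index=True)


def _bowl_surface(scale: float, grid_rows: int, grid_ranges: int):
    """Quadratic bowl centered on the grid, amplitude ``scale`` meters."""

    def f(r, c):
        rn = (r - (grid_rows + 1) / 2.0) / max(grid_rows / 2.0, 1.0)
        cn = (c - (grid_ranges + 1) / 2.0) / max(grid_ranges / 2.0, 1.0)
        return scale * (rn**2 + cn**2 - 2.0 / 3.0)

    return f


def simulate_trial(config: ScenarioConfig = ScenarioConfig(), seed: int | None = None) -> TrialData:
    """Simulate a full multi-year trial (the study conditions in one call).

    Genotype-by-year deviations of the growth parameters are drawn with
    variance ``gy_var_ratio`` times the genotypic variance; the within-year
    replicate layout is re-randomized per year. Deterministic for a fixed
    seed.
    """
    if seed is not None:
        config = config.replace(seed=seed)
    master = np.random.default_rng(config.seed)
    gcfg = config.genotype
    genotypes = draw_genotype_params(gcfg, master)

    ratio = np.sqrt(gcfg.gy_var_ratio)
    layouts: dict[int, pd.DataFrame] = {}
    temps: dict[int, TemperatureSeries] = {}
    all_heights = []
    all_truth = []
    for year in config.years:
        sowing = pd.Timestamp(year=year - 1, month=config.sowing_month, day=config.sowing_day)
        end = pd.Timestamp(year=year, month=config.season_end_month, day=config.season_end_day)
        temp = simulate_temperature(year, sowing, end, config.temperature, master)
        temps[year] = temp

        order = master.permutation(len(genotypes))
        layout = layout_augmented_design(
            list(genotypes["genotype"].to_numpy()[order]),
            config.grid_rows,
            config.grid_ranges,
            config.gap,
        )
        layout["plot_id"] = [f"{year}_{p}" for p in layout["plot_id"]]
        layouts[year] = layout

        eff = genotypes.copy()
        n = len(eff)
        eff["true_slope"] = eff["true_slope"] + master.normal(0, gcfg.slope_sd * ratio, n)
        eff["true_vigour"] = eff["true_vigour"] + master.normal(0, gcfg.vigour_sd * ratio, n)
        eff["true_start_gdd"] = eff["true_start_gdd"] + master.normal(0, gcfg.start_gdd_sd * ratio, n)
        eff["true_end_gdd"] = eff["true_end_gdd"] + master.normal(0, gcfg.se_gdd_sd * ratio, n)

        schedule = measurement_schedule(
            pd.Timestamp(year=year, month=config.measure_start_month, day=config.measure_start_day),
            config.measure_span_days,
        )
        heights, truth = simulate_height_series(
            eff,
            layout,
            temp,
            noise_sd=config.noise_sd,
            schedule=schedule,
            seed=master,
            t_crit_true=gcfg.t_crit_true,
        )
        all_heights.append(heights)
        all_truth.append(truth)

    heights = pd.concat(all_heights, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)

    offsets = None
    if config.spatial_surface_scale > 0 or config.spatial_row_sd > 0 or config.spatial_range_sd > 0:
        surf = (
            _bowl_surface(config.spatial_surface_scale, config.grid_rows, config.grid_ranges)
            if config.spatial_surface_scale > 0
            else None
        )
        parts = []
        off_parts = []
        for year in config.years:
            h_year = heights[heights["year"] == year]
            mod, off = inject_spatial_field(
                h_year,
                layouts[year],
                surface=surf,
                row_sd=config.spatial_row_sd,
                range_sd=config.spatial_range_sd,
                seed=master,
            )
            off.insert(1, "year", year)
            parts.append(mod)
            off_parts.append(off)
        heights = pd.concat(parts, ignore_index=True)
        offsets = pd.concat(off_parts, ignore_index=True)

    return TrialData(
        config=config,
        genotypes=genotypes,
        layouts=layouts,
        temperatures=temps,
        heights=heights,
        truth_plots=truth,
        offsets=offsets,
    )


def write_trial_csvs(trial: TrialData, outdir) -> dict[str, str]:
    """Write the tidy CSVs of a simulated trial; returns name -> path."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = os.path.join(outdir, name)
        frame.to_csv(path, index=False, date_format="%Y-%m-%d")
        paths[name] = path

    _write("plots.csv", trial.layout_frame())
    _write("heights.csv", trial.heights[["plot_id", "date", "height_m"]])
    _write("temperature.csv", trial.temperature_frame())
    _write(
        "truth.csv",
        trial.genotypes[
            ["genotype", "true_slope", "true_vigour", "true_start_gdd", "true_end_gdd"]
        ],
    )
    _write("truth_plots.csv", trial.truth_plots)
    _write(
        "alleles.csv",
        trial.genotypes[["genotype", "rht_b1", "rht_d1", "ppd_d1"]].rename(
            columns={"rht_b1": "Rht-B1", "rht_d1": "Rht-D1", "ppd_d1": "Ppd-D1"}
        ),
    )
    if trial.offsets is not None:
        _write("spatial_offsets.csv", trial.offsets)
    return paths
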