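"""Thermal-stress and climate-variability metrics from weekly SST series.

Heat stress follows the Degree Heating Week (DHW) convention of the NOAA
Coral Reef Watch heritage product: the HotSpot is the positive anomaly of
weekly SST above the maximum monthly mean climatology (MMM), and DHW is the
trailing 12-week sum of HotSpots that reach at least 1 degC, in degC-weeks.
DHW > 4 flags significant bleaching risk ("Alert Level I"), > 8 severe risk.
Historical metrics summarize a pre-event baseline (default 1985-2009):
the coefficient of variation of weekly SST, dispersion of annual thermal
maxima, and the mean intensity/duration/frequency of past DHW stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DHW_WINDOW_WEEKS = 12
HOTSPOT_THRESHOLD = 1.0  # degC above MMM for a HotSpot to accumulate


@dataclass
class SSTSeries:
    """Weekly sea-surface-temperature series for one site.

    ``week_start`` must be strictly increasing at 7-day spacing; gaps of at
    most 2 weeks are linearly interpolated on construction, larger gaps are
    rejected.  ``baseline_window`` is the (start_year, end_year) span used
    for climatology and historical metrics.
    """

    site_id: str
    week_start: pd.DatetimeIndex
    sst: np.ndarray
    baseline_window: tuple[int, int] = (1985, 2009)
    interpolated_weeks: int = field(default=0, init=False)

    def __post_init__(self):
        idx = pd.DatetimeIndex(self.week_start)
        sst = np.asarray(self.sst, dtype=float)
        if len(idx) != len(sst):
            raise ValueError("week_start and sst length mismatch")
        if len(idx) < 2:
            raise ValueError("need at least two weeks of SST")
        steps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if (steps <= 0).any():
            raise ValueError("week_start must be strictly increasing")
        if (steps % 7 != 0).any():
            raise ValueError("week_start spacing must be whole weeks")
        if (steps > 21).any():
            bad = idx[1:][steps > 21][0]
            raise ValueError(f"gap longer than 2 weeks before {bad.date()}")
        if (steps > 7).any():
            full = pd.date_range(idx[0], idx[-1], freq="7D")
            ser = pd.Series(sst, index=idx).reindex(full)
            self.interpolated_weeks = int(ser.isna().sum())
            ser = ser.interpolate(method="linear")
            idx, sst = full, ser.to_numpy()
        if np.isnan(sst).any():
            raise ValueError("SST contains missing values")
        self.week_start = idx
        self.sst = sst

    @property
    def years(self) -> np.ndarray:
        return self.week_start.year.to_numpy()

    def baseline_mask(self) -> np.ndarray:
        y0, y1 = self.baseline_window
        return (self.years >= y0) & (self.years <= y1)


def read_sst_table(path, baseline_window=(1985, 2009)) -> dict[str, SSTSeries]:
    """Read per-site weekly SST from delimited text.

    Columns: ``site_id``, ``week_start`` (ISO-8601 date), ``sst_c``; one file
    may hold many sites.  Delimiter sniffed (comma/tab).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, parse_dates=["week_start"])
    for col in ("site_id", "week_start", "sst_c"):
        if col not in df.columns:
            raise ValueError(f"SST file missing column {col!r}")
    out = {}
    for site, grp in df.groupby("site_id"):
        grp = grp.sort_values("week_start")
        out[site] = SSTSeries(
            str(site),
            pd.DatetimeIndex(grp["week_start"]),
            grp["sst_c"].to_numpy(float),
            baseline_window,
        )
    return out


def write_sst_table(series: dict[str, SSTSeries], path, sep=",") -> None:
    frames = [
        pd.DataFrame(
            {"site_id": s.site_id, "week_start": s.week_start.strftime("%Y-%m-%d"),
             "sst_c": s.sst}
        )
        for s in series.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


# --- climatology -------------------------------------------------------------

def monthly_climatology_mmm(s: SSTSeries, min_years: int = 2) -> dict:
    """Monthly-mean climatology and the maximum monthly mean (MMM).

    Weeks are assigned to the calendar month of their start date; monthly
    means are taken over all baseline weeks of that month, and MMM is the
    warmest of the twelve.
    """
    mask = s.baseline_mask()
    years = np.unique(s.years[mask])
    # complete years: all 12 months represented
    months = s.week_start.month.to_numpy()
    complete = [
        y for y in years if len(np.unique(months[mask & (s.years == y)])) == 12
    ]
    if len(complete) < min_years:
        raise ValueError(
            f"baseline window {s.baseline_window} has {len(complete)} complete "
            f"years; need >= {min_years}"
        )
    monthly = np.array(
        [s.sst[mask & (months == m)].mean() for m in range(1, 13)]
    )
    return {"monthly_means": monthly, "MMM": float(monthly.max())}


# --- DHW ---------------------------------------------------------------------

def dhw_series(
    s: SSTSeries,
    mmm: float,
    window: int = DHW_WINDOW_WEEKS,
    threshold: float = HOTSPOT_THRESHOLD,
) -> np.ndarray:
    """Weekly Degree Heating Weeks: trailing ``window``-week (inclusive) sum
    of HotSpots (SST - MMM) that reach ``threshold``; partial windows at the
    start use the available weeks."""
    if not np.isfinite(mmm):
        raise ValueError("MMM must be finite")
    hotspot = np.maximum(0.0, s.sst - mmm)
    contrib = np.where(hotspot >= threshold, hotspot, 0.0)
    return (
        pd.Series(contrib).rolling(window, min_periods=1).sum().to_numpy()
    )


@dataclass(frozen=True)
class EventStressMetrics:
    """Heat-stress summary over one bleaching-event window."""

    MaxSST_event: float
    MaxDHW_event: float
    WkDHW4: int      # weeks with DHW > 4 (strict)
    WkDHW8: int      # weeks with DHW > 8 (strict)
    weeks_alert1: int  # weeks with DHW >= 4 (Alert Level I duration)
    event_window: tuple


def event_stress_metrics(
    s: SSTSeries,
    dhw: np.ndarray,
    window: tuple,
    strict: bool = True,
) -> EventStressMetrics:
    """Event metrics over ``window`` = (start, end) dates, inclusive.

    ``WkDHW4``/``WkDHW8`` use strict inequality by default (``strict=False``
    switches to >=); Alert Level I duration always counts DHW >= 4.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    mask = (s.week_start >= start) & (s.week_start <= end)
    if not mask.any():
        raise ValueError(f"event window {window} contains no weeks")
    d, t = dhw[mask], s.sst[mask]
    gt = np.greater if strict else np.greater_equal
    return EventStressMetrics(
        MaxSST_event=float(t.max()),
        MaxDHW_event=float(d.max()),
        WkDHW4=int(gt(d, 4.0).sum()),
        WkDHW8=int(gt(d, 8.0).sum()),
        weeks_alert1=int((d >= 4.0).sum()),
        event_window=(str(start.date()), str(end.date())),
    )


# --- historical metrics ------------------------------------------------------

@dataclass(frozen=True)
class HistoricalClimateMetrics:
    CV_SST: float        # sd/mean of weekly SST over the baseline
    sigma_wk: float      # sd across years of annual max weekly SST
    sigma_mon: float     # sd across years of annual max monthly-mean SST
    MaxSST_avg: float    # mean annual max weekly SST
    MMM: float
    MaxDHW_avg: float    # mean annual max DHW
    WkDHW4_avg: float    # mean annual count of weeks DHW > 4
    WkDHW8_avg: float
    fDHW4: float         # fraction of years with annual max DHW > 4
    fDHW8: float
    n_years: int


def historical_climate_metrics(
    s: SSTSeries,
    mmm: float | None = None,
    dhw: np.ndarray | None = None,
    min_years: int = 5,
    strict: bool = True,
) -> HistoricalClimateMetrics:
    """Pre-event climate-variability metrics over the baseline window.

    Annual maxima use all weeks whose start date falls in the calendar year.
    Standard deviations are sample (n-1).
    """
    if mmm is None:
        mmm = monthly_climatology_mmm(s)["MMM"]
    if dhw is None:
        dhw = dhw_series(s, mmm)
    mask = s.baseline_mask()
    years = s.years
    months = s.week_start.month.to_numpy()
    uyears = [
        y for y in np.unique(years[mask])
        if len(np.unique(months[mask & (years == y)])) == 12
    ]
    if len(uyears) < min_years:
        raise ValueError(
            f"baseline has {len(uyears)} complete years; need >= {min_years}"
        )
    sst_b = s.sst[mask]
    ann_max_wk = np.array([s.sst[mask & (years == y)].max() for y in uyears])
    ann_max_mon = np.array(
        [
            max(
                s.sst[mask & (years == y) & (months == m)].mean()
                for m in range(1, 13)
            )
            for y in uyears
        ]
    )
    ann_max_dhw = np.array([dhw[mask & (years == y)].max() for y in uyears])
    gt = np.greater if strict else np.greater_equal
    wk4 = np.array([gt(dhw[mask & (years == y)], 4.0).sum() for y in uyears])
    wk8 = np.array([gt(dhw[mask & (years == y)], 8.0).sum() for y in uyears])
    return HistoricalClimateMetrics(
        CV_SST=float(np.std(sst_b, ddof=1) / np.mean(sst_b)),
        sigma_wk=float(np.std(ann_max_wk, ddof=1)),
        sigma_mon=float(np.std(ann_max_mon, ddof=1)),
        MaxSST_avg=float(ann_max_wk.mean()),
        MMM=float(mmm),
        MaxDHW_avg=float(ann_max_dhw.mean()),
        WkDHW4_avg=float(wk4.mean()),
        WkDHW8_avg=float(wk8.mean()),
        fDHW4=float(gt(ann_max_dhw, 4.0).mean()),
        fDHW8=float(gt(ann_max_dhw, 8.0).mean()),
        n_years=len(uyears),
    )


def site_metric_table(
    series: dict[str, SSTSeries],
    event_window: tuple,
) -> pd.DataFrame:
    """One row per site with event-stress and historical climate metrics."""
    rows = []
    for site, s in series.items():
        mmm = monthly_climatology_mmm(s)["MMM"]
        dhw = dhw_series(s, mmm)
        ev = event_stress_metrics(s, dhw, event_window)
        hist = historical_climate_metrics(s, mmm=mmm, dhw=dhw)
        row = {"site_id": site}
        row.update({k: v for k, v in ev.__dict__.items() if k != "event_window"})
        row.update(hist.__dict__)
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")
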