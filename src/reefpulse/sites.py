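"""Site context: human-disturbance population metric and the per-site predictor table.

The population metric proxies local human disturbance: the population of the
village(s) nearest a reef site divided by the along-coast distance to the
village center, summed when several villages are designated, then
standardized by the mean across all field sites (so the metric averages 1).
"""

from __future__ import annotations

import pandas as pd

ENV_COLUMNS = [
    "site_id", "atoll", "lat", "long", "depth",
    "PAR", "chl_a", "chl_a_avg", "waveh", "expos",
]

VILLAGE_COLUMNS = ["site_id", "village_id", "population", "coast_dist_km"]


def read_villages(path, sep=",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in VILLAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"village file missing columns {missing}")
    return df


def population_metric(villages: pd.DataFrame, standardize: bool = True) -> pd.Series:
    """Per-site population/distance metric from closest-village records.

    ``villages`` has one row per (site, designated village) with columns
    ``site_id, village_id, population, coast_dist_km``; contributions of
    multiple villages are summed.  Standardization divides by the mean of
    the raw metric across sites.
    """
    if (villages["coast_dist_km"] <= 0).any():
        bad = villages.loc[villages["coast_dist_km"] <= 0, "site_id"].tolist()
        raise ValueError(f"non-positive coastline distance for sites {bad}")
    if (villages["population"] < 0).any():
        raise ValueError("negative village population")
    raw = (
        (villages["population"] / villages["coast_dist_km"])
        .groupby(villages["site_id"])
        .sum()
        .rename("pop_metric")
        .sort_index()
    )
    if not standardize:
        return raw
    if len(raw) < 2:
        raise ValueError("standardization needs >= 2 sites")
    return raw / raw.mean()


def assemble_site_table(
    env: pd.DataFrame,
    thermal: pd.DataFrame | None = None,
    ra_por: pd.Series | None = None,
    pop_metric: pd.Series | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Join environment, thermal metrics, RA_POR and the population metric
    into one predictor row per site.

    Returns ``(table, join_report)``; sites present in only some sources are
    listed in the report (and raise when ``strict``).  Missing values stay
    as NaN markers, never dropped.
    """
    missing_cols = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing_cols:
        raise ValueError(f"environment table missing columns {missing_cols}")
    if env["site_id"].duplicated().any():
        dups = env.loc[env["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_id in environment table: {dups}")
    bad_expos = ~env["expos"].isin([1, 2, 3, 4])
    if bad_expos.any():
        raise ValueError(
            f"exposure class must be 1-4; bad rows {env.loc[bad_expos, 'site_id'].tolist()}"
        )

    table = env.set_index("site_id").sort_index()
    report: dict[str, list] = {}
    sources = {"thermal": thermal, "RA_POR": ra_por, "pop_metric": pop_metric}
    for name, src in sources.items():
        if src is None:
            continue
        if isinstance(src, pd.Series):
            src = src.to_frame(name)
        src = src.copy()
        if isinstance(src.index, pd.MultiIndex):
            src.index = src.index.get_level_values("site_id")
            src = src.groupby(level=0).mean(numeric_only=True)
        only_env = sorted(set(table.index) - set(src.index))
        only_src = sorted(set(src.index) - set(table.index))
        if only_env or only_src:
            report[name] = sorted(only_env + only_src)
        table = table.join(src, how="left")
    if strict and report:
        raise ValueError(f"site keys not shared by all sources: {report}")
    return table.sort_index(), report


def write_site_table(table: pd.DataFrame, path, sep=",") -> None:
    table.to_csv(path, sep=sep)
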