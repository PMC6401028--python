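"""Photo-quadrat point-count surveys: data model, I/O, cover and community matrices.

A survey is a hierarchy of point records (site -> depth band -> transect ->
image -> point).  Each point carries a benthic label; coral points further
carry a genus-level taxon and, for live/bleached/recently-dead coral, a
bleaching-severity state.  Benthic cover is the fraction of points per
category, computed on the pooled transect (25 images x 50 points = 1,250
points by default).  The community matrix holds each coral taxon's share of
live coral per site, after dropping taxa rarer than a pooled-share threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# --- controlled vocabularies -------------------------------------------------

#: Live coral; ``taxon`` identifies the genus (Porites split three ways).
CORAL_LIVE = "coral"
CORAL_BLEACHED = "coral_bleached"
CORAL_RECENT_DEAD = "coral_recently_dead"
#: Dead coral overgrown by turf algae (< ~2 cm) or crustose coralline algae.
CORAL_DEAD_TURF = "coral_dead_turf"
CORAL_DEAD_CCA = "coral_dead_cca"

#: Coral categories whose points are scored on the bleaching-severity scale.
SCOREABLE_CORAL = (CORAL_LIVE, CORAL_BLEACHED, CORAL_RECENT_DEAD)
#: Dead-coral categories that carry a taxon (where identifiable) but no
#: bleaching state: these colonies died before the scored event.
DEAD_CORAL = (CORAL_RECENT_DEAD, CORAL_DEAD_TURF, CORAL_DEAD_CCA)
CORAL_CATEGORIES = (CORAL_LIVE, CORAL_BLEACHED) + DEAD_CORAL

NON_CORAL = ("macroalgae", "turf_algae", "cca", "sand", "rubble", "other")
BENTHIC_LABELS = CORAL_CATEGORIES + NON_CORAL

#: Genus-level coral taxa.  *Porites* is split into branching, massive and
#: the encrusting *Porites rus*; the octocoral *Heliopora* is included.
CORAL_TAXA = (
    "acropora",
    "pocillopora",
    "montipora",
    "porites_branching",
    "porites_massive",
    "porites_rus",
    "heliopora",
    "favites",
    "favia",
    "lobophyllia",
    "pavona",
    "goniastrea",
    "leptastrea",
    "hydnophora",
    "fungia",
    "millepora",
    "unidentified",
)

#: Ordered bleaching-severity categories (normal -> recently dead).
BLEACH_STATES = (
    "normal",
    "pale",
    "bleached_0_20",
    "bleached_20_50",
    "bleached_50_80",
    "bleached_80_100",
    "recently_dead",
)

DEPTH_BANDS = ("shallow_3_5m", "deep_10_12m")

#: Massive *Porites* + *Porites rus*: the RA_POR numerator.
PORITES_RA_TAXA = ("porites_massive", "porites_rus")

COLUMNS = [
    "site_id",
    "atoll",
    "depth_band",
    "year",
    "transect",
    "image",
    "point",
    "label",
    "taxon",
    "bleach_state",
]


class SurveyValidationError(ValueError):
    """Raised when point-count records violate the survey schema."""


@dataclass
class SurveyDataset:
    """Validated collection of photo-quadrat point records.

    Parameters
    ----------
    records : pandas.DataFrame
        Long-format table with :data:`COLUMNS`; one row per scored point.
    points_per_image, images_per_transect : int
        Design constants; a complete transect has their product in points
        (1,250 under the defaults).
    """

    records: pd.DataFrame
    points_per_image: int = 50
    images_per_transect: int = 25
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.records = validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sites(self) -> list[str]:
        return sorted(self.records["site_id"].unique())

    def subset(self, **keys) -> "SurveyDataset":
        """Restrict to records matching the given column values."""
        mask = pd.Series(True, index=self.records.index)
        for col, val in keys.items():
            if col not in self.records.columns:
                raise KeyError(col)
            mask &= self.records[col] == val
        return SurveyDataset(
            self.records[mask].reset_index(drop=True),
            self.points_per_image,
            self.images_per_transect,
        )


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"missing required columns: {missing}")
    df = df[COLUMNS].copy()
    df["taxon"] = df["taxon"].replace({"": None, np.nan: None})
    df["bleach_state"] = df["bleach_state"].replace({"": None, np.nan: None})

    bad_label = ~df["label"].isin(BENTHIC_LABELS)
    if bad_label.any():
        rows = df.index[bad_label].tolist()[:20]
        labels = sorted(df.loc[bad_label, "label"].unique())
        raise SurveyValidationError(
            f"unknown benthic labels {labels} at rows {rows}"
        )
    bad_depth = ~df["depth_band"].isin(DEPTH_BANDS)
    if bad_depth.any():
        raise SurveyValidationError(
            f"unknown depth bands {sorted(df.loc[bad_depth, 'depth_band'].unique())}"
        )

    is_coral = df["label"].isin(CORAL_CATEGORIES)
    state_on_noncoral = df["bleach_state"].notna() & ~is_coral
    if state_on_noncoral.any():
        rows = df.index[state_on_noncoral].tolist()[:20]
        raise SurveyValidationError(
            f"bleach_state given for non-coral label at rows {rows}"
        )
    scoreable = df["label"].isin(SCOREABLE_CORAL)
    state_missing = scoreable & df["bleach_state"].isna()
    if state_missing.any():
        rows = df.index[state_missing].tolist()[:20]
        raise SurveyValidationError(
            f"bleach_state required for live/bleached/recently-dead coral; "
            f"missing at rows {rows}"
        )
    bad_state = df["bleach_state"].notna() & ~df["bleach_state"].isin(BLEACH_STATES)
    if bad_state.any():
        raise SurveyValidationError(
            f"unknown bleach states {sorted(df.loc[bad_state, 'bleach_state'].unique())}"
        )
    # recently-dead label and state must agree
    rd_label = df["label"] == CORAL_RECENT_DEAD
    rd_state = df["bleach_state"] == "recently_dead"
    clash = (rd_label & df["bleach_state"].notna() & ~rd_state) | (rd_state & ~rd_label)
    if clash.any():
        raise SurveyValidationError(
            f"recently-dead label/state mismatch at rows {df.index[clash].tolist()[:20]}"
        )

    taxon_missing = is_coral & df["taxon"].isna()
    if taxon_missing.any():
        raise SurveyValidationError(
            "coral points must carry a taxon ('unidentified' if unknown); "
            f"missing at rows {df.index[taxon_missing].tolist()[:20]}"
        )
    bad_taxon = df["taxon"].notna() & ~df["taxon"].isin(CORAL_TAXA)
    if bad_taxon.any():
        raise SurveyValidationError(
            f"unknown coral taxa {sorted(df.loc[bad_taxon, 'taxon'].unique())}"
        )

    dup = df.duplicated(
        subset=["site_id", "depth_band", "year", "transect", "image", "point"]
    )
    if dup.any():
        raise SurveyValidationError(
            f"duplicate point index within image at rows {df.index[dup].tolist()[:20]}"
        )
    df["year"] = df["year"].astype(int)
    df["image"] = df["image"].astype(int)
    df["point"] = df["point"].astype(int)
    return df.reset_index(drop=True)


# --- I/O ---------------------------------------------------------------------

def read_point_counts(
    path: str | Path,
    schema: dict[str, str] | None = None,
    sep: str | None = None,
) -> SurveyDataset:
    """Read a long-format point-count file into a validated :class:`SurveyDataset`.

    Parameters
    ----------
    path : path
        Delimited text (comma default, tab accepted) with a header row.
    schema : dict, optional
        Mapping from file column names to the canonical :data:`COLUMNS`.
    sep : str, optional
        Field delimiter; sniffed from the header line when omitted.
    """
    path = Path(path)
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SurveyValidationError(
            f"{path.name}: missing required columns {missing}"
        )
    return SurveyDataset(df)


def write_point_counts(ds: SurveyDataset, path: str | Path, sep: str = ",") -> None:
    ds.records.to_csv(path, sep=sep, index=False)


# --- cover -------------------------------------------------------------------

GROUP_KEYS = ["site_id", "depth_band", "year"]


def compute_cover(
    ds: SurveyDataset,
    grouping: str = "by_site_depth_year",
    by_transect: bool = False,
) -> pd.DataFrame:
    """Benthic cover fractions per group, pooled over the entire transect.

    Returns a DataFrame indexed by (site_id, depth_band, year) — plus
    transect when ``by_transect`` — with one column per benthic label (all
    labels reported, zero-count included) and an ``n_points`` column.  Cover
    fractions over the mutually exclusive labels sum to 1 in each row.
    """
    if grouping != "by_site_depth_year":
        raise ValueError(f"unknown grouping {grouping!r}")
    if len(ds.records) == 0:
        raise ValueError("empty dataset: no groups to compute cover for")
    keys = GROUP_KEYS + (["transect"] if by_transect else [])
    counts = (
        ds.records.groupby(keys)["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(BENTHIC_LABELS), fill_value=0)
    )
    n = counts.sum(axis=1)
    if (n == 0).any():
        empty = counts.index[n == 0].tolist()
        raise ValueError(f"empty groups: {empty}")
    cover = counts.div(n, axis=0)
    cover["n_points"] = n
    return cover


def cover_long(cover: pd.DataFrame) -> pd.DataFrame:
    """Long-format (group keys, category, cover, n_points) view of a cover table."""
    value_cols = [c for c in cover.columns if c != "n_points"]
    out = (
        cover[value_cols]
        .stack()
        .rename("cover")
        .reset_index()
        .rename(columns={f"level_{len(cover.index.names)}": "category"})
    )
    out = out.merge(
        cover["n_points"].reset_index(), on=list(cover.index.names), how="left"
    )
    return out


# --- community matrix --------------------------------------------------------

def live_coral_taxon_counts(ds: SurveyDataset, by_depth: bool = True) -> pd.DataFrame:
    """Counts of live-coral points per taxon, one row per site (x depth band)."""
    live = ds.records[ds.records["label"] == CORAL_LIVE]
    keys = ["site_id", "depth_band"] if by_depth else ["site_id"]
    counts = (
        live.groupby(keys)["taxon"]
        .value_counts()
        .unstack(fill_value=0)
    )
    return counts.reindex(columns=sorted(counts.columns))


def build_community_matrix(
    counts: pd.DataFrame, min_share: float = 0.005
) -> pd.DataFrame:
    """Relative-abundance community matrix with pooled rare-taxon filtering.

    Parameters
    ----------
    counts : DataFrame
        Sites (rows) x coral taxa (columns) point counts (from
        :func:`live_coral_taxon_counts`).
    min_share : float
        Taxa whose share of the *pooled* coral observations across all rows
        is ``<= min_share`` are dropped before rows are renormalized
        (default 0.5%, the readability filter used for ordination).

    Returns row-normalized shares (rows sum to 1); all-zero rows raise.
    The threshold is recorded in ``DataFrame.attrs['min_share']``.
    """
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("no live coral observations in any row")
    pooled_share = counts.sum(axis=0) / total
    keep = pooled_share > min_share
    if not keep.any():
        raise ValueError("rare-taxon filter removed every taxon")
    kept = counts.loc[:, keep[keep].index]
    row_sums = kept.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError(
            f"rows with no coral after filtering: {row_sums.index[row_sums == 0].tolist()}"
        )
    mat = kept.div(row_sums, axis=0)
    mat = mat[sorted(mat.columns)]
    mat.attrs["min_share"] = min_share
    return mat


# --- per-site taxon summaries ------------------------------------------------

def taxon_summaries(ds: SurveyDataset, by_depth: bool = True) -> pd.DataFrame:
    """Per-site live fractions by taxon and the *Porites* relative abundance.

    ``live_fraction(taxon)`` = live points / (live + bleached + recently dead
    + turf-dead + CCA-dead points) of that taxon; NaN (not 0) when the taxon
    has no coral points in the group.  ``RA_POR`` is the share of massive
    *Porites* plus *Porites rus* among live coral points.
    """
    coral = ds.records[ds.records["label"].isin(CORAL_CATEGORIES)]
    if coral.empty:
        raise ValueError("dataset contains no coral points")
    keys = ["site_id", "depth_band"] if by_depth else ["site_id"]

    total = coral.groupby(keys + ["taxon"]).size().unstack(fill_value=0)
    live = (
        coral[coral["label"] == CORAL_LIVE]
        .groupby(keys + ["taxon"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=total.columns, fill_value=0)
    )
    live_fraction = live / total.replace(0, np.nan)
    live_fraction.columns = [f"live_fraction_{t}" for t in live_fraction.columns]

    live_counts = (
        coral[coral["label"] == CORAL_LIVE].groupby(keys)["taxon"].value_counts().unstack(fill_value=0)
    )
    live_total = live_counts.sum(axis=1)
    por_cols = [t for t in PORITES_RA_TAXA if t in live_counts.columns]
    por = live_counts[por_cols].sum(axis=1) if por_cols else pd.Series(0, index=live_counts.index)
    ra_por = (por / live_total.replace(0, np.nan)).fillna(0.0).rename("RA_POR")

    out = live_fraction.join(ra_por, how="outer")
    out["RA_POR"] = out["RA_POR"].fillna(0.0)
    return out
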